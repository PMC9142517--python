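"""Coumarin-3-carboxylic-acid (C3CA) chemical dosimetry.

C3CA scavenges the hydroxyl radicals produced by water radiolysis and a
fixed fraction (4.7 ± 0.6%) of the scavenged radicals is converted to the
fluorescent product 7OH-C3CA, independently of radiation quality.  The
measured 7OH-C3CA concentration therefore gives the OH yield, and with
the Co-60 gamma G value (2.7 radicals per 100 eV) the Co-60-equivalent
absorbed dose.  Copper-chloride-bearing solutions scavenge part of the
radicals (chlorine, pH); that chemistry is not modelled kinetically but
absorbed into a single empirical correction factor — the ratio of the
buffer to the copper-chloride calibration slopes (≈ 2.6).

Uncertainties propagate first order (delta method) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AVOGADRO",
    "EV_PER_GRAY_PER_KG",
    "ChemistryConstants",
    "ChemSample",
    "CalibrationFit",
    "CorrectionFactor",
    "Measurement",
    "fit_linear",
    "correction_factor",
    "ohc3ca_to_oh",
    "co60_equivalent_dose",
    "oh_molarity_per_gray",
    "dose_from_concentration",
]

AVOGADRO = 6.02214076e23
EV_PER_JOULE = 1.0 / 1.602176634e-19
EV_PER_GRAY_PER_KG = EV_PER_JOULE  # 1 Gy = 1 J/kg


@dataclass(frozen=True)
class ChemistryConstants:
    """Constants of the C3CA dosimeter chemistry."""

    conversion_efficiency: float = 0.047     # OH -> 7OH-C3CA fraction
    conversion_efficiency_sd: float = 0.006
    g_oh_per_100ev: float = 2.7              # Co-60 gamma G value
    c3ca_mol_l: float = 5e-4

    def __post_init__(self):
        if not 0.0 < self.conversion_efficiency < 1.0:
            raise ValueError("conversion efficiency must be in (0, 1)")
        if self.g_oh_per_100ev <= 0:
            raise ValueError("G value must be positive")


@dataclass
class ChemSample:
    """One 7OH-C3CA measurement (a point of the volume or dose series)."""

    volume_ul: float
    duration_s: float
    measured_7ohc3ca_mol_l: float
    label: str = "cu64"  # gamma_buffer | gamma_cucl | cu64
    dose_gy: float | None = None  # for gamma calibration series
    correction_applied: bool = False

    def __post_init__(self):
        if self.volume_ul <= 0:
            raise ValueError("sample volume must be positive")
        if self.measured_7ohc3ca_mol_l < 0:
            raise ValueError("concentration must be non-negative")


@dataclass(frozen=True)
class CalibrationFit:
    """Ordinary least-squares line y = slope·x + intercept."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    n_points: int
    fit_range: tuple

    def predict(self, x):
        return self.slope * np.asarray(x) + self.intercept


@dataclass(frozen=True)
class CorrectionFactor:
    """Multiplicative rescaling for copper-chloride-series slopes."""

    value: float
    sigma: float = 0.0
    provenance: str = "ratio of buffer slope to copper-chloride slope"

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("correction factor must be positive")

    def apply(self, sample: ChemSample) -> ChemSample:
        """Return a corrected copy; refuses to correct twice."""
        if sample.correction_applied:
            raise ValueError("correction factor already applied to this sample")
        return ChemSample(
            sample.volume_ul,
            sample.duration_s,
            sample.measured_7ohc3ca_mol_l * self.value,
            sample.label,
            sample.dose_gy,
            correction_applied=True,
        )


@dataclass(frozen=True)
class Measurement:
    """A value with a first-order propagated standard uncertainty."""

    value: float
    sigma: float

    def __mul__(self, k: float) -> "Measurement":
        return Measurement(self.value * k, abs(self.sigma * k))

    __rmul__ = __mul__


def fit_linear(x, y, range_max: float | None = None) -> CalibrationFit:
    """OLS fit of y on x, optionally restricted to ``x <= range_max``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if range_max is not None:
        keep = x <= range_max
        x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"linear fit needs at least 3 points in range (got {x.size})")
    res = stats.linregress(x, y)
    lo, hi = float(x.min()), float(x.max()) if range_max is None else float(range_max)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        n_points=int(x.size),
        fit_range=(lo, hi),
    )


def correction_factor(fit_buffer: CalibrationFit, fit_cucl: CalibrationFit) -> CorrectionFactor:
    """Ratio of buffer to copper-chloride calibration slopes, with SE."""
    if fit_buffer.slope <= 0 or fit_cucl.slope <= 0:
        raise ValueError("calibration slopes must be positive")
    value = fit_buffer.slope / fit_cucl.slope
    sigma = value * math.sqrt(
        (fit_buffer.slope_se / fit_buffer.slope) ** 2 + (fit_cucl.slope_se / fit_cucl.slope) ** 2
    )
    return CorrectionFactor(value, sigma)


def ohc3ca_to_oh(conc_7ohc3ca_mol_l, constants: ChemistryConstants = ChemistryConstants()) -> Measurement:
    """Hydroxyl-radical concentration from the 7OH-C3CA concentration.

    OH = measured / conversion_efficiency; the uncertainty carries the
    relative uncertainty of the conversion efficiency.
    """
    c = float(conc_7ohc3ca_mol_l)
    if c < 0:
        raise ValueError("concentration must be non-negative")
    eff = constants.conversion_efficiency
    oh = c / eff
    sigma = oh * constants.conversion_efficiency_sd / eff
    return Measurement(oh, sigma)


def co60_equivalent_dose(oh_mol, mass_kg: float, constants: ChemistryConstants = ChemistryConstants()):
    """Co-60-equivalent absorbed dose (Gy) from an OH amount in moles.

    dose = N_OH × (100 eV / G) × 1.602e-19 J/eV / mass.  Accepts a float
    or a :class:`Measurement`; returns the same kind.
    """
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    meas = isinstance(oh_mol, Measurement)
    amount = oh_mol.value if meas else float(oh_mol)
    n_radicals = amount * AVOGADRO
    energy_ev = n_radicals * 100.0 / constants.g_oh_per_100ev
    dose = energy_ev / EV_PER_GRAY_PER_KG / mass_kg
    if meas:
        return Measurement(dose, dose * oh_mol.sigma / amount if amount > 0 else 0.0)
    return dose


def oh_molarity_per_gray(constants: ChemistryConstants = ChemistryConstants()) -> float:
    """OH concentration produced per gray in water (mol/L per Gy)."""
    # 1 Gy in 1 kg (= 1 L) water: 6.24e18 eV -> G/100 radicals per eV
    return EV_PER_GRAY_PER_KG * constants.g_oh_per_100ev / 100.0 / AVOGADRO


def dose_from_concentration(
    conc_7ohc3ca_mol_l: float,
    constants: ChemistryConstants = ChemistryConstants(),
    n_decays: float | None = None,
) -> Measurement:
    """Full dosimeter chain: 7OH-C3CA concentration → Co-60-equivalent dose (Gy).

    The sample volume cancels for concentrations (moles per litre over the
    mass of a litre), so no volume argument is needed.  With ``n_decays``
    the result is per decay.
    """
    oh = ohc3ca_to_oh(conc_7ohc3ca_mol_l, constants)
    # concentration in mol/L over the 1-kg mass of a litre of water
    dose = co60_equivalent_dose(oh, 1.0, constants)
    if n_decays is not None:
        dose = Measurement(dose.value / n_decays, dose.sigma / n_decays)
    return dose
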