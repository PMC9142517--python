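"""Electron stopping powers, CSDA ranges and photon attenuation for liquid water.

The package ships two small plain-text tables (see ``augerdose/data``):

* ``water_electron_stopping.txt`` — total electron mass stopping power of
  liquid water from the 7.4 eV tracking cutoff up to 1 MeV.  Rows at and
  above 10 keV follow the Berger–Seltzer collision stopping-power formula;
  rows below 10 keV are a track-structure-motivated compilation chosen to
  reproduce the canonical low-energy anchors (LET ≈ 26 keV/μm near 150 eV,
  ≈ 7–8 keV/μm at 2 keV, CSDA range ≈ 120 nm at 2 keV).
* ``water_photon_attenuation.txt`` — photon mass attenuation coefficient of
  water over 0.5–10 keV, covering the characteristic X-ray lines of the
  Ni daughter of Cu-64.

All interpolation is log–log linear.  CSDA ranges are obtained by
integrating the reciprocal stopping power on a dense logarithmic energy
grid; queries interpolate the precomputed cumulative integral.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "ELECTRON_CUTOFF_MEV",
    "StoppingPowerTable",
    "AttenuationTable",
    "RangeResult",
    "berger_seltzer_stopping_power",
    "load_stopping_power_table",
    "load_attenuation_table",
]

#: Tracking cutoff: electrons below this kinetic energy deposit locally (MeV).
ELECTRON_CUTOFF_MEV = 7.4e-6

_ELECTRON_MC2 = 0.510998950  # electron rest energy, MeV
_WATER_Z_OVER_A = 0.55509
_WATER_I_MEV = 75e-6  # mean excitation energy of water


def berger_seltzer_stopping_power(energy_mev):
    """Berger–Seltzer collision mass stopping power of liquid water.

    Closed-form Møller collision stopping power for electrons (density
    effect neglected, adequate below ~1 MeV), in MeV·cm²/g.  Valid for
    kinetic energies well above the K-shell binding; used here for
    E ≥ 10 keV as the analytic reference for the packaged table.
    """
    T = np.asarray(energy_mev, dtype=float)
    tau = T / _ELECTRON_MC2
    beta2 = 1.0 - 1.0 / (1.0 + tau) ** 2
    lnterm = np.log(tau * tau * (tau + 2.0) / (2.0 * (_WATER_I_MEV / _ELECTRON_MC2) ** 2))
    f_tau = 1.0 - beta2 + (tau**2 / 8.0 - (2.0 * tau + 1.0) * np.log(2.0)) / (tau + 1.0) ** 2
    return 0.153536 / beta2 * _WATER_Z_OVER_A * (lnterm + f_tau)


def _loglog_interp(x, xg, yg):
    return np.exp(np.interp(np.log(x), np.log(xg), np.log(yg)))


@dataclass(frozen=True)
class RangeResult:
    """A CSDA range evaluation.

    ``csda_range`` is the path length along the track (cm); the expected
    straight-line penetration is ``csda_range * detour_factor``.
    """

    energy_mev: float
    csda_range_cm: float
    detour_factor: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.detour_factor <= 1.0:
            raise ValueError("detour_factor must be in (0, 1]")
        if self.csda_range_cm < 0.0:
            raise ValueError("csda_range_cm must be >= 0")

    @property
    def penetration_cm(self) -> float:
        return self.csda_range_cm * self.detour_factor


class StoppingPowerTable:
    """Energy-indexed total electron mass stopping power for liquid water.

    Parameters
    ----------
    energy_mev : array-like
        Strictly increasing electron kinetic energies (MeV).
    stopping_mev_cm2_g : array-like
        Total mass stopping power at those energies (MeV·cm²/g), > 0.
    density_g_cm3 : float
        Medium density; 1.0 for liquid water.
    """

    def __init__(self, energy_mev, stopping_mev_cm2_g, density_g_cm3: float = 1.0, n_range_nodes: int = 6000):
        e = np.asarray(energy_mev, dtype=float)
        s = np.asarray(stopping_mev_cm2_g, dtype=float)
        if e.ndim != 1 or e.size < 2 or s.shape != e.shape:
            raise ValueError("energy and stopping-power arrays must be matching 1-D arrays")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(s <= 0):
            raise ValueError("stopping power must be strictly positive")
        if density_g_cm3 <= 0:
            raise ValueError("density must be positive")
        self.energy_mev = e
        self.stopping_mev_cm2_g = s
        self.density_g_cm3 = float(density_g_cm3)
        self._log_e = np.log(e)
        self._log_s = np.log(s)
        # Cumulative CSDA range on a dense log grid: R(E) = int dE'/S(E').
        x = np.linspace(self._log_e[0], self._log_e[-1], n_range_nodes)
        integrand = np.exp(x) / np.exp(np.interp(x, self._log_e, self._log_s))  # E/S dlnE
        from scipy.integrate import cumulative_trapezoid

        r = cumulative_trapezoid(integrand, x, initial=0.0) / self.density_g_cm3
        self._range_log_e = x
        self._range_cm = r

    # -- bounds -----------------------------------------------------------
    @property
    def e_min(self) -> float:
        return float(self.energy_mev[0])

    @property
    def e_max(self) -> float:
        return float(self.energy_mev[-1])

    def _check_bounds(self, energy_mev, lower=None):
        lo = self.e_min if lower is None else lower
        e = np.asarray(energy_mev, dtype=float)
        if np.any(e < lo * (1 - 1e-12)) or np.any(e > self.e_max * (1 + 1e-12)):
            raise ValueError(
                f"electron energy outside table bounds [{lo:g}, {self.e_max:g}] MeV"
            )

    # -- evaluation -------------------------------------------------------
    def __call__(self, energy_mev):
        """Interpolated (log–log) total mass stopping power, MeV·cm²/g."""
        self._check_bounds(energy_mev)
        out = _loglog_interp(energy_mev, self.energy_mev, self.stopping_mev_cm2_g)
        return float(out) if np.isscalar(energy_mev) else out

    def stopping_power(self, energy_mev):
        return self(energy_mev)

    def let_kev_um(self, energy_mev):
        """Linear energy transfer at unit density, keV/μm."""
        return self(energy_mev) * self.density_g_cm3 * 0.1

    def csda_range(self, energy_mev):
        """CSDA range (cm): integral of 1/S from the table floor to E.

        Energies at or below the table floor (the tracking cutoff for the
        packaged table) have zero range; energies above the table maximum
        raise a range error.
        """
        e = np.asarray(energy_mev, dtype=float)
        if np.any(e > self.e_max * (1 + 1e-12)):
            raise ValueError(f"electron energy above table bound {self.e_max:g} MeV")
        below = e <= self.e_min
        e_clip = np.clip(e, self.e_min, self.e_max)
        r = np.interp(np.log(e_clip), self._range_log_e, self._range_cm)
        r = np.where(below, 0.0, r)
        return float(r) if np.isscalar(energy_mev) else r

    def energy_at_range(self, range_cm):
        """Inverse of :meth:`csda_range`: residual energy after consuming
        ``csda_range(E0) - range_cm`` of path.  Clipped to the table floor."""
        r = np.clip(np.asarray(range_cm, dtype=float), 0.0, self._range_cm[-1])
        log_e = np.interp(r, self._range_cm, self._range_log_e)
        out = np.exp(log_e)
        return float(out) if np.isscalar(range_cm) else out

    def range_result(self, energy_mev, detour_factor: float = 1.0) -> RangeResult:
        return RangeResult(float(energy_mev), float(self.csda_range(energy_mev)), detour_factor)


class AttenuationTable:
    """Photon mass attenuation coefficients μ/ρ for liquid water, 0.5–10 keV."""

    def __init__(self, energy_kev, mu_rho_cm2_g, density_g_cm3: float = 1.0):
        e = np.asarray(energy_kev, dtype=float)
        m = np.asarray(mu_rho_cm2_g, dtype=float)
        if e.ndim != 1 or e.size < 2 or m.shape != e.shape:
            raise ValueError("energy and mu/rho arrays must be matching 1-D arrays")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(m <= 0):
            raise ValueError("mu/rho must be strictly positive")
        self.energy_kev = e
        self.mu_rho_cm2_g = m
        self.density_g_cm3 = float(density_g_cm3)

    def _check_bounds(self, energy_kev):
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < self.energy_kev[0] * (1 - 1e-12)) or np.any(e > self.energy_kev[-1] * (1 + 1e-12)):
            raise ValueError(
                f"photon energy outside table bounds [{self.energy_kev[0]:g}, {self.energy_kev[-1]:g}] keV"
            )

    def mu_rho(self, energy_kev):
        self._check_bounds(energy_kev)
        out = _loglog_interp(energy_kev, self.energy_kev, self.mu_rho_cm2_g)
        return float(out) if np.isscalar(energy_kev) else out

    def attenuation_length(self, energy_kev):
        """Mean free path 1/(μ/ρ · ρ), in cm."""
        out = 1.0 / (self.mu_rho(energy_kev) * self.density_g_cm3)
        return out


def _read_two_column(name: str):
    text = resources.files("augerdose.data").joinpath(name).read_text()
    rows = [ln.split() for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    arr = np.array(rows, dtype=float)
    return arr[:, 0], arr[:, 1]


def load_stopping_power_table() -> StoppingPowerTable:
    """Load the packaged liquid-water electron stopping-power table."""
    e_ev, s = _read_two_column("water_electron_stopping.txt")
    return StoppingPowerTable(e_ev * 1e-6, s)


def load_attenuation_table() -> AttenuationTable:
    """Load the packaged liquid-water photon attenuation table."""
    e_kev, mu = _read_two_column("water_photon_attenuation.txt")
    return AttenuationTable(e_kev, mu)
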