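"""D10 and relative biological effectiveness (RBE) arithmetic.

The dose delivered by an internal emitter is the product of the number
of decays (activity × duration, optionally half-life-corrected) and the
simulated dose per decay.  D10 — the absorbed dose at 10% clonogenic
survival — is extracted from survival curves either by log-linear
interpolation or from a linear-quadratic (LQ) fit
``SF = exp(−αD − βD²)``.  RBE is the gamma-reference D10 divided by the
test-radiation D10.

The packaged reference table (``data/reference_d10.csv``) lists D10 and
published RBE for CHO wild-type and repair-deficient xrs5 cells under
gamma rays, protons, carbon and iron ions, and Cu-64.  For Cu-64 the
published RBE values differ from the plain gamma/test D10 ratio; both
the reported and the ratio-derived values are therefore exposed side by
side and never silently reconciled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ExposureSpec",
    "SurvivalCurve",
    "RbeRecord",
    "decays_from_exposure",
    "dose_from_exposure",
    "d10_from_survival",
    "rbe",
    "build_rbe_table",
    "load_reference_d10",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class ExposureSpec:
    """Internal-emitter exposure: per-cell activity, duration, dose per decay."""

    activity_bq: float
    duration_s: float = 5 * 3600.0
    dose_per_decay_gy: float = 0.0
    half_life_s: float | None = None  # None -> constant-activity mode
    max_duration_s: float = 365 * 86400.0

    def __post_init__(self):
        if self.activity_bq < 0 or self.duration_s <= 0 or self.dose_per_decay_gy < 0:
            raise ValueError("activity, duration and dose per decay must be non-negative")
        if self.duration_s > self.max_duration_s:
            raise ValueError("duration exceeds the configured practical bound")
        if self.half_life_s is not None and self.half_life_s <= 0:
            raise ValueError("half-life must be positive")


def decays_from_exposure(spec: ExposureSpec) -> float:
    """Number of decays: A·t, or (A/λ)(1 − e^(−λt)) with decay correction."""
    if spec.half_life_s is None:
        return spec.activity_bq * spec.duration_s
    lam = math.log(2.0) / spec.half_life_s
    return spec.activity_bq / lam * -math.expm1(-lam * spec.duration_s)


def dose_from_exposure(spec: ExposureSpec) -> float:
    """Absorbed dose (Gy) = decays × dose per decay."""
    return decays_from_exposure(spec) * spec.dose_per_decay_gy


@dataclass
class SurvivalCurve:
    """Clonogenic survival data: dose (Gy, ascending) and surviving fraction."""

    doses_gy: np.ndarray
    surviving_fractions: np.ndarray
    model: str = "auto"  # loglinear | linear_quadratic | auto

    def __post_init__(self):
        d = np.asarray(self.doses_gy, dtype=float)
        sf = np.asarray(self.surviving_fractions, dtype=float)
        if d.shape != sf.shape or d.ndim != 1 or d.size < 3:
            raise ValueError("need >= 3 matching dose/survival points")
        if np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(sf <= 0) or np.any(sf > 1):
            raise ValueError("surviving fractions must lie in (0, 1]")
        if self.model not in ("loglinear", "linear_quadratic", "auto"):
            raise ValueError(f"unknown survival model {self.model!r}")
        self.doses_gy = d
        self.surviving_fractions = sf

    def fit_lq(self):
        """Least-squares LQ parameters (α, β) on −ln SF, β constrained ≥ 0."""
        d = self.doses_gy
        y = -np.log(self.surviving_fractions)
        A = np.column_stack([d, d**2])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        alpha, beta = float(coef[0]), float(coef[1])
        if beta < 0:  # refit pure exponential
            alpha = float(np.sum(d * y) / np.sum(d * d))
            beta = 0.0
        return alpha, beta


def d10_from_survival(curve: SurvivalCurve) -> float:
    """Dose at 10% survival.

    ``loglinear``: interpolate log SF against dose (data must span
    SF = 0.1).  ``linear_quadratic``: solve αD + βD² = ln 10 for the
    positive root.  ``auto``: LQ for ≥ 4 points, log-linear otherwise.
    """
    model = curve.model
    if model == "auto":
        model = "linear_quadratic" if curve.doses_gy.size >= 4 else "loglinear"
    if model == "loglinear":
        logsf = np.log(curve.surviving_fractions)
        target = math.log(0.1)
        if logsf.min() > target:
            raise ValueError("survival data do not span SF = 0.1; cannot interpolate")
        # log SF decreases with dose; np.interp needs ascending x
        return float(np.interp(target, logsf[::-1], curve.doses_gy[::-1]))
    alpha, beta = curve.fit_lq()
    if beta == 0.0:
        if alpha <= 0:
            raise ValueError("non-positive fitted alpha; SF = 0.1 unreachable")
        return LN10 / alpha
    disc = alpha**2 + 4.0 * beta * LN10
    return (-alpha + math.sqrt(disc)) / (2.0 * beta)


def rbe(d10_reference_gy: float, d10_test_gy: float) -> float:
    """RBE = reference (gamma) D10 over test D10."""
    if d10_reference_gy <= 0 or d10_test_gy <= 0:
        raise ValueError("D10 values must be positive")
    return d10_reference_gy / d10_test_gy


@dataclass(frozen=True)
class RbeRecord:
    radiation: str
    let_kev_um: float | None
    d10_gy: float
    rbe: float
    rbe_reported: float | None = None

    def rounded(self, ndigits: int = 2) -> "RbeRecord":
        """Serialization-time half-up rounding of the derived RBE."""
        from decimal import ROUND_HALF_UP, Decimal

        q = Decimal(10) ** -ndigits
        r = float(Decimal(repr(self.rbe)).quantize(q, rounding=ROUND_HALF_UP))
        return RbeRecord(self.radiation, self.let_kev_um, self.d10_gy, r, self.rbe_reported)


def build_rbe_table(records, reference_label: str = "gamma") -> list:
    """Compute ratio-derived RBE per row against the reference radiation.

    ``records`` is an iterable of ``(radiation, let, d10)`` or
    ``(radiation, let, d10, rbe_reported)`` tuples; row order is kept and
    values stay at full precision (round at serialization only).
    """
    rows = [tuple(r) for r in records]
    ref = [r for r in rows if r[0] == reference_label]
    if not ref:
        raise ValueError(f"reference radiation {reference_label!r} not present")
    d10_ref = float(ref[0][2])
    out = []
    for r in rows:
        radiation, let, d10 = r[0], r[1], float(r[2])
        reported = float(r[3]) if len(r) > 3 and r[3] is not None else None
        out.append(RbeRecord(radiation, let, d10, rbe(d10_ref, d10), reported))
    return out


def load_reference_d10() -> pd.DataFrame:
    """Packaged reference D10/RBE table for CHO wild-type and xrs5 cells."""
    import io

    text = resources.files("augerdose.data").joinpath("reference_d10.csv").read_text()
    return pd.read_csv(io.StringIO(text), comment="#")
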