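"""Sampling of the Cu-64 decay scheme.

Cu-64 decays by β⁻ emission (40%, endpoint 0.573 MeV, daughter ⁶⁴Zn),
β⁺ emission (19%, endpoint 0.656 MeV, daughter ⁶⁴Ni) and electron
capture (41%).  Electron capture leaves an inner-shell vacancy in the
nickel daughter which relaxes either by K fluorescence (characteristic
X-rays around 7.5 keV) or by Auger-electron emission.  The Auger cascade
is represented by a single electron drawn from a discrete spectrum with
mean ≈ 2 keV, so that the per-decay Auger energy budget (≈ 22% of decays
emitting, ≈ 2 keV mean energy) matches the scheme-level emission data.

β spectra follow the allowed-transition Fermi shape
``p·E_tot·(Q−T)²·F(Z, T)`` with the nonrelativistic Coulomb factor
``F = 2πη / (1 − e^(−2πη))``, η = ±Zα/β — enhancement at low energy for
β⁻, suppression for β⁺.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "BetaSpectrum",
    "XrayLine",
    "DecayScheme",
    "EmittedParticle",
    "DecayEvent",
    "load_cu64_scheme",
    "sample_channel",
    "sample_beta_energy",
    "sample_relaxation",
    "sample_decay",
    "isotropic_directions",
]

_ELECTRON_MC2 = 0.510998950
_ALPHA = 1.0 / 137.035999


class BetaSpectrum:
    """Allowed β spectrum with nonrelativistic Coulomb correction.

    Parameters
    ----------
    endpoint_mev : float
        Spectrum endpoint (Q value shared with the neutrino).
    charge_sign : int
        +1 for β⁻ (Coulomb attraction of the daughter, low-energy
        enhancement), −1 for β⁺ (suppression).
    daughter_z : int
        Atomic number of the daughter nucleus.
    """

    def __init__(self, endpoint_mev: float, charge_sign: int, daughter_z: int, n_grid: int = 2048):
        if endpoint_mev <= 0:
            raise ValueError("endpoint must be positive")
        if charge_sign not in (+1, -1):
            raise ValueError("charge_sign must be +1 (beta-) or -1 (beta+)")
        self.endpoint_mev = float(endpoint_mev)
        self.charge_sign = int(charge_sign)
        self.daughter_z = int(daughter_z)
        # open grid on (0, Q): density vanishes at both ends
        t = np.linspace(0.0, endpoint_mev, n_grid + 2)[1:-1]
        d = self.density(t)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (d[1:] + d[:-1]) * np.diff(t))])
        self._norm = cdf[-1]
        self._grid = t
        self._cdf = cdf / cdf[-1]

    def fermi_function(self, kinetic_mev):
        T = np.asarray(kinetic_mev, dtype=float)
        gamma = 1.0 + T / _ELECTRON_MC2
        beta = np.sqrt(np.clip(1.0 - 1.0 / gamma**2, 1e-30, None))
        eta = self.charge_sign * self.daughter_z * _ALPHA / beta
        x = 2.0 * np.pi * eta
        # 2*pi*eta / (1 - exp(-2*pi*eta)), stable for both signs
        with np.errstate(over="ignore", under="ignore"):
            out = np.where(np.abs(x) < 1e-8, 1.0, x / -np.expm1(-x))
        return out

    def density(self, kinetic_mev):
        """Unnormalised spectral density; zero outside (0, endpoint)."""
        T = np.asarray(kinetic_mev, dtype=float)
        inside = (T > 0.0) & (T < self.endpoint_mev)
        Ts = np.where(inside, T, 0.5 * self.endpoint_mev)
        e_tot = Ts + _ELECTRON_MC2
        p = np.sqrt(Ts * (Ts + 2.0 * _ELECTRON_MC2))
        d = p * e_tot * (self.endpoint_mev - Ts) ** 2 * self.fermi_function(Ts)
        return np.where(inside, d, 0.0)

    def mean(self) -> float:
        """Mean kinetic energy by quadrature of the spectral density."""
        t = self._grid
        d = self.density(t)
        return float(np.trapezoid(t * d, t) / np.trapezoid(d, t))

    def sample(self, rng: np.random.Generator, size=None):
        """Inverse-CDF sampling on the precomputed grid."""
        u = rng.random(size)
        out = np.interp(u, self._cdf, self._grid)
        return float(out) if size is None else out


@dataclass(frozen=True)
class XrayLine:
    label: str
    energy_kev: float
    per_decay_fraction: float


@dataclass
class DecayScheme:
    """Branching ratios and emission data for an EC/β radionuclide."""

    name: str = "Cu-64"
    p_beta_minus: float = 0.40
    e_max_beta_minus: float = 0.573
    beta_minus_daughter_z: int = 30
    p_beta_plus: float = 0.19
    e_max_beta_plus: float = 0.656
    beta_plus_daughter_z: int = 28
    p_ec: float = 0.41
    p_k_vacancy_given_ec: float = 0.88
    k_fluorescence_yield: float = 0.41
    xray_lines: tuple = (
        XrayLine("l", 0.85, 0.005),
        XrayLine("ka1", 7.48, 0.094),
        XrayLine("ka2", 7.46, 0.048),
        XrayLine("kb1", 8.27, 0.011),
        XrayLine("kb3", 8.27, 0.0058),
    )
    auger_energies_kev: tuple = (0.11, 0.74, 0.84, 6.25, 7.46)
    auger_weights: tuple = (0.2966, 0.25, 0.20, 0.2284, 0.025)
    _spectra: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.validate()

    def validate(self):
        probs = [
            self.p_beta_minus,
            self.p_beta_plus,
            self.p_ec,
            self.p_k_vacancy_given_ec,
            self.k_fluorescence_yield,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(self.p_beta_minus + self.p_beta_plus + self.p_ec - 1.0) > 1e-9:
            raise ValueError("channel probabilities must sum to 1")
        if self.e_max_beta_minus <= 0 or self.e_max_beta_plus <= 0:
            raise ValueError("beta endpoints must be positive")
        if any(line.energy_kev <= 0 or line.per_decay_fraction < 0 for line in self.xray_lines):
            raise ValueError("X-ray line energies must be positive and fractions non-negative")
        w = np.asarray(self.auger_weights, dtype=float)
        e = np.asarray(self.auger_energies_kev, dtype=float)
        if np.any(e <= 0) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("Auger spectrum weights must be non-negative and sum to 1")
        mean = float(e @ w / w.sum())
        if not 1.5 <= mean <= 2.5:
            raise ValueError(f"Auger spectrum mean {mean:.3f} keV outside [1.5, 2.5] keV")

    # -- derived quantities ----------------------------------------------
    @property
    def auger_mean_kev(self) -> float:
        w = np.asarray(self.auger_weights)
        return float(np.asarray(self.auger_energies_kev) @ w / w.sum())

    @property
    def p_auger_per_decay(self) -> float:
        """Analytic probability that a decay emits Auger electrons."""
        return self.p_ec * self.p_k_vacancy_given_ec * (1.0 - self.k_fluorescence_yield)

    @property
    def p_xray_per_decay(self) -> float:
        return self.p_ec * self.p_k_vacancy_given_ec * self.k_fluorescence_yield

    @property
    def xray_relative_weights(self) -> np.ndarray:
        f = np.array([line.per_decay_fraction for line in self.xray_lines], dtype=float)
        return f / f.sum()

    @property
    def xray_mean_kev(self) -> float:
        e = np.array([line.energy_kev for line in self.xray_lines])
        return float(e @ self.xray_relative_weights)

    def beta_spectrum(self, channel: str) -> BetaSpectrum:
        if channel not in self._spectra:
            if channel == "beta_minus":
                self._spectra[channel] = BetaSpectrum(self.e_max_beta_minus, +1, self.beta_minus_daughter_z)
            elif channel == "beta_plus":
                self._spectra[channel] = BetaSpectrum(self.e_max_beta_plus, -1, self.beta_plus_daughter_z)
            else:
                raise ValueError(f"no beta spectrum for channel {channel!r}")
        return self._spectra[channel]

    def mean_electron_energy_per_decay(self) -> float:
        """Closed-form expected emitted electron+positron energy per decay (MeV)."""
        return (
            self.p_beta_minus * self.beta_spectrum("beta_minus").mean()
            + self.p_beta_plus * self.beta_spectrum("beta_plus").mean()
            + self.p_auger_per_decay * self.auger_mean_kev * 1e-3
        )

    # -- serialization ----------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "DecayScheme":
        known = {"name", "beta_minus", "beta_plus", "ec", "xray_lines", "auger_spectrum"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown decay-scheme keys: {sorted(unknown)}")
        lines = tuple(
            XrayLine(x["label"], float(x["energy_kev"]), float(x["per_decay_fraction"]))
            for x in d["xray_lines"]
        )
        return cls(
            name=d.get("name", "unnamed"),
            p_beta_minus=float(d["beta_minus"]["probability"]),
            e_max_beta_minus=float(d["beta_minus"]["endpoint_mev"]),
            beta_minus_daughter_z=int(d["beta_minus"]["daughter_z"]),
            p_beta_plus=float(d["beta_plus"]["probability"]),
            e_max_beta_plus=float(d["beta_plus"]["endpoint_mev"]),
            beta_plus_daughter_z=int(d["beta_plus"]["daughter_z"]),
            p_ec=float(d["ec"]["probability"]),
            p_k_vacancy_given_ec=float(d["ec"]["p_k_vacancy"]),
            k_fluorescence_yield=float(d["ec"]["k_fluorescence_yield"]),
            xray_lines=lines,
            auger_energies_kev=tuple(float(e) for e in d["auger_spectrum"]["energies_kev"]),
            auger_weights=tuple(float(w) for w in d["auger_spectrum"]["weights"]),
        )

    @classmethod
    def from_yaml(cls, path) -> "DecayScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_cu64_scheme() -> DecayScheme:
    """Load the packaged Cu-64 default scheme."""
    text = resources.files("augerdose.data").joinpath("cu64_scheme.yaml").read_text()
    return DecayScheme.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class EmittedParticle:
    species: str  # electron | positron | photon
    origin_label: str  # beta_minus | beta_plus | auger | xray | annihilation
    energy_mev: float
    direction: np.ndarray
    position: np.ndarray

    def __post_init__(self):
        if self.energy_mev <= 0:
            raise ValueError("particle energy must be positive")
        n = float(np.linalg.norm(self.direction))
        if abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")


@dataclass(frozen=True)
class DecayEvent:
    channel: str  # beta_minus | beta_plus | ec
    particles: tuple


_CHANNELS = np.array(["beta_minus", "beta_plus", "ec"])


def sample_channel(scheme: DecayScheme, rng: np.random.Generator, size=None):
    """Sample the decay channel label(s) with the scheme's branching ratios."""
    p = [scheme.p_beta_minus, scheme.p_beta_plus, scheme.p_ec]
    idx = rng.choice(3, size=size, p=p)
    out = _CHANNELS[idx]
    return str(out) if size is None else out


def sample_beta_energy(endpoint_mev, charge_sign, daughter_z, rng, size=None):
    """Draw kinetic energies from the allowed Fermi β spectrum (MeV)."""
    return BetaSpectrum(endpoint_mev, charge_sign, daughter_z).sample(rng, size)


def isotropic_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit vectors uniform on the sphere, shape (n, 3)."""
    z = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def sample_relaxation(scheme: DecayScheme, rng: np.random.Generator, position=None):
    """Relax an electron-capture vacancy; return the emitted particle list.

    With probability ``p_k_vacancy_given_ec`` the capture leaves an
    inner-shell vacancy; the vacancy fluoresces (one X-ray photon drawn
    from the line weights) with probability ``k_fluorescence_yield`` and
    otherwise emits one Auger electron drawn from the cascade spectrum.
    """
    pos = np.zeros(3) if position is None else np.asarray(position, dtype=float)
    if rng.random() >= scheme.p_k_vacancy_given_ec:
        return []
    direction = isotropic_directions(rng, 1)[0]
    if rng.random() < scheme.k_fluorescence_yield:
        i = rng.choice(len(scheme.xray_lines), p=scheme.xray_relative_weights)
        line = scheme.xray_lines[i]
        return [EmittedParticle("photon", "xray", line.energy_kev * 1e-3, direction, pos)]
    w = np.asarray(scheme.auger_weights) / np.sum(scheme.auger_weights)
    i = rng.choice(len(scheme.auger_energies_kev), p=w)
    return [EmittedParticle("electron", "auger", scheme.auger_energies_kev[i] * 1e-3, direction, pos)]


def sample_emission_counts(scheme: DecayScheme, n_decays: int, rng: np.random.Generator) -> dict:
    """Vectorised emission statistics over many decays.

    Returns channel counts, the number of decays emitting at least one
    Auger electron, and per-line X-ray counts — the quantities the
    scheme-level emission fractions are checked against.
    """
    p = np.array([scheme.p_beta_minus, scheme.p_beta_plus, scheme.p_ec])
    ch = rng.choice(3, size=n_decays, p=p)
    ec = ch == 2
    vacancy = np.zeros(n_decays, bool)
    vacancy[ec] = rng.random(ec.sum()) < scheme.p_k_vacancy_given_ec
    fluoresce = np.zeros(n_decays, bool)
    fluoresce[vacancy] = rng.random(vacancy.sum()) < scheme.k_fluorescence_yield
    auger = vacancy & ~fluoresce
    n_xray = int(fluoresce.sum())
    line_counts = np.bincount(
        rng.choice(len(scheme.xray_lines), size=n_xray, p=scheme.xray_relative_weights),
        minlength=len(scheme.xray_lines),
    )
    return {
        "n_decays": n_decays,
        "channel_counts": {
            "beta_minus": int((ch == 0).sum()),
            "beta_plus": int((ch == 1).sum()),
            "ec": int(ec.sum()),
        },
        "n_auger_decays": int(auger.sum()),
        "n_xray_decays": n_xray,
        "xray_line_counts": {line.label: int(c) for line, c in zip(scheme.xray_lines, line_counts)},
    }


def sample_decay(scheme: DecayScheme, position, rng: np.random.Generator) -> DecayEvent:
    """Sample one full decay: channel, emitted particles, isotropic directions."""
    pos = np.asarray(position, dtype=float)
    channel = sample_channel(scheme, rng)
    particles = []
    if channel in ("beta_minus", "beta_plus"):
        spec = scheme.beta_spectrum(channel)
        e = spec.sample(rng)
        species = "electron" if channel == "beta_minus" else "positron"
        particles.append(EmittedParticle(species, channel, e, isotropic_directions(rng, 1)[0], pos))
    else:
        particles.extend(sample_relaxation(scheme, rng, pos))
    return DecayEvent(channel, tuple(particles))
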