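"""Hydroxyapatite saturation state and enzymatic hydrolysis kinetics.

The saturation index is SI = log10(IAP/Ks) with
IAP = a(Ca2+)^5 * a(PO4^3-)^3 * a(OH-) for hydroxyapatite Ca5(PO4)3OH and
log Ks = -57.74. Speciation is a documented simplification of a full
geochemical code: orthophosphate protonation from the three phosphoric-acid
pKa values, OH- from the water ion product, single-ion activity coefficients
from the Davies equation, ionic strength solved by fixed-point iteration.
Ca-phosphate ion pairs and carbonate equilibria are neglected, which biases
SI upward by at most about one unit in the assay conditions modeled here.

Assay kinetics: absorbance at 405 nm converts to released p-nitrophenol
(hence orthophosphate) through Beer-Lambert with epsilon = 18,000 1/(M cm);
the hydrolysis rate is the least-squares slope of the initial linear phase,
scaled by the reaction volume, in pmol/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import (
    DAVIES_A,
    DETECTION_LIMIT_CA,
    DETECTION_LIMIT_PI,
    EPSILON_PNP_405,
    LOG_K_HYDROXYAPATITE,
    LOG_KW,
    PHOSPHORIC_PKA,
)


@dataclass
class SolutionComposition:
    """Total dissolved Ca and orthophosphate with a fixed pH, at 25 degC.

    ``background_electrolyte`` is an optional list of (concentration mol/L,
    charge) pairs contributing to ionic strength but not to any equilibrium.
    """

    total_ca: float   # mol/L
    total_pi: float   # mol/L
    ph: float
    background_electrolyte: list[tuple[float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_ca < 0 or self.total_pi < 0:
            raise ValueError("total concentrations must be >= 0")
        if not 0 < self.ph < 14:
            raise ValueError(f"pH {self.ph} out of range (0, 14)")


@dataclass
class SpeciationResult:
    activities: dict[str, float]      # Ca2+, H3PO4, H2PO4-, HPO4 2-, PO4 3-, OH-
    concentrations: dict[str, float]
    ionic_strength: float
    gamma: dict[int, float]           # |charge| -> activity coefficient


def davies_log_gamma(charge: int, ionic_strength: float, a_coeff: float = DAVIES_A) -> float:
    """Davies equation: log10 gamma_z = -A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I)."""
    if ionic_strength <= 0:
        return 0.0
    s = np.sqrt(ionic_strength)
    return -a_coeff * charge * charge * (s / (1.0 + s) - 0.3 * ionic_strength)


def speciate(
    composition: SolutionComposition,
    ideal: bool = False,
    tol: float = 1e-8,
    max_iter: int = 500,
    initial_ionic_strength: float = 0.0,
) -> SpeciationResult:
    """Simplified equilibrium speciation of the Ca / orthophosphate system.

    Phosphate protonation fractions follow the three phosphoric-acid pKa
    values (activity-corrected); OH- comes from Kw; Davies coefficients are
    recomputed from the ionic strength until |dI| < ``tol``. With
    ``ideal=True`` all activity coefficients are fixed at 1.
    """
    ka = [10.0 ** -pk for pk in PHOSPHORIC_PKA]
    a_h = 10.0 ** -composition.ph
    a_oh = 10.0 ** LOG_KW / a_h
    ionic = initial_ionic_strength
    for _ in range(max_iter):
        gamma = {z: 1.0 if ideal else 10.0 ** davies_log_gamma(z, ionic) for z in (0, 1, 2, 3)}
        # concentration ratios between successive protonation states
        r1 = ka[0] * gamma[0] / (a_h * gamma[1])        # [H2PO4-]/[H3PO4]
        r2 = ka[1] * gamma[1] / (a_h * gamma[2])        # [HPO4 2-]/[H2PO4-]
        r3 = ka[2] * gamma[2] / (a_h * gamma[3])        # [PO4 3-]/[HPO4 2-]
        denom = 1.0 + r1 + r1 * r2 + r1 * r2 * r3
        c_h3 = composition.total_pi / denom
        c_h2 = c_h3 * r1
        c_h1 = c_h2 * r2
        c_p = c_h1 * r3
        c_ca = composition.total_ca
        c_oh = a_oh / gamma[1]
        c_hplus = a_h / gamma[1]
        new_ionic = 0.5 * (
            4.0 * c_ca + c_h2 + 4.0 * c_h1 + 9.0 * c_p + c_oh + c_hplus
            + sum(c * z * z for c, z in composition.background_electrolyte)
        )
        if ideal:
            new_ionic, converged = 0.0, True
        else:
            converged = abs(new_ionic - ionic) < tol
        ionic = new_ionic
        if converged:
            break
    else:
        raise RuntimeError("ionic-strength iteration did not converge")
    concentrations = {
        "Ca2+": c_ca, "H3PO4": c_h3, "H2PO4-": c_h2,
        "HPO4 2-": c_h1, "PO4 3-": c_p, "OH-": c_oh,
    }
    charge_of = {"Ca2+": 2, "H3PO4": 0, "H2PO4-": 1, "HPO4 2-": 2, "PO4 3-": 3, "OH-": 1}
    activities = {k: c * gamma[charge_of[k]] for k, c in concentrations.items()}
    return SpeciationResult(activities, concentrations, ionic, gamma)


def saturation_index_hydroxyapatite(
    composition: SolutionComposition,
    ideal: bool = False,
    log_ks: float = LOG_K_HYDROXYAPATITE,
    detection_limit_ca: float = DETECTION_LIMIT_CA,
    detection_limit_pi: float = DETECTION_LIMIT_PI,
) -> float | None:
    """SI = log10(IAP/Ks) with IAP = a(Ca2+)^5 a(PO4^3-)^3 a(OH-).

    Returns None (undefined) when total Ca or total orthophosphate is at or
    below its detection limit, mirroring the exclusion rule used for the
    assay solutions.
    """
    if composition.total_ca <= detection_limit_ca or composition.total_pi <= detection_limit_pi:
        return None
    sp = speciate(composition, ideal=ideal)
    log_iap = (
        5.0 * np.log10(sp.activities["Ca2+"])
        + 3.0 * np.log10(sp.activities["PO4 3-"])
        + np.log10(sp.activities["OH-"])
    )
    return float(log_iap - log_ks)


# ---------------------------------------------------------------------------
# Assay kinetics
# ---------------------------------------------------------------------------

@dataclass
class AssayConfig:
    epsilon: float = EPSILON_PNP_405  # 1/(M cm)
    path_length: float = 1.0          # cm
    reaction_volume: float = 1e-3     # L

    def __post_init__(self) -> None:
        if min(self.epsilon, self.path_length, self.reaction_volume) <= 0:
            raise ValueError("assay parameters must be positive")


@dataclass
class KineticsSeries:
    """A time series of absorbance or concentration values."""

    times: np.ndarray    # s, strictly increasing
    values: np.ndarray
    series_kind: str     # "absorbance" | "concentration"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values differ in length")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if self.series_kind not in ("absorbance", "concentration"):
            raise ValueError(f"unknown series kind {self.series_kind!r}")


def absorbance_to_concentration(a405: float | np.ndarray, config: AssayConfig) -> float | np.ndarray:
    """Beer-Lambert: c = A / (epsilon * l), in mol/L."""
    arr = np.asarray(a405, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative absorbance")
    out = arr / (config.epsilon * config.path_length)
    return float(out) if np.isscalar(a405) else out


def _linear_fit(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    res = stats.linregress(t, c)
    return float(res.slope), float(res.rvalue ** 2)


def hydrolysis_rate(
    series: KineticsSeries,
    config: AssayConfig,
    min_points: int = 4,
    r2_threshold: float = 0.98,
) -> float:
    """Initial-phase hydrolysis rate in pmol/s.

    The concentration-vs-time slope is fitted over the longest prefix of at
    least ``min_points`` points with R^2 >= ``r2_threshold`` (the initial
    linear phase); the slope (mol/L/s) times the reaction volume gives the
    release rate. Falls back to the best-R^2 minimal prefix when no prefix
    qualifies.
    """
    if len(series.times) < min_points:
        raise ValueError(f"need at least {min_points} points")
    conc = (
        absorbance_to_concentration(series.values, config)
        if series.series_kind == "absorbance"
        else series.values
    )
    t = series.times
    best_slope = None
    best_r2 = -np.inf
    chosen = None
    for k in range(min_points, len(t) + 1):
        slope, r2 = _linear_fit(t[:k], conc[:k])
        if r2 >= r2_threshold:
            chosen = slope  # longest qualifying prefix wins
        if r2 > best_r2:
            best_r2, best_slope = r2, slope
    slope = chosen if chosen is not None else best_slope
    return float(slope * config.reaction_volume * 1e12)  # mol/s -> pmol/s
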