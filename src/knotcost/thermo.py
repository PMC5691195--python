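"""Free-energy extraction and the knotting thermodynamic cycle.

Two independent routes give the unfolding free energy of each molecule
class:

* **Crooks fluctuation theorem (CFT).**  With refolding works sign-flipped
  onto the unfolding-work axis, the forward and reverse W^(F=0)
  distributions cross at the equilibrium ΔG°.  Gaussian fits are used,
  so the crossing is the root of a quadratic between the two means.
* **Coexistence force.**  Folded and unfolded lifetimes ln τ(F) cross at
  F₁/₂; ΔG = F₁/₂·Δx(F₁/₂) − W_s(F₁/₂) with the extension from the
  class's contour length.

The native-state knotting free energy ΔG_N comes from Boltzmann-weighted
conformer populations (or direct molecule counts), and the thermodynamic
cycle closes on the unfolded-state knotting cost:

    ΔG_U = ΔG_unfold(knotted) − ΔG_unfold(unknotted) − ΔG_N,

with ΔG_N = G_N,unknotted − G_N,knotted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import rt_kcal
from .wlc import WLCParams, stretch_work, wlc_extension

__all__ = [
    "GaussianWorkFit", "StabilityEstimate", "KnotCycle", "FitQualityError",
    "fit_work_distribution", "cft_delta_g", "f_half", "delta_g_f_half",
    "boltzmann_state_probabilities", "delta_g_native", "knotting_cost_cycle",
]


class FitQualityError(RuntimeError):
    """The fitted work distributions admit no crossing between the means."""


@dataclass(frozen=True)
class GaussianWorkFit:
    """Gaussian fit of a zero-force work distribution (kcal/mol)."""

    mean: float
    sd: float
    n: int
    direction: str  # "fold" | "unfold"

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.n < 2:
            raise ValueError("need at least two work values")


@dataclass
class StabilityEstimate:
    """Unfolding free energies of one molecule class (kcal/mol)."""

    topology: str                  # "knotted" | "unknotted"
    dg_cft: float = np.nan
    dg_cft_err: float = np.nan
    dg_f_half: float = np.nan
    f_half: float = np.nan

    @property
    def dg_mean(self) -> float:
        """Average of the CFT and F₁/₂ routes (when both exist)."""
        vals = [v for v in (self.dg_cft, self.dg_f_half) if np.isfinite(v)]
        return float(np.mean(vals)) if vals else np.nan


@dataclass(frozen=True)
class KnotCycle:
    """Closed thermodynamic cycle for the unfolded-state knotting cost."""

    dg_unfold_knotted: float
    dg_unfold_unknotted: float
    dg_native: float
    dg_unfolded_knotting: float
    propagated_err: float = np.nan


def fit_work_distribution(works, direction: str) -> GaussianWorkFit:
    """Maximum-likelihood Gaussian fit (sample mean/SD) of work values.

    ``fold``-direction works are expected already sign-flipped onto the
    unfolding-work axis.
    """
    w = np.asarray(works, dtype=float)
    if w.size < 2:
        raise ValueError("need at least two work values")
    return GaussianWorkFit(mean=float(w.mean()),
                           sd=float(w.std(ddof=1)), n=int(w.size),
                           direction=direction)


def cft_delta_g(fold: GaussianWorkFit, unfold: GaussianWorkFit) -> float:
    """CFT estimate of ΔG°: crossing of the two Gaussian densities.

    Both fits must live on the unfolding-work axis (refolding works
    sign-flipped upstream).  With equal spreads the crossing is the
    midpoint of the means; otherwise it is the quadratic root lying
    between them.  A pathological pair with no root between the means
    raises :class:`FitQualityError`.
    """
    m1, s1 = fold.mean, fold.sd
    m2, s2 = unfold.mean, unfold.sd
    lo, hi = min(m1, m2), max(m1, m2)
    if np.isclose(s1, s2):
        return 0.5 * (m1 + m2)
    # equal-density condition: quadratic a w^2 + b w + c = 0
    a = 1.0 / s2**2 - 1.0 / s1**2
    b = 2.0 * (m1 / s1**2 - m2 / s2**2)
    c = m2**2 / s2**2 - m1**2 / s1**2 + 2.0 * np.log(s2 / s1)
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise FitQualityError("work-distribution fits admit no crossing")
    roots = np.array([(-b - np.sqrt(disc)) / (2 * a),
                      (-b + np.sqrt(disc)) / (2 * a)])
    inside = roots[(roots >= lo) & (roots <= hi)]
    if inside.size == 0:
        raise FitQualityError("no crossing between the distribution means")
    return float(inside[0])


def f_half(folded_lifetimes, unfolded_lifetimes) -> float:
    """Coexistence force from force-dependent lifetimes.

    Each series is an (F, τ) table; straight lines are fitted to
    ln τ versus F and their crossing returned.  The result is symmetric
    under exchanging the two series.  Parallel lines raise ValueError.
    """
    def _fit(series):
        arr = np.asarray(series, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("each lifetime series needs >= 2 (F, tau) rows")
        if np.any(arr[:, 1] <= 0):
            raise ValueError("lifetimes must be positive")
        return np.polyfit(arr[:, 0], np.log(arr[:, 1]), 1)

    mf, bf = _fit(folded_lifetimes)
    mu, bu = _fit(unfolded_lifetimes)
    if np.isclose(mf, mu):
        raise ValueError("lifetime lines are parallel: no crossing")
    return float((bu - bf) / (mf - mu))


def delta_g_f_half(f_half_pn: float, params: WLCParams) -> float:
    """Equilibrium free energy from the coexistence force (kcal/mol).

    ΔG = F₁/₂ · Δx(F₁/₂) − W_s(F₁/₂), with the extension change taken
    from the class's WLC at F₁/₂ and the stretching work of the unfolded
    state subtracted.
    """
    from .constants import KCAL_MOL_PER_PN_NM
    if f_half_pn < 0:
        raise ValueError("F_1/2 must be >= 0")
    if f_half_pn == 0.0:
        return 0.0
    dx = wlc_extension(f_half_pn, params)
    return f_half_pn * dx * KCAL_MOL_PER_PN_NM - stretch_work(f_half_pn,
                                                              params)


def boltzmann_state_probabilities(energies, kt: float = 1.0) -> np.ndarray:
    """Normalized Boltzmann probabilities of conformer energies.

    P_i = exp(−G_i/kT) / Σ_j exp(−G_j/kT), computed stably via a
    log-sum-exp shift.  Energies and kT share any one unit (the Rosetta
    convention sets kT = 1 REU).
    """
    g = np.asarray(energies, dtype=float)
    if g.size == 0:
        raise ValueError("energies must be non-empty")
    if not np.all(np.isfinite(g)):
        raise ValueError("energies must be finite")
    if kt <= 0:
        raise ValueError("kT must be positive")
    logp = -g / kt
    return np.exp(logp - logsumexp(logp))


def delta_g_native(p_unknotted: float, p_knotted: float,
                   rt: float | None = None,
                   temperature: float = 298.15) -> float:
    """Native-state knotting free energy ΔG_N = −RT ln(P_unknotted/P_knotted).

    Inputs may be probabilities or raw molecule counts (only their ratio
    matters).  Positive when the knotted native state is the more
    populated (lower) one.
    """
    if p_unknotted <= 0 or p_knotted <= 0:
        raise ValueError("populations must be positive (zero counts give "
                         "an unbounded free energy)")
    rt = rt if rt is not None else rt_kcal(temperature)
    return float(-rt * np.log(p_unknotted / p_knotted))


def knotting_cost_cycle(dg_knotted: float, dg_unknotted: float,
                        dg_native: float, *, err_knotted: float = 0.0,
                        err_unknotted: float = 0.0,
                        err_native: float = 0.0) -> KnotCycle:
    """Close the thermodynamic cycle on the unfolded-state knotting cost.

    ΔG_U = ΔG_unfold(knotted) − ΔG_unfold(unknotted) − ΔG_N; input
    uncertainties propagate in quadrature.
    """
    dg_u = dg_knotted - dg_unknotted - dg_native
    err = float(np.sqrt(err_knotted**2 + err_unknotted**2 + err_native**2))
    return KnotCycle(dg_unfold_knotted=float(dg_knotted),
                     dg_unfold_unknotted=float(dg_unknotted),
                     dg_native=float(dg_native),
                     dg_unfolded_knotting=float(dg_u),
                     propagated_err=err)
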