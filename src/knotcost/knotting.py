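"""Monte Carlo estimation of the entropic knotting free energy ΔG_S.

The equilibrium fraction p of trefoil-knotted conformations in an
excluded-volume chain ensemble gives the free-energy cost of spontaneous
knot formation in the unfolded state,

    ΔG_S = −RT ln[p / (1 − p)],

which for p ≪ 1 is just −RT ln p.  Two ensembles are supported:

``ring`` (default)
    Equilibrium closed polygons sampled by hard-core crankshaft MCMC,
    the ensemble used in classical circular-DNA knotting calculations.
``open``
    I.i.d. open chains (dimerization sampling) whose knot type is
    assigned after closure at infinity; the closure scheme is a
    cross-checkable option.

Counts are converted to Wilson binomial intervals; for the ring ensemble
consecutive samples can be correlated, so the interval uses the number of
distinct knotting *events* (maximal runs of knotted samples) as the
effective count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from statsmodels.stats.proportion import proportion_confint

from . import _kernels
from .alexander import projection_directions
from .chains import ChainParams, SamplingBudgetError
from .constants import rt_kcal

__all__ = [
    "KnottingEstimate",
    "DiameterScan",
    "LengthScan",
    "ExtrapolationError",
    "knotting_probability",
    "delta_g_s",
    "scan_chain_length",
    "scan_diameter",
    "interpolate_effective_diameter",
]


class ExtrapolationError(ValueError):
    """Requested value lies outside the fitted/scanned range."""


@dataclass
class KnottingEstimate:
    """Knot census of one chain ensemble.

    ``n_knot`` maps class labels to counts; ``p_knot`` is the trefoil
    fraction (or the any-knot fraction when requested); ``ci95`` is a
    Wilson score interval; ``delta_g_s`` is −RT ln(p/(1−p)) with a
    delta-method standard error.  When no knot was observed,
    ``delta_g_s`` is +inf and ``delta_g_s_lower_bound`` holds the bound
    implied by the one-sided CI.
    """

    n_total: int
    n_knot: dict = field(default_factory=dict)
    n_events: int = 0
    p_knot: float = 0.0
    ci95: tuple = (0.0, 1.0)
    delta_g_s: float = np.inf
    delta_g_s_err: float = np.nan
    delta_g_s_lower_bound: float | None = None
    temperature: float = 298.15
    mean_rg: float = np.nan
    sem_rg: float = np.nan
    params: ChainParams | None = None
    ensemble: str = "ring"


def _wilson(k: int, n: int) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def _finish_estimate(est: KnottingEstimate) -> KnottingEstimate:
    """Fill ΔG_S and its error from the counts already in ``est``."""
    rt = rt_kcal(est.temperature)
    p = est.p_knot
    lo, hi = est.ci95
    if p <= 0.0:
        est.delta_g_s = np.inf
        est.delta_g_s_lower_bound = -rt * np.log(hi / (1.0 - hi)) if hi > 0 else np.inf
        return est
    if p >= 1.0:
        est.delta_g_s = -np.inf
        return est
    est.delta_g_s = -rt * np.log(p / (1.0 - p))
    # delta method through g(p) = -RT ln(p/(1-p)); sigma_p from the CI width
    sigma_p = (hi - lo) / (2.0 * 1.959964)
    est.delta_g_s_err = rt * sigma_p / (p * (1.0 - p))
    return est


def knotting_probability(params: ChainParams, n_samples: int,
                         seed: int | None = None, *,
                         ensemble: str = "ring",
                         closure: str = "infinity",
                         classify: str = "trefoil",
                         stride: int | None = None,
                         burn_in: int | None = None,
                         attempt_budget: int = 10**12) -> KnottingEstimate:
    """Estimate the equilibrium trefoil fraction and ΔG_S.

    Parameters
    ----------
    params:
        Chain geometry (N, Kuhn length, diameter, temperature).
    n_samples:
        Number of classified conformations.
    seed:
        Seed for the Monte Carlo stream (falls back to ``params.seed``).
    ensemble:
        "ring" for equilibrium closed polygons (crankshaft MCMC) or
        "open" for i.i.d. open chains closed post hoc.
    closure:
        Closure scheme for the open ensemble: "infinity" or "direct".
    classify:
        "trefoil" counts (|Δ(−1)|, |Δ(−2)|) = (3, 7) only; "any" counts
        every non-unknot class.
    stride, burn_in:
        Ring-MCMC decorrelation stride and burn-in in moves; defaults
        scale with chain length.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if params.n_segments < 3:
        raise ValueError("knotting requires >= 3 segments")
    if classify not in ("trefoil", "any"):
        raise ValueError("classify must be 'trefoil' or 'any'")
    seed = seed if seed is not None else (params.seed or 1)
    seed = int(seed) % (2**31 - 2) + 1
    # fixed, seed-derived projection direction pool for the whole census
    dirs = projection_directions(np.array([[float(seed), 0.0, 0.0]]), 16)

    n, l, d = params.n_segments, params.kuhn_length, params.diameter
    if ensemble == "ring":
        stride = stride if stride is not None else max(40, int(0.6 * n))
        burn_in = burn_in if burn_in is not None else 100 * n
        counts, events, nproj, rg_sum, rg2_sum, _ = _kernels.ring_census(
            n_samples, n, l, d, dirs, seed, stride, burn_in)
    elif ensemble == "open":
        mode = {"infinity": 0, "direct": 1}[closure]
        counts, nproj, rg_sum, rg2_sum, _ = _kernels.knot_census(
            n_samples, n, l, d, dirs, seed, attempt_budget, mode)
        if counts[0] < 0:
            raise SamplingBudgetError(
                f"attempt budget exhausted at N={n}, D={d}")
        events = None
    else:
        raise ValueError(f"unknown ensemble: {ensemble!r}")

    n_unknot, n_trefoil, n_other = (int(c) for c in counts)
    total = n_unknot + n_trefoil + n_other
    k = n_trefoil if classify == "trefoil" else n_trefoil + n_other
    if ensemble == "open":
        events = k
    # correlated ring samples: base the interval on distinct knot events
    if k > 0 and events < k:
        n_eff = max(int(round(total * events / k)), events)
        lo, hi = _wilson(events, n_eff)
    else:
        lo, hi = _wilson(k, total)
    mean_rg = rg_sum / total
    sem_rg = np.sqrt(max(rg2_sum / total - mean_rg**2, 0.0) / total)
    est = KnottingEstimate(
        n_total=total,
        n_knot={"unknot": n_unknot, "trefoil": n_trefoil, "other": n_other},
        n_events=int(events),
        p_knot=k / total,
        ci95=(lo, hi),
        temperature=params.temperature,
        mean_rg=float(mean_rg),
        sem_rg=float(sem_rg),
        params=params,
        ensemble=ensemble,
    )
    return _finish_estimate(est)


def delta_g_s(estimate, temperature: float | None = None) -> float:
    """Entropic knotting free energy −RT ln(p/(1−p)) in kcal/mol.

    ``estimate`` may be a :class:`KnottingEstimate` or a plain knot
    fraction.  Raises for p in {0, 1}, where the odds are unbounded.
    """
    if isinstance(estimate, KnottingEstimate):
        p = estimate.p_knot
        temperature = temperature or estimate.temperature
    else:
        p = float(estimate)
        temperature = temperature or 298.15
    if not 0.0 < p < 1.0:
        raise ValueError("knot fraction must lie strictly in (0, 1); "
                         "the free energy is unbounded at the endpoints")
    return float(-rt_kcal(temperature) * np.log(p / (1.0 - p)))


@dataclass
class LengthScan:
    """ΔG_S versus chain length, with an exponential fit A·exp(−N/N0)
    valid only on the sampled interval."""

    table: pd.DataFrame
    estimates: list
    fit_amplitude: float = np.nan
    fit_decay_n: float = np.nan
    n_range: tuple = (np.nan, np.nan)

    def predict(self, n: float) -> float:
        lo, hi = self.n_range
        if not lo <= n <= hi:
            raise ExtrapolationError(
                f"N={n} outside the sampled interval [{lo}, {hi}]")
        return float(self.fit_amplitude * np.exp(-n / self.fit_decay_n))


def _estimates_to_table(estimates, xkey, xvals) -> pd.DataFrame:
    rows = []
    for x, est in zip(xvals, estimates):
        rows.append({
            xkey: x,
            "n": est.n_total,
            "n_trefoil": est.n_knot["trefoil"],
            "n_other": est.n_knot["other"],
            "n_events": est.n_events,
            "p_knot": est.p_knot,
            "ci_lo": est.ci95[0],
            "ci_hi": est.ci95[1],
            "dG_S": est.delta_g_s,
            "dG_S_err": est.delta_g_s_err,
            "mean_rg": est.mean_rg,
        })
    return pd.DataFrame(rows)


def scan_chain_length(lengths, diameter: float, n_samples, seed: int = 1, *,
                      kuhn_length: float = 1.4, temperature: float = 298.15,
                      ensemble: str = "ring", **kw) -> LengthScan:
    """ΔG_S as a function of the number of Kuhn segments N.

    ``n_samples`` may be a single count or one count per length.  Fits
    ΔG_S(N) = A exp(−N/N0) over lengths with a finite estimate; the fit
    is only valid (and only evaluated) on the sampled interval.
    """
    lengths = list(lengths)
    if any(n < 3 for n in lengths):
        raise ValueError("all chain lengths must be >= 3 segments")
    if np.isscalar(n_samples):
        n_samples = [int(n_samples)] * len(lengths)
    estimates = []
    for i, (n, ns) in enumerate(zip(lengths, n_samples)):
        params = ChainParams(n_segments=int(n), kuhn_length=kuhn_length,
                             diameter=diameter, temperature=temperature)
        estimates.append(knotting_probability(
            params, ns, seed=seed + 7919 * i, ensemble=ensemble, **kw))
    table = _estimates_to_table(estimates, "N", lengths)
    scan = LengthScan(table=table, estimates=estimates)
    ok = np.isfinite(table["dG_S"].to_numpy(dtype=float))
    if ok.sum() >= 2:
        x = table.loc[ok, "N"].to_numpy(dtype=float)
        y = table.loc[ok, "dG_S"].to_numpy(dtype=float)
        err = table.loc[ok, "dG_S_err"].to_numpy(dtype=float)
        try:
            popt, _ = curve_fit(lambda n, a, n0: a * np.exp(-n / n0),
                                x, y, p0=(y.max(), x.max()), sigma=err,
                                maxfev=10000)
            scan.fit_amplitude, scan.fit_decay_n = map(float, popt)
            scan.n_range = (float(x.min()), float(x.max()))
        except RuntimeError:
            pass
    return scan


@dataclass
class DiameterScan:
    """ΔG_S versus relative diameter D/2P with a weighted linear fit."""

    table: pd.DataFrame
    estimates: list
    slope: float = np.nan
    intercept: float = np.nan
    cov: np.ndarray | None = None

    def predict(self, d_over_2p: float) -> float:
        return float(self.intercept + self.slope * d_over_2p)

    def confidence_band(self, d_over_2p, alpha: float = 0.05):
        """Half-width of the (1−alpha) confidence band of the fitted line."""
        from scipy.stats import norm
        x = np.asarray(d_over_2p, dtype=float)
        var = (self.cov[0, 0] + 2 * x * self.cov[0, 1]
               + x**2 * self.cov[1, 1])
        return norm.ppf(1 - alpha / 2) * np.sqrt(var)


def scan_diameter(d_over_2p_values, n_segments: int, n_samples,
                  seed: int = 1, *, kuhn_length: float = 1.4,
                  temperature: float = 298.15, ensemble: str = "ring",
                  **kw) -> DiameterScan:
    """ΔG_S at fixed N over a strictly increasing grid of D/2P values.

    Fits ΔG_S = a + b·(D/2P) by weighted least squares (weights from the
    per-point delta-method errors).
    """
    xs = [float(x) for x in d_over_2p_values]
    if any(b <= a for a, b in zip(xs, xs[1:])):
        raise ValueError("d_over_2p values must be strictly increasing")
    if np.isscalar(n_samples):
        n_samples = [int(n_samples)] * len(xs)
    estimates = []
    for i, (x, ns) in enumerate(zip(xs, n_samples)):
        params = ChainParams(n_segments=n_segments, kuhn_length=kuhn_length,
                             diameter=x * kuhn_length,
                             temperature=temperature)
        estimates.append(knotting_probability(
            params, ns, seed=seed + 104729 * i, ensemble=ensemble, **kw))
    table = _estimates_to_table(estimates, "d_over_2p", xs)
    scan = DiameterScan(table=table, estimates=estimates)
    ok = np.isfinite(table["dG_S"].to_numpy(dtype=float))
    if ok.sum() >= 3:
        import statsmodels.api as sm
        x = table.loc[ok, "d_over_2p"].to_numpy(dtype=float)
        y = table.loc[ok, "dG_S"].to_numpy(dtype=float)
        err = table.loc[ok, "dG_S_err"].to_numpy(dtype=float)
        res = sm.WLS(y, sm.add_constant(x), weights=1.0 / err**2).fit()
        scan.intercept, scan.slope = map(float, res.params)
        # absolute-sigma covariance: the per-point errors are known
        # (delta-method), so (X' W X)^-1 is used without rescaling by
        # the estimated residual variance
        scan.cov = np.asarray(res.normalized_cov_params)
    return scan


def interpolate_effective_diameter(scan: DiameterScan,
                                   target_dg: float) -> tuple[float, tuple]:
    """Solve the fitted ΔG_S(D/2P) line for a target free energy.

    Returns the relative diameter and a 95% CI propagated from the fit
    covariance.  Raises :class:`ExtrapolationError` when the target lies
    outside the scanned free-energy range.
    """
    if scan.cov is None or not np.isfinite(scan.slope):
        raise ValueError("scan has no valid linear fit (need >= 3 rows)")
    y = scan.table["dG_S"].to_numpy(dtype=float)
    y = y[np.isfinite(y)]
    ylo, yhi = y.min(), y.max()
    if not min(ylo, yhi) <= target_dg <= max(ylo, yhi):
        raise ExtrapolationError(
            f"target ΔG_S={target_dg} outside the scanned range "
            f"[{ylo:.2f}, {yhi:.2f}]")
    x = (target_dg - scan.intercept) / scan.slope
    # delta method: x = (dg − a)/b, ∂x/∂a = −1/b, ∂x/∂b = −x/b
    va = scan.cov[0, 0]
    vb = scan.cov[1, 1]
    vab = scan.cov[0, 1]
    var_x = (va + 2 * x * vab + x * x * vb) / scan.slope**2
    half = 1.959964 * np.sqrt(max(var_x, 0.0))
    return float(x), (float(x - half), float(x + half))
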