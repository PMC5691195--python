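"""Force-dependent rate models and rupture-force analysis.

Unfolding under a force ramp is a first-passage problem with a
force-dependent rate.  Two rate laws are supported:

* Bell: k(F) = k₀ exp(F·Δx‡ / kT)
* Dudko–Hummer–Szabo (DHS):
  k(F) = k₀ (1 − νFΔx‡/ΔG‡)^{1/ν−1} exp{(ΔG‡/kT)[1 − (1 − νFΔx‡/ΔG‡)^{1/ν}]}
  with shape ν = 1/2 (cusp) or 2/3 (linear-cubic); ν = 1 recovers Bell
  exactly and ΔG‡ → ∞ recovers it asymptotically.

Refolding on a decreasing ramp uses the same laws with the negative-Δx
convention (the rate grows as the force drops).  Rupture-force
histograms are converted to rate estimates by the standard
histogram transformation  k(F_i) = r(F_i) · h(F_i) / S(F_i),  where h is
the rupture-force density, S the survival fraction and r the loading
rate, and models are fitted to the resulting (F, k) tables by weighted
least squares on ln k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .cluster import histogram_bins
from .constants import DEFAULT_TEMPERATURE, PN_NM_PER_KCAL_MOL, kt_pn_nm
from .wlc import WLCParams, wlc_extension

log = logging.getLogger(__name__)

__all__ = [
    "KineticModel", "LoadingProtocol", "NonConvergenceError",
    "bell_rate", "dhs_rate", "loading_rate",
    "rates_from_force_histogram", "fit_kinetic_model",
    "simulate_rupture_forces",
]


class NonConvergenceError(RuntimeError):
    """A nonlinear kinetic fit failed to converge."""


@dataclass(frozen=True)
class KineticModel:
    """Parameters of a force-dependent rate law.

    ``dx_ddagger`` (nm) is positive for unfolding (rate accelerates with
    force) and negative for refolding against force.  ``dg_ddagger``
    (kcal/mol) and ``nu`` are DHS-only; a model with ``dg_ddagger=None``
    is Bell-type.
    """

    k0: float
    dx_ddagger: float
    dg_ddagger: float | None = None
    nu: float = 0.5
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")
        if self.dg_ddagger is not None:
            if self.dg_ddagger <= 0:
                raise ValueError("DHS barrier height must be positive")
            if not 0 < self.nu <= 1:
                raise ValueError("DHS shape nu must lie in (0, 1]")

    @property
    def is_dhs(self) -> bool:
        return self.dg_ddagger is not None


@dataclass(frozen=True)
class LoadingProtocol:
    """Constant-speed force-ramp protocol.

    The effective loading rate is ``pulling_speed × effective_stiffness``
    in the constant-rate approximation; with a WLC supplied, the chain
    compliance is put in series with the trap (see :func:`loading_rate`).
    """

    pulling_speed: float = 100.0          # nm/s
    effective_stiffness: float = 0.1      # pN/nm
    force_window: tuple = (2.0, 30.0)     # pN

    def __post_init__(self) -> None:
        if self.pulling_speed <= 0 or self.effective_stiffness <= 0:
            raise ValueError("speed and stiffness must be positive")
        if self.force_window[0] >= self.force_window[1]:
            raise ValueError("force window must be increasing")


def bell_rate(force, model: KineticModel):
    """Bell rate k(F) = k₀ exp(F Δx‡ / kT), s⁻¹."""
    f = np.asarray(force, dtype=float)
    kt = kt_pn_nm(model.temperature)
    out = model.k0 * np.exp(f * model.dx_ddagger / kt)
    return float(out) if np.isscalar(force) else out


def dhs_rate(force, model: KineticModel):
    """Dudko–Hummer–Szabo rate, s⁻¹; domain ends at the critical force."""
    if not model.is_dhs:
        raise ValueError("model has no barrier height; use bell_rate")
    f = np.asarray(force, dtype=float)
    kt = kt_pn_nm(model.temperature)
    dg = model.dg_ddagger * PN_NM_PER_KCAL_MOL  # to pN nm
    nu = model.nu
    arg = 1.0 - nu * f * model.dx_ddagger / dg
    if np.any(arg <= 0):
        raise ValueError("force at or beyond the DHS critical force")
    out = (model.k0 * arg ** (1.0 / nu - 1.0)
           * np.exp(dg / kt * (1.0 - arg ** (1.0 / nu))))
    return float(out) if np.isscalar(force) else out


def rate(force, model: KineticModel):
    """Dispatch to the Bell or DHS law according to the model."""
    return dhs_rate(force, model) if model.is_dhs else bell_rate(force, model)


def loading_rate(force, protocol: LoadingProtocol,
                 wlc: WLCParams | None = None):
    """Loading rate r(F) in pN/s.

    Without a WLC this is the constant ``speed × stiffness``.  With one,
    the unfolded-chain compliance dx/dF is placed in series with the
    trap: r(F) = v / (1/k_trap + dx_wlc/dF).
    """
    f = np.asarray(force, dtype=float)
    if wlc is None:
        out = np.full_like(f, protocol.pulling_speed
                           * protocol.effective_stiffness)
        return float(out) if np.isscalar(force) else out
    eps = 1e-4
    dxdf = np.array([(wlc_extension(fi + eps, wlc)
                      - wlc_extension(max(fi - eps, 0.0), wlc))
                     / (eps + min(fi, eps)) for fi in np.atleast_1d(f)])
    out = protocol.pulling_speed / (1.0 / protocol.effective_stiffness + dxdf)
    return float(out[0]) if np.isscalar(force) else out


def rates_from_force_histogram(rip_forces, protocol: LoadingProtocol, *,
                               direction: str = "unfold",
                               wlc: WLCParams | None = None,
                               n_bins: int | None = None) -> pd.DataFrame:
    """Transform a rupture-force histogram into rate estimates.

    Per bin i (width w, count n_i, N total):

        k(F_i) = r(F_i) · n_i / (w · N · S_i)

    with the survival fraction S_i of molecules that have not yet made
    the transition at the bin centre — those with larger rupture force
    for unfolding (rising ramp), smaller for refolding (falling ramp).
    Empty bins are dropped with a logged warning.  The default bin count
    follows the 3 + log₂N rule.
    """
    forces = np.sort(np.asarray(rip_forces, dtype=float))
    if forces.size < 30:
        raise ValueError("need at least 30 rupture forces")
    if direction not in ("unfold", "fold"):
        raise ValueError("direction must be 'unfold' or 'fold'")
    nb = n_bins if n_bins is not None else histogram_bins(forces.size)
    counts, edges = np.histogram(forces, bins=nb)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = edges[1] - edges[0]
    n_total = forces.size
    rows = []
    cum = np.cumsum(counts)
    for i, (c, fc) in enumerate(zip(counts, centers)):
        if c == 0:
            log.warning("dropping empty force bin at %.2f pN", fc)
            continue
        if direction == "unfold":
            surv = (n_total - cum[i] + 0.5 * c) / n_total
        else:
            surv = (cum[i] - 0.5 * c) / n_total
        r = loading_rate(fc, protocol, wlc)
        k = r * (c / (w * n_total)) / surv
        # Poisson bin count drives the uncertainty of ln k
        rows.append({"force_pN": fc, "k_per_s": k,
                     "se_ln_k": 1.0 / np.sqrt(c), "n_in_bin": int(c)})
    return pd.DataFrame(rows)


def fit_kinetic_model(rate_table: pd.DataFrame, model_kind: str = "bell", *,
                      nu: float = 0.5,
                      temperature: float = DEFAULT_TEMPERATURE,
                      direction: str = "unfold"):
    """Fit a rate law to an (F, k) table by weighted least squares on ln k.

    Bell fits are linear (exact); DHS fits hold ν fixed and optimize
    (k₀, Δx‡, ΔG‡) — narrow force windows make a free ν ill-conditioned.
    Returns (KineticModel, dict of 1σ standard errors).
    """
    f = rate_table["force_pN"].to_numpy(dtype=float)
    k = rate_table["k_per_s"].to_numpy(dtype=float)
    if f.size < 3:
        raise ValueError("need at least 3 rate points")
    se = (rate_table["se_ln_k"].to_numpy(dtype=float)
          if "se_ln_k" in rate_table else np.ones_like(f))
    wgt = 1.0 / se**2
    kt = kt_pn_nm(temperature)
    lnk = np.log(k)
    sign = 1.0 if direction == "unfold" else -1.0

    if model_kind == "bell":
        # weighted linear regression lnk = b0 + b1 F
        sw = np.sqrt(wgt)
        X = np.column_stack([np.ones_like(f), f])
        beta, *_ = np.linalg.lstsq(X * sw[:, None], lnk * sw, rcond=None)
        cov = np.linalg.inv(X.T @ (wgt[:, None] * X))
        model = KineticModel(k0=float(np.exp(beta[0])),
                             dx_ddagger=float(beta[1] * kt),
                             temperature=temperature)
        errs = {"ln_k0": float(np.sqrt(cov[0, 0])),
                "dx_ddagger": float(np.sqrt(cov[1, 1]) * kt)}
        return model, errs

    if model_kind != "dhs":
        raise ValueError("model_kind must be 'bell' or 'dhs'")

    def _ln_dhs(force, ln_k0, dx, dg_kcal):
        dg = dg_kcal * PN_NM_PER_KCAL_MOL
        arg = 1.0 - nu * force * (sign * dx) / dg
        arg = np.maximum(arg, 1e-9)
        return (ln_k0 + (1.0 / nu - 1.0) * np.log(arg)
                + dg / kt * (1.0 - arg ** (1.0 / nu)))

    p0 = (float(lnk[0]), 1.0, 10.0)
    try:
        popt, pcov = curve_fit(_ln_dhs, f, lnk, p0=p0, sigma=se,
                               absolute_sigma=True, maxfev=20000)
    except RuntimeError as exc:
        raise NonConvergenceError(f"DHS fit did not converge: {exc}") from exc
    if not np.all(np.isfinite(pcov)):
        raise NonConvergenceError("DHS fit covariance is singular")
    model = KineticModel(k0=float(np.exp(popt[0])),
                         dx_ddagger=float(sign * popt[1]),
                         dg_ddagger=float(popt[2]), nu=nu,
                         temperature=temperature)
    perr = np.sqrt(np.diag(pcov))
    errs = {"ln_k0": float(perr[0]), "dx_ddagger": float(perr[1]),
            "dg_ddagger": float(perr[2])}
    return model, errs


def simulate_rupture_forces(model: KineticModel, protocol: LoadingProtocol,
                            n: int, seed=None, *,
                            direction: str = "unfold",
                            wlc: WLCParams | None = None,
                            grid_size: int = 2000) -> np.ndarray:
    """First-passage sampling of transition forces under a force ramp.

    The time-inhomogeneous hazard k(F(t)) is integrated on a force grid
    into the cumulative hazard Λ(F); inverse-CDF sampling maps uniform
    deviates onto transition forces.  Unfolding runs up the ramp from
    the lower window edge, refolding down from the upper edge.  Forces
    that survive the whole window are clipped to its far edge.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    f_lo, f_hi = protocol.force_window
    grid = np.linspace(f_lo, f_hi, grid_size)
    if model.is_dhs:
        dg = model.dg_ddagger * PN_NM_PER_KCAL_MOL
        f_crit = dg / (model.nu * abs(model.dx_ddagger))
        grid = grid[grid < 0.999 * f_crit]
        if grid.size < 2:
            raise ValueError("force window lies beyond the DHS critical "
                             "force")
    k_grid = rate(grid, model)
    r_grid = np.abs(loading_rate(grid, protocol, wlc))
    haz = k_grid / r_grid
    if direction == "unfold":
        lam = np.concatenate([[0.0], np.cumsum(
            0.5 * (haz[1:] + haz[:-1]) * np.diff(grid))])
        x_axis = grid
    elif direction == "fold":
        # integrate downward from the top of the window
        lam = np.concatenate([[0.0], np.cumsum(
            0.5 * (haz[::-1][1:] + haz[::-1][:-1]) * np.diff(grid))])
        x_axis = grid[::-1]
    else:
        raise ValueError("direction must be 'unfold' or 'fold'")
    targets = -np.log(rng.uniform(size=n))
    out = np.interp(targets, lam, x_axis,
                    left=x_axis[0], right=x_axis[-1])
    return out
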