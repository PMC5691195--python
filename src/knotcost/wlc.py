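"""Worm-like-chain mechanics for single-molecule pulling records.

Force–extension behavior of the unfolded polypeptide follows the
Marko–Siggia interpolation formula

    F(x) = (kT/P) [ 1/(4 (1 − x/L_c)^2) − 1/4 + x/L_c ],

with persistence length P (0.65 nm for unfolded protein, held fixed) and
contour length L_c (0.35 nm per residue).  The module provides the force
law and its numerical inverse, contour-length estimation from rips, the
reversible stretching work W_s, the rectangle-rule observed rip work
W_obs = F·Δx (in which the DNA-handle stretching work cancels), and the
zero-force work W^(F=0) = W_obs − W_s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from .constants import (DEFAULT_TEMPERATURE, KCAL_MOL_PER_PN_NM,
                        NM_PER_RESIDUE, kt_pn_nm)

__all__ = [
    "WLCParams", "Rip", "ContourEstimate", "WorkRecord",
    "wlc_force", "wlc_extension", "theoretical_contour_length",
    "experimental_contour_length", "stretch_work", "observed_work",
    "work_at_zero_force", "detect_rips",
]


@dataclass(frozen=True)
class WLCParams:
    """Worm-like chain parameters (nm, K)."""

    persistence_length: float = 0.65
    contour_length: float = 42.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.persistence_length <= 0 or self.contour_length <= 0:
            raise ValueError("lengths must be positive")
        if self.persistence_length >= self.contour_length:
            raise ValueError("persistence length must be < contour length")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class Rip:
    """One unfolding or refolding transition in a pulling cycle."""

    force: float            # transition force, pN
    delta_x: float          # molecular extension change, nm
    direction: str          # "unfold" | "fold"
    molecule_id: str = ""
    cycle_index: int = 0

    def __post_init__(self) -> None:
        if self.force < 0:
            raise ValueError("force must be >= 0")
        if self.delta_x <= 0:
            raise ValueError("delta_x must be positive")
        if self.direction not in ("unfold", "fold"):
            raise ValueError("direction must be 'unfold' or 'fold'")


@dataclass
class ContourEstimate:
    """Per-rip experimental contour lengths and their summary."""

    values: np.ndarray

    @property
    def l_c_exp(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


@dataclass(frozen=True)
class WorkRecord:
    """Work bookkeeping for one rip, all in kcal/mol.

    ``w_zero`` is the work extrapolated to zero force,
    W^(F=0) = W_obs − W_s.
    """

    w_obs: float
    w_s: float
    direction: str

    @property
    def w_zero(self) -> float:
        return self.w_obs - self.w_s


def wlc_force(extension: float, params: WLCParams) -> float:
    """Marko–Siggia force (pN) at a given extension (nm)."""
    x = float(extension)
    lc = params.contour_length
    if x < 0:
        raise ValueError("extension must be >= 0")
    if x >= lc:
        raise ValueError("extension must be below the contour length "
                         "(WLC force diverges)")
    r = x / lc
    kt_over_p = kt_pn_nm(params.temperature) / params.persistence_length
    return kt_over_p * (0.25 / (1.0 - r) ** 2 - 0.25 + r)


def wlc_extension(force: float, params: WLCParams) -> float:
    """Extension (nm) at a given force (pN); inverse of :func:`wlc_force`.

    The force law is strictly monotone, so the root is unique; solved by
    bracketing to 1e-12 relative tolerance.
    """
    f = float(force)
    if f < 0:
        raise ValueError("force must be >= 0")
    if f == 0.0:
        return 0.0
    lc = params.contour_length
    return brentq(lambda x: wlc_force(x, params) - f,
                  0.0, lc * (1.0 - 1e-12), rtol=1e-12, maxiter=200)


def theoretical_contour_length(n_residues: int,
                               nm_per_residue: float = NM_PER_RESIDUE) -> float:
    """Contour length (nm) of a fully extended polypeptide."""
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    return n_residues * nm_per_residue


def experimental_contour_length(rip, params: WLCParams,
                                delta_x: float | None = None) -> float:
    """Contour length inferred from one rip.

    The measured extension change Δx_exp is compared with the change
    Δx_theoretical predicted by the WLC (with the theoretical contour
    length, ``params.contour_length``) at the rip force:

        L_c,exp = (Δx_exp / Δx_theoretical) · L_c,theoretical

    ``rip`` may be a :class:`Rip` or a bare force in pN (then ``delta_x``
    must be given).
    """
    if isinstance(rip, Rip):
        force, dx_exp = rip.force, rip.delta_x
    else:
        force, dx_exp = float(rip), float(delta_x)
    if force <= 0:
        raise ValueError("rip force must be positive")
    dx_theory = wlc_extension(force, params)
    return (dx_exp / dx_theory) * params.contour_length


def stretch_work(force: float, params: WLCParams) -> float:
    """Reversible work W_s (kcal/mol) to stretch the unfolded chain.

    Integrates the WLC force law from zero extension to the extension at
    ``force`` by adaptive quadrature (relative tolerance 1e-10).
    """
    f = float(force)
    if f < 0:
        raise ValueError("force must be >= 0")
    if f == 0.0:
        return 0.0
    x_end = wlc_extension(f, params)
    w_pn_nm, _ = quad(lambda x: wlc_force(x, params), 0.0, x_end,
                      epsrel=1e-10, limit=200)
    return w_pn_nm * KCAL_MOL_PER_PN_NM


def observed_work(rip: Rip) -> float:
    """Rectangle-rule rip work W_obs = F·Δx in kcal/mol.

    The rectangle spans the extension change at the transition force, so
    the work of stretching the DNA handles cancels.
    """
    return rip.force * rip.delta_x * KCAL_MOL_PER_PN_NM


def work_at_zero_force(rip: Rip, params: WLCParams) -> WorkRecord:
    """Observed work corrected to zero force: W^(F=0) = W_obs − W_s."""
    return WorkRecord(w_obs=observed_work(rip),
                      w_s=stretch_work(rip.force, params),
                      direction=rip.direction)


def detect_rips(trace: pd.DataFrame, *, min_force_jump: float = 1.0,
                max_jump_points: int = 3) -> list[Rip]:
    """Locate two-state transitions in force–extension records.

    ``trace`` needs columns ``time_s``, ``extension_nm``, ``force_pN``,
    ``ramp_id`` and ``direction`` ("pull" or "relax"); comment headers
    should be stripped by the reader.  Within each ramp the largest force
    discontinuity of the right sign (drop on pull, jump on relax)
    exceeding ``min_force_jump`` within ``max_jump_points`` samples is
    reported as one rip; ramps without such a discontinuity yield none.
    """
    required = {"extension_nm", "force_pN", "ramp_id", "direction"}
    missing = required - set(trace.columns)
    if missing:
        raise ValueError(f"trace is missing columns: {sorted(missing)}")
    rips: list[Rip] = []
    for (ramp_id, direction), g in trace.groupby(["ramp_id", "direction"],
                                                 sort=True):
        f = g["force_pN"].to_numpy(dtype=float)
        x = g["extension_nm"].to_numpy(dtype=float)
        if len(f) < max_jump_points + 1:
            continue
        sign = -1.0 if direction == "pull" else 1.0
        best, best_i = 0.0, None
        for w in range(1, max_jump_points + 1):
            jump = sign * (f[w:] - f[:-w])
            i = int(np.argmax(jump))
            if jump[i] > best:
                best, best_i, best_w = jump[i], i, w
        if best_i is None or best < min_force_jump:
            continue
        i, w = best_i, best_w
        mol, cyc = str(ramp_id), 0
        if "molecule_id" in g.columns:
            mol = str(g["molecule_id"].iloc[0])
        if "cycle" in g.columns:
            cyc = int(g["cycle"].iloc[0])
        # transition force: the branch force just before the discontinuity
        # (the force drops on unfolding and rises on refolding)
        rips.append(Rip(force=float(max(f[i], 0.0)),
                        delta_x=float(abs(x[i + w] - x[i])),
                        direction="unfold" if direction == "pull" else "fold",
                        molecule_id=mol, cycle_index=cyc))
    return rips
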