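"""Excluded-volume freely-jointed chains at Kuhn-segment resolution.

The unfolded polypeptide is modeled as a chain of N rigid segments of one
Kuhn length each, with hard-cylinder excluded volume: two non-adjacent
segments may not approach closer (midline to midline) than the effective
chain diameter D.  Open chains are sampled i.i.d. by dimerization
(equivalent to rejection sampling); equilibrium closed polygons are
sampled by crankshaft Markov-chain Monte Carlo (see
:func:`knotcost.knotting.knotting_probability`).

A chain of ``n`` segments is represented as an ``(n+1, 3)`` float array of
vertex positions in nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .constants import DEFAULT_TEMPERATURE

__all__ = [
    "ChainParams",
    "SamplingBudgetError",
    "generate_chain",
    "generate_ensemble",
    "sample_open_mcmc",
    "has_overlap",
    "close_chain",
    "radius_of_gyration",
    "bond_lengths",
]


class SamplingBudgetError(RuntimeError):
    """Raised when the sampler cannot produce a non-overlapping chain
    within its attempt budget."""


@dataclass(frozen=True)
class ChainParams:
    """Parameters of the excluded-volume freely-jointed chain.

    Attributes
    ----------
    n_segments:
        Number of Kuhn segments N (>= 3 for knotting work; >= 1 allowed
        for plain chain generation).
    kuhn_length:
        Kuhn (statistical segment) length in nm; 1.4 nm ~ 3.7 residues
        for an unfolded polypeptide.
    diameter:
        Effective hard-cylinder diameter D in nm; 0 gives a phantom
        chain.
    temperature:
        Absolute temperature in K (used when converting knot fractions
        to free energies).
    seed:
        Optional master seed for reproducible ensembles.
    """

    n_segments: int
    kuhn_length: float = 1.4
    diameter: float = 0.49
    temperature: float = DEFAULT_TEMPERATURE
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.kuhn_length <= 0:
            raise ValueError("kuhn_length must be positive")
        if not 0 <= self.diameter < self.kuhn_length:
            raise ValueError("diameter must satisfy 0 <= D < kuhn_length")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def d_over_2p(self) -> float:
        """Relative chain diameter D/2P with the Kuhn length as 2P."""
        return self.diameter / self.kuhn_length


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def generate_chain(params: ChainParams, rng=None,
                   attempt_budget: int = 10**9) -> np.ndarray:
    """Sample one open excluded-volume chain.

    Bond directions are isotropic and bond lengths exactly
    ``kuhn_length``; for ``diameter > 0`` the returned chain satisfies
    the hard-cylinder constraint.  Sampling is by dimerization, which
    draws from the same uniform self-avoiding ensemble as naive
    rejection sampling.

    Raises
    ------
    SamplingBudgetError
        If no valid chain is produced within ``attempt_budget``
        sub-chain attempts.
    """
    rng = _rng(params.seed if rng is None else rng)
    verts = np.empty((params.n_segments + 1, 3))
    counter = np.zeros(1, dtype=np.int64)
    np.random.seed(_kernel_seed(rng))  # numba kernels use the legacy state
    ok = _kernels._dimerize(verts, params.n_segments, params.kuhn_length,
                            params.diameter, counter, attempt_budget)
    if not ok:
        raise SamplingBudgetError(
            f"no self-avoiding chain within {attempt_budget} attempts "
            f"(N={params.n_segments}, D={params.diameter})")
    return verts


def generate_ensemble(params: ChainParams, n_samples: int,
                      rng=None) -> np.ndarray:
    """Sample ``n_samples`` i.i.d. open chains; shape (n, N+1, 3)."""
    rng = _rng(params.seed if rng is None else rng)
    out = np.empty((n_samples, params.n_segments + 1, 3))
    for i in range(n_samples):
        out[i] = generate_chain(params, rng)
    return out


def sample_open_mcmc(params: ChainParams, n_samples: int, rng=None,
                     stride: int = 50, burn_in: int = 2000) -> np.ndarray:
    """Sample open chains by Metropolis crankshaft/pivot moves.

    Cross-check sampler for :func:`generate_ensemble`: both target the
    uniform hard-cylinder ensemble, but these samples are correlated
    (decorrelation stride ``stride`` moves).  Starts from a freshly
    rejection-sampled chain, so no equilibration bias at any stride.
    """
    rng = _rng(params.seed if rng is None else rng)
    verts = generate_chain(params, rng)
    out = np.empty((n_samples, params.n_segments + 1, 3))
    _kernels.mcmc_sweeps(verts, params.diameter, burn_in, _kernel_seed(rng))
    for i in range(n_samples):
        _kernels.mcmc_sweeps(verts, params.diameter, stride,
                             _kernel_seed(rng))
        out[i] = verts
    return out


def has_overlap(chain: np.ndarray, diameter: float) -> bool:
    """True iff any non-adjacent segment pair is closer than ``diameter``.

    Adjacent segments (sharing a vertex) are exempt; distance is the
    3-D minimum distance between segment midlines.
    """
    chain = np.ascontiguousarray(chain, dtype=np.float64)
    if diameter <= 0:
        return False
    return bool(_kernels._has_overlap(chain, diameter))


def close_chain(chain: np.ndarray, mode: str = "infinity") -> np.ndarray:
    """Close an open chain into a polygon whose knot type is assigned to it.

    mode="infinity" (default) extends each terminus radially away from
    the chain centroid to a far sphere and joins the rays there, which
    minimizes spurious knotting and is deterministic given the chain;
    mode="direct" joins the termini with a single chord.  Chains whose
    termini already coincide are returned as the polygon over their
    distinct vertices.
    """
    chain = np.ascontiguousarray(chain, dtype=np.float64)
    if mode == "direct":
        if np.allclose(chain[0], chain[-1]):
            return chain[:-1].copy()
        return chain.copy()
    if mode != "infinity":
        raise ValueError(f"unknown closure mode: {mode!r}")
    out = np.empty((chain.shape[0] + 3, 3))
    nv = _kernels._close_at_infinity(chain, out)
    return out[:nv].copy()


def radius_of_gyration(ensemble: np.ndarray) -> tuple[float, float]:
    """Ensemble mean and standard error of the radius of gyration.

    Rg of one chain is the root-mean-square vertex distance from the
    chain centroid.  ``ensemble`` is (n_chains, n_vertices, 3) or a
    single (n_vertices, 3) chain.
    """
    ensemble = np.asarray(ensemble, dtype=np.float64)
    if ensemble.ndim == 2:
        ensemble = ensemble[None]
    if ensemble.shape[0] == 0:
        raise ValueError("empty ensemble")
    centred = ensemble - ensemble.mean(axis=1, keepdims=True)
    rg = np.sqrt((centred**2).sum(axis=2).mean(axis=1))
    sem = rg.std(ddof=1) / np.sqrt(len(rg)) if len(rg) > 1 else 0.0
    return float(rg.mean()), float(sem)


def bond_lengths(chain: np.ndarray) -> np.ndarray:
    """Lengths of consecutive bonds (for invariant checks)."""
    chain = np.asarray(chain, dtype=np.float64)
    return np.linalg.norm(np.diff(chain, axis=0), axis=1)
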