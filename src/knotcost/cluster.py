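"""Biphasic (two-step) clustering of paired refolding/unfolding forces.

Each pulling cycle contributes one (F_R, F_U) point in the plane.  The
two-step procedure first preclusters nearby points greedily, then merges
the preclusters by centroid-linkage agglomeration until one element
remains; cutting the merge sequence at k = 2 separates the two molecule
classes.  Distances are plain Euclidean in pN (both axes share units, so
no feature scaling is applied).

Centroid linkage can produce inversions (a later merge at a smaller
distance); they are detected and logged, and cluster cuts use merge
order, never merge height.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["ForcePair", "Precluster", "Dendrogram", "histogram_bins",
           "precluster", "agglomerate", "cluster_force_pairs",
           "gmm_crosscheck"]


@dataclass(frozen=True)
class ForcePair:
    """One refolding/unfolding force pair (pN)."""

    f_refold: float
    f_unfold: float
    molecule_id: str = ""
    label: str | None = None  # optional ground truth for synthetic data

    def __post_init__(self) -> None:
        if self.f_refold <= 0 or self.f_unfold <= 0:
            raise ValueError("forces must be positive")


@dataclass
class Precluster:
    """A group of nearby points with its running centroid."""

    indices: list = field(default_factory=list)
    centroid: np.ndarray = None
    _sum: np.ndarray = None

    def add(self, idx: int, xy: np.ndarray) -> None:
        self.indices.append(idx)
        self._sum = xy.copy() if self._sum is None else self._sum + xy
        self.centroid = self._sum / len(self.indices)


def histogram_bins(n: int) -> int:
    """Bin-count rule: round(3 + log₂ n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return int(round(3.0 + np.log2(n)))


def _as_xy(points) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        return points[["f_refold", "f_unfold"]].to_numpy(dtype=float)
    if len(points) and isinstance(points[0], ForcePair):
        return np.array([[p.f_refold, p.f_unfold] for p in points])
    return np.asarray(points, dtype=float).reshape(len(points), 2)


def precluster(points, distance_threshold: float) -> list[Precluster]:
    """Greedy sequential preclustering in the (F_R, F_U) plane.

    Each point joins the nearest existing precluster centroid when that
    centroid lies within ``distance_threshold``; otherwise it starts a
    new precluster.  Points are processed in canonical (lexicographic)
    order so the result is invariant to the input ordering.
    """
    xy = _as_xy(points)
    if xy.shape[0] < 1:
        raise ValueError("need at least one point")
    order = np.lexsort((xy[:, 1], xy[:, 0]))
    clusters: list[Precluster] = []
    for i in order:
        p = xy[i]
        best, best_d = None, np.inf
        for c in clusters:
            d = float(np.linalg.norm(p - c.centroid))
            if d < best_d:
                best, best_d = c, d
        if best is not None and best_d <= distance_threshold:
            best.add(i, p)
        else:
            c = Precluster()
            c.add(i, p)
            clusters.append(c)
    return clusters


@dataclass
class Dendrogram:
    """Centroid-linkage merge history over preclusters.

    ``merges`` holds (index_a, index_b, distance, new_index) tuples in
    merge order; member lists index the original points.
    """

    merges: list
    members_history: list
    n_leaves: int
    point_count: int

    def labels_at(self, k: int) -> np.ndarray:
        """Point labels after cutting the merge sequence at k clusters.

        Uses merge order (the first ``n_leaves − k`` merges), not merge
        height, so centroid inversions cannot scramble the cut.
        """
        if not 1 <= k <= self.n_leaves:
            raise ValueError(f"k must be in [1, {self.n_leaves}]")
        groups = [set(m) for m in self.members_history[0]]
        for a, b, _, _ in self.merges[: self.n_leaves - k]:
            groups[a] |= groups[b]
            groups[b] = None
        labels = np.full(self.point_count, -1, dtype=int)
        lab = 0
        for g in groups:
            if g:
                labels[sorted(g)] = lab
                lab += 1
        return labels


def agglomerate(preclusters: list[Precluster]) -> Dendrogram:
    """Centroid-linkage agglomeration of preclusters.

    Repeatedly merges the closest pair of centroids (ties broken by
    lowest index pair), replacing the pair by the member-weighted
    centroid, until one element remains.
    """
    if len(preclusters) < 2:
        raise ValueError("need at least two preclusters")
    cents = [c.centroid.copy() for c in preclusters]
    sizes = [len(c.indices) for c in preclusters]
    members = [list(c.indices) for c in preclusters]
    alive = list(range(len(cents)))
    merges = []
    history = [ [list(m) for m in members] ]
    last_d = -np.inf
    n_pts = sum(sizes)
    while len(alive) > 1:
        best = None
        for ai in range(len(alive)):
            for bi in range(ai + 1, len(alive)):
                a, b = alive[ai], alive[bi]
                d = float(np.linalg.norm(cents[a] - cents[b]))
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        if d < last_d - 1e-12:
            log.info("centroid-linkage inversion at distance %.3f", d)
        last_d = d
        new_size = sizes[a] + sizes[b]
        cents[a] = (cents[a] * sizes[a] + cents[b] * sizes[b]) / new_size
        sizes[a] = new_size
        members[a] = members[a] + members[b]
        merges.append((a, b, d, a))
        alive.remove(b)
    return Dendrogram(merges=merges, members_history=history,
                      n_leaves=len(preclusters), point_count=n_pts)


def cluster_force_pairs(points, k: int = 2, *,
                        distance_threshold: float | None = None,
                        min_class_fraction: float = 0.05):
    """Full biphasic pipeline: precluster, agglomerate, cut at k.

    ``distance_threshold`` defaults to half the pooled standard
    deviation of the point cloud.  Isolated extreme points would
    otherwise survive as single-member "classes" at the k-cut, so the
    cut is deepened until k substantive clusters (each holding at least
    ``min_class_fraction`` of the points) exist; points in smaller
    outlier clusters are assigned to the nearest substantive class
    centroid.

    Returns (labels, summary DataFrame); the summary lists per-class
    counts and force means/SDs, ordered by increasing mean unfolding
    force (class 0 = low-force).  When the points carry molecule ids,
    each molecule is assigned by majority vote of its rips and
    ``molecule_class`` is included in ``summary.attrs``.
    """
    xy = _as_xy(points)
    n = xy.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of points")
    if distance_threshold is None:
        distance_threshold = 0.5 * float(np.sqrt(xy.var(axis=0).mean()))
    pcs = precluster(points, distance_threshold)
    if len(pcs) < k:
        raise ValueError(
            f"only {len(pcs)} preclusters formed; lower the threshold")
    if len(pcs) == 1:
        raw = np.zeros(n, dtype=int)
    else:
        dendro = agglomerate(pcs)
        min_size = max(1, int(np.ceil(min_class_fraction * n)))
        raw = None
        for k_cut in range(k, dendro.n_leaves + 1):
            cand = dendro.labels_at(k_cut)
            sizes = np.bincount(cand, minlength=k_cut)
            big = np.argsort(sizes)[::-1][:k]
            if sizes[big[-1]] >= min_size:
                # fold any outlier clusters into the nearest big centroid
                cents = np.stack([xy[cand == c].mean(axis=0) for c in big])
                raw = np.empty(n, dtype=int)
                for c in np.unique(cand):
                    sel = cand == c
                    where = np.where(big == c)[0]
                    if where.size:
                        raw[sel] = where[0]
                    else:
                        d = np.linalg.norm(xy[sel][:, None, :]
                                           - cents[None, :, :], axis=2)
                        raw[sel] = np.argmin(d, axis=1)
                break
        if raw is None:
            raw = dendro.labels_at(k)
    # relabel classes by increasing mean unfolding force
    order = np.argsort([xy[raw == c, 1].mean() for c in range(k)])
    labels = np.empty_like(raw)
    for new, old in enumerate(order):
        labels[raw == old] = new
    rows = []
    for c in range(k):
        sel = xy[labels == c]
        rows.append({
            "class": c,
            "n": int(sel.shape[0]),
            "f_refold_mean": float(sel[:, 0].mean()),
            "f_refold_sd": float(sel[:, 0].std(ddof=1)) if len(sel) > 1 else 0.0,
            "f_unfold_mean": float(sel[:, 1].mean()),
            "f_unfold_sd": float(sel[:, 1].std(ddof=1)) if len(sel) > 1 else 0.0,
        })
    summary = pd.DataFrame(rows)
    if k > 1:
        # descriptive report only; k stays fixed by the caller
        from sklearn.metrics import silhouette_score
        summary.attrs["silhouette"] = float(silhouette_score(xy, labels))
    mols = None
    if isinstance(points, pd.DataFrame):
        if "molecule_id" in points.columns:
            mols = points["molecule_id"].to_numpy()
    elif len(points) and isinstance(points[0], ForcePair):
        mols = np.array([p.molecule_id for p in points])
    if mols is not None and len(set(mols)) > 1:
        vote = (pd.DataFrame({"molecule_id": mols, "label": labels})
                .groupby("molecule_id")["label"]
                .agg(lambda s: int(s.value_counts().idxmax())))
        summary.attrs["molecule_class"] = vote.to_dict()
    return labels, summary


def gmm_crosscheck(points, k: int = 2, seed: int = 0) -> pd.DataFrame:
    """Gaussian-mixture cross-check report (never the primary method)."""
    from sklearn.mixture import GaussianMixture
    xy = _as_xy(points)
    gm = GaussianMixture(n_components=k, random_state=seed).fit(xy)
    order = np.argsort(gm.means_[:, 1])
    return pd.DataFrame({
        "class": range(k),
        "weight": gm.weights_[order],
        "f_refold_mean": gm.means_[order, 0],
        "f_unfold_mean": gm.means_[order, 1],
    })
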