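"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: plain-Python
geometry, sympy symbolic determinants, and brute-force O(N^2)/O(n^3)
loops.
"""

from __future__ import annotations

import numpy as np
import sympy


def brute_min_segment_distance(chain: np.ndarray) -> float:
    """Minimum distance over all non-adjacent segment pairs, by dense
    point sampling along each segment (slow, independent of the
    package's closed-form routine)."""
    n_seg = len(chain) - 1
    ts = np.linspace(0.0, 1.0, 41)
    best = np.inf
    for i in range(n_seg):
        pi = chain[i][None] + ts[:, None] * (chain[i + 1] - chain[i])[None]
        for j in range(i + 2, n_seg):
            pj = chain[j][None] + ts[:, None] * (chain[j + 1] - chain[j])[None]
            d = np.linalg.norm(pi[:, None, :] - pj[None, :, :], axis=2).min()
            best = min(best, d)
    return best


def segment_pair_distance(p0, p1, q0, q1, samples: int = 61) -> float:
    ts = np.linspace(0.0, 1.0, samples)
    a = p0[None] + ts[:, None] * (p1 - p0)[None]
    b = q0[None] + ts[:, None] * (q1 - q0)[None]
    return float(np.linalg.norm(a[:, None] - b[None, :], axis=2).min())


def alexander_dets_reference(polygon: np.ndarray,
                             direction=(0.123, 0.456, 0.88)) -> tuple:
    """|Δ(−1)| and 2-power-normalized |Δ(−2)| via a symbolic Alexander
    polynomial computed from a freshly coded planar diagram.

    Projects along ``direction``, finds crossings with plain 2x2 linear
    algebra, writes the Burau-type underpass relations into a sympy
    matrix with symbolic t, and evaluates the (n−1)-minor determinant
    exactly.
    """
    poly = np.asarray(polygon, dtype=float)
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    xy = np.column_stack([poly @ e1, poly @ e2])
    z = poly @ u
    nv = len(poly)

    crossings = []  # (under_pos, over_pos, sign)
    for i in range(nv):
        i1 = (i + 1) % nv
        for j in range(i + 2, nv):
            j1 = (j + 1) % nv
            if j1 == i:
                continue
            r = xy[i1] - xy[i]
            s = xy[j1] - xy[j]
            denom = r[0] * s[1] - r[1] * s[0]
            if abs(denom) < 1e-12:
                continue
            w = xy[j] - xy[i]
            ti = (w[0] * s[1] - w[1] * s[0]) / denom
            tj = (w[0] * r[1] - w[1] * r[0]) / denom
            if not (1e-9 < ti < 1 - 1e-9 and 1e-9 < tj < 1 - 1e-9):
                continue
            zi = z[i] + ti * (z[i1] - z[i])
            zj = z[j] + tj * (z[j1] - z[j])
            cross_z = r[0] * s[1] - r[1] * s[0]
            if zi < zj:
                crossings.append((i + ti, j + tj, np.sign(cross_z)))
            else:
                crossings.append((j + tj, i + ti, -np.sign(cross_z)))
    n = len(crossings)
    if n < 3:
        return 1, 1
    # sign convention: epsilon = sign of cross(d_under, d_over)
    under_sorted = sorted(range(n), key=lambda k: crossings[k][0])
    upos = [crossings[k][0] for k in under_sorted]
    t = sympy.Symbol("t")
    M = sympy.zeros(n, n)
    for row, k in enumerate(under_sorted):
        _, opos, eps = crossings[k]
        gen = -1
        for q in range(n):
            if upos[q] < opos:
                gen = q
        if gen == -1:
            gen = n - 1
        in_arc = (row - 1) % n
        out_arc = row
        if eps > 0:
            M[row, in_arc] += t
            M[row, out_arc] += -1
            M[row, gen] += 1 - t
        else:
            M[row, in_arc] += 1
            M[row, out_arc] += -t
            M[row, gen] += t - 1
    minor = M[: n - 1, : n - 1]
    d1 = abs(int(minor.subs(t, -1).det()))
    d2 = abs(int(minor.subs(t, -2).det()))
    while d2 > 1 and d2 % 2 == 0:
        d2 //= 2
    return d1, d2


def centroid_linkage_reference(points: np.ndarray) -> list:
    """Brute-force centroid-linkage merge order on singleton leaves."""
    pts = [np.asarray(p, dtype=float) for p in points]
    sizes = [1] * len(pts)
    alive = list(range(len(pts)))
    merges = []
    while len(alive) > 1:
        best = None
        for ai in range(len(alive)):
            for bi in range(ai + 1, len(alive)):
                a, b = alive[ai], alive[bi]
                d = float(np.linalg.norm(pts[a] - pts[b]))
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        pts[a] = (pts[a] * sizes[a] + pts[b] * sizes[b]) / (sizes[a] + sizes[b])
        sizes[a] += sizes[b]
        merges.append((a, b, d))
        alive.remove(b)
    return merges


def marko_siggia_work_closed_form(force, lc, p, kt) -> float:
    """Analytic antiderivative of the Marko–Siggia force law, pN nm."""
    from scipy.optimize import brentq

    def f_of_x(x):
        r = x / lc
        return kt / p * (0.25 / (1 - r) ** 2 - 0.25 + r)

    if force == 0:
        return 0.0
    x = brentq(lambda v: f_of_x(v) - force, 0, lc * (1 - 1e-12), rtol=1e-13)
    r = x / lc
    anti = kt / p * (x * x / (2 * lc) + lc / (4 * (1 - r)) - lc / 4 - x / 4)
    return anti
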