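"""Numba kernels for excluded-volume chain sampling and knot classification.

Everything here is nopython-compiled and operates on bare float64 arrays;
the public API in :mod:`knotcost.chains` / :mod:`knotcost.knotting` wraps
these with typed containers and error handling.

Geometry conventions: a chain of ``n`` segments is an ``(n+1, 3)`` vertex
array; a closed polygon of ``V`` edges is a ``(V, 3)`` array with an implied
edge from the last vertex back to the first.
"""

import numpy as np
from numba import njit

# classification codes
UNKNOT = 0
TREFOIL = 1
OTHER = 2
PROJECTION_FAILED = -1


@njit(cache=True)
def _seg_seg_dist2(p0x, p0y, p0z, p1x, p1y, p1z,
                   q0x, q0y, q0z, q1x, q1y, q1z):
    """Squared minimum distance between 3-D segments p0-p1 and q0-q1."""
    # direction vectors
    ux, uy, uz = p1x - p0x, p1y - p0y, p1z - p0z
    vx, vy, vz = q1x - q0x, q1y - q0y, q1z - q0z
    wx, wy, wz = p0x - q0x, p0y - q0y, p0z - q0z
    a = ux * ux + uy * uy + uz * uz
    b = ux * vx + uy * vy + uz * vz
    c = vx * vx + vy * vy + vz * vz
    d = ux * wx + uy * wy + uz * wz
    e = vx * wx + vy * wy + vz * wz
    denom = a * c - b * b
    if denom > 1e-14 * a * c:
        s = (b * e - c * d) / denom
    else:
        s = 0.0
    if s < 0.0:
        s = 0.0
    elif s > 1.0:
        s = 1.0
    # clamp t for this s, then re-clamp s
    if c > 0.0:
        t = (b * s + e) / c
    else:
        t = 0.0
    if t < 0.0:
        t = 0.0
        if a > 0.0:
            s = -d / a
            if s < 0.0:
                s = 0.0
            elif s > 1.0:
                s = 1.0
    elif t > 1.0:
        t = 1.0
        if a > 0.0:
            s = (b - d) / a
            if s < 0.0:
                s = 0.0
            elif s > 1.0:
                s = 1.0
    dx = wx + s * ux - t * vx
    dy = wy + s * uy - t * vy
    dz = wz + s * uz - t * vz
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def _grow_chain(verts, n_seg, kuhn, diameter):
    """Grow a freely-jointed chain with hard-cylinder excluded volume.

    Fills ``verts`` ((n_seg+1, 3)) in place.  Returns True on success,
    False as soon as a newly placed segment overlaps an earlier
    non-adjacent one (caller restarts: early-exit rejection sampling is
    distributionally identical to generate-then-test).
    """
    verts[0, 0] = 0.0
    verts[0, 1] = 0.0
    verts[0, 2] = 0.0
    d2 = diameter * diameter
    for i in range(n_seg):
        # isotropic direction via normalized Gaussian triple
        while True:
            gx = np.random.standard_normal()
            gy = np.random.standard_normal()
            gz = np.random.standard_normal()
            nrm = np.sqrt(gx * gx + gy * gy + gz * gz)
            if nrm > 1e-12:
                break
        verts[i + 1, 0] = verts[i, 0] + kuhn * gx / nrm
        verts[i + 1, 1] = verts[i, 1] + kuhn * gy / nrm
        verts[i + 1, 2] = verts[i, 2] + kuhn * gz / nrm
        if diameter > 0.0:
            # new segment i = (verts[i], verts[i+1]) vs segments 0..i-2
            for j in range(i - 1):
                dd = _seg_seg_dist2(
                    verts[j, 0], verts[j, 1], verts[j, 2],
                    verts[j + 1, 0], verts[j + 1, 1], verts[j + 1, 2],
                    verts[i, 0], verts[i, 1], verts[i, 2],
                    verts[i + 1, 0], verts[i + 1, 1], verts[i + 1, 2])
                if dd < d2:
                    return False
    return True


@njit(cache=True)
def _dimerize(out, n, kuhn, diameter, counter, budget):
    """Unbiased excluded-volume chain by dimerization (Alexandrowicz).

    Fills ``out[:n+1]``.  Short pieces are grown by direct rejection; longer
    chains are formed by concatenating two independent self-avoiding halves
    and rejecting the pair whenever any inter-half segment pair comes
    closer than ``diameter``.  Equivalent to plain rejection sampling but
    with per-chain cost that stays polynomial in n.  ``counter`` (int64[1])
    accumulates attempted sub-chain generations; returns False once it
    exceeds ``budget``.
    """
    if n <= 16:
        while True:
            counter[0] += 1
            if counter[0] > budget:
                return False
            if _grow_chain(out, n, kuhn, diameter):
                return True
    n1 = n // 2
    n2 = n - n1
    buf = np.empty((n2 + 1, 3))
    d2 = diameter * diameter
    while True:
        if not _dimerize(out, n1, kuhn, diameter, counter, budget):
            return False
        if not _dimerize(buf, n2, kuhn, diameter, counter, budget):
            return False
        # translate second half onto the end of the first
        tx = out[n1, 0] - buf[0, 0]
        ty = out[n1, 1] - buf[0, 1]
        tz = out[n1, 2] - buf[0, 2]
        ok = True
        if diameter > 0.0:
            for j in range(n2):
                bx0 = buf[j, 0] + tx
                by0 = buf[j, 1] + ty
                bz0 = buf[j, 2] + tz
                bx1 = buf[j + 1, 0] + tx
                by1 = buf[j + 1, 1] + ty
                bz1 = buf[j + 1, 2] + tz
                # first-half segment indices 0..n1-1; junction pair
                # (n1-1, n1) is adjacent and exempt
                imax = n1 - 1 if j == 0 else n1
                for i in range(imax):
                    dd = _seg_seg_dist2(
                        out[i, 0], out[i, 1], out[i, 2],
                        out[i + 1, 0], out[i + 1, 1], out[i + 1, 2],
                        bx0, by0, bz0, bx1, by1, bz1)
                    if dd < d2:
                        ok = False
                        break
                if not ok:
                    break
        if ok:
            for j in range(1, n2 + 1):
                out[n1 + j, 0] = buf[j, 0] + tx
                out[n1 + j, 1] = buf[j, 1] + ty
                out[n1 + j, 2] = buf[j, 2] + tz
            return True


@njit(cache=True)
def _has_overlap(verts, diameter):
    """True iff any pair of non-adjacent segments is closer than diameter."""
    n_seg = verts.shape[0] - 1
    d2 = diameter * diameter
    for i in range(n_seg):
        for j in range(i + 2, n_seg):
            dd = _seg_seg_dist2(
                verts[i, 0], verts[i, 1], verts[i, 2],
                verts[i + 1, 0], verts[i + 1, 1], verts[i + 1, 2],
                verts[j, 0], verts[j, 1], verts[j, 2],
                verts[j + 1, 0], verts[j + 1, 1], verts[j + 1, 2])
            if dd < d2:
                return True
    return False


@njit(cache=True)
def _has_overlap_closed(verts, diameter):
    """Overlap test for a closed polygon (wrap-around edge included)."""
    nv = verts.shape[0]
    d2 = diameter * diameter
    for i in range(nv):
        i1 = (i + 1) % nv
        for j in range(i + 2, nv):
            j1 = (j + 1) % nv
            if j1 == i:  # wrap edge adjacent to edge 0
                continue
            dd = _seg_seg_dist2(
                verts[i, 0], verts[i, 1], verts[i, 2],
                verts[i1, 0], verts[i1, 1], verts[i1, 2],
                verts[j, 0], verts[j, 1], verts[j, 2],
                verts[j1, 0], verts[j1, 1], verts[j1, 2])
            if dd < d2:
                return True
    return False


@njit(cache=True)
def _radius_of_gyration(verts):
    nv = verts.shape[0]
    cx = 0.0
    cy = 0.0
    cz = 0.0
    for i in range(nv):
        cx += verts[i, 0]
        cy += verts[i, 1]
        cz += verts[i, 2]
    cx /= nv
    cy /= nv
    cz /= nv
    s = 0.0
    for i in range(nv):
        dx = verts[i, 0] - cx
        dy = verts[i, 1] - cy
        dz = verts[i, 2] - cz
        s += dx * dx + dy * dy + dz * dz
    return np.sqrt(s / nv)


@njit(cache=True)
def _close_at_infinity(verts, out):
    """Close an open chain by radial rays to a far sphere.

    ``out`` has room for verts.shape[0] + 3 points.  Each terminus is
    extended radially away from the chain centroid to radius R far outside
    the chain, and the two far points are joined through a third far point
    so the closure arc never approaches the chain.  Returns the number of
    vertices written (V or V+3 when termini coincide).
    """
    nv = verts.shape[0]
    cx = 0.0
    cy = 0.0
    cz = 0.0
    for i in range(nv):
        cx += verts[i, 0]
        cy += verts[i, 1]
        cz += verts[i, 2]
    cx /= nv
    cy /= nv
    cz /= nv
    rmax = 0.0
    for i in range(nv):
        dx = verts[i, 0] - cx
        dy = verts[i, 1] - cy
        dz = verts[i, 2] - cz
        rr = dx * dx + dy * dy + dz * dz
        if rr > rmax:
            rmax = rr
    R = 100.0 * (np.sqrt(rmax) + 1.0)

    # coincident termini: already a closed polygon
    ex = verts[nv - 1, 0] - verts[0, 0]
    ey = verts[nv - 1, 1] - verts[0, 1]
    ez = verts[nv - 1, 2] - verts[0, 2]
    if ex * ex + ey * ey + ez * ez < 1e-18:
        for i in range(nv - 1):
            out[i, 0] = verts[i, 0]
            out[i, 1] = verts[i, 1]
            out[i, 2] = verts[i, 2]
        return nv - 1

    for i in range(nv):
        out[i, 0] = verts[i, 0]
        out[i, 1] = verts[i, 1]
        out[i, 2] = verts[i, 2]

    # unit radial directions of the two termini
    u1x = verts[nv - 1, 0] - cx
    u1y = verts[nv - 1, 1] - cy
    u1z = verts[nv - 1, 2] - cz
    n1 = np.sqrt(u1x * u1x + u1y * u1y + u1z * u1z)
    if n1 < 1e-12:
        u1x, u1y, u1z, n1 = 1.0, 0.0, 0.0, 1.0
    u1x /= n1
    u1y /= n1
    u1z /= n1
    u2x = verts[0, 0] - cx
    u2y = verts[0, 1] - cy
    u2z = verts[0, 2] - cz
    n2 = np.sqrt(u2x * u2x + u2y * u2y + u2z * u2z)
    if n2 < 1e-12:
        u2x, u2y, u2z, n2 = -1.0, 0.0, 0.0, 1.0
    u2x /= n2
    u2y /= n2
    u2z /= n2

    # intermediate far direction; fall back to a perpendicular when the
    # terminal rays are antipodal
    mx = u1x + u2x
    my = u1y + u2y
    mz = u1z + u2z
    mn = np.sqrt(mx * mx + my * my + mz * mz)
    if mn < 1e-6:
        # any vector perpendicular to u1
        if abs(u1x) < 0.9:
            mx, my, mz = 0.0, -u1z, u1y
        else:
            mx, my, mz = -u1z, 0.0, u1x
        mn = np.sqrt(mx * mx + my * my + mz * mz)
    mx /= mn
    my /= mn
    mz /= mn

    out[nv, 0] = cx + R * u1x
    out[nv, 1] = cy + R * u1y
    out[nv, 2] = cz + R * u1z
    out[nv + 1, 0] = cx + R * mx
    out[nv + 1, 1] = cy + R * my
    out[nv + 1, 2] = cz + R * mz
    out[nv + 2, 0] = cx + R * u2x
    out[nv + 2, 1] = cy + R * u2y
    out[nv + 2, 2] = cz + R * u2z
    return nv + 3


@njit(cache=True)
def _tri_seg_possible(ax, ay, az, bx, by, bz, cx, cy, cz,
                      px, py, pz, qx, qy, qz, strict):
    """Does segment p-q (possibly) pierce triangle a-b-c?

    Non-strict mode is conservative (borderline configurations count as
    intersecting, so the vertex is simply not removed); strict mode
    requires a clearly interior transversal crossing and is used for the
    two polygon edges that share a vertex with the triangle.
    """
    e1x, e1y, e1z = bx - ax, by - ay, bz - az
    e2x, e2y, e2z = cx - ax, cy - ay, cz - az
    # triangle normal
    nx = e1y * e2z - e1z * e2y
    ny = e1z * e2x - e1x * e2z
    nz = e1x * e2y - e1y * e2x
    nlen = np.sqrt(nx * nx + ny * ny + nz * nz)
    l1 = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    l2 = np.sqrt(e2x * e2x + e2y * e2y + e2z * e2z)
    if nlen < 1e-12 * l1 * l2 + 1e-300:
        # degenerate (collinear) triangle: conservative
        return not strict
    nx /= nlen
    ny /= nlen
    nz /= nlen
    # signed distances of the segment endpoints to the triangle plane
    dp = nx * (px - ax) + ny * (py - ay) + nz * (pz - az)
    dq = nx * (qx - ax) + ny * (qy - ay) + nz * (qz - az)
    dlen = np.sqrt((qx - px) ** 2 + (qy - py) ** 2 + (qz - pz) ** 2)
    tol_d = 1e-9 * (l1 + l2 + dlen)
    if dp > tol_d and dq > tol_d:
        return False
    if dp < -tol_d and dq < -tol_d:
        return False
    if abs(dp - dq) < tol_d:
        # segment (near-)parallel to and touching the plane: conservative
        return not strict
    # plane-crossing point
    t = dp / (dp - dq)
    ix = px + t * (qx - px) - ax
    iy = py + t * (qy - py) - ay
    iz = pz + t * (qz - pz) - az
    # barycentric coordinates via the 2x2 Gram system
    d11 = e1x * e1x + e1y * e1y + e1z * e1z
    d12 = e1x * e2x + e1y * e2y + e1z * e2z
    d22 = e2x * e2x + e2y * e2y + e2z * e2z
    di1 = ix * e1x + iy * e1y + iz * e1z
    di2 = ix * e2x + iy * e2y + iz * e2z
    denom = d11 * d22 - d12 * d12
    if abs(denom) < 1e-300:
        return not strict
    u = (d22 * di1 - d12 * di2) / denom
    v = (d11 * di2 - d12 * di1) / denom
    tol = 1e-9
    if strict:
        return (u > tol and v > tol and u + v < 1.0 - tol
                and t > tol and t < 1.0 - tol)
    return (u > -tol and v > -tol and u + v < 1.0 + tol
            and t > -tol and t < 1.0 + tol)


@njit(cache=True)
def _simplify_polygon(poly, nv):
    """Topology-preserving vertex elimination on a closed polygon.

    Repeatedly removes vertex i when the triangle (i-1, i, i+1) is pierced
    by no other polygon edge (so the two edges at i can be isotoped onto
    the chord).  Operates in place; returns the reduced vertex count.
    Reduction to 3 or fewer vertices certifies the unknot.
    """
    changed = True
    while changed and nv > 3:
        changed = False
        i = 0
        while i < nv and nv > 3:
            im1 = (i - 1) % nv
            ip1 = (i + 1) % nv
            ax, ay, az = poly[im1, 0], poly[im1, 1], poly[im1, 2]
            bx, by, bz = poly[i, 0], poly[i, 1], poly[i, 2]
            cx, cy, cz = poly[ip1, 0], poly[ip1, 1], poly[ip1, 2]
            # a vertex lying on the chord a-c is removable outright (the
            # two edges already coincide with the chord); this also
            # handles collinear runs that defeat the triangle test
            acx, acy, acz = cx - ax, cy - ay, cz - az
            abx, aby, abz = bx - ax, by - ay, bz - az
            ac2 = acx * acx + acy * acy + acz * acz
            if ac2 > 0.0:
                s = (abx * acx + aby * acy + abz * acz) / ac2
                if -1e-12 <= s <= 1.0 + 1e-12:
                    px = ax + s * acx - bx
                    py = ay + s * acy - by
                    pz = az + s * acz - bz
                    if (px * px + py * py + pz * pz
                            < 1e-20 * max(ac2, 1.0)):
                        for k in range(i, nv - 1):
                            poly[k, 0] = poly[k + 1, 0]
                            poly[k, 1] = poly[k + 1, 1]
                            poly[k, 2] = poly[k + 1, 2]
                        nv -= 1
                        changed = True
                        continue
            blocked = False
            for j in range(nv):
                # skip the triangle's own edges (im1,i) and (i,ip1)
                if j == im1 or j == i:
                    continue
                j1 = (j + 1) % nv
                # edges sharing vertex a (edge ending at im1) or c
                # (edge starting at ip1) get the strict interior test
                strict = (j1 == im1) or (j == ip1)
                if _tri_seg_possible(ax, ay, az, bx, by, bz, cx, cy, cz,
                                     poly[j, 0], poly[j, 1], poly[j, 2],
                                     poly[j1, 0], poly[j1, 1], poly[j1, 2],
                                     strict):
                    blocked = True
                    break
            if not blocked:
                for k in range(i, nv - 1):
                    poly[k, 0] = poly[k + 1, 0]
                    poly[k, 1] = poly[k + 1, 1]
                    poly[k, 2] = poly[k + 1, 2]
                nv -= 1
                changed = True
            else:
                i += 1
    return nv


@njit(cache=True)
def _det_abs(mat, n):
    """|det| of the leading n x n block via partial-pivot elimination."""
    if n == 0:
        return 1.0
    det = 1.0
    for col in range(n):
        piv = col
        best = abs(mat[col, col])
        for r in range(col + 1, n):
            if abs(mat[r, col]) > best:
                best = abs(mat[r, col])
                piv = r
        if best == 0.0:
            return 0.0
        if piv != col:
            for c in range(col, n):
                tmp = mat[col, c]
                mat[col, c] = mat[piv, c]
                mat[piv, c] = tmp
        det *= mat[col, col]
        inv = 1.0 / mat[col, col]
        for r in range(col + 1, n):
            factor = mat[r, col] * inv
            if factor != 0.0:
                for c in range(col, n):
                    mat[r, c] -= factor * mat[col, c]
    return abs(det)


@njit(cache=True)
def _alexander_dets(poly, nv, ux, uy, uz):
    """Alexander determinant magnitudes |Δ(-1)|, |Δ(-2)| from one projection.

    Projects the closed polygon along (ux, uy, uz), lists crossings, builds
    the Alexander matrix from the underpass (Burau-type) relations
    ``t·x_in − x_out + (1−t)·x_over = 0`` (sign-mirrored for negative
    crossings), deletes one row and column, and evaluates |det| at t = −1
    and t = −2.  The t = −2 value is normalized by stripping powers of 2
    (the polynomial is only defined up to ±t^k).

    Returns (ok, d1, d2); ok = False means a non-generic projection and
    the caller should retry with a fresh direction.
    """
    # orthonormal basis perpendicular to u
    if abs(ux) < 0.9:
        e1x, e1y, e1z = 0.0, -uz, uy
    else:
        e1x, e1y, e1z = -uz, 0.0, ux
    n1 = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x /= n1
    e1y /= n1
    e1z /= n1
    e2x = uy * e1z - uz * e1y
    e2y = uz * e1x - ux * e1z
    e2z = ux * e1y - uy * e1x

    X = np.empty(nv)
    Y = np.empty(nv)
    Z = np.empty(nv)
    for i in range(nv):
        X[i] = poly[i, 0] * e1x + poly[i, 1] * e1y + poly[i, 2] * e1z
        Y[i] = poly[i, 0] * e2x + poly[i, 1] * e2y + poly[i, 2] * e2z
        Z[i] = poly[i, 0] * ux + poly[i, 1] * uy + poly[i, 2] * uz

    max_cross = 4 * nv * nv
    under_pos = np.empty(max_cross)
    over_pos = np.empty(max_cross)
    sign = np.empty(max_cross, dtype=np.int64)
    ncross = 0
    tol = 1e-9
    for i in range(nv):
        i1 = (i + 1) % nv
        rix = X[i1] - X[i]
        riy = Y[i1] - Y[i]
        for j in range(i + 2, nv):
            j1 = (j + 1) % nv
            if j1 == i:
                continue
            rjx = X[j1] - X[j]
            rjy = Y[j1] - Y[j]
            denom = rix * rjy - riy * rjx
            wx = X[j] - X[i]
            wy = Y[j] - Y[i]
            scale = (abs(rix) + abs(riy)) * (abs(rjx) + abs(rjy))
            if abs(denom) < 1e-12 * scale + 1e-300:
                # parallel in projection: degenerate only if they overlap
                cross_w = wx * riy - wy * rix
                if abs(cross_w) < tol * (abs(rix) + abs(riy) + 1.0):
                    return False, 0.0, 0.0
                continue
            s = (wx * rjy - wy * rjx) / denom
            t = (wx * riy - wy * rix) / denom
            if s <= -tol or s >= 1.0 + tol or t <= -tol or t >= 1.0 + tol:
                continue
            if s < tol or s > 1.0 - tol or t < tol or t > 1.0 - tol:
                return False, 0.0, 0.0  # crossing at a vertex: re-project
            zi = Z[i] + s * (Z[i1] - Z[i])
            zj = Z[j] + t * (Z[j1] - Z[j])
            if abs(zi - zj) < 1e-12:
                return False, 0.0, 0.0
            if ncross >= max_cross:
                return False, 0.0, 0.0
            # crossing sign from (under dir) x (over dir)
            if zi < zj:
                upos = i + s
                opos = j + t
                cr = rix * rjy - riy * rjx
            else:
                upos = j + t
                opos = i + s
                cr = rjx * riy - rjy * rix
            under_pos[ncross] = upos
            over_pos[ncross] = opos
            sign[ncross] = 1 if cr > 0.0 else -1
            ncross += 1

    if ncross < 3:
        return True, 1.0, 1.0

    # order underpasses along the chain
    order = np.argsort(under_pos[:ncross])
    upos_sorted = np.empty(ncross)
    for k in range(ncross):
        upos_sorted[k] = under_pos[order[k]]

    n = ncross
    d_out = np.empty(2)
    for it in range(2):
        tval = -1.0 if it == 0 else -2.0
        A = np.zeros((n, n))
        for kk in range(n):
            cidx = order[kk]
            # generator of the overpass arc: arc m spans
            # (upos_sorted[m], upos_sorted[m+1])
            op = over_pos[cidx]
            m = -1
            for q in range(n):
                if upos_sorted[q] < op:
                    m = q
            if m == -1:
                m = n - 1
            in_arc = (kk - 1) % n
            out_arc = kk
            if sign[cidx] > 0:
                A[kk, in_arc] += tval
                A[kk, out_arc] += -1.0
                A[kk, m] += 1.0 - tval
            else:
                A[kk, in_arc] += 1.0
                A[kk, out_arc] += -tval
                A[kk, m] += tval - 1.0
        d_out[it] = _det_abs(A, n - 1)

    d1 = d_out[0]
    d2 = d_out[1]
    if d1 > 1e14 or d2 > 1e14 or not np.isfinite(d1) or not np.isfinite(d2):
        return True, 1e15, 1e15  # hugely complex: certainly not unknot/trefoil
    d1 = np.rint(d1)
    d2 = np.rint(d2)
    # Δ(-2) defined up to a power of ±t: strip factors of 2
    while d2 > 1.0 and d2 % 2.0 == 0.0:
        d2 /= 2.0
    return True, d1, d2


@njit(cache=True)
def _classify_polygon(poly, nv, dirs):
    """Knot class of a closed polygon, retrying projections on degeneracy.

    Returns (code, d1, d2) with code in {UNKNOT, TREFOIL, OTHER} or
    PROJECTION_FAILED when every candidate direction was non-generic.
    """
    for k in range(dirs.shape[0]):
        ok, d1, d2 = _alexander_dets(poly, nv, dirs[k, 0], dirs[k, 1],
                                     dirs[k, 2])
        if ok:
            i1 = int(d1)
            i2 = int(d2)
            if i1 == 1:
                return UNKNOT, i1, i2
            if i1 == 3 and i2 == 7:
                return TREFOIL, i1, i2
            return OTHER, i1, i2
    return PROJECTION_FAILED, 0, 0


@njit(cache=True)
def knot_census(n_chains, n_seg, kuhn, diameter, dirs, seed,
                attempt_budget, closure_mode):
    """Batched pipeline: sample -> close -> simplify -> classify.

    closure_mode 0 joins the termini by radial rays to a far sphere
    (closure at infinity, the default); 1 joins them directly with a
    single chord (cross-check variant).

    Returns (counts[3], n_failed_projection, rg_sum, rg2_sum, attempts)
    where counts are (unknot, trefoil, other) over classified chains.
    """
    np.random.seed(seed)
    counts = np.zeros(3, dtype=np.int64)
    nproj_failed = 0
    rg_sum = 0.0
    rg2_sum = 0.0
    attempts = 0
    verts = np.empty((n_seg + 1, 3))
    work = np.empty((n_seg + 4, 3))
    counter = np.zeros(1, dtype=np.int64)
    for _ in range(n_chains):
        counter[0] = 0
        if not _dimerize(verts, n_seg, kuhn, diameter, counter,
                         attempt_budget):
            counts[0] = -1  # sampling-budget failure sentinel
            return counts, nproj_failed, rg_sum, rg2_sum, attempts
        attempts += counter[0]
        rg = _radius_of_gyration(verts)
        rg_sum += rg
        rg2_sum += rg * rg
        if closure_mode == 1:
            nv = verts.shape[0]
            for i in range(nv):
                work[i, 0] = verts[i, 0]
                work[i, 1] = verts[i, 1]
                work[i, 2] = verts[i, 2]
        else:
            nv = _close_at_infinity(verts, work)
        nv = _simplify_polygon(work, nv)
        if nv <= 3:
            counts[UNKNOT] += 1
            continue
        code, _, _ = _classify_polygon(work, nv, dirs)
        if code == PROJECTION_FAILED:
            nproj_failed += 1
        else:
            counts[code] += 1
    return counts, nproj_failed, rg_sum, rg2_sum, attempts


@njit(cache=True)
def _moved_overlap(poly, i, j, n_seg, diameter):
    """Overlap test after a crankshaft move that displaced the cyclic
    vertex range i+1..j-1 of a closed polygon.

    Segment k spans vertices (k, k+1 mod n).  Segments i..j-1 (cyclic)
    changed; the fully-moved interior ones are mutually rigid, so only
    changed-vs-unchanged pairs and the two hinge segments vs the rest of
    the changed arc need testing.  Adjacent segments are exempt.
    """
    d2 = diameter * diameter
    # changed segment indices: i, i+1, ..., j-1 (cyclic)
    nch = (j - i) % n_seg
    for a in range(nch):
        sa = (i + a) % n_seg
        sa1 = (sa + 1) % n_seg
        # vs unchanged segments
        for b in range(nch, n_seg):
            sb = (i + b) % n_seg
            sb1 = (sb + 1) % n_seg
            if sb1 == sa or sa1 == sb:
                continue
            if _seg_seg_dist2(
                    poly[sa, 0], poly[sa, 1], poly[sa, 2],
                    poly[sa1, 0], poly[sa1, 1], poly[sa1, 2],
                    poly[sb, 0], poly[sb, 1], poly[sb, 2],
                    poly[sb1, 0], poly[sb1, 1], poly[sb1, 2]) < d2:
                return True
    # hinge segments (first and last changed) vs interior changed ones
    for h in range(2):
        sh = i if h == 0 else (j - 1) % n_seg
        sh1 = (sh + 1) % n_seg
        for a in range(nch):
            sa = (i + a) % n_seg
            if sa == sh:
                continue
            sa1 = (sa + 1) % n_seg
            if sa1 == sh or sh1 == sa:
                continue
            if h == 1 and sa == i:
                continue  # hinge-hinge pair handled once (h == 0 covers it)
            if _seg_seg_dist2(
                    poly[sh, 0], poly[sh, 1], poly[sh, 2],
                    poly[sh1, 0], poly[sh1, 1], poly[sh1, 2],
                    poly[sa, 0], poly[sa, 1], poly[sa, 2],
                    poly[sa1, 0], poly[sa1, 1], poly[sa1, 2]) < d2:
                return True
    return False


@njit(cache=True)
def ring_census(n_chains, n_seg, kuhn, diameter, dirs, seed,
                sweeps_per_sample, burn_in):
    """Equilibrium closed-polygon ensemble via crankshaft Markov chain.

    Starts from a regular planar ring of n_seg equal bonds and applies
    hard-core Metropolis crankshaft moves: two hinge vertices are chosen,
    the shorter arc between them is rigidly rotated about the hinge axis
    by a uniform angle, and the move is accepted iff the result has no
    cylinder overlap.  Moves preserve ring closure and bond lengths
    exactly, and large-angle rotations interconvert knot types, so the
    chain samples the full equilibrium topology distribution.  Every
    ``sweeps_per_sample`` moves one polygon is classified.

    Returns (counts[3], knot_events, n_failed_projection, rg_sum, rg2_sum,
    n_accepted).  ``knot_events`` counts maximal runs of consecutive
    non-unknot samples; clumped runs signal correlated samples and are
    used for honest confidence intervals.
    """
    np.random.seed(seed)
    counts = np.zeros(3, dtype=np.int64)
    knot_events = 0
    prev_knotted = False
    nproj_failed = 0
    accepted = 0
    rg_sum = 0.0
    rg2_sum = 0.0
    radius = kuhn / (2.0 * np.sin(np.pi / n_seg))
    poly = np.empty((n_seg, 3))
    for i in range(n_seg):
        ang = 2.0 * np.pi * i / n_seg
        poly[i, 0] = radius * np.cos(ang)
        poly[i, 1] = radius * np.sin(ang)
        poly[i, 2] = 0.0
    undo = np.empty((n_seg, 3))
    work = np.empty((n_seg, 3))
    n_moves_total = burn_in + n_chains * sweeps_per_sample
    sampled = 0
    for mv in range(n_moves_total):
        i = int(np.random.random() * n_seg)
        span = 2 + int(np.random.random() * (n_seg - 3))
        if span > n_seg - span:
            # rotating the complementary arc differs only by a global
            # rotation; always move the shorter arc
            i = (i + span) % n_seg
            span = n_seg - span
        j = (i + span) % n_seg
        axx = poly[j, 0] - poly[i, 0]
        axy = poly[j, 1] - poly[i, 1]
        axz = poly[j, 2] - poly[i, 2]
        nrm = np.sqrt(axx * axx + axy * axy + axz * axz)
        if nrm > 1e-12:
            # stash the arc, rotate in place, undo on rejection
            nmoved = span - 1
            for a in range(nmoved):
                k = (i + 1 + a) % n_seg
                undo[a, 0] = poly[k, 0]
                undo[a, 1] = poly[k, 1]
                undo[a, 2] = poly[k, 2]
            theta = (np.random.random() * 2.0 - 1.0) * np.pi
            ct = np.cos(theta)
            st = np.sin(theta)
            ax = axx / nrm
            ay = axy / nrm
            az = axz / nrm
            for a in range(nmoved):
                k = (i + 1 + a) % n_seg
                vx = poly[k, 0] - poly[i, 0]
                vy = poly[k, 1] - poly[i, 1]
                vz = poly[k, 2] - poly[i, 2]
                dot = ax * vx + ay * vy + az * vz
                cx = ay * vz - az * vy
                cy = az * vx - ax * vz
                cz = ax * vy - ay * vx
                poly[k, 0] = poly[i, 0] + vx * ct + cx * st + ax * dot * (1.0 - ct)
                poly[k, 1] = poly[i, 1] + vy * ct + cy * st + ay * dot * (1.0 - ct)
                poly[k, 2] = poly[i, 2] + vz * ct + cz * st + az * dot * (1.0 - ct)
            if diameter > 0.0 and _moved_overlap(poly, i, j, n_seg, diameter):
                for a in range(nmoved):
                    k = (i + 1 + a) % n_seg
                    poly[k, 0] = undo[a, 0]
                    poly[k, 1] = undo[a, 1]
                    poly[k, 2] = undo[a, 2]
            else:
                accepted += 1
        if mv >= burn_in and (mv - burn_in + 1) % sweeps_per_sample == 0:
            if sampled >= n_chains:
                break
            sampled += 1
            rg = _radius_of_gyration(poly)
            rg_sum += rg
            rg2_sum += rg * rg
            for k in range(n_seg):
                work[k, 0] = poly[k, 0]
                work[k, 1] = poly[k, 1]
                work[k, 2] = poly[k, 2]
            nv = _simplify_polygon(work, n_seg)
            if nv <= 3:
                counts[UNKNOT] += 1
                prev_knotted = False
                continue
            code, _, _ = _classify_polygon(work, nv, dirs)
            if code == PROJECTION_FAILED:
                nproj_failed += 1
                prev_knotted = False
            else:
                counts[code] += 1
                if code != UNKNOT:
                    if not prev_knotted:
                        knot_events += 1
                    prev_knotted = True
                else:
                    prev_knotted = False
    return counts, knot_events, nproj_failed, rg_sum, rg2_sum, accepted


@njit(cache=True)
def _rotate_about_axis(poly, i0, i1, ax, ay, az, px, py, pz, theta):
    """Rodrigues rotation of vertices i0..i1 (inclusive) about the unit
    axis (ax,ay,az) through point (px,py,pz), in place."""
    ct = np.cos(theta)
    st = np.sin(theta)
    for i in range(i0, i1 + 1):
        vx = poly[i, 0] - px
        vy = poly[i, 1] - py
        vz = poly[i, 2] - pz
        dot = ax * vx + ay * vy + az * vz
        cx = ay * vz - az * vy
        cy = az * vx - ax * vz
        cz = ax * vy - ay * vx
        poly[i, 0] = px + vx * ct + cx * st + ax * dot * (1.0 - ct)
        poly[i, 1] = py + vy * ct + cy * st + ay * dot * (1.0 - ct)
        poly[i, 2] = pz + vz * ct + cz * st + az * dot * (1.0 - ct)


@njit(cache=True)
def mcmc_sweeps(verts, diameter, n_moves, seed):
    """Metropolis crankshaft/pivot sampling of an open excluded-volume chain.

    Hard-core potential: a move is accepted iff the new conformation has no
    overlap.  Crankshaft moves rotate an interior sub-chain about the axis
    joining its end vertices; pivot moves rotate a terminal sub-chain about
    a random axis through the hinge vertex.  Bond lengths are preserved
    exactly.  Returns the number of accepted moves.
    """
    np.random.seed(seed)
    nv = verts.shape[0]
    trial = np.empty((nv, 3))
    accepted = 0
    for _ in range(n_moves):
        for i in range(nv):
            trial[i, 0] = verts[i, 0]
            trial[i, 1] = verts[i, 1]
            trial[i, 2] = verts[i, 2]
        theta = (np.random.random() * 2.0 - 1.0) * np.pi
        if np.random.random() < 0.5 and nv >= 4:
            # crankshaft: hinge pair (i, j), rotate i+1..j-1
            i = int(np.random.random() * (nv - 2))
            j = i + 2 + int(np.random.random() * (nv - i - 2))
            if j >= nv:
                j = nv - 1
            axx = trial[j, 0] - trial[i, 0]
            axy = trial[j, 1] - trial[i, 1]
            axz = trial[j, 2] - trial[i, 2]
            nrm = np.sqrt(axx * axx + axy * axy + axz * axz)
            if nrm < 1e-12:
                continue
            _rotate_about_axis(trial, i + 1, j - 1, axx / nrm, axy / nrm,
                               axz / nrm, trial[i, 0], trial[i, 1],
                               trial[i, 2], theta)
        else:
            # pivot: hinge at i, rotate tail i+1..nv-1 about random axis
            i = int(np.random.random() * (nv - 1))
            while True:
                gx = np.random.standard_normal()
                gy = np.random.standard_normal()
                gz = np.random.standard_normal()
                nrm = np.sqrt(gx * gx + gy * gy + gz * gz)
                if nrm > 1e-12:
                    break
            _rotate_about_axis(trial, i + 1, nv - 1, gx / nrm, gy / nrm,
                               gz / nrm, trial[i, 0], trial[i, 1],
                               trial[i, 2], theta)
        if diameter > 0.0 and _has_overlap(trial, diameter):
            continue
        for i in range(nv):
            verts[i, 0] = trial[i, 0]
            verts[i, 1] = trial[i, 1]
            verts[i, 2] = trial[i, 2]
        accepted += 1
    return accepted
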