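"""Numba-compiled numerical kernels.

Everything here operates on plain float64 arrays so the hot Monte Carlo
loop never touches Python objects.  Cylinders are stored as two arrays of
shape (M, 3): centres of mass and unit axes, with M = 2N and duplex ``d``
owning cylinders ``2d`` and ``2d + 1``.  Inner loops are written with
scalar components to avoid heap allocation.

The hard-core overlap test for two congruent finite cylinders is staged:

1. bounding-sphere rejection (centre distance >= sqrt(L^2 + D^2));
2. axis segment-segment distance >= D  =>  no overlap (each cylinder is
   contained in its spherocylinder);
3. if the closest points of the two axis segments are interior to both
   segments by at least D/2 and closer than D, the midpoint between them
   lies inside both cylinders  =>  overlap;
4. otherwise an exact GJK query on the two convex bodies decides
   end-dominated contacts (rim-rim, rim-lateral, disk-disk).

Grazing, zero-volume contacts count as non-overlapping (tolerance ``tol``
in nm on the boundary).
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# small vector helpers
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _dot(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


@njit(cache=True, inline="always")
def _cross(a, b):
    out = np.empty(3)
    out[0] = a[1] * b[2] - a[2] * b[1]
    out[1] = a[2] * b[0] - a[0] * b[2]
    out[2] = a[0] * b[1] - a[1] * b[0]
    return out


@njit(cache=True)
def _rodrigues(v, k, theta):
    """Rotate v about unit axis k by angle theta."""
    c = np.cos(theta)
    s = np.sin(theta)
    kv = _dot(k, v)
    kxv = _cross(k, v)
    out = np.empty(3)
    for i in range(3):
        out[i] = v[i] * c + kxv[i] * s + k[i] * kv * (1.0 - c)
    return out


@njit(cache=True)
def _rand_unit():
    """Uniform random unit vector (Gaussian trick)."""
    while True:
        x = np.random.normal()
        y = np.random.normal()
        z = np.random.normal()
        n2 = x * x + y * y + z * z
        if n2 > 1e-12:
            n = np.sqrt(n2)
            out = np.empty(3)
            out[0] = x / n
            out[1] = y / n
            out[2] = z / n
            return out


@njit(cache=True)
def _rand_rotmat():
    """Uniform random rotation matrix from a random unit quaternion."""
    q0 = np.random.normal()
    q1 = np.random.normal()
    q2 = np.random.normal()
    q3 = np.random.normal()
    n = np.sqrt(q0 * q0 + q1 * q1 + q2 * q2 + q3 * q3)
    q0 /= n
    q1 /= n
    q2 /= n
    q3 /= n
    R = np.empty((3, 3))
    R[0, 0] = 1 - 2 * (q2 * q2 + q3 * q3)
    R[0, 1] = 2 * (q1 * q2 - q0 * q3)
    R[0, 2] = 2 * (q1 * q3 + q0 * q2)
    R[1, 0] = 2 * (q1 * q2 + q0 * q3)
    R[1, 1] = 1 - 2 * (q1 * q1 + q3 * q3)
    R[1, 2] = 2 * (q2 * q3 - q0 * q1)
    R[2, 0] = 2 * (q1 * q3 - q0 * q2)
    R[2, 1] = 2 * (q2 * q3 + q0 * q1)
    R[2, 2] = 1 - 2 * (q1 * q1 + q2 * q2)
    return R


@njit(cache=True, inline="always")
def _mi(x, e):
    """Minimum-image a scalar separation component."""
    return x - e * np.round(x / e)


@njit(cache=True, inline="always", fastmath=True)
def _mi2(x, e, inve):
    """Minimum-image with a precomputed reciprocal edge (hot loops)."""
    return x - e * np.floor(x * inve + 0.5)


# ---------------------------------------------------------------------------
# segment-segment distance (closest points between the two cylinder axes)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always", fastmath=True)
def _seg_seg_s(rx, ry, rz, ux, uy, uz, vx, vy, vz, h):
    """Squared distance and closest-point parameters between two segments
    of half-length h: S1(s) = s*u, S2(t) = r + t*v, with s, t in [-h, h]."""
    b = ux * vx + uy * vy + uz * vz
    d = ux * rx + uy * ry + uz * rz
    e = vx * rx + vy * ry + vz * rz
    denom = 1.0 - b * b
    if denom > 1e-14:
        s = (d - b * e) / denom
    else:
        s = 0.0
    if s > h:
        s = h
    elif s < -h:
        s = -h
    t = b * s - e
    if t > h:
        t = h
    elif t < -h:
        t = -h
    s = b * t + d
    if s > h:
        s = h
    elif s < -h:
        s = -h
    dx = s * ux - (rx + t * vx)
    dy = s * uy - (ry + t * vy)
    dz = s * uz - (rz + t * vz)
    return dx * dx + dy * dy + dz * dz, s, t


@njit(cache=True)
def seg_seg_dist2(dr, u1, u2, h):
    d2, _s, _t = _seg_seg_s(dr[0], dr[1], dr[2], u1[0], u1[1], u1[2],
                            u2[0], u2[1], u2[2], h)
    return d2


# ---------------------------------------------------------------------------
# GJK boolean intersection for two congruent finite cylinders
# ---------------------------------------------------------------------------


@njit(cache=True)
def _support_cyl(d, u, hL, r):
    """Farthest point of a cylinder (centred at origin, axis u, half-length
    hL, radius r) in direction d."""
    du = _dot(d, u)
    out = np.empty(3)
    axv = hL if du >= 0.0 else -hL
    wx = d[0] - du * u[0]
    wy = d[1] - du * u[1]
    wz = d[2] - du * u[2]
    wn = np.sqrt(wx * wx + wy * wy + wz * wz)
    if wn > 1e-12:
        f = r / wn
        out[0] = axv * u[0] + f * wx
        out[1] = axv * u[1] + f * wy
        out[2] = axv * u[2] + f * wz
    else:
        out[0] = axv * u[0]
        out[1] = axv * u[1]
        out[2] = axv * u[2]
    return out


@njit(cache=True)
def _support_mk(d, dr, u1, u2, hL, r):
    """Support of the Minkowski difference (cyl1 at origin) - (cyl2 at dr)."""
    nd = np.empty(3)
    nd[0] = -d[0]
    nd[1] = -d[1]
    nd[2] = -d[2]
    a = _support_cyl(d, u1, hL, r)
    b = _support_cyl(nd, u2, hL, r)
    out = np.empty(3)
    out[0] = a[0] - (dr[0] + b[0])
    out[1] = a[1] - (dr[1] + b[1])
    out[2] = a[2] - (dr[2] + b[2])
    return out


@njit(cache=True)
def _do_simplex(S, dim):
    """Update the GJK simplex; returns (contains_origin, new_dim, v)."""
    v = np.empty(3)
    while True:
        if dim == 2:
            A = S[1].copy()
            B = S[0].copy()
            ab = B - A
            ao = -A
            if _dot(ab, ao) > 0.0:
                abab = _dot(ab, ab)
                abao = _dot(ab, ao)
                for i in range(3):
                    v[i] = ao[i] * abab - ab[i] * abao
                if _dot(v, v) < 1e-18:
                    # origin on the line through AB: any perpendicular works
                    ref = np.zeros(3)
                    ref[0] = 1.0
                    if abs(ab[0]) > 0.9 * np.sqrt(abab):
                        ref[0] = 0.0
                        ref[1] = 1.0
                    v = _cross(ab, ref)
                return False, 2, v
            S[0] = A
            dim = 1
            for i in range(3):
                v[i] = ao[i]
            return False, 1, v
        elif dim == 3:
            A = S[2].copy()
            B = S[1].copy()
            C = S[0].copy()
            ab = B - A
            ac = C - A
            ao = -A
            abc = _cross(ab, ac)
            if _dot(_cross(abc, ac), ao) > 0.0:
                if _dot(ac, ao) > 0.0:
                    S[0] = C
                    S[1] = A
                    dim = 2
                    acac = _dot(ac, ac)
                    acao = _dot(ac, ao)
                    for i in range(3):
                        v[i] = ao[i] * acac - ac[i] * acao
                    if _dot(v, v) < 1e-18:
                        ref = np.zeros(3)
                        ref[0] = 1.0
                        if abs(ac[0]) > 0.9 * np.sqrt(acac):
                            ref[0] = 0.0
                            ref[1] = 1.0
                        v = _cross(ac, ref)
                    return False, 2, v
                S[0] = B
                S[1] = A
                dim = 2
                continue
            if _dot(_cross(ab, abc), ao) > 0.0:
                S[0] = B
                S[1] = A
                dim = 2
                continue
            dabc = _dot(abc, ao)
            if dabc > 1e-18:
                for i in range(3):
                    v[i] = abc[i]
                return False, 3, v
            elif dabc < -1e-18:
                S[0] = B
                S[1] = C
                for i in range(3):
                    v[i] = -abc[i]
                return False, 3, v
            else:
                # origin in (or degenerate) triangle plane; search off-plane
                if _dot(abc, abc) < 1e-18:
                    for i in range(3):
                        v[i] = ao[i]
                    return False, 3, v
                for i in range(3):
                    v[i] = abc[i]
                return False, 3, v
        else:  # dim == 4
            A = S[3].copy()
            B = S[2].copy()
            C = S[1].copy()
            Dp = S[0].copy()
            ab = B - A
            ac = C - A
            ad = Dp - A
            ao = -A
            # face ABC, opposite D
            n = _cross(ab, ac)
            if _dot(n, ad) > 0.0:
                for i in range(3):
                    n[i] = -n[i]
            if _dot(n, ao) > 0.0:
                S[0] = C
                S[1] = B
                S[2] = A
                dim = 3
                continue
            # face ACD, opposite B
            n = _cross(ac, ad)
            if _dot(n, ab) > 0.0:
                for i in range(3):
                    n[i] = -n[i]
            if _dot(n, ao) > 0.0:
                S[0] = Dp
                S[1] = C
                S[2] = A
                dim = 3
                continue
            # face ADB, opposite C
            n = _cross(ad, ab)
            if _dot(n, ac) > 0.0:
                for i in range(3):
                    n[i] = -n[i]
            if _dot(n, ao) > 0.0:
                S[0] = B
                S[1] = Dp
                S[2] = A
                dim = 3
                continue
            return True, 4, v


@njit(cache=True)
def _gjk_overlap(dr, u1, u2, hL, r, tol):
    """Exact convex intersection: is the origin strictly inside the
    Minkowski difference of the two cylinders?  Touching within ``tol``
    counts as non-overlapping."""
    v = np.empty(3)
    v[0] = -dr[0]
    v[1] = -dr[1]
    v[2] = -dr[2]
    if _dot(v, v) < 1e-18:
        v[0] = 1.0
    S = np.zeros((4, 3))
    dim = 0
    for _it in range(100):
        vn = np.sqrt(_dot(v, v))
        if vn < 1e-14:
            # origin on the simplex boundary: zero-volume contact
            return False
        w = _support_mk(v, dr, u1, u2, hL, r)
        if _dot(w, v) < tol * vn:
            return False
        dup = False
        for k in range(dim):
            dx = w[0] - S[k, 0]
            dy = w[1] - S[k, 1]
            dz = w[2] - S[k, 2]
            if dx * dx + dy * dy + dz * dz < 1e-20:
                dup = True
                break
        if dup:
            return False
        S[dim] = w
        dim += 1
        if dim == 1:
            for k in range(3):
                v[k] = -w[k]
            continue
        contains, dim, v = _do_simplex(S, dim)
        if contains:
            return True
    return False


@njit(cache=True, inline="always", fastmath=True)
def _cyl_overlap_s(rx, ry, rz, ux, uy, uz, vx, vy, vz, L, D, tol):
    """Scalar-argument staged overlap test (see module docstring).

    Cylinder 1 sits at the origin with axis u; cylinder 2 at r with axis v.
    The caller has already applied the minimum image to r and guaranteed
    r.r < L^2 + D^2 (bounding spheres).
    """
    hL = 0.5 * L
    rad = 0.5 * D
    sd2, s, t = _seg_seg_s(rx, ry, rz, ux, uy, uz, vx, vy, vz, hL)
    Deff = D - tol
    if sd2 >= Deff * Deff:
        return False
    if abs(s) <= hL - rad and abs(t) <= hL - rad:
        return True
    dr = np.empty(3)
    dr[0] = rx
    dr[1] = ry
    dr[2] = rz
    u1 = np.empty(3)
    u1[0] = ux
    u1[1] = uy
    u1[2] = uz
    u2 = np.empty(3)
    u2[0] = vx
    u2[1] = vy
    u2[2] = vz
    return _gjk_overlap(dr, u1, u2, hL, rad, tol)


@njit(cache=True)
def cyl_overlap(dr, u1, u2, L, D, tol):
    """Array-argument staged overlap test for two congruent cylinders."""
    d2 = _dot(dr, dr)
    if d2 >= L * L + D * D:
        return False
    return _cyl_overlap_s(dr[0], dr[1], dr[2], u1[0], u1[1], u1[2],
                          u2[0], u2[1], u2[2], L, D, tol)


# ---------------------------------------------------------------------------
# pairwise interaction scans
# ---------------------------------------------------------------------------


@njit(cache=True)
def _pair_state(pi, ui, pj, uj, box, L, D, a_off, delta, tol, periodic):
    """(overlap, bonded) for cylinder i against cylinder j."""
    if periodic:
        dx = _mi(pj[0] - pi[0], box[0])
        dy = _mi(pj[1] - pi[1], box[1])
        dz = _mi(pj[2] - pi[2], box[2])
    else:
        dx = pj[0] - pi[0]
        dy = pj[1] - pi[1]
        dz = pj[2] - pi[2]
    d2 = dx * dx + dy * dy + dz * dz
    reach = 2.0 * a_off + delta
    lim = L * L + D * D
    if reach * reach > lim:
        lim = reach * reach
    if d2 >= lim:
        return False, False
    ov = False
    if d2 < L * L + D * D:
        ov = _cyl_overlap_s(dx, dy, dz, ui[0], ui[1], ui[2],
                            uj[0], uj[1], uj[2], L, D, tol)
    if ov:
        return True, False
    ax_ = (pj[0] + a_off * uj[0]) - (pi[0] + a_off * ui[0])
    ay_ = (pj[1] + a_off * uj[1]) - (pi[1] + a_off * ui[1])
    az_ = (pj[2] + a_off * uj[2]) - (pi[2] + a_off * ui[2])
    if periodic:
        ax_ = _mi(ax_, box[0])
        ay_ = _mi(ay_, box[1])
        az_ = _mi(az_, box[2])
    bonded = ax_ * ax_ + ay_ * ay_ + az_ * az_ < delta * delta
    return False, bonded


@njit(cache=True)
def _cyl_env(i, cand_p, cand_u, pos, ax, box, L, D, a_off, delta, tol,
             hard_on, wells_on, include_intra, skip):
    """Scan cylinder i (at a candidate pose) against all others.

    Returns (n_bonds, overlap_flag); ``skip`` is excluded entirely (the
    rigidly co-moving partner), or -1.
    """
    M = pos.shape[0]
    partner = i ^ 1
    nb = 0
    for j in range(M):
        if j == i or j == skip:
            continue
        ov, bd = _pair_state(cand_p, cand_u, pos[j], ax[j], box,
                             L, D, a_off, delta, tol, True)
        if hard_on and ov:
            return -1, True
        if wells_on and bd:
            if j == partner and not include_intra:
                continue
            nb += 1
    return nb, False


@njit(cache=True)
def tether_sat(pi, ui, pj, uj, box, b_off, sigma):
    """Is the tether |B_i - B_j| < sigma satisfied (minimum image)?"""
    d2 = 0.0
    for k in range(3):
        d = (pj[k] - b_off * uj[k]) - (pi[k] - b_off * ui[k])
        d = _mi(d, box[k])
        d2 += d * d
    return d2 < sigma * sigma


@njit(cache=True)
def full_scan(pos, ax, box, L, D, a_off, b_off, sigma, delta, tol,
              hard_on, wells_on, tether_on, include_intra):
    """O(M^2) scan of the whole system.

    Returns (ok, first_bad_i, first_bad_j, n_bonds_total, bond_pairs) where
    bond_pairs is an int64 array of encoded inter-duplex bonds
    (di * ndup + dj with di < dj) used for cluster bookkeeping.  ``ok``
    turns False on the first hard-core or tether violation.
    """
    M = pos.shape[0]
    ndup = M // 2
    nb = 0
    bond_buf = np.empty(4 * M + 4, dtype=np.int64)
    nbonds_inter = 0
    if tether_on:
        for d in range(ndup):
            i = 2 * d
            j = i + 1
            if not tether_sat(pos[i], ax[i], pos[j], ax[j], box, b_off, sigma):
                return False, i, j, 0, bond_buf[:0]
    reach = 2.0 * a_off + delta
    lim_h = L * L + D * D
    lim = lim_h if lim_h > reach * reach else reach * reach
    for i in range(M):
        pix = pos[i, 0]
        piy = pos[i, 1]
        piz = pos[i, 2]
        uix = ax[i, 0]
        uiy = ax[i, 1]
        uiz = ax[i, 2]
        aix = pix + a_off * uix
        aiy = piy + a_off * uiy
        aiz = piz + a_off * uiz
        for j in range(i + 1, M):
            dx = _mi(pos[j, 0] - pix, box[0])
            dy = _mi(pos[j, 1] - piy, box[1])
            dz = _mi(pos[j, 2] - piz, box[2])
            d2 = dx * dx + dy * dy + dz * dz
            if d2 >= lim:
                continue
            if hard_on and d2 < lim_h:
                if _cyl_overlap_s(dx, dy, dz, uix, uiy, uiz,
                                  ax[j, 0], ax[j, 1], ax[j, 2], L, D, tol):
                    return False, i, j, 0, bond_buf[:0]
            if wells_on:
                bx = _mi(pos[j, 0] + a_off * ax[j, 0] - aix, box[0])
                by = _mi(pos[j, 1] + a_off * ax[j, 1] - aiy, box[1])
                bz = _mi(pos[j, 2] + a_off * ax[j, 2] - aiz, box[2])
                if bx * bx + by * by + bz * bz < delta * delta:
                    di = i // 2
                    dj = j // 2
                    if di == dj:
                        if include_intra:
                            nb += 1
                    else:
                        nb += 1
                        if nbonds_inter >= bond_buf.shape[0]:
                            newbuf = np.empty(2 * bond_buf.shape[0],
                                              dtype=np.int64)
                            newbuf[:nbonds_inter] = bond_buf[:nbonds_inter]
                            bond_buf = newbuf
                        bond_buf[nbonds_inter] = di * ndup + dj
                        nbonds_inter += 1
    return True, -1, -1, nb, bond_buf[:nbonds_inter]


@njit(cache=True)
def _cluster_labels(bond_pairs, ndup):
    """Union-find connected components of the duplex-level bond graph."""
    parent = np.empty(ndup, dtype=np.int64)
    for i in range(ndup):
        parent[i] = i
    for b in range(bond_pairs.shape[0]):
        di = bond_pairs[b] // ndup
        dj = bond_pairs[b] % ndup
        while parent[di] != di:
            parent[di] = parent[parent[di]]
            di = parent[di]
        while parent[dj] != dj:
            parent[dj] = parent[parent[dj]]
            dj = parent[dj]
        if di != dj:
            parent[dj] = di
    labels = np.empty(ndup, dtype=np.int64)
    ncl = 0
    for i in range(ndup):
        r = i
        while parent[r] != r:
            r = parent[r]
        if r == i:
            labels[i] = ncl
            ncl += 1
        else:
            labels[i] = -1
    for i in range(ndup):
        if labels[i] < 0:
            r = i
            while parent[r] != r:
                r = parent[r]
            labels[i] = labels[r]
    return labels, ncl


@njit(cache=True)
def any_overlap(cand_p, cand_u, pos, ax, box, L, D, tol, periodic):
    """Does a candidate cylinder overlap any cylinder in pos/ax?"""
    lim = L * L + D * D
    for j in range(pos.shape[0]):
        if periodic:
            dx = _mi(pos[j, 0] - cand_p[0], box[0])
            dy = _mi(pos[j, 1] - cand_p[1], box[1])
            dz = _mi(pos[j, 2] - cand_p[2], box[2])
        else:
            dx = pos[j, 0] - cand_p[0]
            dy = pos[j, 1] - cand_p[1]
            dz = pos[j, 2] - cand_p[2]
        if dx * dx + dy * dy + dz * dz >= lim:
            continue
        if _cyl_overlap_s(dx, dy, dz, cand_u[0], cand_u[1], cand_u[2],
                          ax[j, 0], ax[j, 1], ax[j, 2], L, D, tol):
            return True
    return False


# ---------------------------------------------------------------------------
# Monte Carlo sweeps
# ---------------------------------------------------------------------------


@njit(cache=True)
def _recompute_asites(pos, ax, a_off, asite):
    for i in range(pos.shape[0]):
        for k in range(3):
            asite[i, k] = pos[i, k] + a_off * ax[i, k]



@njit(cache=True, fastmath=True)
def _bond_list(asite, box, M, ndup, d2well):
    """Inter-duplex bond pairs (duplex-level codes) from the cached A
    sites, with a one-component early reject."""
    ibx = 1.0 / box[0]
    iby = 1.0 / box[1]
    ibz = 1.0 / box[2]
    bond_buf = np.empty(4 * M + 4, dtype=np.int64)
    nbond = 0
    for i in range(M):
        aix = asite[i, 0]
        aiy = asite[i, 1]
        aiz = asite[i, 2]
        for j in range(i + 1, M):
            if j == (i ^ 1):
                continue
            wx = _mi2(asite[j, 0] - aix, box[0], ibx)
            if wx * wx >= d2well:
                continue
            wy = _mi2(asite[j, 1] - aiy, box[1], iby)
            wz = _mi2(asite[j, 2] - aiz, box[2], ibz)
            if wx * wx + wy * wy + wz * wz < d2well:
                if nbond >= bond_buf.shape[0]:
                    nb2 = np.empty(2 * bond_buf.shape[0], dtype=np.int64)
                    nb2[:nbond] = bond_buf[:nbond]
                    bond_buf = nb2
                bond_buf[nbond] = (i // 2) * ndup + (j // 2)
                nbond += 1
    return np.unique(bond_buf[:nbond])


@njit(cache=True, fastmath=True)
def run_sweeps(pos, ax, box, n_sweeps, seed,
               L, D, a_off, b_off, sigma, delta, u0, tol,
               beta_P, max_trans, max_rot, max_lnedge,
               n_single, n_duplex, n_volume, cluster_moves,
               hard_on, wells_on, tether_on, include_intra,
               edge_floor, n_bonds_start,
               sample_every,
               snap_pos, snap_ax, snap_box, snap_stats,
               acc):
    """Run ``n_sweeps`` NPT sweeps in place.

    One sweep = ``n_single`` single-cylinder attempts + ``n_duplex``
    rigid-duplex attempts + ``n_volume`` volume attempts (axes cycled).
    Snapshots are written every ``sample_every`` sweeps into the
    preallocated ``snap_*`` arrays; ``acc`` accumulates
    [attempts, accepts] per move class (single, duplex, volume).
    Returns the final total bond count (intra + inter).
    """
    np.random.seed(seed)
    M = pos.shape[0]
    ndup = M // 2
    n_bonds = n_bonds_start
    isample = 0
    nsample_max = snap_stats.shape[0]
    lim_h = L * L + D * D
    reach = 2.0 * a_off + delta
    lim = lim_h if lim_h > reach * reach else reach * reach
    d2well = delta * delta
    ibx = 1.0 / box[0]
    iby = 1.0 / box[1]
    ibz = 1.0 / box[2]
    asite = np.empty((M, 3))
    _recompute_asites(pos, ax, a_off, asite)
    new_pos = np.empty((M, 3))
    new_asite = np.empty((M, 3))
    cand_p = np.empty((2, 3))
    cand_u = np.empty((2, 3))
    cand_a = np.empty((2, 3))
    bonds_old = np.empty(0, dtype=np.int64)
    for sweep in range(n_sweeps):
        # ---- single-cylinder moves -------------------------------------
        for _m in range(n_single):
            acc[0, 0] += 1
            i = int(np.random.random() * M)
            if i >= M:
                i = M - 1
            partner = i ^ 1
            if np.random.random() < 0.5:
                for k in range(3):
                    cand_p[0, k] = pos[i, k] + (2.0 * np.random.random() - 1.0) * max_trans
                    cand_u[0, k] = ax[i, k]
                if tether_on and not tether_sat(cand_p[0], cand_u[0],
                                                pos[partner], ax[partner],
                                                box, b_off, sigma):
                    continue
            else:
                nvec = _rand_unit()
                theta = (2.0 * np.random.random() - 1.0) * max_rot
                u = _rodrigues(ax[i], nvec, theta)
                un = np.sqrt(_dot(u, u))
                for k in range(3):
                    cand_u[0, k] = u[k] / un
                for k in range(3):
                    cand_p[0, k] = (pos[i, k] - b_off * ax[i, k]) + b_off * cand_u[0, k]
            for k in range(3):
                cand_a[0, k] = cand_p[0, k] + a_off * cand_u[0, k]
            # one fused pass: candidate overlap + new/old bond counts
            npx = cand_p[0, 0]
            npy = cand_p[0, 1]
            npz = cand_p[0, 2]
            nux = cand_u[0, 0]
            nuy = cand_u[0, 1]
            nuz = cand_u[0, 2]
            nax_ = cand_a[0, 0]
            nay_ = cand_a[0, 1]
            naz_ = cand_a[0, 2]
            oax = asite[i, 0]
            oay = asite[i, 1]
            oaz = asite[i, 2]
            opx = pos[i, 0]
            opy = pos[i, 1]
            opz = pos[i, 2]
            nb_new = 0
            nb_old = 0
            rejected = False
            for j in range(M):
                if j == i:
                    continue
                dx = _mi2(pos[j, 0] - npx, box[0], ibx)
                dxx = dx * dx
                if dxx < lim:
                    dy = _mi2(pos[j, 1] - npy, box[1], iby)
                    dz = _mi2(pos[j, 2] - npz, box[2], ibz)
                    d2 = dxx + dy * dy + dz * dz
                    if d2 < lim_h and hard_on:
                        if _cyl_overlap_s(dx, dy, dz, nux, nuy, nuz,
                                          ax[j, 0], ax[j, 1], ax[j, 2],
                                          L, D, tol):
                            rejected = True
                            break
                    if wells_on and d2 < lim and (include_intra
                                                  or j != partner):
                        wx = _mi2(asite[j, 0] - nax_, box[0], ibx)
                        wy = _mi2(asite[j, 1] - nay_, box[1], iby)
                        wz = _mi2(asite[j, 2] - naz_, box[2], ibz)
                        if wx * wx + wy * wy + wz * wz < d2well:
                            nb_new += 1
                if wells_on and n_bonds > 0 and (include_intra
                                                 or j != partner):
                    # old-pose bond: cheap component-wise reject on the
                    # cached A-site separation (skipped when the global
                    # bond count is zero: there is nothing to find)
                    wx = _mi2(asite[j, 0] - oax, box[0], ibx)
                    if wx * wx < d2well:
                        wy = _mi2(asite[j, 1] - oay, box[1], iby)
                        wz = _mi2(asite[j, 2] - oaz, box[2], ibz)
                        if wx * wx + wy * wy + wz * wz < d2well:
                            nb_old += 1
            if rejected:
                continue
            if wells_on:
                dU = -u0 * (nb_new - nb_old)
                if dU > 0.0 and np.random.random() >= np.exp(-dU):
                    continue
                n_bonds += nb_new - nb_old
            for k in range(3):
                pos[i, k] = cand_p[0, k]
                ax[i, k] = cand_u[0, k]
                asite[i, k] = cand_a[0, k]
            acc[0, 1] += 1
        # ---- rigid-duplex moves ----------------------------------------
        for _m in range(n_duplex):
            acc[1, 0] += 1
            dpx = int(np.random.random() * ndup)
            if dpx >= ndup:
                dpx = ndup - 1
            i0 = 2 * dpx
            i1 = i0 + 1
            if np.random.random() < 0.5:
                sx = (2.0 * np.random.random() - 1.0) * max_trans
                sy = (2.0 * np.random.random() - 1.0) * max_trans
                sz = (2.0 * np.random.random() - 1.0) * max_trans
                cand_p[0, 0] = pos[i0, 0] + sx
                cand_p[0, 1] = pos[i0, 1] + sy
                cand_p[0, 2] = pos[i0, 2] + sz
                cand_p[1, 0] = pos[i1, 0] + sx
                cand_p[1, 1] = pos[i1, 1] + sy
                cand_p[1, 2] = pos[i1, 2] + sz
                for k in range(3):
                    cand_u[0, k] = ax[i0, k]
                    cand_u[1, k] = ax[i1, k]
            else:
                nvec = _rand_unit()
                theta = (2.0 * np.random.random() - 1.0) * max_rot
                r0 = np.empty(3)
                r1 = np.empty(3)
                for k in range(3):
                    cen = 0.5 * (pos[i0, k] + pos[i1, k])
                    r0[k] = pos[i0, k] - cen
                    r1[k] = pos[i1, k] - cen
                r0r = _rodrigues(r0, nvec, theta)
                r1r = _rodrigues(r1, nvec, theta)
                u0r = _rodrigues(ax[i0], nvec, theta)
                u1r = _rodrigues(ax[i1], nvec, theta)
                n0 = np.sqrt(_dot(u0r, u0r))
                n1 = np.sqrt(_dot(u1r, u1r))
                for k in range(3):
                    cen = 0.5 * (pos[i0, k] + pos[i1, k])
                    cand_p[0, k] = cen + r0r[k]
                    cand_p[1, k] = cen + r1r[k]
                    cand_u[0, k] = u0r[k] / n0
                    cand_u[1, k] = u1r[k] / n1
            for w in range(2):
                for k in range(3):
                    cand_a[w, k] = cand_p[w, k] + a_off * cand_u[w, k]
            nb_new = 0
            nb_old = 0
            rejected = False
            # mutual pair via minimum image at the candidate poses
            dx = _mi2(cand_p[1, 0] - cand_p[0, 0], box[0], ibx)
            dy = _mi2(cand_p[1, 1] - cand_p[0, 1], box[1], iby)
            dz = _mi2(cand_p[1, 2] - cand_p[0, 2], box[2], ibz)
            d2 = dx * dx + dy * dy + dz * dz
            if hard_on and d2 < lim_h:
                if _cyl_overlap_s(dx, dy, dz, cand_u[0, 0], cand_u[0, 1],
                                  cand_u[0, 2], cand_u[1, 0], cand_u[1, 1],
                                  cand_u[1, 2], L, D, tol):
                    rejected = True
            if not rejected and wells_on and include_intra:
                wx = _mi2(cand_a[1, 0] - cand_a[0, 0], box[0], ibx)
                wy = _mi2(cand_a[1, 1] - cand_a[0, 1], box[1], iby)
                wz = _mi2(cand_a[1, 2] - cand_a[0, 2], box[2], ibz)
                if wx * wx + wy * wy + wz * wz < d2well:
                    nb_new += 1
                wx = _mi2(asite[i1, 0] - asite[i0, 0], box[0], ibx)
                wy = _mi2(asite[i1, 1] - asite[i0, 1], box[1], iby)
                wz = _mi2(asite[i1, 2] - asite[i0, 2], box[2], ibz)
                if wx * wx + wy * wy + wz * wz < d2well:
                    nb_old += 1
            if rejected:
                continue
            for w in range(2):
                iw = i0 if w == 0 else i1
                npx = cand_p[w, 0]
                npy = cand_p[w, 1]
                npz = cand_p[w, 2]
                nax_ = cand_a[w, 0]
                nay_ = cand_a[w, 1]
                naz_ = cand_a[w, 2]
                oax = asite[iw, 0]
                oay = asite[iw, 1]
                oaz = asite[iw, 2]
                for j in range(M):
                    if j == i0 or j == i1:
                        continue
                    dx = _mi2(pos[j, 0] - npx, box[0], ibx)
                    dxx = dx * dx
                    if dxx < lim:
                        dy = _mi2(pos[j, 1] - npy, box[1], iby)
                        dz = _mi2(pos[j, 2] - npz, box[2], ibz)
                        d2 = dxx + dy * dy + dz * dz
                        if d2 < lim_h and hard_on:
                            if _cyl_overlap_s(dx, dy, dz, cand_u[w, 0],
                                              cand_u[w, 1], cand_u[w, 2],
                                              ax[j, 0], ax[j, 1], ax[j, 2],
                                              L, D, tol):
                                rejected = True
                                break
                        if wells_on and d2 < lim:
                            wx = _mi2(asite[j, 0] - nax_, box[0], ibx)
                            wy = _mi2(asite[j, 1] - nay_, box[1], iby)
                            wz = _mi2(asite[j, 2] - naz_, box[2], ibz)
                            if wx * wx + wy * wy + wz * wz < d2well:
                                nb_new += 1
                    if wells_on and n_bonds > 0:
                        wx = _mi2(asite[j, 0] - oax, box[0], ibx)
                        if wx * wx < d2well:
                            wy = _mi2(asite[j, 1] - oay, box[1], iby)
                            wz = _mi2(asite[j, 2] - oaz, box[2], ibz)
                            if wx * wx + wy * wy + wz * wz < d2well:
                                nb_old += 1
                if rejected:
                    break
            if rejected:
                continue
            if wells_on:
                dU = -u0 * (nb_new - nb_old)
                if dU > 0.0 and np.random.random() >= np.exp(-dU):
                    continue
                n_bonds += nb_new - nb_old
            for k in range(3):
                pos[i0, k] = cand_p[0, k]
                pos[i1, k] = cand_p[1, k]
                ax[i0, k] = cand_u[0, k]
                ax[i1, k] = cand_u[1, k]
                asite[i0, k] = cand_a[0, k]
                asite[i1, k] = cand_a[1, k]
            acc[1, 1] += 1
        # ---- anisotropic volume moves ----------------------------------
        if n_volume > 0 and wells_on:
            bonds_old = _bond_list(asite, box, M, ndup, d2well)
        for kvol in range(n_volume):
            acc[2, 0] += 1
            axis = kvol % 3
            uln = (2.0 * np.random.random() - 1.0) * max_lnedge
            f = np.exp(uln)
            if box[axis] * f < edge_floor:
                # below this edge the minimum-image convention is invalid
                # (second periodic images come into interaction range)
                continue
            V_old = box[0] * box[1] * box[2]
            V_new = V_old * f
            if cluster_moves and wells_on:
                labels, ncl = _cluster_labels(bonds_old, ndup)
            else:
                labels = np.arange(ndup)
                ncl = ndup
            cent = np.zeros(ncl)
            cnt = np.zeros(ncl)
            for d in range(ndup):
                c = labels[d]
                cent[c] += 0.5 * (pos[2 * d, axis] + pos[2 * d + 1, axis])
                cnt[c] += 1.0
            for c in range(ncl):
                cent[c] /= cnt[c]
            for m in range(M):
                for k in range(3):
                    new_pos[m, k] = pos[m, k]
                    new_asite[m, k] = asite[m, k]
            for d in range(ndup):
                shift = cent[labels[d]] * (f - 1.0)
                new_pos[2 * d, axis] += shift
                new_pos[2 * d + 1, axis] += shift
                new_asite[2 * d, axis] += shift
                new_asite[2 * d + 1, axis] += shift
            bL = box[axis]
            box_new_axis = bL * f
            # overlap + bond scan of the scaled configuration
            bx = box[0]
            by = box[1]
            bz = box[2]
            if axis == 0:
                bx = box_new_axis
            elif axis == 1:
                by = box_new_axis
            else:
                bz = box_new_axis
            ok = True
            nb_new_total = 0
            inbx = 1.0 / bx
            inby = 1.0 / by
            inbz = 1.0 / bz
            done_scan = False
            for i in range(M):
                if done_scan:
                    break
                for j in range(i + 1, M):
                    dx = _mi2(new_pos[j, 0] - new_pos[i, 0], bx, inbx)
                    dxx = dx * dx
                    if dxx >= lim:
                        continue
                    dy = _mi2(new_pos[j, 1] - new_pos[i, 1], by, inby)
                    dz = _mi2(new_pos[j, 2] - new_pos[i, 2], bz, inbz)
                    d2 = dxx + dy * dy + dz * dz
                    if d2 >= lim:
                        continue
                    if hard_on and d2 < lim_h:
                        if _cyl_overlap_s(dx, dy, dz,
                                          ax[i, 0], ax[i, 1], ax[i, 2],
                                          ax[j, 0], ax[j, 1], ax[j, 2],
                                          L, D, tol):
                            ok = False
                            done_scan = True
                            break
                    if wells_on and d2 < lim:
                        wx = _mi2(new_asite[j, 0] - new_asite[i, 0], bx, inbx)
                        wy = _mi2(new_asite[j, 1] - new_asite[i, 1], by, inby)
                        wz = _mi2(new_asite[j, 2] - new_asite[i, 2], bz, inbz)
                        if wx * wx + wy * wy + wz * wz < d2well:
                            if j == (i ^ 1):
                                if include_intra:
                                    nb_new_total += 1
                            else:
                                nb_new_total += 1
            if not ok:
                continue
            if cluster_moves and wells_on:
                # every existing bond joins duplexes of one cluster, and
                # clusters move rigidly: bonds can only be created, never
                # broken, so a changed total count flags a graph change
                if nb_new_total != n_bonds:
                    continue
                dU = 0.0
            elif wells_on:
                dU = -u0 * (nb_new_total - n_bonds)
            else:
                dU = 0.0
            arg = -dU - beta_P * (V_new - V_old) + (ncl + 1) * uln
            if arg < 0.0 and np.random.random() >= np.exp(arg):
                continue
            for m in range(M):
                pos[m, axis] = new_pos[m, axis]
                asite[m, axis] = new_asite[m, axis]
            box[axis] = box_new_axis
            ibx = 1.0 / box[0]
            iby = 1.0 / box[1]
            ibz = 1.0 / box[2]
            if wells_on and not cluster_moves:
                n_bonds = nb_new_total
                bonds_old = _bond_list(asite, box, M, ndup, d2well)
            acc[2, 1] += 1
        # ---- sampling ---------------------------------------------------
        if sample_every > 0 and (sweep + 1) % sample_every == 0:
            if isample < nsample_max:
                snap_pos[isample] = pos
                snap_ax[isample] = ax
                snap_box[isample] = box
                snap_stats[isample, 0] = sweep + 1
                snap_stats[isample, 1] = box[0] * box[1] * box[2]
                snap_stats[isample, 2] = n_bonds
                isample += 1
    return n_bonds


# ---------------------------------------------------------------------------
# excluded-volume hit-or-miss integration
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def xv_hits(posA, axA, posB, axB, L, D, half_box, n_samples, seed,
            mode, tol):
    """Hit-or-miss samples for the pair excluded volume of two rigid
    conformers (no periodic boundaries).

    mode: 0 = fully fixed orientations, 1 = independent azimuthal rotations
    of each conformer about the z axis, 2 = independent isotropic
    rotations.  Returns (hits, outer_hits) where outer_hits counts hits
    with any displacement component beyond 95% of the half box
    (containment check).
    """
    np.random.seed(seed)
    mA = posA.shape[0]
    mB = posB.shape[0]
    hits = 0
    outer = 0
    pA = np.empty((mA, 3))
    uA = np.empty((mA, 3))
    pB = np.empty((mB, 3))
    uB = np.empty((mB, 3))
    lim = L * L + D * D
    for _s in range(n_samples):
        dx = (2.0 * np.random.random() - 1.0) * half_box[0]
        dy = (2.0 * np.random.random() - 1.0) * half_box[1]
        dz = (2.0 * np.random.random() - 1.0) * half_box[2]
        if mode == 0:
            for a in range(mA):
                for k in range(3):
                    pA[a, k] = posA[a, k]
                    uA[a, k] = axA[a, k]
            for b in range(mB):
                for k in range(3):
                    pB[b, k] = posB[b, k]
                    uB[b, k] = axB[b, k]
        elif mode == 1:
            phiA = 2.0 * np.pi * np.random.random()
            phiB = 2.0 * np.pi * np.random.random()
            ca = np.cos(phiA)
            sa = np.sin(phiA)
            cb = np.cos(phiB)
            sb = np.sin(phiB)
            for a in range(mA):
                pA[a, 0] = ca * posA[a, 0] - sa * posA[a, 1]
                pA[a, 1] = sa * posA[a, 0] + ca * posA[a, 1]
                pA[a, 2] = posA[a, 2]
                uA[a, 0] = ca * axA[a, 0] - sa * axA[a, 1]
                uA[a, 1] = sa * axA[a, 0] + ca * axA[a, 1]
                uA[a, 2] = axA[a, 2]
            for b in range(mB):
                pB[b, 0] = cb * posB[b, 0] - sb * posB[b, 1]
                pB[b, 1] = sb * posB[b, 0] + cb * posB[b, 1]
                pB[b, 2] = posB[b, 2]
                uB[b, 0] = cb * axB[b, 0] - sb * axB[b, 1]
                uB[b, 1] = sb * axB[b, 0] + cb * axB[b, 1]
                uB[b, 2] = axB[b, 2]
        else:
            RA = _rand_rotmat()
            RB = _rand_rotmat()
            for a in range(mA):
                for k in range(3):
                    pA[a, k] = (RA[k, 0] * posA[a, 0] + RA[k, 1] * posA[a, 1]
                                + RA[k, 2] * posA[a, 2])
                    uA[a, k] = (RA[k, 0] * axA[a, 0] + RA[k, 1] * axA[a, 1]
                                + RA[k, 2] * axA[a, 2])
            for b in range(mB):
                for k in range(3):
                    pB[b, k] = (RB[k, 0] * posB[b, 0] + RB[k, 1] * posB[b, 1]
                                + RB[k, 2] * posB[b, 2])
                    uB[b, k] = (RB[k, 0] * axB[b, 0] + RB[k, 1] * axB[b, 1]
                                + RB[k, 2] * axB[b, 2])
        hit = False
        for a in range(mA):
            for b in range(mB):
                rx = pB[b, 0] + dx - pA[a, 0]
                ry = pB[b, 1] + dy - pA[a, 1]
                rz = pB[b, 2] + dz - pA[a, 2]
                if rx * rx + ry * ry + rz * rz >= lim:
                    continue
                if _cyl_overlap_s(rx, ry, rz, uA[a, 0], uA[a, 1], uA[a, 2],
                                  uB[b, 0], uB[b, 1], uB[b, 2], L, D, tol):
                    hit = True
                    break
            if hit:
                break
        if hit:
            hits += 1
            if (abs(dx) > 0.95 * half_box[0] or abs(dy) > 0.95 * half_box[1]
                    or abs(dz) > 0.95 * half_box[2]):
                outer += 1
    return hits, outer
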