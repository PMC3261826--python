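"""Numba kernels: RNG, interaction sampling, ray stepping, history loop.

Everything here is nopython-compiled and operates on packed arrays prepared
by :mod:`physics`, :mod:`geometry` and :mod:`transport`.  One independent
counter-seeded RNG stream per history makes results independent of execution
order and lets paired runs share primaries (common random numbers).

Units inside the kernels: energies in eV, lengths in cm.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# particle kinds
NEUTRON = 0
PHOTON = 1

# deposit tags
TAG_PROTON = 0        # H recoil (neutron lineage)
TAG_NEUTRON = 1       # heavy recoil / sub-cutoff neutron termination
TAG_E_NLINEAGE = 2    # electron progeny of neutron-induced photons
TAG_E_GLINEAGE = 3    # electron progeny of primary photons
N_TAGS = 4

M_EC2_EV = 0.51099895e6
PAIR_THRESHOLD_EV = 2.0 * M_EC2_EV
KT_300K_EV = 0.02585  # kT at 300 K

_EPS = 1.0e-7  # cm, boundary nudge
_BIG = 1.0e30


# ----------------------------------------------------------------------------
# RNG: xorshift128+ seeded through splitmix64, one stream per history
# ----------------------------------------------------------------------------

@njit(cache=True, inline="always", fastmath=True)
def _splitmix64(z):
    z = z + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def init_state(seed, history):
    """Independent 128-bit stream for (seed, history)."""
    state = np.empty(2, dtype=np.uint64)
    base = np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15) + np.uint64(history)
    s0 = _splitmix64(base)
    s1 = _splitmix64(s0 + np.uint64(0x9E3779B97F4A7C15))
    if s0 == np.uint64(0) and s1 == np.uint64(0):
        s1 = np.uint64(1)
    state[0] = s0
    state[1] = s1
    return state


@njit(cache=True, inline="always", fastmath=True)
def _next_u64(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 = s1 ^ s0 ^ (s1 >> np.uint64(18)) ^ (s0 >> np.uint64(5))
    state[1] = s1
    return s1 + s0


@njit(cache=True, inline="always", fastmath=True)
def rand(state):
    """Uniform double in [2^-54, 1)."""
    return (_next_u64(state) >> np.uint64(11)) * 1.1102230246251565e-16 + 5.551115123125783e-17


# ----------------------------------------------------------------------------
# direction helpers
# ----------------------------------------------------------------------------

@njit(cache=True, inline="always", fastmath=True)
def isotropic_dir(state):
    mu = 2.0 * rand(state) - 1.0
    phi = 6.283185307179586 * rand(state)
    s = np.sqrt(max(0.0, 1.0 - mu * mu))
    return s * np.cos(phi), s * np.sin(phi), mu


@njit(cache=True, inline="always", fastmath=True)
def rotate_dir(ux, uy, uz, mu, phi):
    """Rotate unit vector u by polar angle acos(mu) about a random azimuth."""
    s = np.sqrt(max(0.0, 1.0 - mu * mu))
    cphi = np.cos(phi)
    sphi = np.sin(phi)
    a = np.sqrt(max(0.0, 1.0 - uz * uz))
    if a > 1.0e-10:
        nx = mu * ux + s * (ux * uz * cphi - uy * sphi) / a
        ny = mu * uy + s * (uy * uz * cphi + ux * sphi) / a
        nz = mu * uz - s * a * cphi
    else:  # beam along +-z: rotate about x/y directly
        sign = 1.0 if uz > 0.0 else -1.0
        nx = s * cphi
        ny = s * sphi
        nz = sign * mu
    norm = 1.0 / np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx * norm, ny * norm, nz * norm


# ----------------------------------------------------------------------------
# cross-section lookup (uniform-in-log grids, linear interpolation in ln E)
# ----------------------------------------------------------------------------

@njit(cache=True, inline="always", fastmath=True)
def _grid_interp(values, lnE0, dln, ng, e):
    u = (np.log(e) - lnE0) / dln
    if u <= 0.0:
        return values[0]
    if u >= ng - 1:
        return values[ng - 1]
    i = int(u)
    f = u - i
    return values[i] * (1.0 - f) + values[i + 1] * f


# ----------------------------------------------------------------------------
# interaction sampling
# ----------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def sample_watt(a_ev, b_inv_ev, state):
    """Watt fission spectrum by the standard two-exponential trick."""
    # E = a*(w + (a*b/4) + (2w*a*b/4)^(1/2)*cos-free form): use the classic
    # algorithm: K = 1 + ab/8; L = a*(K + sqrt(K^2-1)); M = L/a - 1
    K = 1.0 + a_ev * b_inv_ev / 8.0
    L = a_ev * (K + np.sqrt(K * K - 1.0))
    M = L / a_ev - 1.0
    while True:
        x = -np.log(rand(state))
        y = -np.log(rand(state))
        if (y - M * (x + 1.0)) ** 2 <= b_inv_ev * L * x:
            return L * x


@njit(cache=True, fastmath=True)
def elastic_asymptotic(E, ux, uy, uz, A, state):
    """Elastic scattering off a stationary nucleus, isotropic in CM."""
    alpha = ((A - 1.0) / (A + 1.0)) ** 2
    mu_cm = 2.0 * rand(state) - 1.0
    E2 = E * ((1.0 + alpha) + (1.0 - alpha) * mu_cm) * 0.5
    denom = np.sqrt(A * A + 2.0 * A * mu_cm + 1.0)
    mu_lab = (1.0 + A * mu_cm) / denom
    if mu_lab > 1.0:
        mu_lab = 1.0
    elif mu_lab < -1.0:
        mu_lab = -1.0
    phi = 6.283185307179586 * rand(state)
    nx, ny, nz = rotate_dir(ux, uy, uz, mu_lab, phi)
    return E2, nx, ny, nz


@njit(cache=True, fastmath=True)
def elastic_free_gas(E, ux, uy, uz, A, kT, state):
    """Elastic scattering off a 300 K Maxwellian free-gas target.

    Target speed is drawn from the relative-speed-weighted Maxwellian by the
    standard two-component rejection scheme, then the collision is isotropic
    in the centre of mass.  Works in units where neutron kinetic energy
    E = v^2 (mass folded into the speed scale).
    """
    vn = np.sqrt(E)
    beta = np.sqrt(A / kT)  # target: E_t = A V^2, Maxwell ~ exp(-A V^2 / kT)
    y = vn * beta
    # sample x = beta*V and target direction cosine mu_t
    while True:
        if rand(state) * (1.7724538509055159 * y + 2.0) < 1.7724538509055159 * y:
            # pdf ~ x^2 exp(-x^2): x^2 = Gamma(3/2) = Exp(1) + N(0,1)^2/2
            z = np.sqrt(-2.0 * np.log(rand(state))) * np.cos(
                6.283185307179586 * rand(state)
            )
            x2 = -np.log(rand(state)) + 0.5 * z * z
        else:
            # pdf ~ x^3 exp(-x^2): x^2 = Gamma(2) = Exp(1)+Exp(1)
            x2 = -np.log(rand(state)) - np.log(rand(state))
        V = np.sqrt(x2) / beta
        mu_t = 2.0 * rand(state) - 1.0
        vrel = np.sqrt(max(1.0e-30, vn * vn + V * V - 2.0 * vn * V * mu_t))
        if rand(state) * (vn + V) <= vrel:
            break
    # target velocity vector (azimuth uniform about the neutron direction)
    phi = 6.283185307179586 * rand(state)
    tx, ty, tz = rotate_dir(ux, uy, uz, mu_t, phi)
    vtx, vty, vtz = V * tx, V * ty, V * tz
    # centre-of-mass frame
    inv = 1.0 / (1.0 + A)
    cx = (vn * ux + A * vtx) * inv
    cy = (vn * uy + A * vty) * inv
    cz = (vn * uz + A * vtz) * inv
    rx = vn * ux - cx
    ry = vn * uy - cy
    rz = vn * uz - cz
    speed_cm = np.sqrt(rx * rx + ry * ry + rz * rz)
    wx, wy, wz = isotropic_dir(state)
    gx = cx + speed_cm * wx
    gy = cy + speed_cm * wy
    gz = cz + speed_cm * wz
    E2 = gx * gx + gy * gy + gz * gz
    g = np.sqrt(E2)
    if g < 1.0e-15:
        return 1.0e-30, ux, uy, uz
    return E2, gx / g, gy / g, gz / g


@njit(cache=True, fastmath=True)
def compton_sample_eps(E_ev, state):
    """Sample epsilon = E'/E from the Klein-Nishina distribution (rejection)."""
    k = E_ev / M_EC2_EV
    eps_min = 1.0 / (1.0 + 2.0 * k)
    a1 = -np.log(eps_min)
    a2 = 0.5 * (1.0 - eps_min * eps_min)
    while True:
        if rand(state) * (a1 + a2) < a1:
            eps = np.exp(-a1 * rand(state))  # pdf ~ 1/eps
        else:
            eps = np.sqrt(eps_min * eps_min + (1.0 - eps_min * eps_min) * rand(state))
        t = (1.0 - eps) / (k * eps)
        sin2 = t * (2.0 - t)
        if rand(state) <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            return eps


# ----------------------------------------------------------------------------
# geometry: first-fit nested boxes, optional voxel grid in a box slot (-2)
# ----------------------------------------------------------------------------

@njit(cache=True, inline="always", fastmath=True)
def material_at(x, y, z, boxes_lo, boxes_hi, box_mat,
                grid_mat, gn0, gn1, gn2, gox, goy, goz, gvx, gvy, gvz):
    """Material index at a point; -1 when outside the world (last box)."""
    for b in range(boxes_lo.shape[0]):
        if (boxes_lo[b, 0] <= x < boxes_hi[b, 0]
                and boxes_lo[b, 1] <= y < boxes_hi[b, 1]
                and boxes_lo[b, 2] <= z < boxes_hi[b, 2]):
            m = box_mat[b]
            if m != -2:
                return m
            i = min(max(int((x - gox) / gvx), 0), gn0 - 1)
            j = min(max(int((y - goy) / gvy), 0), gn1 - 1)
            kk = min(max(int((z - goz) / gvz), 0), gn2 - 1)
            return grid_mat[(i * gn1 + j) * gn2 + kk]
    return -1


@njit(cache=True, inline="always", fastmath=True)
def _in_grid_box(x, y, z, boxes_lo, boxes_hi, box_mat):
    for b in range(boxes_lo.shape[0]):
        if (boxes_lo[b, 0] <= x < boxes_hi[b, 0]
                and boxes_lo[b, 1] <= y < boxes_hi[b, 1]
                and boxes_lo[b, 2] <= z < boxes_hi[b, 2]):
            return box_mat[b] == -2
    return False


@njit(cache=True, inline="always", fastmath=True)
def _boundary_distance_boxes(x, y, z, ux, uy, uz, boxes_lo, boxes_hi):
    """Distance to the nearest box face crossing ahead of the point."""
    tbest = _BIG
    for b in range(boxes_lo.shape[0]):
        tmin = -_BIG
        tmax = _BIG
        hit = True
        for ax in range(3):
            p = x if ax == 0 else (y if ax == 1 else z)
            u = ux if ax == 0 else (uy if ax == 1 else uz)
            lo = boxes_lo[b, ax]
            hi = boxes_hi[b, ax]
            if abs(u) < 1.0e-14:
                if p < lo or p >= hi:
                    hit = False
                    break
            else:
                t1 = (lo - p) / u
                t2 = (hi - p) / u
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > tmin:
                    tmin = t1
                if t2 < tmax:
                    tmax = t2
        if not hit or tmax < tmin:
            continue
        if tmin > _EPS and tmin < tbest:
            tbest = tmin
        if tmax > _EPS and tmax < tbest:
            tbest = tmax
    return tbest


@njit(cache=True, inline="always", fastmath=True)
def _safe_distance(x, y, z, bfound, boxes_lo, boxes_hi):
    """Lower bound on the distance to any surface, for nested box sets.

    Interior distance to the containing box's faces, and for every
    non-containing box the largest per-axis gap (a lower bound on the
    Euclidean distance to that box).  Ancestor boxes are skipped: with
    properly nested geometries their faces lie beyond the current box.
    """
    ds = _BIG
    for ax in range(3):
        p = x if ax == 0 else (y if ax == 1 else z)
        d1 = p - boxes_lo[bfound, ax]
        d2 = boxes_hi[bfound, ax] - p
        if d1 < ds:
            ds = d1
        if d2 < ds:
            ds = d2
    for b in range(boxes_lo.shape[0]):
        if b == bfound:
            continue
        gap = 0.0
        for ax in range(3):
            p = x if ax == 0 else (y if ax == 1 else z)
            g1 = boxes_lo[b, ax] - p
            g2 = p - boxes_hi[b, ax]
            if g1 > gap:
                gap = g1
            if g2 > gap:
                gap = g2
        if gap > 0.0 and gap < ds:
            ds = gap
    return ds


@njit(cache=True, inline="always", fastmath=True)
def _voxel_face_distance(x, y, z, ux, uy, uz, gox, goy, goz, gvx, gvy, gvz):
    tbest = _BIG
    for ax in range(3):
        p = x if ax == 0 else (y if ax == 1 else z)
        u = ux if ax == 0 else (uy if ax == 1 else uz)
        o = gox if ax == 0 else (goy if ax == 1 else goz)
        d = gvx if ax == 0 else (gvy if ax == 1 else gvz)
        if abs(u) < 1.0e-14:
            continue
        i = np.floor((p - o) / d)
        if u > 0.0:
            t = ((i + 1.0) * d + o - p) / u
        else:
            t = (i * d + o - p) / u
        if t < _EPS:
            t = _EPS
        if t < tbest:
            tbest = t
    return tbest


@njit(cache=True)
def traverse_grid(x, y, z, ux, uy, uz, gn, gorigin, gvoxel, out_idx, out_len):
    """Ordered voxel walk of a ray through a grid (incremental stepping).

    Returns the number of traversed voxels; ``out_idx`` receives flat C-order
    voxel indices and ``out_len`` the chord length inside each voxel.
    """
    # advance to the grid if outside
    lox, loy, loz = gorigin[0], gorigin[1], gorigin[2]
    hix = lox + gn[0] * gvoxel[0]
    hiy = loy + gn[1] * gvoxel[1]
    hiz = loz + gn[2] * gvoxel[2]
    tmin = 0.0
    tmax = _BIG
    for ax in range(3):
        p = x if ax == 0 else (y if ax == 1 else z)
        u = ux if ax == 0 else (uy if ax == 1 else uz)
        lo = lox if ax == 0 else (loy if ax == 1 else loz)
        hi = hix if ax == 0 else (hiy if ax == 1 else hiz)
        if abs(u) < 1.0e-14:
            if p < lo or p >= hi:
                return 0
        else:
            t1 = (lo - p) / u
            t2 = (hi - p) / u
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    if tmax <= tmin:
        return 0
    t = tmin + _EPS if tmin > 0.0 else 0.0
    n = 0
    while t < tmax - _EPS and n < out_idx.shape[0]:
        px = x + t * ux
        py = y + t * uy
        pz = z + t * uz
        i = int((px - lox) / gvoxel[0])
        j = int((py - loy) / gvoxel[1])
        kk = int((pz - loz) / gvoxel[2])
        if i < 0 or i >= gn[0] or j < 0 or j >= gn[1] or kk < 0 or kk >= gn[2]:
            break
        step = _voxel_face_distance(px, py, pz, ux, uy, uz,
                                    lox, loy, loz, gvoxel[0], gvoxel[1], gvoxel[2])
        seg = min(step, tmax - t)
        out_idx[n] = (i * gn[1] + j) * gn[2] + kk
        out_len[n] = seg
        n += 1
        t += seg + _EPS
    return n


# ----------------------------------------------------------------------------
# scoring helpers
# ----------------------------------------------------------------------------

@njit(cache=True, inline="always", fastmath=True)
def _region_at(x, y, z, score_mode,
               cham_x0, cham_pitch, cham_n, cham_r, cham_hh,
               region_map, boxes_lo, boxes_hi, box_mat,
               gn0, gn1, gn2, gox, goy, goz, gvx, gvy, gvz):
    if score_mode == 0:
        k = int(np.floor((x - cham_x0) / cham_pitch + 0.5))
        if k < 0 or k >= cham_n:
            return -1
        xc = cham_x0 + k * cham_pitch
        dx = x - xc
        if dx * dx + y * y <= cham_r * cham_r and abs(z) <= cham_hh:
            return k
        return -1
    else:
        if not _in_grid_box(x, y, z, boxes_lo, boxes_hi, box_mat):
            return -1
        i = min(max(int((x - gox) / gvx), 0), gn0 - 1)
        j = min(max(int((y - goy) / gvy), 0), gn1 - 1)
        kk = min(max(int((z - goz) / gvz), 0), gn2 - 1)
        return region_map[(i * gn1 + j) * gn2 + kk]


@njit(cache=True, inline="always", fastmath=True)
def _hist_add(slot, val, h, mark, pos, tlist, tval, tcount):
    """Accumulate into the per-history sparse buffer; returns new tcount."""
    if mark[slot] == h:
        tval[pos[slot]] += val
        return tcount
    if tcount >= tlist.shape[0]:
        return tcount  # buffer full: drop (guarded by generous capacity)
    mark[slot] = h
    pos[slot] = tcount
    tlist[tcount] = slot
    tval[tcount] = val
    return tcount + 1


@njit(cache=True, inline="always", fastmath=True)
def _fl_bin(E, fl_lnE0, fl_dln, fl_nbins):
    b = int((np.log(E) - fl_lnE0) / fl_dln)
    if b < 0:
        b = 0
    elif b >= fl_nbins:
        b = fl_nbins - 1
    return b


@njit(cache=True, inline="always", fastmath=True)
def _chamber_chords(px, py, pz, ux, uy, uz, seg, E, h,
                    cham_x0, cham_pitch, cham_n, cham_r, cham_hh,
                    fl_lnE0, fl_dln, fl_nbins,
                    fl_mark, fl_pos, fl_tlist, fl_tval, fl_tcount):
    """Track-length pieces of a flight segment inside the chamber cylinders."""
    xlo = min(px, px + seg * ux) - cham_r
    xhi = max(px, px + seg * ux) + cham_r
    kmin = int(np.floor((xlo - cham_x0) / cham_pitch))
    kmax = int(np.floor((xhi - cham_x0) / cham_pitch)) + 1
    if kmin < 0:
        kmin = 0
    if kmax >= cham_n:
        kmax = cham_n - 1
    b = _fl_bin(E, fl_lnE0, fl_dln, fl_nbins)
    for k in range(kmin, kmax + 1):
        xc = cham_x0 + k * cham_pitch
        # quadratic for |(p + s u) - axis|^2 = r^2 in the (x, y) plane
        ox = px - xc
        a = ux * ux + uy * uy
        bq = 2.0 * (ox * ux + py * uy)
        c = ox * ox + py * py - cham_r * cham_r
        if a < 1.0e-14:
            if c > 0.0:
                continue
            s0, s1 = 0.0, seg
        else:
            disc = bq * bq - 4.0 * a * c
            if disc <= 0.0:
                continue
            sq = np.sqrt(disc)
            s0 = (-bq - sq) / (2.0 * a)
            s1 = (-bq + sq) / (2.0 * a)
        # z-slab |pz + s uz| <= hh
        if abs(uz) > 1.0e-14:
            za = (-cham_hh - pz) / uz
            zb = (cham_hh - pz) / uz
            if za > zb:
                za, zb = zb, za
            if za > s0:
                s0 = za
            if zb < s1:
                s1 = zb
        elif abs(pz) > cham_hh:
            continue
        if s0 < 0.0:
            s0 = 0.0
        if s1 > seg:
            s1 = seg
        if s1 > s0:
            slot = k * fl_nbins + b
            fl_tcount = _hist_add(slot, s1 - s0, h, fl_mark, fl_pos,
                                  fl_tlist, fl_tval, fl_tcount)
    return fl_tcount


# ----------------------------------------------------------------------------
# flight sampling (piecewise-exponential across boundaries; Woodcock option)
# ----------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _fly(x, y, z, ux, uy, uz, E, kind, h, state,
         # physics
         lnE0_n, dln_n, ng_n, sig_tot_n, lnE0_g, dln_g, ng_g, sig_tot_g,
         # geometry
         boxes_lo, boxes_hi, box_mat, grid_mat,
         gn0, gn1, gn2, gox, goy, goz, gvx, gvy, gvz,
         # fluence tally (chamber or grid-region track lengths, neutrons only)
         fl_mode, region_map,
         cham_x0, cham_pitch, cham_n, cham_r, cham_hh,
         fl_lnE0, fl_dln, fl_nbins,
         fl_mark, fl_pos, fl_tlist, fl_tval, fl_tcount):
    """Advance to the next collision.  Returns (hit, x, y, z, mat, fl_tcount)."""
    tau = -np.log(rand(state))
    # the cross-section lookup index depends only on E within the flight
    if kind == NEUTRON:
        u_e = (np.log(E) - lnE0_n) / dln_n
        ng = ng_n
    else:
        u_e = (np.log(E) - lnE0_g) / dln_g
        ng = ng_g
    if u_e <= 0.0:
        ie = 0
        fe = 0.0
    elif u_e >= ng - 1:
        ie = ng - 2
        fe = 1.0
    else:
        ie = int(u_e)
        fe = u_e - ie
    while True:
        # single first-fit pass: containing box, material, grid membership
        bfound = -1
        for b in range(boxes_lo.shape[0]):
            if (boxes_lo[b, 0] <= x < boxes_hi[b, 0]
                    and boxes_lo[b, 1] <= y < boxes_hi[b, 1]
                    and boxes_lo[b, 2] <= z < boxes_hi[b, 2]):
                bfound = b
                break
        if bfound < 0:
            return False, x, y, z, -1, fl_tcount
        m = box_mat[bfound]
        in_grid = m == -2
        if in_grid:
            i = min(max(int((x - gox) / gvx), 0), gn0 - 1)
            j = min(max(int((y - goy) / gvy), 0), gn1 - 1)
            kk = min(max(int((z - goz) / gvz), 0), gn2 - 1)
            m = grid_mat[(i * gn1 + j) * gn2 + kk]
        if m <= 0:
            sig = 0.0  # material slot 0 is vacuum by construction
        elif kind == NEUTRON:
            row = sig_tot_n[m]
            sig = row[ie] * (1.0 - fe) + row[ie + 1] * fe
        else:
            row = sig_tot_g[m]
            sig = row[ie] * (1.0 - fe) + row[ie + 1] * fe
        if not in_grid and sig > 0.0:
            # nearest-surface shortcut: a flight shorter than the distance
            # to any surface needs no boundary search at all
            d = tau / sig
            if d < _safe_distance(x, y, z, bfound, boxes_lo, boxes_hi):
                if fl_mode == 1 and kind == NEUTRON:
                    fl_tcount = _chamber_chords(
                        x, y, z, ux, uy, uz, d, E, h,
                        cham_x0, cham_pitch, cham_n, cham_r, cham_hh,
                        fl_lnE0, fl_dln, fl_nbins,
                        fl_mark, fl_pos, fl_tlist, fl_tval, fl_tcount)
                return True, x + d * ux, y + d * uy, z + d * uz, m, fl_tcount
        if in_grid:
            tgeo = _voxel_face_distance(x, y, z, ux, uy, uz,
                                        gox, goy, goz, gvx, gvy, gvz)
        else:
            tgeo = _boundary_distance_boxes(x, y, z, ux, uy, uz, boxes_lo, boxes_hi)
        if sig > 0.0 and sig * tgeo >= tau:
            d = tau / sig
            if fl_mode == 1 and kind == NEUTRON:
                fl_tcount = _chamber_chords(x, y, z, ux, uy, uz, d, E, h,
                                            cham_x0, cham_pitch, cham_n, cham_r,
                                            cham_hh, fl_lnE0, fl_dln, fl_nbins,
                                            fl_mark, fl_pos, fl_tlist, fl_tval,
                                            fl_tcount)
            elif fl_mode == 2 and kind == NEUTRON and in_grid:
                i = int((x - gox) / gvx)
                j = int((y - goy) / gvy)
                kk = int((z - goz) / gvz)
                reg = region_map[(i * gn1 + j) * gn2 + kk]
                if reg >= 0:
                    b = _fl_bin(E, fl_lnE0, fl_dln, fl_nbins)
                    fl_tcount = _hist_add(reg * fl_nbins + b, d, h, fl_mark,
                                          fl_pos, fl_tlist, fl_tval, fl_tcount)
            return True, x + d * ux, y + d * uy, z + d * uz, m, fl_tcount
        # cross into the next region
        if fl_mode == 1 and kind == NEUTRON:
            fl_tcount = _chamber_chords(x, y, z, ux, uy, uz, tgeo, E, h,
                                        cham_x0, cham_pitch, cham_n, cham_r,
                                        cham_hh, fl_lnE0, fl_dln, fl_nbins,
                                        fl_mark, fl_pos, fl_tlist, fl_tval,
                                        fl_tcount)
        elif fl_mode == 2 and kind == NEUTRON and in_grid:
            i = int((x - gox) / gvx)
            j = int((y - goy) / gvy)
            kk = int((z - goz) / gvz)
            reg = region_map[(i * gn1 + j) * gn2 + kk]
            if reg >= 0:
                b = _fl_bin(E, fl_lnE0, fl_dln, fl_nbins)
                fl_tcount = _hist_add(reg * fl_nbins + b, tgeo, h, fl_mark,
                                      fl_pos, fl_tlist, fl_tval, fl_tcount)
        tau -= sig * tgeo
        x += (tgeo + _EPS) * ux
        y += (tgeo + _EPS) * uy
        z += (tgeo + _EPS) * uz


@njit(cache=True, fastmath=True)
def _fly_woodcock(x, y, z, ux, uy, uz, E, kind, state,
                  lnE0_n, dln_n, ng_n, sig_tot_n, lnE0_g, dln_g, ng_g, sig_tot_g,
                  maj_n, maj_g,
                  boxes_lo, boxes_hi, box_mat, grid_mat,
                  gn0, gn1, gn2, gox, goy, goz, gvx, gvy, gvz):
    """Woodcock (delta) tracking against a global majorant."""
    if kind == NEUTRON:
        sig_maj = _grid_interp(maj_n, lnE0_n, dln_n, ng_n, E)
    else:
        sig_maj = _grid_interp(maj_g, lnE0_g, dln_g, ng_g, E)
    if sig_maj <= 0.0:
        return False, x, y, z, -1
    while True:
        d = -np.log(rand(state)) / sig_maj
        x += d * ux
        y += d * uy
        z += d * uz
        m = material_at(x, y, z, boxes_lo, boxes_hi, box_mat, grid_mat,
                        gn0, gn1, gn2, gox, goy, goz, gvx, gvy, gvz)
        if m < 0:
            return False, x, y, z, -1
        if m == 0:
            continue
        if kind == NEUTRON:
            sig = _grid_interp(sig_tot_n[m], lnE0_n, dln_n, ng_n, E)
        else:
            sig = _grid_interp(sig_tot_g[m], lnE0_g, dln_g, ng_g, E)
        if rand(state) * sig_maj <= sig:
            return True, x, y, z, m


# ----------------------------------------------------------------------------
# the history loop
# ----------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def run_histories(
    n_hist, hist0, seed,
    # source
    p_neutron, edges_n, cum_n, edges_g, cum_g, log_in_bin,
    src_x, ylo, yhi, zlo, zhi,
    use_fixed, fx_kind, fx_E, fx_px, fx_py, fx_pz, fx_ux, fx_uy, fx_uz,
    # physics (neutron)
    lnE0_n, dln_n, sig_el, sig_cap, sig_tot_n,
    elem_count, elem_A, elem_isH, elem_Q,
    # physics (photon)
    lnE0_g, dln_g, sig_co, sig_pe, sig_pr, sig_tot_g,
    # config
    cut_n, cut_g, thermal_cut, kT, woodcock, maj_n, maj_g,
    # geometry
    boxes_lo, boxes_hi, box_mat, grid_mat, gn, gorigin, gvoxel,
    # scoring
    score_mode, cham_x0, cham_pitch, cham_n, cham_r, cham_hh,
    region_map, n_regions,
    # fluence tally
    fl_mode, fl_lnE0, fl_dln, fl_nbins, n_fl_regions,
    # outputs
    sum_x, sum_x2, fl_sum, fl_sum2, audit, record_audit,
    events, n_events_cap, record_events,
):
    """Transport ``n_hist`` primaries and accumulate history-by-history tallies.

    Returns (E_src, Q_released, E_dep, E_escaped, n_events) totals in eV.
    """
    ng_n = sig_tot_n.shape[1]
    ng_g = sig_tot_g.shape[1]
    gn0, gn1, gn2 = gn[0], gn[1], gn[2]
    gox, goy, goz = gorigin[0], gorigin[1], gorigin[2]
    gvx, gvy, gvz = gvoxel[0], gvoxel[1], gvoxel[2]

    # per-history sparse accumulators (dose)
    nslots = n_regions * N_TAGS
    mark = np.full(nslots, -1, dtype=np.int64)
    pos = np.zeros(nslots, dtype=np.int64)
    tcap = 65536
    tlist = np.zeros(tcap, dtype=np.int64)
    tval = np.zeros(tcap, dtype=np.float64)
    # per-history sparse accumulators (fluence)
    nfl = n_fl_regions * fl_nbins if fl_mode > 0 else 1
    fl_mark = np.full(nfl, -1, dtype=np.int64)
    fl_pos = np.zeros(nfl, dtype=np.int64)
    fl_tlist = np.zeros(tcap, dtype=np.int64)
    fl_tval = np.zeros(tcap, dtype=np.float64)

    # secondary stack
    scap = 256
    st_kind = np.zeros(scap, dtype=np.int64)
    st_lin = np.zeros(scap, dtype=np.int64)
    st_E = np.zeros(scap, dtype=np.float64)
    st_p = np.zeros((scap, 3), dtype=np.float64)
    st_u = np.zeros((scap, 3), dtype=np.float64)

    tot_src = 0.0
    tot_q = 0.0
    tot_dep = 0.0
    tot_esc = 0.0
    n_ev = 0

    for h in range(n_hist):
        state = init_state(seed, hist0 + h)
        # ---- primary ----
        if use_fixed:
            kind = fx_kind
            E0 = fx_E
            px, py, pz = fx_px, fx_py, fx_pz
            dx, dy, dz = fx_ux, fx_uy, fx_uz
        else:
            kind = NEUTRON if rand(state) < p_neutron else PHOTON
            r = rand(state)
            if kind == NEUTRON:
                ib = np.searchsorted(cum_n, r)
                if ib >= cum_n.shape[0]:
                    ib = cum_n.shape[0] - 1
                lo = edges_n[ib]
                hi = edges_n[ib + 1]
            else:
                ib = np.searchsorted(cum_g, r)
                if ib >= cum_g.shape[0]:
                    ib = cum_g.shape[0] - 1
                lo = edges_g[ib]
                hi = edges_g[ib + 1]
            f = rand(state)
            if log_in_bin:
                E0 = lo * (hi / lo) ** f
            else:
                E0 = lo + (hi - lo) * f
            px = src_x
            py = ylo + (yhi - ylo) * rand(state)
            pz = zlo + (zhi - zlo) * rand(state)
            dx, dy, dz = 1.0, 0.0, 0.0

        sp = 0
        st_kind[sp] = kind
        st_lin[sp] = 0 if kind == NEUTRON else 1
        st_E[sp] = E0
        st_p[sp, 0] = px
        st_p[sp, 1] = py
        st_p[sp, 2] = pz
        st_u[sp, 0] = dx
        st_u[sp, 1] = dy
        st_u[sp, 2] = dz
        sp = 1

        e_src = E0
        q_rel = 0.0
        e_dep = 0.0
        e_esc = 0.0
        tcount = 0
        fl_tcount = 0

        while sp > 0:
            sp -= 1
            kind = st_kind[sp]
            lin = st_lin[sp]
            E = st_E[sp]
            x = st_p[sp, 0]
            y = st_p[sp, 1]
            z = st_p[sp, 2]
            ux = st_u[sp, 0]
            uy = st_u[sp, 1]
            uz = st_u[sp, 2]

            while True:
                # cutoff terminations (local kerma deposit of the remainder)
                if kind == NEUTRON and E <= cut_n:
                    reg = _region_at(x, y, z, score_mode, cham_x0, cham_pitch,
                                     cham_n, cham_r, cham_hh, region_map,
                                     boxes_lo, boxes_hi, box_mat,
                                     gn0, gn1, gn2, gox, goy, goz, gvx, gvy, gvz)
                    e_dep += E
                    if reg >= 0:
                        tcount = _hist_add(reg * N_TAGS + TAG_NEUTRON, E, h,
                                           mark, pos, tlist, tval, tcount)
                    if record_events and n_ev < n_events_cap:
                        events[n_ev, 0] = reg
                        events[n_ev, 1] = TAG_NEUTRON
                        events[n_ev, 2] = E
                        events[n_ev, 3] = x
                        events[n_ev, 4] = h
                        n_ev += 1
                    break
                if kind == PHOTON and E <= cut_g:
                    tag = TAG_E_NLINEAGE if lin == 0 else TAG_E_GLINEAGE
                    reg = _region_at(x, y, z, score_mode, cham_x0, cham_pitch,
                                     cham_n, cham_r, cham_hh, region_map,
                                     boxes_lo, boxes_hi, box_mat,
                                     gn0, gn1, gn2, gox, goy, goz, gvx, gvy, gvz)
                    e_dep += E
                    if reg >= 0:
                        tcount = _hist_add(reg * N_TAGS + tag, E, h,
                                           mark, pos, tlist, tval, tcount)
                    if record_events and n_ev < n_events_cap:
                        events[n_ev, 0] = reg
                        events[n_ev, 1] = tag
                        events[n_ev, 2] = E
                        events[n_ev, 3] = x
                        events[n_ev, 4] = h
                        n_ev += 1
                    break

                if woodcock:
                    hit, x, y, z, m = _fly_woodcock(
                        x, y, z, ux, uy, uz, E, kind, state,
                        lnE0_n, dln_n, ng_n, sig_tot_n, lnE0_g, dln_g, ng_g,
                        sig_tot_g, maj_n, maj_g,
                        boxes_lo, boxes_hi, box_mat, grid_mat,
                        gn0, gn1, gn2, gox, goy, goz, gvx, gvy, gvz)
                else:
                    hit, x, y, z, m, fl_tcount = _fly(
                        x, y, z, ux, uy, uz, E, kind, h, state,
                        lnE0_n, dln_n, ng_n, sig_tot_n,
                        lnE0_g, dln_g, ng_g, sig_tot_g,
                        boxes_lo, boxes_hi, box_mat, grid_mat,
                        gn0, gn1, gn2, gox, goy, goz, gvx, gvy, gvz,
                        fl_mode, region_map,
                        cham_x0, cham_pitch, cham_n, cham_r, cham_hh,
                        fl_lnE0, fl_dln, fl_nbins,
                        fl_mark, fl_pos, fl_tlist, fl_tval, fl_tcount)
                if not hit:
                    e_esc += E
                    break

                reg = _region_at(x, y, z, score_mode, cham_x0, cham_pitch,
                                 cham_n, cham_r, cham_hh, region_map,
                                 boxes_lo, boxes_hi, box_mat,
                                 gn0, gn1, gn2, gox, goy, goz, gvx, gvy, gvz)

                if kind == NEUTRON:
                    # select target element and channel (shared interp index)
                    u_e = (np.log(E) - lnE0_n) / dln_n
                    if u_e <= 0.0:
                        ie = 0
                        fe = 0.0
                    elif u_e >= ng_n - 1:
                        ie = ng_n - 2
                        fe = 1.0
                    else:
                        ie = int(u_e)
                        fe = u_e - ie
                    row = sig_tot_n[m]
                    sig_tot = row[ie] * (1.0 - fe) + row[ie + 1] * fe
                    xi = rand(state) * sig_tot
                    acc = 0.0
                    jsel = 0
                    is_cap = False
                    done = False
                    for j in range(elem_count[m]):
                        row = sig_el[m, j]
                        acc += row[ie] * (1.0 - fe) + row[ie + 1] * fe
                        if xi < acc:
                            jsel = j
                            is_cap = False
                            done = True
                            break
                        row = sig_cap[m, j]
                        acc += row[ie] * (1.0 - fe) + row[ie + 1] * fe
                        if xi < acc:
                            jsel = j
                            is_cap = True
                            done = True
                            break
                    if not done:
                        jsel = elem_count[m] - 1
                        is_cap = True
                    if is_cap:
                        # kinetic energy deposits locally, tagged neutron
                        e_dep += E
                        if reg >= 0:
                            tcount = _hist_add(reg * N_TAGS + TAG_NEUTRON, E, h,
                                               mark, pos, tlist, tval, tcount)
                        if record_events and n_ev < n_events_cap:
                            events[n_ev, 0] = reg
                            events[n_ev, 1] = TAG_NEUTRON
                            events[n_ev, 2] = E
                            events[n_ev, 3] = x
                            events[n_ev, 4] = h
                            n_ev += 1
                        Q = elem_Q[m, jsel]
                        q_rel += Q
                        if elem_isH[m, jsel] == 1:
                            # 2.2246 MeV capture gamma, isotropic
                            wx, wy, wz = isotropic_dir(state)
                            if sp < scap:
                                st_kind[sp] = PHOTON
                                st_lin[sp] = 0
                                st_E[sp] = Q
                                st_p[sp, 0] = x
                                st_p[sp, 1] = y
                                st_p[sp, 2] = z
                                st_u[sp, 0] = wx
                                st_u[sp, 1] = wy
                                st_u[sp, 2] = wz
                                sp += 1
                        else:
                            # capture gammas of heavier nuclei deposit locally
                            e_dep += Q
                            if reg >= 0:
                                tcount = _hist_add(reg * N_TAGS + TAG_E_NLINEAGE,
                                                   Q, h, mark, pos, tlist, tval,
                                                   tcount)
                            if record_events and n_ev < n_events_cap:
                                events[n_ev, 0] = reg
                                events[n_ev, 1] = TAG_E_NLINEAGE
                                events[n_ev, 2] = Q
                                events[n_ev, 3] = x
                                events[n_ev, 4] = h
                                n_ev += 1
                        break
                    else:
                        A = elem_A[m, jsel]
                        if E < thermal_cut:
                            E2, nx2, ny2, nz2 = elastic_free_gas(
                                E, ux, uy, uz, A, kT, state)
                        else:
                            E2, nx2, ny2, nz2 = elastic_asymptotic(
                                E, ux, uy, uz, A, state)
                        dep = E - E2  # recoil (signed: free-gas may upscatter)
                        tag = TAG_PROTON if A < 1.5 else TAG_NEUTRON
                        e_dep += dep
                        if reg >= 0:
                            tcount = _hist_add(reg * N_TAGS + tag, dep, h,
                                               mark, pos, tlist, tval, tcount)
                        if record_events and n_ev < n_events_cap:
                            events[n_ev, 0] = reg
                            events[n_ev, 1] = tag
                            events[n_ev, 2] = dep
                            events[n_ev, 3] = x
                            events[n_ev, 4] = h
                            n_ev += 1
                        E = E2
                        ux, uy, uz = nx2, ny2, nz2
                        continue
                else:
                    # photon: compton / photoelectric / pair
                    tag = TAG_E_NLINEAGE if lin == 0 else TAG_E_GLINEAGE
                    s_co = _grid_interp(sig_co[m], lnE0_g, dln_g, ng_g, E)
                    s_pe = _grid_interp(sig_pe[m], lnE0_g, dln_g, ng_g, E)
                    s_pr = _grid_interp(sig_pr[m], lnE0_g, dln_g, ng_g, E)
                    xi = rand(state) * (s_co + s_pe + s_pr)
                    if xi < s_co:
                        eps = compton_sample_eps(E, state)
                        T = E * (1.0 - eps)
                        k = E / M_EC2_EV
                        mu = 1.0 - (1.0 / eps - 1.0) / k
                        if mu > 1.0:
                            mu = 1.0
                        elif mu < -1.0:
                            mu = -1.0
                        e_dep += T
                        if reg >= 0:
                            tcount = _hist_add(reg * N_TAGS + tag, T, h,
                                               mark, pos, tlist, tval, tcount)
                        if record_events and n_ev < n_events_cap:
                            events[n_ev, 0] = reg
                            events[n_ev, 1] = tag
                            events[n_ev, 2] = T
                            events[n_ev, 3] = x
                            events[n_ev, 4] = h
                            n_ev += 1
                        E *= eps
                        phi = 6.283185307179586 * rand(state)
                        ux, uy, uz = rotate_dir(ux, uy, uz, mu, phi)
                        continue
                    elif xi < s_co + s_pe:
                        e_dep += E
                        if reg >= 0:
                            tcount = _hist_add(reg * N_TAGS + tag, E, h,
                                               mark, pos, tlist, tval, tcount)
                        if record_events and n_ev < n_events_cap:
                            events[n_ev, 0] = reg
                            events[n_ev, 1] = tag
                            events[n_ev, 2] = E
                            events[n_ev, 3] = x
                            events[n_ev, 4] = h
                            n_ev += 1
                        break
                    else:
                        dep = E - PAIR_THRESHOLD_EV
                        e_dep += dep
                        if reg >= 0:
                            tcount = _hist_add(reg * N_TAGS + tag, dep, h,
                                               mark, pos, tlist, tval, tcount)
                        if record_events and n_ev < n_events_cap:
                            events[n_ev, 0] = reg
                            events[n_ev, 1] = tag
                            events[n_ev, 2] = dep
                            events[n_ev, 3] = x
                            events[n_ev, 4] = h
                            n_ev += 1
                        # annihilation in place: two back-to-back 511 keV photons
                        wx, wy, wz = isotropic_dir(state)
                        if sp + 1 < scap:
                            sgn = 1.0
                            for _two in range(2):
                                st_kind[sp] = PHOTON
                                st_lin[sp] = lin
                                st_E[sp] = M_EC2_EV
                                st_p[sp, 0] = x
                                st_p[sp, 1] = y
                                st_p[sp, 2] = z
                                st_u[sp, 0] = sgn * wx
                                st_u[sp, 1] = sgn * wy
                                st_u[sp, 2] = sgn * wz
                                sp += 1
                                sgn = -1.0
                        break

        # ---- flush per-history accumulators ----
        for t in range(tcount):
            slot = tlist[t]
            v = tval[t]
            sum_x[slot] += v
            sum_x2[slot] += v * v
        for t in range(fl_tcount):
            slot = fl_tlist[t]
            v = fl_tval[t]
            fl_sum[slot] += v
            fl_sum2[slot] += v * v

        tot_src += e_src
        tot_q += q_rel
        tot_dep += e_dep
        tot_esc += e_esc
        if record_audit:
            audit[h, 0] = e_src
            audit[h, 1] = q_rel
            audit[h, 2] = e_dep
            audit[h, 3] = e_esc

    return tot_src, tot_q, tot_dep, tot_esc, n_ev
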