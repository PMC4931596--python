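"""Numba-compiled hot paths: segment distances, wall tests, MC sweeps.

All kernels work in reduced units (rod diameter D = 1 is the unit of
length unless an explicit diameter argument says otherwise).  They are
deliberately scalar-argument heavy: numba specializes these signatures
once and the call overhead stays tiny.

The RNG used inside the sweep kernels is numba's internal Mersenne
Twister seeded explicitly at kernel entry, so a run is bit-reproducible
for a given seed.
"""

import numpy as np
from numba import njit

__all__ = [
    "seg_dist",
    "rod_fits",
    "overlaps_any_brute",
    "count_violations",
    "insert_random",
    "relax_toward",
    "run_sweeps",
]


@njit(cache=True, inline="always")
def _clamp(x, lo, hi):
    if x < lo:
        return lo
    if x > hi:
        return hi
    return x


@njit(cache=True)
def seg_dist(p1x, p1y, p1z, u1x, u1y, u1z, l1,
             p2x, p2y, p2z, u2x, u2y, u2z, l2):
    """Minimum distance between two finite segments.

    Segment i is {p_i + s u_i : |s| <= l_i} with u_i a unit vector.
    Closed-form clamped solution (Ericson's closest-point recipe adapted
    to a centred parameterization), exact for all configurations
    including parallel and degenerate ones.
    """
    rx = p1x - p2x
    ry = p1y - p2y
    rz = p1z - p2z
    b = u1x * u2x + u1y * u2y + u1z * u2z
    d = u1x * rx + u1y * ry + u1z * rz
    e = u2x * rx + u2y * ry + u2z * rz
    denom = 1.0 - b * b
    if denom > 1e-14:
        s = _clamp((b * e - d) / denom, -l1, l1)
    else:
        s = _clamp(-d, -l1, l1)
    # closest point on segment 2 to P1(s), then re-optimize s; one
    # extra sweep guards the rare clamped-corner cases
    t = 0.0
    for _ in range(2):
        t = _clamp(b * s + e, -l2, l2)
        s = _clamp(b * t - d, -l1, l1)
    wx = rx + s * u1x - t * u2x
    wy = ry + s * u1y - t * u2y
    wz = rz + s * u1z - t * u2z
    return np.sqrt(wx * wx + wy * wy + wz * wz)


@njit(cache=True, inline="always")
def _seg_origin_dist_2d(x1, y1, x2, y2):
    # distance from the origin to the 2D segment (x1,y1)-(x2,y2)
    dx = x2 - x1
    dy = y2 - y1
    dd = dx * dx + dy * dy
    if dd < 1e-24:
        return np.sqrt(x1 * x1 + y1 * y1)
    t = _clamp(-(x1 * dx + y1 * dy) / dd, 0.0, 1.0)
    cx = x1 + t * dx
    cy = y1 + t * dy
    return np.sqrt(cx * cx + cy * cy)


@njit(cache=True)
def rod_fits(px, py, pz, ux, uy, uz, halfL, dia, Rout, Rin, H):
    """Hard-wall feasibility of a spherocylinder in a disk/annulus chamber.

    Both axis endpoints must clear the plates by dia/2 and the outer
    wall by dia/2 (sufficient by convexity of the cylinder); if an
    inner hole is present the axis segment must keep its in-plane
    distance from the chamber axis at or above Rin + dia/2.  Tangency
    is allowed.
    """
    hd = 0.5 * dia
    e1x = px - halfL * ux
    e1y = py - halfL * uy
    e1z = pz - halfL * uz
    e2x = px + halfL * ux
    e2y = py + halfL * uy
    e2z = pz + halfL * uz
    if e1z < hd - 1e-12 or e1z > H - hd + 1e-12:
        return False
    if e2z < hd - 1e-12 or e2z > H - hd + 1e-12:
        return False
    rmax = Rout - hd
    if e1x * e1x + e1y * e1y > rmax * rmax + 1e-12:
        return False
    if e2x * e2x + e2y * e2y > rmax * rmax + 1e-12:
        return False
    if Rin > 0.0:
        if _seg_origin_dist_2d(e1x, e1y, e2x, e2y) < Rin + hd - 1e-12:
            return False
    return True


@njit(cache=True)
def overlaps_any_brute(pos, u, halfL, dia, skip, tx, ty, tz, tux, tuy, tuz):
    """True if the trial rod (t*, tu*) overlaps any rod except ``skip``."""
    N = pos.shape[0]
    reach = 2.0 * halfL + dia
    reach2 = reach * reach
    for j in range(N):
        if j == skip:
            continue
        dx = pos[j, 0] - tx
        dy = pos[j, 1] - ty
        dz = pos[j, 2] - tz
        if dx * dx + dy * dy + dz * dz > reach2:
            continue
        dist = seg_dist(tx, ty, tz, tux, tuy, tuz, halfL,
                        pos[j, 0], pos[j, 1], pos[j, 2],
                        u[j, 0], u[j, 1], u[j, 2], halfL)
        if dist < dia:
            return True
    return False


@njit(cache=True)
def count_violations(pos, u, halfL, dia, wall_dia, Rout, Rin, H):
    """(number of overlapping pairs, number of wall-violating rods);
    pair overlaps tested at ``dia``, walls at ``wall_dia``."""
    N = pos.shape[0]
    reach = 2.0 * halfL + dia
    reach2 = reach * reach
    n_ov = 0
    n_wall = 0
    for i in range(N):
        if not rod_fits(pos[i, 0], pos[i, 1], pos[i, 2],
                        u[i, 0], u[i, 1], u[i, 2], halfL, wall_dia,
                        Rout, Rin, H):
            n_wall += 1
        for j in range(i + 1, N):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            if dx * dx + dy * dy + dz * dz > reach2:
                continue
            dist = seg_dist(pos[i, 0], pos[i, 1], pos[i, 2],
                            u[i, 0], u[i, 1], u[i, 2], halfL,
                            pos[j, 0], pos[j, 1], pos[j, 2],
                            u[j, 0], u[j, 1], u[j, 2], halfL)
            if dist < dia:
                n_ov += 1
    return n_ov, n_wall


@njit(cache=True)
def violator_flags(pos, u, halfL, dia, wall_dia, Rout, Rin, H):
    """Boolean flag per rod: involved in any overlap or wall violation."""
    N = pos.shape[0]
    flags = np.zeros(N, np.bool_)
    reach = 2.0 * halfL + dia
    reach2 = reach * reach
    for i in range(N):
        if not rod_fits(pos[i, 0], pos[i, 1], pos[i, 2],
                        u[i, 0], u[i, 1], u[i, 2], halfL, wall_dia,
                        Rout, Rin, H):
            flags[i] = True
        for j in range(i + 1, N):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            if dx * dx + dy * dy + dz * dz > reach2:
                continue
            dist = seg_dist(pos[i, 0], pos[i, 1], pos[i, 2],
                            u[i, 0], u[i, 1], u[i, 2], halfL,
                            pos[j, 0], pos[j, 1], pos[j, 2],
                            u[j, 0], u[j, 1], u[j, 2], halfL)
            if dist < dia:
                flags[i] = True
                flags[j] = True
    return flags


@njit(cache=True, inline="always")
def _rand_unit_3d():
    while True:
        kx = np.random.normal()
        ky = np.random.normal()
        kz = np.random.normal()
        n2 = kx * kx + ky * ky + kz * kz
        if n2 > 1e-12:
            inv = 1.0 / np.sqrt(n2)
            return kx * inv, ky * inv, kz * inv


@njit(cache=True, inline="always")
def _rotate_about(ux, uy, uz, kx, ky, kz, psi):
    # Rodrigues rotation of u about unit axis k by angle psi
    c = np.cos(psi)
    s = np.sin(psi)
    kdu = kx * ux + ky * uy + kz * uz
    cx = ky * uz - kz * uy
    cy = kz * ux - kx * uz
    cz = kx * uy - ky * ux
    nx = ux * c + cx * s + kx * kdu * (1.0 - c)
    ny = uy * c + cy * s + ky * kdu * (1.0 - c)
    nz = uz * c + cz * s + kz * kdu * (1.0 - c)
    inv = 1.0 / np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx * inv, ny * inv, nz * inv


@njit(cache=True)
def insert_random(N, halfL, dia, wall_dia, Rout, Rin, H, two_d, seed,
                  max_tries):
    """Rejection-sample N non-overlapping rods of diameter ``dia``.

    Wall clearances are enforced at ``wall_dia`` (the final diameter) so
    that they never tighten while the cores are inflated later.
    Returns (pos, u, n_placed); n_placed < N means the try budget ran out.
    """
    np.random.seed(seed)
    pos = np.zeros((N, 3))
    u = np.zeros((N, 3))
    placed = 0
    tries = 0
    hd = 0.5 * wall_dia
    while placed < N and tries < max_tries:
        tries += 1
        x = (np.random.random() * 2.0 - 1.0) * Rout
        y = (np.random.random() * 2.0 - 1.0) * Rout
        if x * x + y * y > Rout * Rout:
            continue
        if two_d:
            z = 0.5 * H
            ang = np.random.random() * np.pi
            ux = np.cos(ang)
            uy = np.sin(ang)
            uz = 0.0
        else:
            z = hd + np.random.random() * (H - wall_dia)
            ux, uy, uz = _rand_unit_3d()
        if not rod_fits(x, y, z, ux, uy, uz, halfL, wall_dia, Rout, Rin, H):
            continue
        if overlaps_any_brute(pos[:placed], u[:placed], halfL, dia, -1,
                              x, y, z, ux, uy, uz):
            continue
        pos[placed, 0] = x
        pos[placed, 1] = y
        pos[placed, 2] = z
        u[placed, 0] = ux
        u[placed, 1] = uy
        u[placed, 2] = uz
        placed += 1
    return pos, u, placed


@njit(cache=True)
def _penalty(pos, u, halfL, dia, wall_dia, Rout, Rin, H, skip,
             x, y, z, ux, uy, uz):
    """Total constraint violation depth of a trial rod: pair overlaps at
    diameter ``dia``, wall clearances at ``wall_dia``."""
    hd = 0.5 * wall_dia
    pen = 0.0
    e1x = x - halfL * ux
    e1y = y - halfL * uy
    e1z = z - halfL * uz
    e2x = x + halfL * ux
    e2y = y + halfL * uy
    e2z = z + halfL * uz
    pen += max(0.0, hd - e1z) + max(0.0, e1z - (H - hd))
    pen += max(0.0, hd - e2z) + max(0.0, e2z - (H - hd))
    rmax = Rout - hd
    pen += max(0.0, np.sqrt(e1x * e1x + e1y * e1y) - rmax)
    pen += max(0.0, np.sqrt(e2x * e2x + e2y * e2y) - rmax)
    if Rin > 0.0:
        pen += max(0.0, (Rin + hd) - _seg_origin_dist_2d(e1x, e1y, e2x, e2y))
    N = pos.shape[0]
    reach = 2.0 * halfL + dia
    reach2 = reach * reach
    for j in range(N):
        if j == skip:
            continue
        dx = pos[j, 0] - x
        dy = pos[j, 1] - y
        dz = pos[j, 2] - z
        if dx * dx + dy * dy + dz * dz > reach2:
            continue
        dist = seg_dist(x, y, z, ux, uy, uz, halfL,
                        pos[j, 0], pos[j, 1], pos[j, 2],
                        u[j, 0], u[j, 1], u[j, 2], halfL)
        if dist < dia:
            pen += dia - dist
    return pen


@njit(cache=True)
def relax_toward(pos, u, halfL, dia_target, wall_dia, Rout, Rin, H, two_d,
                 n_sweeps, delta_t, delta_r, seed, temperature):
    """Overlap-removal sweeps used while inflating rod diameters.

    Moves are accepted when they do not increase the rod's violation
    depth measured at ``dia_target``, or thermally (Metropolis on the
    penalty at the given temperature) so that the greedy descent cannot
    deadlock in a locally jammed cluster; once the configuration is
    feasible at the target diameter and the temperature is zero this
    reduces to hard-core MC.  Init-only: makes no claim of detailed
    balance.
    """
    np.random.seed(seed)
    N = pos.shape[0]
    for _ in range(n_sweeps):
        # systematic order: every rod (violators included) is attempted
        # once per sweep, which drains the violation tail much faster
        # than uniform random picking.  Proposal amplitudes span two
        # decades so tightly caged rods still receive acceptable fine
        # moves (a fixed-amplitude joint move almost always digs a
        # near-wall rod deeper into a constraint).
        for i in range(N):
            scale = 10.0 ** (-2.0 * np.random.random())
            dt_eff = delta_t * scale
            dr_eff = delta_r * scale
            x = pos[i, 0] + (np.random.random() * 2.0 - 1.0) * dt_eff
            y = pos[i, 1] + (np.random.random() * 2.0 - 1.0) * dt_eff
            if two_d:
                z = pos[i, 2]
                ang = (np.random.random() * 2.0 - 1.0) * dr_eff
                c = np.cos(ang)
                s = np.sin(ang)
                ux = c * u[i, 0] - s * u[i, 1]
                uy = s * u[i, 0] + c * u[i, 1]
                uz = 0.0
            else:
                z = pos[i, 2] + (np.random.random() * 2.0 - 1.0) * dt_eff
                kx, ky, kz = _rand_unit_3d()
                psi = np.random.random() * dr_eff
                ux, uy, uz = _rotate_about(u[i, 0], u[i, 1], u[i, 2],
                                           kx, ky, kz, psi)
            pen_old = _penalty(pos, u, halfL, dia_target, wall_dia,
                               Rout, Rin, H, i,
                               pos[i, 0], pos[i, 1], pos[i, 2],
                               u[i, 0], u[i, 1], u[i, 2])
            pen_new = _penalty(pos, u, halfL, dia_target, wall_dia,
                               Rout, Rin, H, i, x, y, z, ux, uy, uz)
            accept = pen_new <= pen_old + 1e-12
            if not accept and temperature > 0.0 and pen_old > 0.0:
                # thermal escape for caged violators only: feasible rods
                # stay strictly feasible, so noise cannot spread
                accept = np.random.random() < np.exp(
                    -(pen_new - pen_old) / temperature)
            if accept:
                pos[i, 0] = x
                pos[i, 1] = y
                pos[i, 2] = z
                u[i, 0] = ux
                u[i, 1] = uy
                u[i, 2] = uz
    n_ov, n_wall = count_violations(pos, u, halfL, dia_target, wall_dia,
                                    Rout, Rin, H)
    return n_ov + n_wall


@njit(cache=True, inline="always")
def _cell_ix(x, Rout, edge, nc):
    ix = int((x + Rout) / edge)
    if ix < 0:
        ix = 0
    elif ix >= nc:
        ix = nc - 1
    return ix


@njit(cache=True)
def _overlap_cells(pos, u, halfL, dia, skip, tx, ty, tz, tux, tuy, tuz,
                   head, nxt, Rout, edge, nc):
    reach = 2.0 * halfL + dia
    reach2 = reach * reach
    cx = _cell_ix(tx, Rout, edge, nc)
    cy = _cell_ix(ty, Rout, edge, nc)
    for ax in range(max(0, cx - 1), min(nc, cx + 2)):
        for ay in range(max(0, cy - 1), min(nc, cy + 2)):
            j = head[ax * nc + ay]
            while j != -1:
                if j != skip:
                    dx = pos[j, 0] - tx
                    dy = pos[j, 1] - ty
                    dz = pos[j, 2] - tz
                    if dx * dx + dy * dy + dz * dz <= reach2:
                        dist = seg_dist(tx, ty, tz, tux, tuy, tuz, halfL,
                                        pos[j, 0], pos[j, 1], pos[j, 2],
                                        u[j, 0], u[j, 1], u[j, 2], halfL)
                        if dist < dia:
                            return True
                j = nxt[j]
    return False


@njit(cache=True)
def run_sweeps(pos, u, halfL, dia, wall_dia, Rout, Rin, H, two_d,
               n_sweeps, delta_t, delta_r, seed,
               snap_every, snap_pos, snap_u, snap_sweep, qser,
               edge, nc):
    """Metropolis sweeps over joint translation+rotation single-rod moves.

    One sweep = N attempted moves on uniformly chosen rods.  A move is
    accepted iff the displaced rod stays inside the chamber and
    overlaps no other rod (hard-particle Metropolis).  Per sweep the
    upper triangle of sum_i u_i u_i^T is accumulated into ``qser``
    (columns xx, yy, zz, xy, xz, yz); snapshots are copied out every
    ``snap_every`` sweeps.  Returns (accepted moves, snapshots stored).
    """
    np.random.seed(seed)
    N = pos.shape[0]
    head = np.full(nc * nc, -1, np.int64)
    nxt = np.full(max(N, 1), -1, np.int64)
    cell = np.empty(max(N, 1), np.int64)
    for i in range(N):
        ci = _cell_ix(pos[i, 0], Rout, edge, nc) * nc + \
            _cell_ix(pos[i, 1], Rout, edge, nc)
        cell[i] = ci
        nxt[i] = head[ci]
        head[ci] = i
    acc = 0
    nsnap = 0
    max_snap = snap_pos.shape[0]
    for sw in range(n_sweeps):
        for _m in range(N):
            i = np.random.randint(0, N)
            tx = pos[i, 0] + (np.random.random() * 2.0 - 1.0) * delta_t
            ty = pos[i, 1] + (np.random.random() * 2.0 - 1.0) * delta_t
            if two_d:
                tz = pos[i, 2]
                ang = (np.random.random() * 2.0 - 1.0) * delta_r
                c = np.cos(ang)
                s = np.sin(ang)
                tux = c * u[i, 0] - s * u[i, 1]
                tuy = s * u[i, 0] + c * u[i, 1]
                tuz = 0.0
            else:
                tz = pos[i, 2] + (np.random.random() * 2.0 - 1.0) * delta_t
                kx, ky, kz = _rand_unit_3d()
                psi = np.random.random() * delta_r
                tux, tuy, tuz = _rotate_about(u[i, 0], u[i, 1], u[i, 2],
                                              kx, ky, kz, psi)
            if not rod_fits(tx, ty, tz, tux, tuy, tuz,
                            halfL, wall_dia, Rout, Rin, H):
                continue
            if _overlap_cells(pos, u, halfL, dia, i, tx, ty, tz,
                              tux, tuy, tuz, head, nxt, Rout, edge, nc):
                continue
            pos[i, 0] = tx
            pos[i, 1] = ty
            pos[i, 2] = tz
            u[i, 0] = tux
            u[i, 1] = tuy
            u[i, 2] = tuz
            ci = _cell_ix(tx, Rout, edge, nc) * nc + \
                _cell_ix(ty, Rout, edge, nc)
            if ci != cell[i]:
                # unlink from old cell
                j = head[cell[i]]
                if j == i:
                    head[cell[i]] = nxt[i]
                else:
                    while nxt[j] != i:
                        j = nxt[j]
                    nxt[j] = nxt[i]
                cell[i] = ci
                nxt[i] = head[ci]
                head[ci] = i
            acc += 1
        qxx = 0.0
        qyy = 0.0
        qzz = 0.0
        qxy = 0.0
        qxz = 0.0
        qyz = 0.0
        for i in range(N):
            qxx += u[i, 0] * u[i, 0]
            qyy += u[i, 1] * u[i, 1]
            qzz += u[i, 2] * u[i, 2]
            qxy += u[i, 0] * u[i, 1]
            qxz += u[i, 0] * u[i, 2]
            qyz += u[i, 1] * u[i, 2]
        qser[sw, 0] = qxx
        qser[sw, 1] = qyy
        qser[sw, 2] = qzz
        qser[sw, 3] = qxy
        qser[sw, 4] = qxz
        qser[sw, 5] = qyz
        if snap_every > 0 and (sw + 1) % snap_every == 0 and nsnap < max_snap:
            for i in range(N):
                for k in range(3):
                    snap_pos[nsnap, i, k] = pos[i, k]
                    snap_u[nsnap, i, k] = u[i, k]
            snap_sweep[nsnap] = sw + 1
            nsnap += 1
    return acc, nsnap
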