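"""Numba kernels: grid ray marching, primary free-path sampling, splatting.

All kernels work on the 2D voxel grid defined by (x0, y0) origin and
(dx, dy) spacing, arrays indexed [iy, ix].  Rays march voxel-by-voxel with
the Amanatides-Woo incremental form of Siddon's algorithm; boundary ties use
the half-open voxel convention (lower boundary inclusive).
"""
from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12
_INF = 1e30


@njit(cache=True, inline="always")
def _clip_segment(px, py, ux, uy, smax, x0, y0, xmax, ymax):
    """Clip ray p + s*u, s in [0, smax], to the grid box. Returns (s0, s1)."""
    s0 = 0.0
    s1 = smax
    if abs(ux) > _EPS:
        ta = (x0 - px) / ux
        tb = (xmax - px) / ux
        lo = min(ta, tb)
        hi = max(ta, tb)
        if lo > s0:
            s0 = lo
        if hi < s1:
            s1 = hi
    elif px < x0 or px >= xmax:
        return 1.0, 0.0
    if abs(uy) > _EPS:
        ta = (y0 - py) / uy
        tb = (ymax - py) / uy
        lo = min(ta, tb)
        hi = max(ta, tb)
        if lo > s0:
            s0 = lo
        if hi < s1:
            s1 = hi
    elif py < y0 or py >= ymax:
        return 1.0, 0.0
    return s0, s1


@njit(cache=True)
def _integral_one(p1x, p1y, p2x, p2y, mu, x0, y0, dx, dy):
    ny, nx = mu.shape
    ex = p2x - p1x
    ey = p2y - p1y
    seglen = np.sqrt(ex * ex + ey * ey)
    if seglen < _EPS:
        return 0.0
    ux = ex / seglen
    uy = ey / seglen
    s0, s1 = _clip_segment(p1x, p1y, ux, uy, seglen,
                           x0, y0, x0 + nx * dx, y0 + ny * dy)
    if s0 >= s1:
        return 0.0
    # enter the grid a hair inside to land in a valid voxel
    s = s0
    px = p1x + (s + 1e-9) * ux
    py = p1y + (s + 1e-9) * uy
    ix = int(np.floor((px - x0) / dx))
    iy = int(np.floor((py - y0) / dy))
    if ix < 0:
        ix = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy < 0:
        iy = 0
    if iy > ny - 1:
        iy = ny - 1
    if ux > _EPS:
        step_x = 1
        s_next_x = s0 + ((x0 + (ix + 1) * dx) - (p1x + s0 * ux)) / ux
        s_dx = dx / ux
    elif ux < -_EPS:
        step_x = -1
        s_next_x = s0 + ((x0 + ix * dx) - (p1x + s0 * ux)) / ux
        s_dx = -dx / ux
    else:
        step_x = 0
        s_next_x = _INF
        s_dx = _INF
    if uy > _EPS:
        step_y = 1
        s_next_y = s0 + ((y0 + (iy + 1) * dy) - (p1y + s0 * uy)) / uy
        s_dy = dy / uy
    elif uy < -_EPS:
        step_y = -1
        s_next_y = s0 + ((y0 + iy * dy) - (p1y + s0 * uy)) / uy
        s_dy = -dy / uy
    else:
        step_y = 0
        s_next_y = _INF
        s_dy = _INF
    total = 0.0
    while s < s1 - _EPS:
        s_stop = min(min(s_next_x, s_next_y), s1)
        if s_stop > s:
            total += mu[iy, ix] * (s_stop - s)
        if s_next_x <= s_next_y:
            ix += step_x
            s_next_x += s_dx
        else:
            iy += step_y
            s_next_y += s_dy
        s = s_stop
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny:
            break
    return total


@njit(cache=True)
def line_integrals(P1, P2, mu, x0, y0, dx, dy):
    """Line integral of ``mu`` along each segment P1[i] -> P2[i] (cm units)."""
    n = P1.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = _integral_one(P1[i, 0], P1[i, 1], P2[i, 0], P2[i, 1],
                               mu, x0, y0, dx, dy)
    return out


@njit(cache=True)
def trace_primaries_kernel(O, D, ebin, tau, type_u, mu_tot, mu_pp, mu_co,
                           matidx, x0, y0, dx, dy, force_pair):
    """March each primary to its sampled first interaction.

    ``tau`` holds the target optical depths (-log u), ``type_u`` the uniforms
    for the interaction-type draw, ``mu_*`` the (n_bins, n_materials)
    coefficient tables and ``matidx`` the (ny, nx) material-id map.

    Returns ``status`` (0 escape, 1 photoelectric, 2 Compton, 3 pair),
    interaction positions, material ids, path lengths from the ray origin,
    and statistical weights (mu_pp/mu_total in forced-pair mode, else 1).
    """
    n = O.shape[0]
    ny, nx = matidx.shape
    status = np.zeros(n, dtype=np.int8)
    pos = np.zeros((n, 2))
    mat_out = np.full(n, -1, dtype=np.int16)
    pathlen = np.zeros(n)
    weight = np.ones(n)
    xmax = x0 + nx * dx
    ymax = y0 + ny * dy
    for i in range(n):
        px = O[i, 0]
        py = O[i, 1]
        ux = D[i, 0]
        uy = D[i, 1]
        eb = ebin[i]
        s0, s1 = _clip_segment(px, py, ux, uy, _INF, x0, y0, xmax, ymax)
        if s0 >= s1:
            continue
        qx = px + (s0 + 1e-9) * ux
        qy = py + (s0 + 1e-9) * uy
        ix = int(np.floor((qx - x0) / dx))
        iy = int(np.floor((qy - y0) / dy))
        if ix < 0:
            ix = 0
        if ix > nx - 1:
            ix = nx - 1
        if iy < 0:
            iy = 0
        if iy > ny - 1:
            iy = ny - 1
        if ux > _EPS:
            step_x = 1
            s_next_x = s0 + ((x0 + (ix + 1) * dx) - (px + s0 * ux)) / ux
            s_dx = dx / ux
        elif ux < -_EPS:
            step_x = -1
            s_next_x = s0 + ((x0 + ix * dx) - (px + s0 * ux)) / ux
            s_dx = -dx / ux
        else:
            step_x = 0
            s_next_x = _INF
            s_dx = _INF
        if uy > _EPS:
            step_y = 1
            s_next_y = s0 + ((y0 + (iy + 1) * dy) - (py + s0 * uy)) / uy
            s_dy = dy / uy
        elif uy < -_EPS:
            step_y = -1
            s_next_y = s0 + ((y0 + iy * dy) - (py + s0 * uy)) / uy
            s_dy = -dy / uy
        else:
            step_y = 0
            s_next_y = _INF
            s_dy = _INF
        depth = 0.0
        s = s0
        t_remaining = tau[i]
        while s < s1 - _EPS:
            s_stop = min(min(s_next_x, s_next_y), s1)
            m = matidx[iy, ix]
            mu_v = mu_tot[eb, m]
            seg = s_stop - s
            if mu_v * seg >= t_remaining and mu_v > 0.0:
                s_int = s + t_remaining / mu_v
                pos[i, 0] = px + s_int * ux
                pos[i, 1] = py + s_int * uy
                pathlen[i] = s_int
                mat_out[i] = m
                if force_pair == 1:
                    status[i] = 3
                    weight[i] = mu_pp[eb, m] / mu_v
                else:
                    u = type_u[i]
                    f_pp = mu_pp[eb, m] / mu_v
                    f_co = mu_co[eb, m] / mu_v
                    if u < f_pp:
                        status[i] = 3
                    elif u < f_pp + f_co:
                        status[i] = 2
                    else:
                        status[i] = 1
                break
            t_remaining -= mu_v * seg
            depth += mu_v * seg
            if s_next_x <= s_next_y:
                ix += step_x
                s_next_x += s_dx
            else:
                iy += step_y
                s_next_y += s_dy
            s = s_stop
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny:
                break
    return status, pos, mat_out, pathlen, weight


@njit(cache=True)
def splat_gaussian(PX, PY, W, img, x0, y0, dx, dy, sigma, trunc):
    """Accumulate truncated-Gaussian splats (mass W[i] each) into ``img``.

    The kernel is renormalised over its in-grid truncated support so each
    splat deposits exactly its weight (up to points falling entirely
    off-grid).
    """
    ny, nx = img.shape
    rad = trunc * sigma
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for i in range(PX.shape[0]):
        cx = PX[i]
        cy = PY[i]
        ix_lo = int(np.floor((cx - rad - x0) / dx))
        ix_hi = int(np.floor((cx + rad - x0) / dx))
        iy_lo = int(np.floor((cy - rad - y0) / dy))
        iy_hi = int(np.floor((cy + rad - y0) / dy))
        if ix_lo < 0:
            ix_lo = 0
        if iy_lo < 0:
            iy_lo = 0
        if ix_hi > nx - 1:
            ix_hi = nx - 1
        if iy_hi > ny - 1:
            iy_hi = ny - 1
        if ix_lo > ix_hi or iy_lo > iy_hi:
            continue
        norm = 0.0
        for iy in range(iy_lo, iy_hi + 1):
            yv = y0 + (iy + 0.5) * dy - cy
            for ix in range(ix_lo, ix_hi + 1):
                xv = x0 + (ix + 0.5) * dx - cx
                r2 = xv * xv + yv * yv
                if r2 <= rad * rad:
                    norm += np.exp(-r2 * inv2s2)
        if norm <= 0.0:
            continue
        scale = W[i] / norm
        for iy in range(iy_lo, iy_hi + 1):
            yv = y0 + (iy + 0.5) * dy - cy
            for ix in range(ix_lo, ix_hi + 1):
                xv = x0 + (ix + 0.5) * dx - cx
                r2 = xv * xv + yv * yv
                if r2 <= rad * rad:
                    img[iy, ix] += scale * np.exp(-r2 * inv2s2)
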