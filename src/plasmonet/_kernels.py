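"""Numba inner loops for the particle simulator.

The per-particle update order matters (collision exclusion is sequential),
so these stages cannot be vectorised; they are compiled instead. All
randomness is pre-drawn by the caller from a single generator, which keeps
runs bit-reproducible and lets a pure-Python reference path consume the
identical draws.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DEG = np.pi / 180.0
NEG_INF = -1.0e30  # sentinel for out-of-arena sensor reads


@njit(cache=True)
def _sensor_value(trail, height, mask, w_h, r, c):
    nrows, ncols = trail.shape
    if r < 0 or r >= nrows or c < 0 or c >= ncols or not mask[r, c]:
        return NEG_INF
    if w_h > 0.0:
        return trail[r, c] - w_h * height[r, c]
    return trail[r, c]


@njit(cache=True)
def sensory_stage(order, pos_r, pos_c, heading, trail, height, mask,
                  w_h, sa, ra, so, tie_draws):
    """Steer every particle, in the given order.

    Three sensors at offset ``so`` ahead at angles {-sa, 0, +sa} relative
    to the heading read trail minus height penalty. The best sensor wins;
    a left/right tie behind the front resolves by the pre-drawn uniform.
    """
    n = order.shape[0]
    for k in range(n):
        i = order[k]
        h = heading[i]
        pr = pos_r[i]
        pc = pos_c[i]
        af = h * DEG
        al = (h - sa) * DEG
        ar = (h + sa) * DEG
        fr = int(np.rint(pr + so * np.sin(af)))
        fc = int(np.rint(pc + so * np.cos(af)))
        lr = int(np.rint(pr + so * np.sin(al)))
        lc = int(np.rint(pc + so * np.cos(al)))
        rr = int(np.rint(pr + so * np.sin(ar)))
        rc = int(np.rint(pc + so * np.cos(ar)))
        f = _sensor_value(trail, height, mask, w_h, fr, fc)
        left = _sensor_value(trail, height, mask, w_h, lr, lc)
        right = _sensor_value(trail, height, mask, w_h, rr, rc)
        if f >= left and f >= right:
            continue
        if left > right:
            h = h - ra
        elif right > left:
            h = h + ra
        else:  # left == right > front: random turn
            h = h - ra if tie_draws[k] < 0.5 else h + ra
        heading[i] = h % 360.0


@njit(cache=True)
def motor_stage(order, pos_r, pos_c, heading, cell_r, cell_c, occ, trail,
                mask, height, ss, deposit, h_max, reset_draws):
    """Move every particle one attempt, in the given order.

    A successful move (destination habitable, passable and unoccupied)
    advances the continuous position and deposits trail at the new cell;
    a blocked move leaves the particle in place with a fresh uniform
    random heading and deposits nothing.
    """
    n = order.shape[0]
    nrows, ncols = mask.shape
    for k in range(n):
        i = order[k]
        a = heading[i] * DEG
        nr = pos_r[i] + ss * np.sin(a)
        nc = pos_c[i] + ss * np.cos(a)
        cr = int(np.rint(nr))
        cc = int(np.rint(nc))
        ok = 0 <= cr < nrows and 0 <= cc < ncols and mask[cr, cc]
        if ok and h_max < 1.0 and height[cr, cc] > h_max:
            ok = False
        if ok:
            same = cr == cell_r[i] and cc == cell_c[i]
            if same or occ[cr, cc] < 0:
                if not same:
                    occ[cell_r[i], cell_c[i]] = -1
                    occ[cr, cc] = i
                    cell_r[i] = cr
                    cell_c[i] = cc
                pos_r[i] = nr
                pos_c[i] = nc
                trail[cr, cc] += deposit
                continue
        heading[i] = reset_draws[k] * 360.0


@njit(cache=True)
def growth_pass(order, pos_r, pos_c, heading, cell_r, cell_c, occ, mask, n,
                counts, g_min, g_max, dir_draws, head_draws):
    """Division: a particle in a comfortably occupied window spawns one
    offspring into a random free 4-neighbour cell. Returns the new count."""
    nrows, ncols = mask.shape
    m = order.shape[0]
    cap = pos_r.shape[0]
    for k in range(m):
        i = order[k]
        cnt = counts[cell_r[i], cell_c[i]]
        if cnt < g_min or cnt > g_max:
            continue
        if n >= cap:
            break
        start = dir_draws[k]
        for d in range(4):
            dd = (start + d) % 4
            if dd == 0:
                rr, cc = cell_r[i] - 1, cell_c[i]
            elif dd == 1:
                rr, cc = cell_r[i], cell_c[i] + 1
            elif dd == 2:
                rr, cc = cell_r[i] + 1, cell_c[i]
            else:
                rr, cc = cell_r[i], cell_c[i] - 1
            if 0 <= rr < nrows and 0 <= cc < ncols and mask[rr, cc] and occ[rr, cc] < 0:
                pos_r[n] = rr
                pos_c[n] = cc
                heading[n] = head_draws[k] * 360.0
                cell_r[n] = rr
                cell_c[n] = cc
                occ[rr, cc] = n
                n += 1
                break
    return n


@njit(cache=True)
def shrink_pass(pos_r, pos_c, heading, cell_r, cell_c, occ, n, counts, s_min):
    """Removal: a particle with fewer than ``s_min`` *other* particles in
    its window dies. All fates are decided against the pre-event counts,
    then survivors are compacted to the front. Returns the new count."""
    j = 0
    for i in range(n):
        if counts[cell_r[i], cell_c[i]] - 1 >= s_min:
            if j != i:
                pos_r[j] = pos_r[i]
                pos_c[j] = pos_c[i]
                heading[j] = heading[i]
                cell_r[j] = cell_r[i]
                cell_c[j] = cell_c[i]
            occ[cell_r[j], cell_c[j]] = j
            j += 1
        else:
            occ[cell_r[i], cell_c[i]] = -1
    return j
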