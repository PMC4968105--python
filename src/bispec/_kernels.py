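"""Numba kernels for the particle-based reaction-diffusion simulator.

Species codes: 0 empty slot, 1 T1, 2 T2, 3 AT1, 4 AT2, 5 AT1T2 (surface),
plus free antibodies A tracked in separate volume arrays.  All lengths in
um, times in s.

The membrane is the z = 0 plane of a cuboid of square base L x L and
height H.  Lateral boundaries are periodic (default) or reflective; top
and bottom are always reflective.  Volume antibodies far from the membrane
(z > far_z) are advanced with a coarse time step (far_mult fine steps at
once); only the near-field population is stepped finely and screened for
reactions.
"""

import math

import numpy as np
from numba import njit

EMPTY, T1, T2, AT1, AT2, AT1T2 = 0, 1, 2, 3, 4, 5

_MAXC = 16384  # association-candidate buffer per step


@njit(cache=True, inline="always")
def _pwrap(x, L):
    if x >= L or x < 0.0:
        x = x % L
    return x


@njit(cache=True, inline="always")
def _reflect(x, L):
    # fold into [0, L]; steps are << L so one or two folds suffice
    while x < 0.0 or x > L:
        if x < 0.0:
            x = -x
        if x > L:
            x = 2.0 * L - x
    return x


@njit(cache=True, inline="always")
def _mi(d, L, periodic):
    if periodic:
        if d > 0.5 * L:
            d -= L
        elif d < -0.5 * L:
            d += L
    return d


@njit(cache=True)
def step_world(
    n_steps, step0,
    L, H, dt, periodic,
    ssp, sx, sy,
    ax, ay, az, abound, abound_stack, n_ab_arr,
    sfree, n_sfree_arr, near, n_near_arr,
    sig_T1, sig_T2, sig_C, sig_A, sig_A_far, far_z, far_mult,
    r_vs, r_ss, place_off,
    p1, p2, p3, p4,
    pd1, pd2, pd34, br3,
    record_every, counts_out, times_out, frame0,
):
    """Advance the world by n_steps (diffusion + reactions), recording counts.

    Mutates every array argument in place.  Counters (n_ab, n_sfree,
    n_near) travel in length-1 int64 arrays so state persists across calls.
    Returns the next frame index.
    """
    cap = ssp.size
    nA = ax.size
    n_ab = n_ab_arr[0]
    n_sfree = n_sfree_arr[0]
    n_near = n_near_arr[0]

    sreact = np.zeros(cap, np.uint8)
    areact = np.zeros(max(nA, 1), np.uint8)
    cand_a = np.empty(_MAXC, np.int64)
    cand_b = np.empty(_MAXC, np.int64)
    cand_ch = np.empty(_MAXC, np.int64)

    r_vs2 = r_vs * r_vs
    r_ss2 = r_ss * r_ss
    frame = frame0

    for istep in range(n_steps):
        gstep = step0 + istep

        # -- far-field volume update and near-list rebuild ------------------
        if gstep % far_mult == 0:
            n_near = 0
            for i in range(nA):
                if abound[i]:
                    continue
                if az[i] > far_z:
                    ax[i] = _pwrap(ax[i] + sig_A_far * np.random.normal(), L) \
                        if periodic else _reflect(ax[i] + sig_A_far * np.random.normal(), L)
                    ay[i] = _pwrap(ay[i] + sig_A_far * np.random.normal(), L) \
                        if periodic else _reflect(ay[i] + sig_A_far * np.random.normal(), L)
                    az[i] = _reflect(az[i] + sig_A_far * np.random.normal(), H)
                if az[i] <= far_z:
                    near[n_near] = i
                    n_near += 1

        # -- fine diffusion: near antibodies --------------------------------
        if sig_A > 0.0:
            for jj in range(n_near):
                i = near[jj]
                if abound[i]:
                    continue
                if periodic:
                    ax[i] = _pwrap(ax[i] + sig_A * np.random.normal(), L)
                    ay[i] = _pwrap(ay[i] + sig_A * np.random.normal(), L)
                else:
                    ax[i] = _reflect(ax[i] + sig_A * np.random.normal(), L)
                    ay[i] = _reflect(ay[i] + sig_A * np.random.normal(), L)
                az[i] = _reflect(az[i] + sig_A * np.random.normal(), H)

        # -- surface diffusion ----------------------------------------------
        for i in range(cap):
            sp = ssp[i]
            if sp == EMPTY:
                continue
            if sp == T1:
                sig = sig_T1
            elif sp == T2:
                sig = sig_T2
            else:
                sig = sig_C
            if sig > 0.0:
                if periodic:
                    sx[i] = _pwrap(sx[i] + sig * np.random.normal(), L)
                    sy[i] = _pwrap(sy[i] + sig * np.random.normal(), L)
                else:
                    sx[i] = _reflect(sx[i] + sig * np.random.normal(), L)
                    sy[i] = _reflect(sy[i] + sig * np.random.normal(), L)

        for i in range(cap):
            sreact[i] = 0
        for jj in range(n_near):
            areact[near[jj]] = 0

        # -- first-order dissociations --------------------------------------
        for i in range(cap):
            sp = ssp[i]
            if sp == AT1 or sp == AT2:
                pd = pd1 if sp == AT1 else pd2
                if pd > 0.0 and np.random.random() < pd:
                    if n_ab > 0:
                        n_ab -= 1
                        ia = abound_stack[n_ab]
                        abound[ia] = False
                        ax[ia] = sx[i]
                        ay[ia] = sy[i]
                        az[ia] = r_vs + place_off
                        areact[ia] = 1
                        near[n_near] = ia
                        n_near += 1
                        ssp[i] = T1 if sp == AT1 else T2
                        sreact[i] = 1
            elif sp == AT1T2:
                if pd34 > 0.0 and np.random.random() < pd34:
                    theta = 2.0 * math.pi * np.random.random()
                    d = r_ss + place_off
                    nx = sx[i] + d * math.cos(theta)
                    ny = sy[i] + d * math.sin(theta)
                    if periodic:
                        nx = _pwrap(nx, L)
                        ny = _pwrap(ny, L)
                    else:
                        nx = _reflect(nx, L)
                        ny = _reflect(ny, L)
                    if np.random.random() < br3:
                        ssp[i] = AT1
                        newsp = T2
                    else:
                        ssp[i] = AT2
                        newsp = T1
                    n_sfree -= 1
                    j = sfree[n_sfree]
                    ssp[j] = newsp
                    sx[j] = nx
                    sy[j] = ny
                    sreact[i] = 1
                    sreact[j] = 1

        # -- association candidates -----------------------------------------
        nc = 0
        if p1 > 0.0 or p2 > 0.0:
            for jj in range(n_near):
                ia = near[jj]
                if abound[ia] or areact[ia]:
                    continue
                z = az[ia]
                if z > r_vs:
                    continue
                z2 = z * z
                for i in range(cap):
                    sp = ssp[i]
                    if sp != T1 and sp != T2:
                        continue
                    if sreact[i]:
                        continue
                    if sp == T1 and p1 <= 0.0:
                        continue
                    if sp == T2 and p2 <= 0.0:
                        continue
                    dx = _mi(ax[ia] - sx[i], L, periodic)
                    dy = _mi(ay[ia] - sy[i], L, periodic)
                    if dx * dx + dy * dy + z2 <= r_vs2 and nc < _MAXC:
                        cand_a[nc] = ia
                        cand_b[nc] = i
                        cand_ch[nc] = 1 if sp == T1 else 2
                        nc += 1
        if p3 > 0.0 or p4 > 0.0:
            for i in range(cap):
                spi = ssp[i]
                if spi != AT1 and spi != AT2:
                    continue
                if sreact[i]:
                    continue
                if spi == AT1:
                    if p3 <= 0.0:
                        continue
                    want = T2
                    ch = 3
                else:
                    if p4 <= 0.0:
                        continue
                    want = T1
                    ch = 4
                for j in range(cap):
                    if ssp[j] != want or sreact[j]:
                        continue
                    dx = _mi(sx[i] - sx[j], L, periodic)
                    dy = _mi(sy[i] - sy[j], L, periodic)
                    if dx * dx + dy * dy <= r_ss2 and nc < _MAXC:
                        cand_a[nc] = i
                        cand_b[nc] = j
                        cand_ch[nc] = ch
                        nc += 1

        # -- resolve in uniformly random order; one reaction per particle ---
        for t in range(nc - 1, 0, -1):
            u = np.random.randint(0, t + 1)
            cand_a[t], cand_a[u] = cand_a[u], cand_a[t]
            cand_b[t], cand_b[u] = cand_b[u], cand_b[t]
            cand_ch[t], cand_ch[u] = cand_ch[u], cand_ch[t]
        for t in range(nc):
            ch = cand_ch[t]
            a = cand_a[t]
            i = cand_b[t]
            if ch <= 2:
                if abound[a] or areact[a] or sreact[i]:
                    continue
                want = T1 if ch == 1 else T2
                if ssp[i] != want:
                    continue
                p = p1 if ch == 1 else p2
                if np.random.random() < p:
                    ssp[i] = AT1 if ch == 1 else AT2
                    abound[a] = True
                    abound_stack[n_ab] = a
                    n_ab += 1
                    areact[a] = 1
                    sreact[i] = 1
            else:
                if sreact[a] or sreact[i]:
                    continue
                if ch == 3 and (ssp[a] != AT1 or ssp[i] != T2):
                    continue
                if ch == 4 and (ssp[a] != AT2 or ssp[i] != T1):
                    continue
                p = p3 if ch == 3 else p4
                if np.random.random() < p:
                    dx = _mi(sx[i] - sx[a], L, periodic)
                    dy = _mi(sy[i] - sy[a], L, periodic)
                    nx = sx[a] + 0.5 * dx
                    ny = sy[a] + 0.5 * dy
                    if periodic:
                        nx = _pwrap(nx, L)
                        ny = _pwrap(ny, L)
                    sx[a] = nx
                    sy[a] = ny
                    ssp[a] = AT1T2
                    ssp[i] = EMPTY
                    sfree[n_sfree] = i
                    n_sfree += 1
                    sreact[a] = 1
                    sreact[i] = 1

        # -- record ----------------------------------------------------------
        if (gstep + 1) % record_every == 0 and frame < counts_out.shape[0]:
            nT1c = 0
            nT2c = 0
            nB1 = 0
            nB2 = 0
            nC = 0
            for i in range(cap):
                sp = ssp[i]
                if sp == T1:
                    nT1c += 1
                elif sp == T2:
                    nT2c += 1
                elif sp == AT1:
                    nB1 += 1
                elif sp == AT2:
                    nB2 += 1
                elif sp == AT1T2:
                    nC += 1
            counts_out[frame, 0] = nA - n_ab
            counts_out[frame, 1] = nT1c
            counts_out[frame, 2] = nT2c
            counts_out[frame, 3] = nB1
            counts_out[frame, 4] = nB2
            counts_out[frame, 5] = nC
            times_out[frame] = (gstep + 1) * dt
            frame += 1

    n_ab_arr[0] = n_ab
    n_sfree_arr[0] = n_sfree
    n_near_arr[0] = n_near
    return frame


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def cal_volume_events(seed, n_steps, L, h, dt, tx, ty, ax, ay, az,
                      sig_A, r, p):
    """Ghost-counted association events between volume tracers and fixed
    surface targets: reactants are not consumed, so the expected event
    count is exactly linear in p (valid in the reaction-limited regime
    where the diffusive step far exceeds the reaction radius)."""
    np.random.seed(seed)
    events = 0
    nT = tx.size
    nA = ax.size
    r2 = r * r
    for _ in range(n_steps):
        for i in range(nA):
            ax[i] = _pwrap(ax[i] + sig_A * np.random.normal(), L)
            ay[i] = _pwrap(ay[i] + sig_A * np.random.normal(), L)
            az[i] = _reflect(az[i] + sig_A * np.random.normal(), h)
            z = az[i]
            if z <= r:
                z2 = z * z
                for j in range(nT):
                    dx = _mi(ax[i] - tx[j], L, True)
                    dy = _mi(ay[i] - ty[j], L, True)
                    if dx * dx + dy * dy + z2 <= r2:
                        if np.random.random() < p:
                            events += 1
    return events


@njit(cache=True)
def cal_surface_decay(seed, n_steps, L, dt, bx, by, tx, ty,
                      sig_b, sig_t, r, p):
    """Pseudo-first-order 2D association: mobile tracers react with (and
    are removed on contact with probability p per step with) a fixed-density
    background that is not consumed.  Returns (events, alive_step_sum) from
    which the effective 2D rate constant follows as
    events / (alive_step_sum * dt * background_density)."""
    np.random.seed(seed)
    nB = bx.size
    nT = tx.size
    alive = np.ones(nT, np.uint8)
    events = 0
    alive_steps = 0
    r2 = r * r
    for _ in range(n_steps):
        for j in range(nB):
            bx[j] = _pwrap(bx[j] + sig_b * np.random.normal(), L)
            by[j] = _pwrap(by[j] + sig_b * np.random.normal(), L)
        for i in range(nT):
            if alive[i] == 0:
                continue
            tx[i] = _pwrap(tx[i] + sig_t * np.random.normal(), L)
            ty[i] = _pwrap(ty[i] + sig_t * np.random.normal(), L)
            alive_steps += 1
            for j in range(nB):
                dx = _mi(tx[i] - bx[j], L, True)
                dy = _mi(ty[i] - by[j], L, True)
                if dx * dx + dy * dy <= r2:
                    if np.random.random() < p:
                        alive[i] = 0
                        events += 1
                        break
    return events, alive_steps
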