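"""Compiled Monte-Carlo photon-transport kernel.

Weighted-photon random walk on a uniform voxel grid using Woodcock (delta)
tracking against the medium's majorant attenuation coefficient:

* free paths are sampled at the majorant ``mu_t_max``; at each tentative
  collision the photon interacts for real with probability
  ``mu_t(voxel) / mu_t_max`` and otherwise continues undeflected;
* fluence is scored with the expected-value collision estimator — every
  tentative collision (real or virtual) deposits ``weight / mu_t_max``,
  which integrates the weight along the path and equals the absorbed
  weight divided by ``mu_a`` in expectation (and remains unbiased where
  ``mu_a`` is zero);
* real collisions absorb the fraction ``mu_a / mu_t`` of the weight
  (implicit capture) and scatter the rest through a Henyey-Greenstein
  deflection at the full scattering coefficient ``mus = musp / (1 - g)``;
* Russian roulette below a weight of 1e-4 with survival factor 10;
* photons leaving the grid are terminated (matched refractive index, no
  boundary reflections).

Randomness is a counter-based splitmix64 stream keyed on
``(run seed, photon index)``, so results are independent of execution order
and bit-reproducible for a given seed.

All distances inside the kernel are mm; coefficient tables are 1/mm.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_S30 = np.uint64(30)
_S27 = np.uint64(27)
_S31 = np.uint64(31)
_S11 = np.uint64(11)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53

_W_MIN = 1e-4
_ROULETTE_M = 10.0


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> _S30)) * _MIX1
    z = (z ^ (z >> _S27)) * _MIX2
    return z ^ (z >> _S31)


@njit(cache=True, inline="always")
def _next_u(state):
    """Advance the stream; return (state, uniform double in [0, 1))."""
    state = state + _GAMMA
    return state, float(_mix64(state) >> _S11) * _INV53


@njit(cache=True, inline="always")
def _photon_state(seed, index):
    return _mix64(np.uint64(seed) ^ _mix64(np.uint64(index) + _GAMMA))


@njit(cache=True, inline="always")
def _hg_cos(g, u):
    if abs(g) < 1e-6:
        return 1.0 - 2.0 * u
    s = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - s * s) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True)
def sample_hg_cosines(g, n, seed):
    """Draw n Henyey-Greenstein scattering cosines (test oracle hook)."""
    out = np.empty(n)
    state = _photon_state(seed, 0)
    for i in range(n):
        state, u = _next_u(state)
        out[i] = _hg_cos(g, u)
    return out


@njit(cache=True, fastmath=True)
def transport(
    labels,
    mua_mm,
    mus_mm,
    g_tab,
    spacing,
    src_pos,
    src_axis,
    src_b1,
    src_b2,
    src_cos_half,
    src_cdf,
    cosine_weighted,
    n_photons,
    seed,
    w0,
    fluence,
    roi_box,
    roi_survival,
    mirror_y0,
    score_box,
):
    """Trace ``n_photons`` and accumulate path-integrated weight (mm scale).

    With ``mirror_y0`` the plane ``y = 0`` is a specular mirror: for a
    source set symmetric about the imaging plane this folds the problem
    onto a half grid containing one LED unit, which is exactly equivalent
    to the full domain by symmetry and doubles the scoring density.

    ``score_box`` is an inclusive voxel-index region ``(ix0, ix1, iy0,
    iy1, iz0, iz1)``: fluence is accumulated only inside it (trajectories
    are unaffected, so in-box values are identical to full scoring).  A
    small box keeps the accumulator cache-resident, which speeds up runs
    that only analyze a narrow band.  Pass ``ix1 < 0`` to score the whole
    grid.

    ``roi_box`` is an importance region ``(x0, x1, y0, y1, z0, z1)`` in
    grid-local mm: photons colliding outside it play Russian roulette with
    survival probability ``roi_survival`` (weight-compensated, so the
    estimate stays unbiased while far-wandering walks are cut short).  Pass
    ``roi_survival = 1`` to disable.

    Returns the energy ledger ``(launched, absorbed, escaped,
    roulette_killed, roulette_boost)``; conservation holds exactly:
    ``launched + roulette_boost == absorbed + escaped + roulette_killed``.
    """
    nx, ny, nz = labels.shape
    h = spacing
    inv_h = 1.0 / h
    lx = nx * h
    ly = ny * h
    lz = nz * h
    n_src = src_cdf.shape[0]

    n_lab = mua_mm.shape[0]
    mut_max = 0.0
    for k in range(n_lab):
        mt = mua_mm[k] + mus_mm[k]
        if mt > mut_max:
            mut_max = mt
    if mut_max <= 0.0:
        mut_max = 1e-12
    inv_mut = 1.0 / mut_max

    # per-label interaction tables: real-collision probability, surviving
    # (scattering) fraction of a real collision
    p_real = np.empty(n_lab)
    albedo = np.empty(n_lab)
    for k in range(n_lab):
        mt = mua_mm[k] + mus_mm[k]
        p_real[k] = mt * inv_mut
        albedo[k] = mus_mm[k] / mt if mt > 0.0 else 0.0

    uniform = True
    lab0 = labels[0, 0, 0]
    for v in labels.flat:
        if v != lab0:
            uniform = False
            break

    sx0, sx1, sy0, sy1, sz0, sz1 = (
        score_box[0],
        score_box[1],
        score_box[2],
        score_box[3],
        score_box[4],
        score_box[5],
    )
    score_all = sx1 < 0

    use_roi = roi_survival < 1.0
    inv_surv = 1.0 / roi_survival if roi_survival > 0.0 else 0.0
    bx0, bx1, by0, by1, bz0, bz1 = (
        roi_box[0],
        roi_box[1],
        roi_box[2],
        roi_box[3],
        roi_box[4],
        roi_box[5],
    )

    absorbed = 0.0
    escaped = 0.0
    rkilled = 0.0
    rboost = 0.0

    for i in range(n_photons):
        state = _photon_state(seed, i)

        # --- source element and emission direction -----------------------
        state, u = _next_u(state)
        e = np.searchsorted(src_cdf, u, side="right")
        if e >= n_src:
            e = n_src - 1
        ch = src_cos_half[e]
        state, u1 = _next_u(state)
        state, u2 = _next_u(state)
        if cosine_weighted:
            ct = math.sqrt(ch * ch + u1 * (1.0 - ch * ch))
        else:
            ct = ch + u1 * (1.0 - ch)
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        phi = 2.0 * math.pi * u2
        cp = math.cos(phi)
        sp = math.sin(phi)
        ux = ct * src_axis[e, 0] + st * (cp * src_b1[e, 0] + sp * src_b2[e, 0])
        uy = ct * src_axis[e, 1] + st * (cp * src_b1[e, 1] + sp * src_b2[e, 1])
        uz = ct * src_axis[e, 2] + st * (cp * src_b1[e, 2] + sp * src_b2[e, 2])

        x = src_pos[e, 0]
        y = src_pos[e, 1]
        z = src_pos[e, 2]

        # --- advance to the grid if launched outside ----------------------
        if x < 0.0 or x >= lx or y < 0.0 or y >= ly or z < 0.0 or z >= lz:
            tmin = 0.0
            tmax = 1.0e30
            miss = False
            for ax in range(3):
                if ax == 0:
                    p, d = x, ux
                    hi = lx
                elif ax == 1:
                    p, d = y, uy
                    hi = ly
                else:
                    p, d = z, uz
                    hi = lz
                if d == 0.0:
                    if p < 0.0 or p > hi:
                        miss = True
                        break
                else:
                    t1 = (0.0 - p) / d
                    t2 = (hi - p) / d
                    if t1 > t2:
                        t1, t2 = t2, t1
                    if t1 > tmin:
                        tmin = t1
                    if t2 < tmax:
                        tmax = t2
            if miss or tmax <= tmin:
                escaped += w0
                continue
            t = tmin + 1e-9
            x += ux * t
            y += uy * t
            z += uz * t
            if x < 0.0 or x >= lx or y < 0.0 or y >= ly or z < 0.0 or z >= lz:
                escaped += w0
                continue

        w = w0
        alive = True
        while alive:
            # tentative free path at the majorant coefficient
            state, u = _next_u(state)
            step = -math.log(1.0 - u) * inv_mut
            x += ux * step
            y += uy * step
            z += uz * step
            if mirror_y0 and y < 0.0:
                y = -y
                uy = -uy
            if x < 0.0 or x >= lx or y < 0.0 or y >= ly or z < 0.0 or z >= lz:
                escaped += w
                break
            ix = int(x * inv_h)
            iy = int(y * inv_h)
            iz = int(z * inv_h)

            # expected-value collision estimator: integral of weight along
            # the path, scored at every tentative collision
            if score_all or (
                sx0 <= ix <= sx1
                and sy0 <= iy <= sy1
                and sz0 <= iz <= sz1
            ):
                fluence[ix, iy, iz] += w * inv_mut

            if uniform:
                lab = lab0
            else:
                lab = labels[ix, iy, iz]
                pr = p_real[lab]
                if pr < 1.0:
                    state, u = _next_u(state)
                    if u >= pr:
                        continue  # virtual collision, direction unchanged

            # real collision: implicit capture, then scatter
            alb = albedo[lab]
            dep = w * (1.0 - alb)
            absorbed += dep
            w *= alb
            if w <= 0.0:
                break

            gg = g_tab[lab]
            state, u = _next_u(state)
            ct = _hg_cos(gg, u)
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            # azimuth by rejection sampling of a unit disc (no trig calls)
            cp = 0.0
            sp = 0.0
            while True:
                state, u = _next_u(state)
                v1 = 2.0 * u - 1.0
                state, u = _next_u(state)
                v2 = 2.0 * u - 1.0
                s2 = v1 * v1 + v2 * v2
                if 0.0 < s2 < 1.0:
                    cp = (v1 * v1 - v2 * v2) / s2
                    sp = 2.0 * v1 * v2 / s2
                    break
            if abs(uz) > 0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct if uz > 0.0 else -ct
            else:
                den = math.sqrt(1.0 - uz * uz)
                nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                nuz = -st * cp * den + uz * ct
                ux, uy, uz = nux, nuy, nuz
            norm = 1.0 / math.sqrt(ux * ux + uy * uy + uz * uz)
            ux *= norm
            uy *= norm
            uz *= norm

            if w < _W_MIN:
                state, u = _next_u(state)
                if u < 1.0 / _ROULETTE_M:
                    rboost += w * (_ROULETTE_M - 1.0)
                    w *= _ROULETTE_M
                else:
                    rkilled += w
                    break

            if use_roi and (
                x < bx0 or x > bx1 or y < by0 or y > by1 or z < bz0 or z > bz1
            ):
                state, u = _next_u(state)
                if u < roi_survival:
                    rboost += w * (inv_surv - 1.0)
                    w *= inv_surv
                else:
                    rkilled += w
                    break

    launched = w0 * n_photons
    return launched, absorbed, escaped, rkilled, rboost
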