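"""Compiled inner loop of the population integrator.

The coupled receptor-channel + Hodgkin-Huxley system is advanced per afferent
with scalar arithmetic, so batching afferents never changes any result.  The
inactivation target of the channel depends only on the stimulus, which is
held constant over a step; it is therefore tabulated once per rib period
(``q_target``) instead of being re-evaluated at every RK4 stage — an exact
rewrite, not an approximation.

If numba is unavailable the engine falls back to the pure-NumPy integrator;
both paths implement the identical scheme.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def rk4_population_kernel(
    sigma,        # (period, B, Nr) channel stimulus, um
    q_target,     # (period, B, Nr) precomputed inactivation targets
    n_steps,
    dt,
    v, m, n, hg,  # (B,) membrane state, modified in place
    p, q,         # (B, Nr) channel state, modified in place
    kp, xp_, ap, itp, itq, gmax,
    g_k, g_na, g_l, v_k, v_na, v_l, i_cm, veq_off,
    a1, b1, c1, a2, b2, c2, a3, c3, a4, c4, a5, c5, a6, b6, c6,
    v_star,
):
    period, n_b, n_r = sigma.shape
    max_ev = int(n_b * (n_steps * dt) / 2.0) + 1024  # refractory bound ~2 ms
    ev_t = np.empty(max_ev)
    ev_id = np.empty(max_ev, np.int64)
    n_ev = 0
    p1 = np.empty(n_r)
    q1 = np.empty(n_r)
    dp = np.empty(n_r)
    dq = np.empty(n_r)
    dp_s = np.empty(n_r)
    dq_s = np.empty(n_r)
    sixth = dt / 6.0
    for i in range(n_steps):
        ip = i % period
        for b in range(n_b):
            vv = v[b]
            mm = m[b]
            nn = n[b]
            hh = hg[b]
            dv_s = 0.0
            dm_s = 0.0
            dn_s = 0.0
            dh_s = 0.0
            for r in range(n_r):
                p1[r] = p[b, r]
                q1[r] = q[b, r]
                dp_s[r] = 0.0
                dq_s[r] = 0.0
            v1 = vv
            m1 = mm
            n1 = nn
            h1 = hh
            for stage in range(4):
                g = 0.0
                for r in range(n_r):
                    sr = sigma[ip, b, r]
                    pt = 1.0 / (1.0 + np.exp(-kp * (sr - xp_ - ap * q1[r])))
                    dp[r] = (pt - p1[r]) * itp
                    dq[r] = (q_target[ip, b, r] - q1[r]) * itq
                    g += p1[r] * (1.0 - q1[r])
                i_stim = gmax * g * (v1 - veq_off)
                x1 = (b1 - v1) / c1
                am = a1 * c1 * (x1 / np.expm1(x1)) if abs(x1) > 1e-12 else a1 * c1
                x2 = (b2 - v1) / c2
                an = a2 * c2 * (x2 / np.expm1(x2)) if abs(x2) > 1e-12 else a2 * c2
                ah = a3 * np.exp(-v1 / c3)
                bm = a4 * np.exp(-v1 / c4)
                bn = a5 * np.exp(-v1 / c5)
                bh = a6 / (np.exp((b6 - v1) / c6) + 1.0)
                n2 = n1 * n1
                dv = (
                    -g_k * n2 * n2 * (v1 - v_k)
                    - g_na * m1 * m1 * m1 * h1 * (v1 - v_na)
                    - g_l * (v1 - v_l)
                    - i_stim
                ) * i_cm
                dm = am * (1.0 - m1) - bm * m1
                dn = an * (1.0 - n1) - bn * n1
                dh = ah * (1.0 - h1) - bh * h1
                w = 2.0 if (stage == 1 or stage == 2) else 1.0
                dv_s += w * dv
                dm_s += w * dm
                dn_s += w * dn
                dh_s += w * dh
                for r in range(n_r):
                    dp_s[r] += w * dp[r]
                    dq_s[r] += w * dq[r]
                if stage < 3:
                    f = dt * 0.5 if stage < 2 else dt
                    v1 = vv + f * dv
                    m1 = mm + f * dm
                    n1 = nn + f * dn
                    h1 = hh + f * dh
                    for r in range(n_r):
                        p1[r] = p[b, r] + f * dp[r]
                        q1[r] = q[b, r] + f * dq[r]
            v_new = vv + sixth * dv_s
            m[b] = mm + sixth * dm_s
            n[b] = nn + sixth * dn_s
            hg[b] = hh + sixth * dh_s
            for r in range(n_r):
                p[b, r] += sixth * dp_s[r]
                q[b, r] += sixth * dq_s[r]
            if vv < v_star and v_new >= v_star and n_ev < max_ev:
                ev_t[n_ev] = (i + 1) * dt
                ev_id[n_ev] = b
                n_ev += 1
            v[b] = v_new
    return ev_t[:n_ev], ev_id[:n_ev], n_ev
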