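"""Numba-compiled inner loop of the Gaussian filter (speed path).

Mirrors :class:`cirpop.kalman.GaussianStateSpace` exactly; the numpy
implementation there is the reference this one is tested against.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


_VAR_FLOOR = 0.25


@njit(cache=True)
def _scalar_update(m, p, idx, coef, y, offset, rvar):
    """One scalar Kalman update in place; returns the loglik contribution."""
    d = m.shape[0]
    hp = np.zeros(d)
    for j in range(d):
        acc = 0.0
        for k in idx:
            acc += p[k, j]
        hp[j] = coef * acc
    s = rvar
    pred = -offset
    for k in idx:
        s += coef * hp[k]
        pred += coef * m[k]
    resid = y - pred
    for j in range(d):
        gain = hp[j] / s
        m[j] += gain * resid
    for j in range(d):
        gj = hp[j] / s
        for k in range(d):
            p[j, k] -= gj * hp[k]
    return -0.5 * (np.log(2.0 * np.pi * s) + resid * resid / s)


@njit(cache=True)
def filter_loglik(
    harvest,  # (T, 6) float
    obs,  # (5, T) float, rows: pre_calves, pre_fy, post_calves, post_females, post_males
    tot,  # (T,) float (nan = missing); ignored unless include_tot
    include_tot,  # bool
    init_mean,  # (7,)
    init_sd,  # (7,)
    mother_idx,  # int array, (1,2) or (2,)
    f_t,  # (B, T)
    phi1_t,  # (B, T)
    phi2,  # (B,)
    p1_t,  # (B, T)
    p2_t,  # (B, T)
):
    b_max, t_max = f_t.shape
    out = np.zeros(b_max)
    pre_c, pre_fy = obs[0], obs[1]
    post_idx = [(0, 3), (1, 2), (4, 5)]
    for b in range(b_max):
        m = init_mean.copy()
        p = np.zeros((7, 7))
        for j in range(7):
            p[j, j] = init_sd[j] ** 2
        ll = 0.0
        s2 = phi2[b]
        v2 = s2 * (1.0 - s2)
        for t in range(t_max):
            if t > 0:
                # ---- predict through harvest + transition
                x = np.empty(6)
                for j in range(6):
                    x[j] = m[j] - harvest[t - 1, j]
                xc = np.maximum(x, 0.0)
                ft = f_t[b, t]
                s1 = phi1_t[b, t]
                q = s2 * ft
                r2 = q * s1 / 2.0
                pool = 0.0
                for col in mother_idx:
                    pool += xc[col]

                a = np.zeros((7, 6))
                for col in mother_idx:
                    a[0, col] = r2
                    a[3, col] = r2
                    a[6, col] = q
                a[1, 0] = s2
                a[4, 3] = s2
                a[2, 1] = s2
                a[2, 2] = s2
                a[5, 4] = s2
                a[5, 5] = s2

                m_new = a @ x
                ap = a @ np.ascontiguousarray(p[:6, :6])
                p_new = ap @ a.T

                p_new[0, 0] += pool * r2 * (1.0 - r2)
                p_new[3, 3] += pool * r2 * (1.0 - r2)
                p_new[0, 3] -= pool * r2 * r2
                p_new[3, 0] -= pool * r2 * r2
                p_new[6, 6] += pool * q * (1.0 - q)
                cov_bc = pool * r2 * (1.0 - q)
                p_new[0, 6] += cov_bc
                p_new[6, 0] += cov_bc
                p_new[3, 6] += cov_bc
                p_new[6, 3] += cov_bc
                p_new[1, 1] += xc[0] * v2
                p_new[4, 4] += xc[3] * v2
                p_new[2, 2] += (xc[1] + xc[2]) * v2
                p_new[5, 5] += (xc[4] + xc[5]) * v2
                for j in range(7):
                    p_new[j, j] += 1e-3
                m = m_new
                p = p_new

            # ---- update with year-t observations
            p1 = p1_t[b, t]
            p2v = p2_t[b, t]
            y = pre_c[t]
            if not np.isnan(y):
                lam = max(m[6], 0.0)
                ll += _scalar_update(
                    m, p, np.array([6]), p1, y, 0.0, lam * p1 * (1 - p1) + _VAR_FLOOR
                )
            y = pre_fy[t]
            if not np.isnan(y):
                lam = max(m[1] + m[2] + m[4], 0.0)
                ll += _scalar_update(
                    m, p, np.array([1, 2, 4]), p1, y, 0.0,
                    lam * p1 * (1 - p1) + _VAR_FLOOR,
                )
            for g in range(3):
                y = obs[2 + g, t]
                if not np.isnan(y):
                    i0, i1 = post_idx[g]
                    harv = harvest[t, i0] + harvest[t, i1]
                    lam = max(m[i0] + m[i1] - harv, 0.0)
                    ll += _scalar_update(
                        m, p, np.array([i0, i1]), p2v, y, p2v * harv,
                        lam * p2v * (1 - p2v) + _VAR_FLOOR,
                    )
            if include_tot:
                y = tot[t]
                if not np.isnan(y):
                    harv = 0.0
                    lam = 0.0
                    for j in range(6):
                        harv += harvest[t, j]
                        lam += m[j]
                    lam = max(lam - harv, 0.0)
                    ll += _scalar_update(
                        m, p, np.array([0, 1, 2, 3, 4, 5]), 1.0, y, harv,
                        max(lam, 1.0),
                    )
            # symmetrise
            for j in range(7):
                for k in range(j + 1, 7):
                    avg = 0.5 * (p[j, k] + p[k, j])
                    p[j, k] = avg
                    p[k, j] = avg
        out[b] = ll
    return out
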