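"""Moment-matched Gaussian state-space machinery for the change-in-ratio model.

The latent annual state is seven-dimensional: the six pre-harvest age–sex
classes ``N_t`` plus ``Calf_t``, the number of calves alive at the early-summer
survey. All binomial transitions and binomial/Poisson observations are replaced
by Gaussians with the exact conditional means and (co)variances, evaluated at
the running filtered mean (an extended-Kalman treatment of the state-dependent
noise). This yields a marginal likelihood of the survey series given the vital
rates and detection probabilities, with the latent states integrated out —
the continuous relaxation counterpart of the integer-state model whose exact
log-density lives in :mod:`cirpop.model`.

Population sizes in the hundreds to thousands make the normal approximation to
these binomials accurate; see docs/methods.md for the error discussion.

Everything is vectorised over a leading batch axis so that a whole ensemble of
parameter vectors is filtered in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _filter_numba as _numba

__all__ = ["GaussianStateSpace"]

# state indices: 0..5 = CLASSES order (cF, yF, adF, cM, yM, adM), 6 = Calf (births)
_CALF = 6
_VAR_FLOOR = 0.25  # keeps observation variances away from zero at boundary p


def _scalar_update(m, p, idx, coef, y, offset, rvar, loglik):
    """Kalman update for one scalar observation y ~ N(coef * sum(z[idx]) - offset, rvar).

    ``m`` (B,7) and ``p`` (B,7,7) are updated in place; the log-likelihood
    contribution is added to ``loglik`` (B,).
    """
    hp = coef[:, None] * p[:, idx, :].sum(axis=1)  # (B,7) = h P
    s = coef * hp[:, idx].sum(axis=1) + rvar  # (B,) innovation variance
    pred = coef * m[:, idx].sum(axis=1) - offset
    resid = y - pred
    gain = hp / s[:, None]
    m += gain * resid[:, None]
    p -= gain[:, :, None] * hp[:, None, :]
    loglik += -0.5 * (np.log(2.0 * np.pi * s) + resid**2 / s)


def _chol_sample(mean, cov, rng):
    """Draw one sample per batch member from N(mean, cov), with jitter fallback."""
    b, d = mean.shape
    jitter = 1e-8
    for _ in range(6):
        try:
            chol = np.linalg.cholesky(cov + jitter * np.eye(d))
            break
        except np.linalg.LinAlgError:
            jitter *= 100.0
    else:  # pragma: no cover - extreme degeneracy
        w, v = np.linalg.eigh(cov)
        chol = v * np.sqrt(np.clip(w, 0.0, None))[:, None, :]
    z = rng.standard_normal((b, d))
    return mean + np.einsum("bij,bj->bi", chol, z)


@dataclass
class _FilterStore:
    m_filt: np.ndarray  # (T, B, 7)
    p_filt: np.ndarray  # (T, B, 7, 7)
    m_pred: np.ndarray  # (T, B, 7) (t=0 row is the prior)
    p_pred: np.ndarray
    cross: np.ndarray  # (T, B, 7, 7) Cov(z_{t-1}, z_t); t=0 row unused


class GaussianStateSpace:
    """Filter/smoother for one survey dataset under given parameter batches.

    Parameters are passed to :meth:`loglik` / :meth:`sample_states` as per-year
    series with a leading batch axis: ``f_t``, ``phi1_t`` of shape (B, T),
    ``phi2`` of shape (B,), ``p1_t``, ``p2_t`` of shape (B, T).
    """

    def __init__(
        self,
        harvest: np.ndarray,
        pre_calves: np.ndarray,
        pre_fy: np.ndarray,
        post_calves: np.ndarray,
        post_females: np.ndarray,
        post_males: np.ndarray,
        tot: Optional[np.ndarray],
        init_mean: np.ndarray,
        init_sd: np.ndarray,
        mothers: str = "yearlings_and_adults",
    ) -> None:
        self.harvest = np.asarray(harvest, dtype=float)
        self.n_years = self.harvest.shape[0]
        self.obs = {
            "pre_calves": np.asarray(pre_calves, dtype=float),
            "pre_fy": np.asarray(pre_fy, dtype=float),
            "post_calves": np.asarray(post_calves, dtype=float),
            "post_females": np.asarray(post_females, dtype=float),
            "post_males": np.asarray(post_males, dtype=float),
        }
        self.tot = None if tot is None else np.asarray(tot, dtype=float)
        self.init_mean = np.asarray(init_mean, dtype=float)
        self.init_sd = np.asarray(init_sd, dtype=float)
        self.mother_idx = (1, 2) if mothers == "yearlings_and_adults" else (2,)
        self._obs_stack = None
        self._tot_arr = None
        self._mother_arr = None

    # ------------------------------------------------------------------ filter

    def _predict(self, m, p, t, f_t, phi1_t, phi2):
        """Propagate the year t-1 posterior through harvest and transition to year t."""
        b = m.shape[0]
        h_prev = self.harvest[t - 1]
        xmean = m[:, :6] - h_prev  # post-harvest mean
        xc = np.clip(xmean, 0.0, None)

        ft = f_t[:, t]
        s1 = phi1_t[:, t]
        q = phi2 * ft  # P(mother alive at calving and calves)
        r2 = q * s1 / 2.0  # per-sex recruitment probability R/2

        pool = xc[:, list(self.mother_idx)].sum(axis=1)

        a = np.zeros((b, 7, 6))
        for col in self.mother_idx:
            a[:, 0, col] = r2
            a[:, 3, col] = r2
            a[:, _CALF, col] = q
        a[:, 1, 0] = phi2
        a[:, 4, 3] = phi2
        a[:, 2, 1] = phi2
        a[:, 2, 2] = phi2
        a[:, 5, 4] = phi2
        a[:, 5, 5] = phi2

        m_pred = np.einsum("bij,bj->bi", a, xmean)

        # conditional covariance of the binomial transition, at the predicted mean
        qmat = np.zeros((b, 7, 7))
        v2 = phi2 * (1.0 - phi2)
        qmat[:, 0, 0] = pool * r2 * (1.0 - r2)
        qmat[:, 3, 3] = pool * r2 * (1.0 - r2)
        qmat[:, 0, 3] = qmat[:, 3, 0] = -pool * r2**2
        qmat[:, _CALF, _CALF] = pool * q * (1.0 - q)
        cov_bc = pool * r2 * (1.0 - q)  # calf class vs births (shared litter)
        qmat[:, 0, _CALF] = qmat[:, _CALF, 0] = cov_bc
        qmat[:, 3, _CALF] = qmat[:, _CALF, 3] = cov_bc
        qmat[:, 1, 1] = xc[:, 0] * v2
        qmat[:, 4, 4] = xc[:, 3] * v2
        qmat[:, 2, 2] = (xc[:, 1] + xc[:, 2]) * v2
        qmat[:, 5, 5] = (xc[:, 4] + xc[:, 5]) * v2

        pnn = p[:, :6, :6]
        ap = np.einsum("bij,bjk->bik", a, pnn)  # (B,7,6)
        p_pred = np.einsum("bik,bjk->bij", ap, a) + qmat
        p_pred[:, np.arange(7), np.arange(7)] += 1e-3  # numerical floor

        cross = np.einsum("bij,bkj->bik", p[:, :, :6], a)  # Cov(z_{t-1}, z_t)
        return m_pred, p_pred, cross

    def _update_year(self, m, p, t, p1_t, p2_t, include_tot, loglik):
        """Assimilate every survey observation of year t (sequential scalar updates)."""
        h_t = self.harvest[t]
        p1 = p1_t[:, t]
        p2 = p2_t[:, t]
        zero = np.zeros(m.shape[0])

        def pool_mean(idx, harv):
            return np.clip(m[:, idx].sum(axis=1) - harv, 0.0, None)

        y = self.obs["pre_calves"][t]
        if not np.isnan(y):
            lam = np.clip(m[:, _CALF], 0.0, None)
            _scalar_update(m, p, [_CALF], p1, y, zero, lam * p1 * (1 - p1) + _VAR_FLOOR, loglik)

        y = self.obs["pre_fy"][t]
        if not np.isnan(y):
            idx = [1, 2, 4]
            lam = pool_mean(idx, 0.0)
            _scalar_update(m, p, idx, p1, y, zero, lam * p1 * (1 - p1) + _VAR_FLOOR, loglik)

        post_groups = (
            ("post_calves", [0, 3]),
            ("post_females", [1, 2]),
            ("post_males", [4, 5]),
        )
        for name, idx in post_groups:
            y = self.obs[name][t]
            if not np.isnan(y):
                harv = h_t[idx].sum()
                lam = pool_mean(idx, harv)
                _scalar_update(
                    m, p, idx, p2, y, p2 * harv, lam * p2 * (1 - p2) + _VAR_FLOOR, loglik
                )

        if include_tot and self.tot is not None:
            y = self.tot[t]
            if not np.isnan(y):
                idx = list(range(6))
                harv = h_t.sum()
                lam = pool_mean(idx, harv)
                ones = np.ones(m.shape[0])
                _scalar_update(
                    m, p, idx, ones, y, np.full(m.shape[0], harv),
                    np.clip(lam, 1.0, None), loglik,
                )

    def _run(self, f_t, phi1_t, phi2, p1_t, p2_t, include_tot, store=False):
        b = phi2.shape[0]
        t_max = self.n_years
        m = np.tile(self.init_mean, (b, 1))
        p = np.tile(np.diag(self.init_sd**2), (b, 1, 1))
        loglik = np.zeros(b)
        stored = (
            _FilterStore(
                m_filt=np.zeros((t_max, b, 7)),
                p_filt=np.zeros((t_max, b, 7, 7)),
                m_pred=np.zeros((t_max, b, 7)),
                p_pred=np.zeros((t_max, b, 7, 7)),
                cross=np.zeros((t_max, b, 7, 7)),
            )
            if store
            else None
        )
        for t in range(t_max):
            if t > 0:
                m, p, cross = self._predict(m, p, t, f_t, phi1_t, phi2)
            else:
                cross = None
            if store:
                stored.m_pred[t] = m
                stored.p_pred[t] = p
                if cross is not None:
                    stored.cross[t] = cross
            self._update_year(m, p, t, p1_t, p2_t, include_tot, loglik)
            p = 0.5 * (p + p.transpose(0, 2, 1))
            if store:
                stored.m_filt[t] = m
                stored.p_filt[t] = p
        return loglik, stored

    def loglik(
        self, f_t, phi1_t, phi2, p1_t, p2_t, include_tot=True, engine="auto"
    ) -> np.ndarray:
        """Marginal Gaussian log-likelihood of the dataset, batched over parameters.

        ``engine="numpy"`` forces the reference implementation; by default a
        numba-compiled equivalent is used when available.
        """
        if engine == "auto":
            engine = "numba" if _numba.HAVE_NUMBA else "numpy"
        if engine == "numba":
            if self._obs_stack is None:
                self._obs_stack = np.stack(
                    [self.obs[k] for k in
                     ("pre_calves", "pre_fy", "post_calves", "post_females", "post_males")]
                )
                self._tot_arr = (
                    self.tot if self.tot is not None else np.full(self.n_years, np.nan)
                )
                self._mother_arr = np.array(self.mother_idx, dtype=np.int64)
            return _numba.filter_loglik(
                self.harvest,
                self._obs_stack,
                self._tot_arr,
                bool(include_tot and self.tot is not None),
                self.init_mean,
                self.init_sd,
                self._mother_arr,
                np.ascontiguousarray(f_t, dtype=float),
                np.ascontiguousarray(phi1_t, dtype=float),
                np.ascontiguousarray(phi2, dtype=float),
                np.ascontiguousarray(p1_t, dtype=float),
                np.ascontiguousarray(p2_t, dtype=float),
            )
        ll, _ = self._run(f_t, phi1_t, phi2, p1_t, p2_t, include_tot, store=False)
        return ll

    # ---------------------------------------------------------------- smoother

    def sample_states(
        self, f_t, phi1_t, phi2, p1_t, p2_t, rng, include_tot=True
    ) -> np.ndarray:
        """One posterior trajectory draw per parameter vector (FFBS).

        Returns an array of shape (B, T, 7): the six pre-harvest classes plus
        the births series, jointly sampled from the Gaussian smoothing
        distribution conditional on each batch member's parameters.
        """
        _, st = self._run(f_t, phi1_t, phi2, p1_t, p2_t, include_tot, store=True)
        t_max, b = self.n_years, phi2.shape[0]
        out = np.zeros((b, t_max, 7))
        z = _chol_sample(st.m_filt[-1], st.p_filt[-1], rng)
        out[:, -1] = z
        for t in range(t_max - 2, -1, -1):
            cross = st.cross[t + 1]  # Cov(z_t, z_{t+1})
            p_pred = st.p_pred[t + 1]
            gain = np.linalg.solve(p_pred, cross.transpose(0, 2, 1)).transpose(0, 2, 1)
            mean = st.m_filt[t] + np.einsum(
                "bij,bj->bi", gain, z - st.m_pred[t + 1]
            )
            cov = st.p_filt[t] - np.einsum("bij,bkj->bik", gain, cross)
            cov = 0.5 * (cov + cov.transpose(0, 2, 1))
            z = _chol_sample(mean, cov, rng)
            out[:, t] = z
        return out
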