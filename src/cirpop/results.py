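"""Posterior results: summaries, convergence diagnostics, latent trajectories, plots."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

from .demography import growth_rate

if TYPE_CHECKING:  # pragma: no cover
    from .model import ChangeInRatioModel, MCMCConfig

__all__ = ["ChangeInRatioResults", "split_rhat", "check_convergence", "summarize_draws"]


def split_rhat(draws: np.ndarray) -> float:
    """Split-chain Gelman–Rubin statistic for one scalar, draws shaped (chain, draw)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(np.asarray(draws, dtype=float), method="split"))


def check_convergence(draws: dict[str, np.ndarray], threshold: float = 1.05) -> pd.DataFrame:
    """Split-R-hat per monitored scalar, with a flag column for values above threshold.

    ``draws`` maps parameter names to (chain, draw) arrays; at least two chains
    are required (a single chain cannot diagnose between-chain disagreement).
    """
    rows = []
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError(f"{name}: R-hat needs >=2 chains, got shape {arr.shape}")
        r = split_rhat(arr)
        rows.append({"parameter": name, "rhat": r, "flagged": bool(r > threshold)})
    return pd.DataFrame(rows).set_index("parameter")


def summarize_draws(draws: dict[str, np.ndarray], rhat: bool = True) -> pd.DataFrame:
    """Posterior mean, sd, central 95% interval (and split-R-hat) per scalar."""
    rows = []
    for name, arr in draws.items():
        flat = np.asarray(arr, dtype=float).reshape(-1)
        if flat.size < 100:
            warnings.warn(f"{name}: only {flat.size} retained draws", stacklevel=2)
        row = {
            "parameter": name,
            "mean": float(np.mean(flat)),
            "sd": float(np.std(flat, ddof=1)) if flat.size > 1 else 0.0,
            "q2.5": float(np.percentile(flat, 2.5)),
            "q97.5": float(np.percentile(flat, 97.5)),
        }
        if rhat and np.asarray(arr).ndim == 2 and arr.shape[0] >= 2:
            row["rhat"] = split_rhat(arr)
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


@dataclass
class ChangeInRatioResults:
    """Posterior draws and derived quantities from a fitted change-in-ratio model.

    ``theta`` holds the retained sampler draws shaped (chain, draw, ndim), where
    every ensemble walker counts as one chain for diagnostics. Latent
    trajectories (pre-harvest classes plus births) are sampled lazily from the
    Gaussian smoothing distribution, one trajectory per retained parameter draw
    (thinned to at most ``max_latent_draws``, enough for stable means and 95%
    intervals), and are clipped below at the harvest vector so that every
    retained trajectory is harvest-feasible.
    """

    model: "ChangeInRatioModel"
    theta: np.ndarray
    mcmc: "MCMCConfig"
    approach: str = ""
    max_latent_draws: int = 1500
    _latent: Optional[np.ndarray] = field(default=None, repr=False)
    _latent_shape: Optional[tuple[int, int]] = field(default=None, repr=False)

    # ------------------------------------------------------------- param draws

    def rate_draws(self) -> dict[str, np.ndarray]:
        """Scalar rate/detection draws as (chain, draw) arrays, plus derived R.

        Under year random effects, ``f`` and ``phi1`` are the across-year means
        of the per-year rates; time-varying detection is reported per year.
        """
        layout = self.model.layout
        c, d, _ = self.theta.shape
        flat = self.theta.reshape(c * d, -1)
        series = layout.unpack(flat)
        out: dict[str, np.ndarray] = {}
        out["f"] = series["f_t"].mean(axis=1).reshape(c, d)
        out["phi1"] = series["phi1_t"].mean(axis=1).reshape(c, d)
        out["phi2"] = series["phi2"].reshape(c, d)
        out["R"] = out["f"] * out["phi1"] * out["phi2"]
        if layout.config.rate_structure == "random_year_effects":
            for name in ("alpha_f", "sigma_f", "alpha_phi1", "sigma_phi1"):
                out[name] = layout.get(flat, name)[:, 0].reshape(c, d)
        if layout.config.detection_structure == "constant":
            out["p1"] = layout.get(flat, "p1")[:, 0].reshape(c, d)
            out["p2"] = layout.get(flat, "p2")[:, 0].reshape(c, d)
        else:
            for t in range(layout.n_years):
                out[f"p1[{t + 1}]"] = series["p1_t"][:, t].reshape(c, d)
                out[f"p2[{t + 1}]"] = series["p2_t"][:, t].reshape(c, d)
        return out

    # ---------------------------------------------------------- latent states

    def _latent_subsample(self) -> tuple[np.ndarray, int, int]:
        c, d, ndim = self.theta.shape
        step = max(1, int(np.ceil(c * d / self.max_latent_draws)))
        sub = self.theta[:, ::step, :]
        return sub.reshape(-1, ndim), c, sub.shape[1]

    def latent_trajectories(self) -> np.ndarray:
        """Posterior trajectory draws shaped (chain, draw, T, 7); cached.

        Columns 0..5 are the pre-harvest classes (clipped at the harvest
        vector), column 6 the births series.
        """
        if self._latent is None:
            flat, c, d = self._latent_subsample()
            series = self.model.layout.unpack(flat)
            rng = np.random.default_rng(np.random.SeedSequence([self.mcmc.seed, 915]))
            states = self.model._ss.sample_states(
                np.clip(series["f_t"], 1e-6, 1 - 1e-6),
                np.clip(series["phi1_t"], 1e-6, 1 - 1e-6),
                np.clip(series["phi2"], 1e-6, 1 - 1e-6),
                np.clip(series["p1_t"], 1e-6, 1 - 1e-6),
                np.clip(series["p2_t"], 1e-6, 1 - 1e-6),
                rng,
                include_tot=self.model.config.include_tot,
            )
            harvest = self.model.data.harvest  # (T, 6)
            states[:, :, :6] = np.maximum(states[:, :, :6], harvest[None, :, :])
            states[:, :, 6] = np.clip(states[:, :, 6], 0.0, None)
            t = states.shape[1]
            self._latent = states.reshape(c, d, t, 7)
            self._latent_shape = (c, d)
        return self._latent

    def abundance_draws(self) -> np.ndarray:
        """Pre-harvest total abundance draws, shaped (chain, draw, T)."""
        return self.latent_trajectories()[:, :, :, :6].sum(axis=3)

    def lambda_draws(self, per_draw: bool = True) -> np.ndarray:
        """Population growth rate per posterior draw (chain, draw).

        ``per_draw=False`` gives the plug-in alternative: a single growth rate
        computed from the posterior-mean abundance series.
        """
        totals = self.abundance_draws()
        if not per_draw:
            return np.array(growth_rate(totals.mean(axis=(0, 1))))
        c, d, t = totals.shape
        flat = totals.reshape(c * d, t)
        lam = (flat[:, -1] / flat[:, 0]) ** (1.0 / (t - 1))
        return lam.reshape(c, d)

    # ------------------------------------------------------------- summaries

    def all_draws(self, include_latent: bool = True) -> dict[str, np.ndarray]:
        out = self.rate_draws()
        if include_latent:
            out["lambda"] = self.lambda_draws()
            totals = self.abundance_draws()
            for t in range(totals.shape[2]):
                out[f"N_total[{t + 1}]"] = totals[:, :, t]
        return out

    def summary(self, include_latent: bool = True) -> pd.DataFrame:
        """Posterior mean, sd, 95% credible interval and split-R-hat per scalar."""
        return summarize_draws(self.all_draws(include_latent=include_latent))

    def check_convergence(self, threshold: float = 1.05) -> pd.DataFrame:
        return check_convergence(self.all_draws(include_latent=False), threshold=threshold)

    def score_against_truth(self, truth) -> dict[str, float]:
        """Percent bias of posterior means against a simulated truth.

        Rates are compared to the realised mean rates, lambda to the realised
        geometric growth of the true pre-harvest totals, and N as the percent
        error of the summed posterior-mean abundance series.
        """
        from .sensitivity import percent_bias

        draws = self.rate_draws()
        true_totals = truth.pre_harvest_totals().astype(float)
        est_totals = self.abundance_draws().mean(axis=(0, 1))
        return {
            "f": percent_bias(float(draws["f"].mean()), float(truth.f_t.mean())),
            "phi1": percent_bias(float(draws["phi1"].mean()), float(truth.phi1_t.mean())),
            "phi2": percent_bias(float(draws["phi2"].mean()), float(truth.phi2)),
            "lambda": percent_bias(
                float(self.lambda_draws().mean()), growth_rate(true_totals)
            ),
            "N": percent_bias(float(est_totals.sum()), float(true_totals.sum())),
        }

    # ------------------------------------------------------------------ output

    def metadata(self) -> dict:
        from dataclasses import asdict

        return {
            "approach": self.approach,
            "mcmc": asdict(self.mcmc),
            "model": {
                "include_tot": self.model.config.include_tot,
                "rate_structure": self.model.config.rate_structure,
                "detection_structure": self.model.config.detection_structure,
                "mothers": self.model.config.mothers,
            },
            "n_chains_total": int(self.theta.shape[0]),
            "n_draws_per_chain": int(self.theta.shape[1]),
        }

    def draws_frame(self) -> pd.DataFrame:
        """All scalar draws in long layout (chain, draw, parameter, value)."""
        records = []
        for name, arr in self.all_draws().items():
            c, d = arr.shape
            records.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), d),
                        "draw": np.tile(np.arange(d), c),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(records, ignore_index=True)

    def plot_trajectory(self, ax=None, truth=None):
        """Posterior mean and 95% band of pre-harvest abundance, optionally vs truth."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        totals = self.abundance_draws().reshape(-1, self.model.data.n_years)
        years = self.model.data.years
        lo, hi = np.percentile(totals, [2.5, 97.5], axis=0)
        ax.fill_between(years, lo, hi, alpha=0.3, label="95% c.i.")
        ax.plot(years, totals.mean(axis=0), label="posterior mean")
        if truth is not None:
            ax.plot(years, truth.pre_harvest_totals(), "k--", label="truth")
        ax.set_xlabel("year")
        ax.set_ylabel("pre-harvest abundance")
        ax.legend()
        return ax

    def plot_rates(self, ax=None):
        """Posterior densities of the three vital rates."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        draws = self.rate_draws()
        for name in ("f", "phi1", "phi2"):
            ax.hist(draws[name].reshape(-1), bins=40, density=True, alpha=0.5, label=name)
        ax.set_xlabel("rate")
        ax.legend()
        return ax
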