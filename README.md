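# cirpop

Hierarchical Bayesian **change-in-ratio** population models for harvested,
age–sex structured wildlife populations.

Many ungulate monitoring programmes collect exactly three things every year: a
spring structure survey (calves vs. a composite female/yearling class), an
autumn structure survey after the hunting season (calves / females / males),
and complete hunter reports of the age–sex composition of the harvest —
sometimes plus an uncorrected winter "minimum count". None of these alone
identifies survival, reproduction or abundance. `cirpop` fits them jointly:
the known harvest pulse perturbs the population's composition, and the change
in the observed ratios before vs. after the pulse, propagated through a
Markovian matrix population model, identifies the demographic rates *and* the
absolute population size — with or without the winter counts.

## The model

The latent pre-harvest population vector
`N_t = [N_cF, N_yF, N_adF, N_cM, N_yM, N_adM]` evolves as

```
X_t     = N_t − H_t                       (known harvest pulse)
N_{t+1} ~ binomial projection of X_t      (matrix A below, stochastic analogue)

        ⎡ 0      φ₂φ₁f/2  φ₂φ₁f/2  0   0   0  ⎤
        ⎢ φ₂     0        0        0   0   0  ⎥
A   =   ⎢ 0      φ₂       φ₂       0   0   0  ⎥
        ⎢ 0      φ₂φ₁f/2  φ₂φ₁f/2  0   0   0  ⎥
        ⎢ 0      0        0        φ₂  0   0  ⎥
        ⎣ 0      0        0        0   φ₂  φ₂ ⎦
```

with fecundity `f`, calf summer survival `φ₁`, annual survival `φ₂` (shared
across classes) and composite recruitment `R = φ₁φ₂f`. Births
`Calf_t ~ Binomial(mothers, φ₂f)` are a latent state so that the spring survey
(taken before summer mortality) separates `f` from `φ₁`. Observations are
binomial structure counts with survey-specific detection probabilities `p₁`
(spring) and `p₂` (autumn), plus optionally Poisson winter totals
`Y_t ~ Poisson(ΣX_t)`; model **M1** includes the winter-count likelihood,
**M2** excludes it. Rates can be time-constant or carry logit-normal year
random effects. Posteriors are sampled by ensemble MCMC over a moment-matched
Gaussian marginal likelihood (latent states integrated out by a Kalman filter;
the exact discrete joint density is also implemented and tested). See
`docs/methods.md` for assumptions, priors and numerical details.

## Worked example

Simulate a 20-year monitoring series with known truth, fit it, and compare:

```python
import numpy as np
from cirpop import ChangeInRatioModel, MCMCConfig, simulate_study

rng = np.random.default_rng(7)
truth, dataset = simulate_study(rng, n_years=20)   # rates drawn from the study ranges
result = ChangeInRatioModel(dataset).fit(MCMCConfig.desk(seed=3))
print(result.summary().loc[["f", "phi1", "phi2", "lambda", "N_total[20]"]].round(3))
print({k: round(v, 3) for k, v in result.score_against_truth(truth).items()})
```

```
                  mean      sd       q2.5      q97.5   rhat
parameter
f                0.819   0.004      0.811      0.828  1.030
phi1             0.932   0.005      0.922      0.942  1.028
phi2             0.935   0.001      0.932      0.937  1.024
lambda           1.083   0.001      1.080      1.084  0.995
N_total[20]  14549.839  53.206  14448.340  14660.293  1.011
{'f': 0.085, 'phi1': -0.793, 'phi2': 0.04, 'lambda': -0.006, 'N': 0.04}
```

The drawn truth here was `f = 0.819`, `φ₁ = 0.940`, `φ₂ = 0.934`: every rate
is recovered within a percent (the last line shows percent bias per
quantity), `λ` essentially exactly, and the 20-year abundance trajectory to a
twentieth of a percent. Mean, central 95% credible interval and split-R-hat
come from 8,000 retained ensemble draws (20 walkers × 400).

The same machinery drives the command line:

```bash
cirpop simulate --seed 42 --years 20 --out demo      # dataset + truth + metadata
cirpop fit demo_dataset.csv --no-tot --seed 1        # M2 fit, summary to CSV
cirpop sensitivity --scenario TOT_BIAS --profile desk --seed 1
cirpop report sensitivity_TOT_BIAS_aggregate.csv --cutoff 5
```

Real monitoring tables are ingested with `cirpop.io.read_monitoring_csv`,
which validates counts, accepts hunter-style three-class harvest, and takes a
`schema_map` to bridge foreign column headers.

## Sensitivity studies

`cirpop.sensitivity` reproduces the replicated simulate–fit–score experiments:
unbiased recovery, winter counts biased low (`TOT_BIAS`), and class-specific
detection bias in the structure surveys (`PRE_FY`, `POST_FEMALE`,
`PRE_AND_POST_FEMALE`, `POST_MALE`), scored as percent bias of the posterior
means against the simulated truth and summarised per bias-grid point, with
`threshold_report` extracting the grid interval where |mean bias| stays under
a cutoff. Headline behaviour: unbiased structure surveys give essentially
unbiased rates, growth rate and abundance (abundance with much larger
replicate spread when counts are excluded); thinned winter counts inflate the
annual-survival estimate; structure-survey bias moves `f` and `φ₁` in opposite
directions while `λ` barely reacts.

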