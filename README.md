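# piddm — diffusion-model analysis of proactive interference

`piddm` implements a complete diffusion-decision-model (DDM) analysis of
proactive interference (PI) in the **recent-probes task**, comparing young
and older adults. It covers the whole analysis chain as a library:

- **Task generation** — recent-probes sessions (three 160-trial blocks;
  240 positive / 120 non-recent negative / 120 recent negative probes) with
  exact recency constraints and an independent sequence auditor.
- **Synthetic cohorts** — participant-level DDM parameters drawn around the
  published young (n = 25) and older (n = 38) group estimates, driven through
  a trial-level Euler–Maruyama simulator.
- **Exact likelihoods** — Wiener first-passage-time densities (adaptive
  small/large-time series, truncation error 1e−10) with analytic Gaussian
  drift variability and Gauss–Legendre quadrature over the uniform
  starting-point and nondecision-time variabilities.
- **Model fitting** — per-participant maximum likelihood over six constrained
  model variants (10–19 free parameters) via coarse-to-fine Nelder–Mead on an
  unconstrained reparameterization, from EZ-style moment starts.
- **Model selection** — BIC per participant; cohort ranking of the variants.
- **Group statistics** — mixed-design ANOVAs (condition × age group), planned
  PI contrasts, and pooled t-tests on boundary separation and nondecision time.
- **Quantile-probability reports** — observed vs predicted response
  proportions and RT quantiles per condition and group (SVG/PNG).

See [docs/methods.md](docs/methods.md) for the scientific and numerical
details, and [examples/](examples/) for runnable walkthroughs of each stage.

## Quick start

```python
from piddm import (
    DDMParameterSet, FitOptions, SessionDesign, SimOptions,
    apply_rt_cutoffs, fit_participant, generate_session, simulate_dataset,
)

# one participant at the published young-adult means
truth = DDMParameterSet(
    v={"positive": 0.366, "nonrecent_negative": 0.290, "recent_negative": 0.230},
    eta=0.10, a=0.176, sz=0.02, ter=0.304, st=0.10,
)
trials = generate_session(SessionDesign(), seed=11)        # 480 trials
data = simulate_dataset(truth, trials, SimOptions(seed=12))
data["participant_id"] = "demo"
filtered, _ = apply_rt_cutoffs(data)                       # 0.2 s - 7 s window

fit = fit_participant(filtered, 1, FitOptions(n_restarts=2, seed=13))
print(round(fit.parameters.v["positive"], 3), round(fit.bic, 1))
```

Output (deterministic given the seeds):

```
0.335 -212.7
```

The full pipeline — synthesize, filter, fit, select, group statistics,
quantile-probability figure — runs from a single config:

```python
from piddm import run_pipeline

manifest = run_pipeline({"seed": 41, "models": [1], "fit": {"n_restarts": 1},
                         "groups": [{"label": "young", "n_participants": 3},
                                    {"label": "older", "n_participants": 3}]},
                        "out/")
```

## Testing and reproducing the results

```bash
pytest                 # unit, property, and acceptance suites
```

The acceptance tests (in `tests/test_acceptance.py`) verify, end to end:
session-design exactness; recovery of the published group-mean parameters
from simulated cohorts; analytic-density correctness against Monte-Carlo and
closed forms; BIC exactness and model recovery; and the statistics layer
against an independent GLM oracle, including the null PI × Age interaction
on recovered drift rates. The headline quantities can be recomputed from
scratch and dumped as JSON with:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness is seed-controlled; fitting is deterministic given the seed.

## Layout

```
src/piddm/
  params.py     parameter containers, conditions, defaults
  models.py     the six constrained model variants
  task.py       session generation, validation, synthetic cohorts
  simulate.py   trial-level Euler-Maruyama simulator
  wfpt.py       first-passage-time densities and likelihoods
  fitting.py    cutoffs, transforms, initialization, Nelder-Mead MLE
  selection.py  BIC and cohort ranking
  stats.py      mixed ANOVA, planned PI contrasts, t-tests
  qpp.py        quantile-probability summaries and figures
  pipeline.py   end-to-end driver with manifest
```
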