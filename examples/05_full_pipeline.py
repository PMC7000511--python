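"""Run the full analysis pipeline on a scaled-down configuration.

Synthesizes a 3 + 3 cohort, applies the RT cutoffs, fits Model 1 to every
participant, selects the winning model, runs the group statistics, and
writes the quantile-probability figure — all artifacts plus a manifest land
in ``pipeline_demo/``.

For the full-scale analysis (25 + 38 participants, all six models, five
restarts) drop the overrides below; that run takes several hours.
"""

from piddm import run_pipeline

config = {
    "seed": 41,
    "groups": [
        {"label": "young", "n_participants": 3},
        {"label": "older", "n_participants": 3},
    ],
    "models": [1],
    "fit": {"n_restarts": 1},
}

manifest = run_pipeline(config, "pipeline_demo")

print(f"participants: {manifest['n_participants']}, trials: {manifest['n_trials']}")
print(f"best model: {manifest['best_model']}")
print(f"artifacts: {', '.join(manifest['artifacts'])}")
ttest = manifest["report"]["ttest_ter"]
print(f"nondecision time, older vs young: t({ttest['df']}) = {ttest['t']:.2f}, p = {ttest['p']:.4f}")
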