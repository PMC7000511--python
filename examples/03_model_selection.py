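"""Compare the six model variants on one simulated participant by BIC.

Data are generated from Model 1 (only drift varies across conditions), so
BIC should prefer Model 1: the more flexible variants improve the likelihood
slightly but pay a larger complexity penalty.
"""

from piddm import (
    DDMParameterSet,
    FitOptions,
    MODEL_SPECS,
    SessionDesign,
    SimOptions,
    apply_rt_cutoffs,
    fit_participant,
    generate_session,
    select_best,
    simulate_dataset,
)

truth = DDMParameterSet(
    v={"positive": 0.366, "nonrecent_negative": 0.290, "recent_negative": 0.230},
    eta=0.10, a=0.176, sz=0.02, ter=0.304, st=0.10,
)
trials = generate_session(SessionDesign(), seed=21)
data = simulate_dataset(truth, trials, SimOptions(seed=22))
data["participant_id"] = "demo"
filtered, _ = apply_rt_cutoffs(data)

fits = []
for mid, spec in MODEL_SPECS.items():
    fit = fit_participant(filtered, spec, FitOptions(n_restarts=1, seed=23 + mid))
    fits.append(fit)
    print(f"{spec.describe():<75} BIC = {fit.bic:9.2f}")

print(f"\nbest model by BIC: Model {select_best(fits)}")
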