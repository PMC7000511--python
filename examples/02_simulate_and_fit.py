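"""Simulate one participant and recover their parameters with Model 1.

The participant's data are generated at the young-adult group means from the
fitted estimates (drift per condition 0.366 / 0.290 / 0.230, boundary 0.176,
nondecision time 0.304 s) and refit by maximum likelihood.
"""

from piddm import (
    DDMParameterSet,
    FitOptions,
    SessionDesign,
    SimOptions,
    apply_rt_cutoffs,
    fit_participant,
    generate_session,
    simulate_dataset,
)

truth = DDMParameterSet(
    v={"positive": 0.366, "nonrecent_negative": 0.290, "recent_negative": 0.230},
    eta=0.10,
    a=0.176,
    sz=0.02,
    ter=0.304,
    st=0.10,
)

trials = generate_session(SessionDesign(), seed=11)
data = simulate_dataset(truth, trials, SimOptions(seed=12))
data["participant_id"] = "demo"
filtered, excluded = apply_rt_cutoffs(data)
print(f"simulated {len(data)} trials, excluded fraction {excluded:.4f}")

fit = fit_participant(filtered, 1, FitOptions(n_restarts=2, seed=13))
print(f"\nModel 1 fit: lnL = {fit.log_likelihood:.2f}, BIC = {fit.bic:.2f}, "
      f"converged = {fit.converged}")
print(f"{'parameter':<22}{'true':>8}{'fitted':>10}")
for cond in truth.v:
    print(f"v[{cond}]".ljust(22) + f"{truth.v[cond]:>8.3f}{fit.parameters.v[cond]:>10.3f}")
print(f"{'a':<22}{truth.a['positive']:>8.3f}{fit.parameters.a['positive']:>10.3f}")
print(f"{'ter':<22}{truth.ter['positive']:>8.3f}{fit.parameters.ter['positive']:>10.3f}")
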