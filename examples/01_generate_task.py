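"""Generate and audit a recent-probes session.

A default session is three 160-trial blocks: half the probes are positive
(in the current four-consonant target set), a quarter are recent negatives
(absent from the current set but present in the previous trial's set — the
proactive-interference probes), and a quarter are non-recent negatives
(absent from the current and two preceding sets).
"""

from piddm import SessionDesign, generate_session, validate_sequence

design = SessionDesign()
trials = generate_session(design, seed=7)

report = validate_sequence(trials)
print(f"trials: {report.n_trials}")
print(f"condition counts: {report.condition_counts}")
print(f"recency violations: {report.n_violations}")

print("\nfirst five trials:")
for t in trials[:5]:
    print(f"  block {t.block} | set {''.join(t.target_set)} | probe {t.probe} | {t.condition}")
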