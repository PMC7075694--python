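"""The size-robustness trade-off, and how two-stage kinetics escapes it.

With constant rates, a large field requires k_b ≈ k_t (small Δk), but near
criticality the field size becomes wildly variable.  A two-stage schedule
— a growth-favouring phase (k_b > k_t) switched to a terminating phase
once the length coordinate reaches 100 μm — produces a comparably large
field at a fraction of the variability.
"""

from dendrosim import (GrowthSchedule, KineticStage, simulate_ensemble,
                       summarize_ensemble)

conditions = {
    "one-stage Δk=0.005": GrowthSchedule.one_stage(0.360, 0.365, n0=30,
                                                   max_events=10 ** 7),
    "one-stage Δk=0.001": GrowthSchedule.one_stage(0.360, 0.361, n0=30,
                                                   max_events=10 ** 7),
    "two-stage": GrowthSchedule.two_stage(KineticStage(0.42, 0.40),
                                          KineticStage(0.36, 0.40),
                                          switch_length=100.0, n0=30),
}

for name, schedule in conditions.items():
    s = summarize_ensemble(simulate_ensemble(schedule, 100, master_seed=7))
    print(f"{name:20s} mean R95 = {s.mean_r95:5.2f} μm   CV = {s.cv_r95:5.1f}%")
print()
print("The two-stage schedule reaches the ~11 μm wide-field scale with a CV")
print("near the compact-field baseline, instead of the 50-70% CV that")
print("near-critical constant rates pay for the same size.")
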