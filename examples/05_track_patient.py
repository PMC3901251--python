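"""Track a patient's network link density through a treatment course.

A synthetic patient is measured at four timepoints whose disease strength
decays under treatment and rebounds after a pause (1.0 -> 0.6 -> 0.3 ->
0.8).  The dual-class model stays fixed (trained on the reference
cohorts), so the density trajectory reflects the patient's state.
"""

from specnet import (
    CohortConfig,
    fit_dataset,
    generate_cohort,
    generate_trajectory,
    track_evolution,
)

config = CohortConfig(seed=42)
model = fit_dataset(generate_cohort(config))

strengths = [1.0, 0.6, 0.3, 0.8]
series = generate_trajectory(config, strengths, seed=123)
trajectory = track_evolution(model, series, threshold=0.65)

print("timepoint  disease strength  link density")
for t, s, d in zip(trajectory.timepoints, strengths, trajectory.densities):
    print(f"   t{t}            {s:.1f}            {d:.3f}")
print("\nThe density trough coincides with the weakest disease signal (t2) and")
print("rises again at the rebound - the network summarizes the patient's")
print("state in one number per visit (single draws fluctuate; averaging")
print("replicate trajectories makes the fall-then-rise shape exact).")
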