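"""Reconstruct and compare one control and one patient network.

The link weight of a bin pair is the normalized probability that the
subject's two intensities follow the disease-group regression line rather
than the control-group line; weights above 0.65 become network links.
Patient networks are star-like: the hub bins collect most links and top
the eigenvector-centrality ranking.
"""

import numpy as np

from specnet import CohortConfig, extract_features, fit_dataset, generate_cohort, reconstruct

config = CohortConfig(seed=42)
cohort = generate_cohort(config)
model = fit_dataset(cohort)
hubs = sorted(config.pattern_layout())
print(f"designated hub bins: {hubs}")

for subject_id in ("control_000", "disease_000"):
    net = reconstruct(cohort.subject_row(subject_id), model, subject_id=subject_id)
    feats = extract_features(net, threshold=0.65)
    top = np.argsort(feats.centrality)[::-1][:5]
    print(f"\n{subject_id}:")
    print(f"  link density    {feats.link_density:.3f}")
    print(f"  clustering      {feats.clustering:.3f}")
    print(f"  efficiency      {feats.efficiency:.3f}")
    print(f"  top-5 central bins: {sorted(int(t) for t in top)}")

print("\nThe patient's most central bins coincide with the hub bins; the")
print("control's central bins are arbitrary (noise-promoted links only).")
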