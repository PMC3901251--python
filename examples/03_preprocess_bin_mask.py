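"""Preprocessing: aggregate raw measurements into bins and mask regions.

Emulates a raw spectrum of 1000 measurements where each spectral feature
spans 10 adjacent measurements (a peak has width), aggregates it into
100 bins of 10 measurements each, and removes an excluded axis region the
way water or drug peaks are removed before modeling.
"""

from specnet import CohortConfig, bin_spectrum, generate_cohort, mask_bins

raw = generate_cohort(
    CohortConfig(n_bins=1000, m_control=10, m_disease=10, feature_width=10, seed=7)
)
print(f"raw:    {raw.m} subjects x {raw.n_bins} measurements")

binned = bin_spectrum(raw, bin_size=10)
print(f"binned: {binned.m} subjects x {binned.n_bins} bins "
      f"(centers {binned.bin_axis[0]:.1f} .. {binned.bin_axis[-1]:.1f})")

masked = mask_bins(binned, [(400.0, 500.0)])
print(f"masked: removed {binned.n_bins - masked.n_bins} bins in [400, 500]")

print("\nprovenance log:")
for entry in masked.provenance:
    print(f"  - {entry}")
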