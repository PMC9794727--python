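"""Bland-Altman agreement between two screens of the same tumor.

Emulates comparing a fresh-tissue culture screen with a long-term-culture
screen of the same sample: identical true sensitivities, independent
measurement noise. Good agreement means a small bias and narrow limits
of agreement (bias +/- 1.96 SD of the paired differences).
"""

from dspscreen import (
    SimConfig,
    bland_altman,
    build_layouts,
    sample_ground_truth,
    screen_sample,
    simulate_raw_plates,
)

config = SimConfig(n_drugs=20, n_samples=2, planted_hits_per_sample=3, seed=17)
truth = sample_ground_truth(config)
layouts = build_layouts(config, truth.library)

# same true curves, two independent noise realizations (plate_suffix keys
# independent RNG substreams)
plates_a, lay_a = simulate_raw_plates(truth, "s001", layouts=layouts)
plates_b, lay_b = simulate_raw_plates(truth, "s001", layouts=layouts, plate_suffix="_ltc")

screen_a = screen_sample(plates_a, {**layouts, **lay_a}, truth.library, sample_id="ftc")
screen_b = screen_sample(plates_b, {**layouts, **lay_b}, truth.library, sample_id="ltc")

dss_a = {m.drug_id: m.dss_asym for m in screen_a.metrics}
dss_b = {m.drug_id: m.dss_asym for m in screen_b.metrics}
pairs = [(dss_a[d], dss_b[d]) for d in sorted(dss_a) if d in dss_b]
stats = bland_altman(pairs)

print(f"paired drugs: {stats.n_pairs}")
print(f"bias (FTC - LTC) = {stats.bias:+.2f} DSS units")
print(f"limits of agreement: [{stats.loa_lower:+.2f}, {stats.loa_upper:+.2f}]")
print(f"outlier drugs outside the LoA: {len(stats.outlier_indices)}")
# a narrow LoA band indicates the two culture models report the same drug
# sensitivities up to measurement noise
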