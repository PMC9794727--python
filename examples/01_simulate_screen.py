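"""Generate a complete synthetic screen set and inspect what it contains.

The generator emits exactly the file set the pipeline consumes: a drug
library, per-plate layouts, raw luminescence counts per sample, a
healthy-control DSS panel, a cohort DSS store and the ground truth that
produced everything.
"""

from pathlib import Path

from dspscreen import SimConfig, sample_ground_truth, write_screen_set

out = Path("scratch/example_screen")
config = SimConfig(n_drugs=20, n_samples=6, planted_hits_per_sample=2, seed=17)
truth = sample_ground_truth(config)
write_screen_set(truth, out)

print(f"screen set written to {out}/")
for f in sorted(out.rglob("*"))[:8]:
    if f.is_file():
        print("  ", f.relative_to(out))
print(f"samples: {len(truth.sample_ids)}, drugs: {len(truth.library)}")
print(f"planted sensitive pairs: {sorted(truth.planted_pairs())[:4]} ...")
# each planted pair is a (sample, drug) combination whose true curve passes
# every hit criterion; the pipeline should rediscover them from raw counts
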