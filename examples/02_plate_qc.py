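"""Normalize a plate, read its robust Z', and watch QC fail when the
controls degrade.

Z' near 1 means the DMSO and benzethonium control populations are far
apart relative to their spread; below 0.5 the plate cannot separate
active from inactive wells and is excluded from analysis.
"""

from dspscreen import (
    SimConfig,
    build_layouts,
    degrade_controls,
    normalize_plate,
    sample_ground_truth,
    simulate_raw_plates,
)

config = SimConfig(n_drugs=20, n_samples=2, planted_hits_per_sample=2, seed=17)
truth = sample_ground_truth(config)
layouts = build_layouts(config, truth.library)
plates, _ = simulate_raw_plates(truth, "s001", layouts=layouts)

plate, layout = plates[0], layouts[plates[0].layout_ref]
clean = normalize_plate(plate, layout)
print(f"clean plate:        Z' = {clean.qc.zprime:.3f}  [{clean.qc.qc_class}]")

for mode in ("pos_drift", "neg_scatter", "separation_loss"):
    damaged = degrade_controls(plate, layout, mode)
    qc = normalize_plate(damaged, layout).qc
    print(f"{mode:18s}  Z' = {qc.zprime:.3f}  [{qc.qc_class}]")
# pos_drift pulls the kill control toward the vehicle level, neg_scatter
# inflates the vehicle-well spread, separation_loss collapses both medians
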