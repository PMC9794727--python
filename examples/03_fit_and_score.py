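"""Fit one drug's dose-response curve and derive its per-drug metrics.

Shows the chain raw counts -> percent inhibition -> asymmetric logistic
fit -> DSS / IC50 / inhibition-at-Cmax, for a planted sensitive pair.
"""

from dspscreen import (
    SimConfig,
    assemble_dose_points,
    build_layouts,
    compute_drug_metrics,
    control_panel_from_truth,
    fit_asym_logistic,
    normalize_plate,
    sample_ground_truth,
    simulate_raw_plates,
)

config = SimConfig(n_drugs=20, n_samples=4, planted_hits_per_sample=2, seed=17)
truth = sample_ground_truth(config)
layouts = build_layouts(config, truth.library)
plates, _ = simulate_raw_plates(truth, "s001", layouts=layouts)
normalized = [normalize_plate(p, layouts[p.layout_ref]) for p in plates]

drug_id = sorted(d for s, d in truth.planted_pairs() if s == "s001")[0]
drug = truth.library[drug_id]
points = assemble_dose_points(normalized, layouts, drug_id,
                              concentrations=drug.concentrations)
fit = fit_asym_logistic(points)
panel = control_panel_from_truth(truth)
m = compute_drug_metrics(fit, points.conc_range, cmax=drug.cmax, panel=panel,
                         drug_id=drug_id, drug_name=drug.name)

true_curve = truth.curves[("s001", drug_id)]
print(f"drug {drug.name} (planted sensitive pair)")
print(f"  fitted: y_max={fit.y_max:.1f}%  log10 EC50={fit.log10_ec50:.2f}  "
      f"slope={fit.slope:.2f}  asym={fit.asym:.2f}  R2={fit.r2:.4f}")
print(f"  truth : y_max={true_curve.y_max:.1f}%  log10 EC50={true_curve.log10_ec50:.2f}")
print(f"  DSS={m.dss_asym:.2f}  sDSS={m.sdss:.2f}  "
      f"IC50={m.ic50_abs:.2e} M (Cmax {drug.cmax:.2e} M)")
print(f"  inhibition at Cmax = {m.inhibition_at_cmax:.1f}%  max effect = {m.max_effect:.1f}%")
# DSS is the normalized area of the curve above the 10% activity threshold;
# sDSS subtracts the healthy-control panel mean for the same drug
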