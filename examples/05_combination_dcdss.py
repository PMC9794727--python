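"""Score an anchored combination screen with dcDSS.

An anchor drug at its own IC25 is dispensed on top of the whole library;
dcDSS = DSS(combo) - DSS(mono) flags drugs whose effect the anchor
potentiates. One synergistic partner is planted here.
"""

import dataclasses

from dspscreen import (
    ConcRange,
    SimConfig,
    anchor_concentration,
    build_layouts,
    dss_asym,
    sample_ground_truth,
    screen_sample,
    simulate_combination_screen,
    simulate_raw_plates,
)

config = SimConfig(n_drugs=16, n_samples=4, planted_hits_per_sample=2,
                   n_control_samples=2, seed=31)
truth = sample_ground_truth(config)
layouts = build_layouts(config, truth.library)
anchor = sorted(d for s, d in truth.planted_pairs() if s == "s001")[0]


def truth_gain(d):
    base = truth.curves[("s001", d)]
    shifted = dataclasses.replace(base, y_max=min(base.y_max + 20.0, 100.0),
                                  log10_ec50=base.log10_ec50 - 1.0)
    return dss_asym(shifted.as_fit(), config.conc_range) - dss_asym(base.as_fit(), config.conc_range)


candidates = [d for d in truth.library.drug_ids
              if d != anchor and not truth.planted[("s001", d)]]
partner = max(candidates, key=truth_gain)

mono_plates, _ = simulate_raw_plates(truth, "s001", layouts=layouts)
combo_plates, combo_layouts, _ = simulate_combination_screen(
    truth, "s001", anchor, synergy_drug_ids=[partner])
all_layouts = {**layouts, **combo_layouts}
mono = screen_sample(mono_plates, all_layouts, truth.library, sample_id="mono")
combo = screen_sample(combo_plates, all_layouts, truth.library, sample_id="combo")

anchor_drug = truth.library[anchor]
ic25 = anchor_concentration(mono.fits[anchor], ConcRange(*anchor_drug.log10_range))
print(f"anchor {anchor_drug.name}: IC25 = {ic25:.2e} M (from its mono curve)")

deltas = sorted(
    ((d, dss_asym(combo.fits[d], config.conc_range) - dss_asym(mono.fits[d], config.conc_range))
     for d in truth.library.drug_ids),
    key=lambda kv: -kv[1],
)
print("top dcDSS (combo minus mono):")
for d, delta in deltas[:3]:
    marker = "  <- planted synergy" if d == partner else ""
    print(f"  {truth.library[d].name:12s} dcDSS = {delta:+6.2f}{marker}")
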