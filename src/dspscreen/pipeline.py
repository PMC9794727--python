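"""End-to-end orchestration: raw plates -> normalized plates -> curve fits
-> per-drug metrics -> cohort-contextualized hit calls -> report.

`run_sample_screen` processes one sample against an existing cohort store;
`run_simulated_cohort` screens a whole synthetic cohort, builds the
fitted-DSS cohort table, and calls hits for every sample with
leave-one-out quantiles — the workhorse behind recall / false-positive
checks of planted hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohort import CohortTable, HitCall, HitCallConfig, build_report, call_hits
from .curves import (
    CurveFit,
    assemble_dose_points,
    fit_asym_logistic,
    fit_asym_logistic_many,
)
from .errors import FitError
from .model import DrugLibrary, PlateLayout, RawPlate
from .qc import (
    DEFAULT_ZPRIME_THRESHOLD,
    MadConvention,
    NormalizedPlate,
    classify_screen,
    normalize_plate,
)
from .scoring import ControlPanel, DrugMetrics, compute_drug_metrics


@dataclass
class SampleScreenResult:
    sample_id: str
    normalized_plates: list[NormalizedPlate]
    screen_type: str
    fits: dict[str, CurveFit]
    metrics: list[DrugMetrics]
    unevaluable: dict[str, str] = field(default_factory=dict)
    hit_calls: list[HitCall] = field(default_factory=list)
    report: dict | None = None

    @property
    def qc_summary(self) -> dict:
        return {
            "screen_type": self.screen_type,
            "plates": [
                {
                    "plate_id": p.plate_id,
                    "zprime": round(p.qc.zprime, 4),
                    "qc_class": p.qc.qc_class,
                }
                for p in self.normalized_plates
            ],
        }


def screen_sample(
    plates: list[RawPlate],
    layouts: dict[str, PlateLayout],
    library: DrugLibrary,
    panel: ControlPanel | None = None,
    sample_id: str = "sample",
    qc_threshold: float = DEFAULT_ZPRIME_THRESHOLD,
    mad_convention: MadConvention = MadConvention.SCALED_MEDIAN_AD,
    dss_threshold: float = 10.0,
) -> SampleScreenResult:
    """Normalize, QC, fit and score one sample screen (no cohort context yet)."""
    normalized = [
        normalize_plate(p, layouts[p.layout_ref], qc_threshold, mad_convention)
        for p in plates
    ]
    screen_type = classify_screen([n.qc for n in normalized], n_expected=3)
    metrics: list[DrugMetrics] = []
    unevaluable: dict[str, str] = {}
    points_by_drug = {}
    for drug in library:
        try:
            points_by_drug[drug.drug_id] = assemble_dose_points(
                normalized, layouts, drug.drug_id, concentrations=drug.concentrations
            )
        except FitError as exc:
            unevaluable[drug.drug_id] = str(exc)
    try:
        fits = fit_asym_logistic_many(list(points_by_drug.values()))
    except FitError:
        # isolate the failing drug(s) by falling back to per-drug fitting
        fits = {}
        for drug_id, pts in points_by_drug.items():
            try:
                fits[drug_id] = fit_asym_logistic(pts)
            except FitError as exc:
                unevaluable[drug_id] = str(exc)
    for drug in library:
        fit = fits.get(drug.drug_id)
        points = points_by_drug.get(drug.drug_id)
        if fit is None or points is None:
            continue
        metrics.append(
            compute_drug_metrics(
                fit,
                points.conc_range,
                cmax=drug.cmax,
                panel=panel,
                drug_id=drug.drug_id,
                drug_name=drug.name,
                threshold_t=dss_threshold,
                max_effect_observed=max(points.conc_means.values()),
            )
        )
    return SampleScreenResult(
        sample_id=sample_id,
        normalized_plates=normalized,
        screen_type=screen_type,
        fits=fits,
        metrics=metrics,
        unevaluable=unevaluable,
    )


def run_sample_screen(
    plates: list[RawPlate],
    layouts: dict[str, PlateLayout],
    library: DrugLibrary,
    cohort: CohortTable | None = None,
    panel: ControlPanel | None = None,
    sample_id: str = "sample",
    diagnosis: str = "unspecified",
    hit_config: HitCallConfig | None = None,
    **screen_kwargs,
) -> SampleScreenResult:
    """Full single-sample pipeline ending in hit calls and the report document."""
    result = screen_sample(plates, layouts, library, panel=panel,
                           sample_id=sample_id, **screen_kwargs)
    result.hit_calls = call_hits(result.metrics, cohort, library,
                                 sample_id=sample_id, config=hit_config)
    result.report = build_report(
        sample_id, result.hit_calls, result.metrics, result.qc_summary,
        diagnosis=diagnosis,
    )
    return result


def run_simulated_cohort(truth, hit_config: HitCallConfig | None = None):
    """Screen every sample of a synthetic cohort and call hits against the
    fitted-DSS cohort table (leave-one-out quantiles).

    Returns (results_by_sample, cohort_table).
    """
    from .simulate import build_layouts, control_panel_from_truth, simulate_raw_plates

    config = truth.config
    layouts = build_layouts(config, truth.library)
    panel = control_panel_from_truth(truth)
    results: dict[str, SampleScreenResult] = {}
    for sid in truth.sample_ids:
        plates, _ = simulate_raw_plates(truth, sid, layouts=layouts)
        results[sid] = screen_sample(
            plates, layouts, truth.library, panel=panel, sample_id=sid,
            dss_threshold=config.dss_threshold,
        )
    dss_rows = {
        sid: {m.drug_id: m.dss_asym for m in res.metrics}
        for sid, res in results.items()
    }
    cohort = CohortTable(pd.DataFrame.from_dict(dss_rows, orient="index"),
                         diagnoses=truth.diagnoses)
    for sid, res in results.items():
        res.hit_calls = call_hits(res.metrics, cohort, truth.library,
                                  sample_id=sid, config=hit_config)
        res.report = build_report(sid, res.hit_calls, res.metrics, res.qc_summary,
                                  diagnosis=truth.diagnoses.get(sid, "unspecified"))
    return results, cohort


def hit_confusion(results: dict, truth) -> dict:
    """Recall / false-positive accounting of called hits vs planted truth."""
    planted = truth.planted_pairs()
    tp = fp = fn = tn = 0
    for sid, res in results.items():
        for call in res.hit_calls:
            pair = (sid, call.drug_id)
            if call.is_hit:
                if pair in planted:
                    tp += 1
                else:
                    fp += 1
            elif pair in planted:
                fn += 1
            else:
                tn += 1
    recall = tp / (tp + fn) if tp + fn else float("nan")
    fpr = fp / (fp + tn) if fp + tn else float("nan")
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn, "recall": recall, "fpr": fpr}
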