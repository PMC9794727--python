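"""Synthetic drug-sensitivity screens with known ground truth.

Emulates the screen design the pipeline expects: 78 drugs x 5 log-spaced
concentrations (1 nM - 10 uM at 10x steps) x duplicate wells, spread over
three 384-well plates per sample, with 16 DMSO, 16 benzethonium and 8
staurosporine control wells per plate.  Luminescence counts follow a
constant-CV multiplicative lognormal noise model around

    count = floor + (baseline - floor) * (1 - y_true(conc) / 100)

which is exactly the inverse of the percent-inhibition normalization, so a
noise-free simulation round-trips through the pipeline to machine
precision.

Each simulated sample carries a few planted sensitive drug-sample pairs
(high-asymptote curves with IC50 well below the clinical Cmax) against a
background of weak null responses; the planted pairs satisfy every hit
criterion by construction and anchor recall / false-positive-rate checks
of the full pipeline.  Control-degradation modes produce plates that fail
the robust Z' QC in distinct ways.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .curves import ConcRange, CurveFit
from .errors import ValidationError
from .model import (
    ROWS,
    DrugLibrary,
    DrugRecord,
    DrugStatus,
    PlateLayout,
    RawPlate,
    WellAddress,
    WellAssignment,
    WellRole,
    write_drug_library,
    write_plate_layout,
    write_raw_plate,
)
from .scoring import ControlPanel, dss_asym

DIAGNOSIS_VOCAB = ("sarcoma", "brain_tumor", "neuroblastoma", "other")
DRUG_CLASS_VOCAB = (
    "apoptotic modulator",
    "conv. chemotherapy",
    "kinase inhibitor",
    "epigenetic modifier",
    "metabolic modifier",
    "other",
)


@dataclass
class SimConfig:
    """All knobs of the synthetic screen; the seed fully determines output."""

    n_drugs: int = 78
    n_samples: int = 40
    conc_min: float = 1e-9            # molar, lowest of the 5-point grid
    n_concentrations: int = 5
    plates_per_sample: int = 3
    n_neg_controls: int = 16          # DMSO wells per plate
    n_pos_controls: int = 16          # benzethonium wells per plate
    n_mid_controls: int = 8           # staurosporine wells per plate
    noise_cv: float = 0.05            # lognormal count CV
    baseline_count: float = 1e5       # DMSO-level luminescence
    floor_count: float = 5e3          # benzethonium-level luminescence
    mid_inhibition_pct: float = 40.0  # staurosporine intermediate effect
    planted_hits_per_sample: int = 3
    n_control_samples: int = 5        # healthy-control panel size
    dss_threshold: float = 10.0
    seed: int = 0

    # planted-hit curve distributions
    hit_ymax: tuple[float, float] = (80.0, 100.0)
    hit_slope: tuple[float, float] = (0.8, 2.0)
    hit_asym: tuple[float, float] = (0.5, 2.0)
    # null (insensitive) curve distributions
    null_ymax: tuple[float, float] = (0.0, 40.0)
    null_slope: tuple[float, float] = (0.5, 2.0)
    null_asym: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if self.planted_hits_per_sample > self.n_drugs:
            raise ValidationError("planted_hits_per_sample cannot exceed n_drugs")
        if self.floor_count <= 0 or self.baseline_count <= self.floor_count:
            raise ValidationError("need baseline_count > floor_count > 0")

    @property
    def conc_grid(self) -> tuple[float, ...]:
        return tuple(self.conc_min * 10.0 ** i for i in range(self.n_concentrations))

    @property
    def conc_range(self) -> ConcRange:
        g = self.conc_grid
        return ConcRange(math.log10(g[0]), math.log10(g[-1]))


@dataclass
class TrueCurve:
    y_min: float
    y_max: float
    log10_ec50: float
    slope: float
    asym: float

    def as_fit(self) -> CurveFit:
        return CurveFit(
            y_min=self.y_min, y_max=self.y_max, log10_ec50=self.log10_ec50,
            slope=self.slope, asym=self.asym, r2=1.0, converged=True, n_points=0,
        )

    def predict_log10(self, x):
        return self.as_fit().predict_log10(x)


@dataclass
class GroundTruth:
    config: SimConfig
    library: DrugLibrary
    sample_ids: list[str]
    diagnoses: dict[str, str]
    curves: dict[tuple[str, str], TrueCurve]        # (sample_id, drug_id)
    planted: dict[tuple[str, str], bool]
    screen_types: dict[str, str] = field(default_factory=dict)
    panel_curves: dict[tuple[str, str], TrueCurve] = field(default_factory=dict)

    def planted_pairs(self) -> set[tuple[str, str]]:
        return {k for k, v in self.planted.items() if v}

    def true_dss(self, sample_id: str, drug_id: str) -> float:
        fit = self.curves[(sample_id, drug_id)].as_fit()
        return dss_asym(fit, self.config.conc_range, self.config.dss_threshold)


def _rng(config: SimConfig, *stream: str) -> np.random.Generator:
    """Independent deterministic substream keyed by config seed + labels.

    Labels are hashed with CRC32 (stable across processes, unlike ``hash``)."""
    key = [config.seed] + [zlib.crc32(s.encode()) for s in stream]
    return np.random.default_rng(np.random.SeedSequence(key))


def build_library(config: SimConfig) -> DrugLibrary:
    """Synthetic clinically-focused library: Cmax near the 4th tested
    concentration (+/- half a decade) so the IC50-below-Cmax criterion is
    exercised on both sides; a mix of approval statuses."""
    rng = _rng(config, "library")
    grid = config.conc_grid
    log_c4 = math.log10(grid[min(3, len(grid) - 1)])
    statuses = [DrugStatus.APPROVED, DrugStatus.APPROVED, DrugStatus.APPROVED,
                DrugStatus.CLINICAL_TRIAL, DrugStatus.INVESTIGATIONAL]
    drugs = []
    for i in range(config.n_drugs):
        cmax = 10.0 ** (log_c4 + rng.uniform(-0.5, 0.5))
        drugs.append(
            DrugRecord(
                drug_id=f"d{i + 1:03d}",
                name=f"drug-{i + 1:03d}",
                drug_class=DRUG_CLASS_VOCAB[i % len(DRUG_CLASS_VOCAB)],
                concentrations=grid,
                cmax=cmax,
                status=statuses[i % len(statuses)],
            )
        )
    return DrugLibrary(drugs=tuple(drugs), library_version=f"synthetic-{config.n_drugs}")


def build_layouts(config: SimConfig, library: DrugLibrary) -> dict[str, PlateLayout]:
    """Partition the library over the plates and lay out each plate.

    Controls sit on the edge columns (DMSO in column 1, benzethonium in
    column 24) and in row A (staurosporine); drug wells fill rows B-O,
    columns 2-23 row-major, 10 wells (5 concentrations x 2 replicates) per
    drug.
    """
    n_plates = config.plates_per_sample
    per_plate = math.ceil(len(library) / n_plates)
    interior = [
        WellAddress(r, c)
        for r in ROWS[1:15]        # rows B..O
        for c in range(2, 24)      # columns 2..23
    ]
    layouts: dict[str, PlateLayout] = {}
    for p in range(n_plates):
        plate_id = f"plate_{p + 1}"
        assignments: list[WellAssignment] = []
        for i in range(config.n_neg_controls):
            assignments.append(WellAssignment(WellAddress(ROWS[i % 16], 1), WellRole.NEG_CONTROL))
        for i in range(config.n_pos_controls):
            assignments.append(WellAssignment(WellAddress(ROWS[i % 16], 24), WellRole.POS_CONTROL))
        for i in range(config.n_mid_controls):
            assignments.append(WellAssignment(WellAddress("A", 2 + i), WellRole.MID_CONTROL))
        plate_drugs = library.drugs[p * per_plate:(p + 1) * per_plate]
        needed = len(plate_drugs) * config.n_concentrations * 2
        if needed > len(interior):
            raise ValidationError(
                f"{plate_id}: {needed} drug wells exceed the {len(interior)} "
                "available interior wells"
            )
        k = 0
        for drug in plate_drugs:
            for ci in range(config.n_concentrations):
                for ri in range(2):
                    assignments.append(
                        WellAssignment(interior[k], WellRole.DRUG, drug.drug_id, ci, ri)
                    )
                    k += 1
        layouts[plate_id] = PlateLayout(plate_id=plate_id, assignments=tuple(assignments))
    return layouts


def _draw_curve(rng: np.random.Generator, config: SimConfig, cmax: float,
                planted: bool) -> TrueCurve:
    x_min, x_max = config.conc_range.x_min, config.conc_range.x_max
    log_cmax = math.log10(cmax)
    if planted:
        # IC50 1-2 decades below Cmax, strong maximal effect: passes every
        # hit criterion with margin
        return TrueCurve(
            y_min=0.0,
            y_max=float(rng.uniform(*config.hit_ymax)),
            log10_ec50=float(rng.uniform(log_cmax - 2.0, log_cmax - 1.0)),
            slope=float(rng.uniform(*config.hit_slope)),
            asym=float(rng.uniform(*config.hit_asym)),
        )
    return TrueCurve(
        y_min=0.0,
        y_max=float(rng.uniform(*config.null_ymax)),
        log10_ec50=float(rng.uniform(x_min, x_max + 1.0)),
        slope=float(rng.uniform(*config.null_slope)),
        asym=float(rng.uniform(*config.null_asym)),
    )


def sample_ground_truth(config: SimConfig, library: DrugLibrary | None = None) -> GroundTruth:
    """Draw true curves and planted-hit labels for the whole cohort.

    Planted hits land only on reportable (approved / clinical-trial) drugs
    and are capped per drug so every planted pair sits in the cohort's top
    quartile for its drug by construction.
    """
    library = library if library is not None else build_library(config)
    rng = _rng(config, "truth")
    sample_ids = [f"s{i + 1:03d}" for i in range(config.n_samples)]
    diagnoses = {
        sid: DIAGNOSIS_VOCAB[int(rng.integers(len(DIAGNOSIS_VOCAB)))] for sid in sample_ids
    }
    reportable = [d.drug_id for d in library if d.status.reportable]
    if config.planted_hits_per_sample > len(reportable):
        raise ValidationError("not enough reportable drugs for the requested planted hits")
    # cap planted hits per drug so every planted pair stays in the cohort's
    # top quartile for that drug: k - 1 <= 0.25 * (n_samples - 1)
    per_drug_cap = max(1, int(0.25 * config.n_samples + 0.75))
    planted_count = {d: 0 for d in reportable}

    curves: dict[tuple[str, str], TrueCurve] = {}
    planted: dict[tuple[str, str], bool] = {}
    for sid in sample_ids:
        k = config.planted_hits_per_sample
        eligible = [d for d in reportable if planted_count[d] < per_drug_cap]
        if len(eligible) < k:  # cap exhausted: fall back to least-loaded drugs
            eligible = sorted(reportable, key=lambda d: (planted_count[d], d))[:max(k, 2 * k)]
        chosen = [str(x) for x in rng.choice(eligible, size=k, replace=False)] if k else []
        for d in chosen:
            planted_count[d] += 1
        chosen_set = set(chosen)
        for drug in library:
            is_hit = drug.drug_id in chosen_set
            curves[(sid, drug.drug_id)] = _draw_curve(rng, config, drug.cmax, is_hit)
            planted[(sid, drug.drug_id)] = is_hit

    panel_rng = _rng(config, "panel")
    panel_curves: dict[tuple[str, str], TrueCurve] = {}
    for j in range(config.n_control_samples):
        cid = f"ctrl{j + 1:02d}"
        for drug in library:
            panel_curves[(cid, drug.drug_id)] = _draw_curve(panel_rng, config, drug.cmax, False)

    return GroundTruth(
        config=config,
        library=library,
        sample_ids=sample_ids,
        diagnoses=diagnoses,
        curves=curves,
        planted=planted,
        screen_types={sid: "full" for sid in sample_ids},
        panel_curves=panel_curves,
    )


def control_panel_from_truth(truth: GroundTruth) -> ControlPanel:
    """DSS of the healthy-control analog samples, from their true curves."""
    panel = ControlPanel()
    for (cid, drug_id), curve in sorted(truth.panel_curves.items()):
        panel.entries.setdefault(drug_id, []).append(
            dss_asym(curve.as_fit(), truth.config.conc_range, truth.config.dss_threshold)
        )
    return panel


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def _well_count(config: SimConfig, inhibition_pct: float) -> float:
    span = config.baseline_count - config.floor_count
    return config.floor_count + span * (1.0 - inhibition_pct / 100.0)


def simulate_raw_plates(
    truth: GroundTruth,
    sample_id: str,
    layouts: dict[str, PlateLayout] | None = None,
    curves: dict[tuple[str, str], TrueCurve] | None = None,
    plate_suffix: str = "",
) -> tuple[list[RawPlate], dict[str, PlateLayout]]:
    """Raw luminescence plates for one sample from its true curves."""
    config = truth.config
    layouts = layouts if layouts is not None else build_layouts(config, truth.library)
    curves = curves if curves is not None else truth.curves
    conc_by_drug = {d.drug_id: d.concentrations for d in truth.library}
    plates: list[RawPlate] = []
    out_layouts: dict[str, PlateLayout] = {}
    for plate_id in sorted(layouts):
        layout = layouts[plate_id]
        rng = _rng(config, "counts", sample_id, plate_id, plate_suffix)
        wells = sorted(layout.assignments, key=lambda a: (a.well.row, a.well.column))
        noise = _lognormal_factors(rng, config.noise_cv, len(wells))
        counts: dict[WellAddress, float] = {}
        for a, f in zip(wells, noise):
            if a.role is WellRole.NEG_CONTROL:
                level = config.baseline_count
            elif a.role is WellRole.POS_CONTROL:
                level = config.floor_count
            elif a.role is WellRole.MID_CONTROL:
                level = _well_count(config, config.mid_inhibition_pct)
            elif a.role is WellRole.DRUG:
                curve = curves[(sample_id, a.drug_id)]  # type: ignore[index]
                conc = conc_by_drug[a.drug_id][a.conc_index]  # type: ignore[index]
                y = float(curve.predict_log10(math.log10(conc)))
                level = _well_count(config, y)
            else:
                continue
            counts[a.well] = max(0.0, level * float(f))
        out_id = plate_id + plate_suffix
        if plate_suffix:
            layout = PlateLayout(plate_id=out_id, assignments=layout.assignments)
        out_layouts[out_id] = layout
        plates.append(RawPlate(plate_id=out_id, counts=counts, layout_ref=out_id))
    return plates, out_layouts


def degrade_controls(
    plate: RawPlate,
    layout: PlateLayout,
    mode: str,
    drift_frac: float = 0.85,
    scatter_factor: float = 5.0,
    collapse_frac: float = 0.9,
    baseline_count: float = 1e5,
) -> RawPlate:
    """Return a copy of the plate with its controls damaged.

    ``pos_drift`` shifts benzethonium counts toward the DMSO baseline,
    ``neg_scatter`` inflates the spread of the DMSO wells about their
    median, ``separation_loss`` collapses both control medians toward their
    common center.  Defaults push the robust Z' below the 0.5 threshold;
    zero-strength parameters leave the plate unchanged.
    """
    neg_wells = {a.well for a in layout.wells_by_role(WellRole.NEG_CONTROL)}
    pos_wells = {a.well for a in layout.wells_by_role(WellRole.POS_CONTROL)}
    if not neg_wells or not pos_wells:
        raise ValidationError(f"plate {plate.plate_id}: no control wells to degrade")
    counts = dict(plate.counts)
    if mode == "pos_drift":
        for w in pos_wells:
            if w in counts:
                counts[w] = counts[w] + drift_frac * (baseline_count - counts[w])
    elif mode == "neg_scatter":
        med = float(np.median([counts[w] for w in neg_wells if w in counts]))
        for w in neg_wells:
            if w in counts:
                counts[w] = max(0.0, med + scatter_factor * (counts[w] - med))
    elif mode == "separation_loss":
        med_neg = float(np.median([counts[w] for w in neg_wells if w in counts]))
        med_pos = float(np.median([counts[w] for w in pos_wells if w in counts]))
        center = 0.5 * (med_neg + med_pos)
        for group, med in ((neg_wells, med_neg), (pos_wells, med_pos)):
            target = med + collapse_frac * (center - med)
            scale = target / med if med else 1.0
            for w in group:
                if w in counts:
                    counts[w] = counts[w] * scale
    else:
        raise ValidationError(f"unknown degradation mode {mode!r}")
    return RawPlate(plate_id=plate.plate_id, counts=counts, layout_ref=plate.layout_ref)


def simulate_combination_screen(
    truth: GroundTruth,
    sample_id: str,
    anchor_drug_id: str,
    synergy_drug_ids: list[str] | None = None,
    ec50_shift_decades: float = 1.0,
    ymax_boost: float = 20.0,
) -> tuple[list[RawPlate], dict[str, PlateLayout], dict[str, TrueCurve]]:
    """Anchored combination arm for one sample.

    The anchor (at its mono IC25) is dispensed on every library well; for
    the designated synergistic partners the combo truth curve gets its EC50
    shifted down and its asymptote raised, all other pairs respond exactly
    as in monotherapy.  Returns the combo plates, their layouts and the
    combo truth curves keyed by drug.
    """
    config = truth.config
    if anchor_drug_id not in truth.library.drug_ids:
        raise ValidationError(f"anchor drug {anchor_drug_id!r} not in library")
    anchor_curve = truth.curves[(sample_id, anchor_drug_id)]
    from .curves import invert_icx

    if invert_icx(anchor_curve.as_fit(), 25.0, config.conc_range) is None:
        raise ValidationError(
            f"anchor {anchor_drug_id}: monotherapy curve never reaches 25% "
            "inhibition within the tested range"
        )
    synergy = set(synergy_drug_ids or [])
    combo_curves: dict[str, TrueCurve] = {}
    for drug in truth.library:
        base = truth.curves[(sample_id, drug.drug_id)]
        if drug.drug_id in synergy:
            combo_curves[drug.drug_id] = TrueCurve(
                y_min=base.y_min,
                y_max=min(base.y_max + ymax_boost, 100.0),
                log10_ec50=base.log10_ec50 - ec50_shift_decades,
                slope=base.slope,
                asym=base.asym,
            )
        else:
            combo_curves[drug.drug_id] = base
    keyed = {(sample_id, d): c for d, c in combo_curves.items()}
    plates, layouts = simulate_raw_plates(
        truth, sample_id, curves=keyed, plate_suffix="_combo"
    )
    return plates, layouts, combo_curves


# ---------------------------------------------------------------------------
# File emission (the artifact set `dsp run` consumes)

def write_screen_set(truth: GroundTruth, out_dir: str | Path) -> None:
    """Write library, layouts, per-sample raw counts, control panel, the
    ground-truth cohort DSS store and ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = truth.config
    write_drug_library(truth.library, out / "drug_library.csv")

    layouts = build_layouts(config, truth.library)
    layout_dir = out / "layouts"
    layout_dir.mkdir(exist_ok=True)
    for plate_id in sorted(layouts):
        write_plate_layout(layouts[plate_id], layout_dir / f"{plate_id}.csv")

    samples_dir = out / "samples"
    samples_dir.mkdir(exist_ok=True)
    for sid in truth.sample_ids:
        plates, _ = simulate_raw_plates(truth, sid, layouts=layouts)
        sdir = samples_dir / sid
        sdir.mkdir(exist_ok=True)
        for plate in plates:
            write_raw_plate(plate, sdir / f"counts_{plate.plate_id}.csv")

    panel = control_panel_from_truth(truth)
    rows = ["drug_id,control_id,dss"]
    for drug_id in sorted(panel.entries):
        for j, v in enumerate(panel.entries[drug_id]):
            rows.append(f"{drug_id},ctrl{j + 1:02d},{v!r}")
    (out / "control_panel.csv").write_text("\n".join(rows) + "\n")

    header = "sample_id," + ",".join(truth.library.drug_ids)
    lines = [header]
    for sid in truth.sample_ids:
        vals = [repr(truth.true_dss(sid, d)) for d in truth.library.drug_ids]
        lines.append(sid + "," + ",".join(vals))
    (out / "cohort.csv").write_text("\n".join(lines) + "\n")

    gt = {
        "config": asdict(truth.config),
        "diagnoses": truth.diagnoses,
        "curves": {
            f"{sid}|{did}": asdict(c) for (sid, did), c in sorted(truth.curves.items())
        },
        "planted": sorted(f"{sid}|{did}" for (sid, did) in truth.planted_pairs()),
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=2, sort_keys=True) + "\n")


def load_control_panel(path: str | Path) -> ControlPanel:
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    panel = ControlPanel()
    for _, row in df.iterrows():
        panel.entries.setdefault(str(row["drug_id"]), []).append(float(row["dss"]))
    return panel
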