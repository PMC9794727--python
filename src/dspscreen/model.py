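"""Domain types and file IO for drug libraries, plate layouts and raw plates.

The screen is organised around 384-well plates (rows A-P, columns 1-24).
Each well either carries a library drug at one of five concentrations in
one of two replicates, or serves as a control: DMSO (vehicle, minimum
effect), benzethonium chloride (maximum kill) or 250 nM staurosporine
(intermediate, monitoring only).

All tabular files are UTF-8 CSV with a header row; wells are written as
letter+number ("B2"); concentrations are molar.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError

ROWS = "ABCDEFGHIJKLMNOP"
N_COLS = 24
N_CONCENTRATIONS = 5
N_REPLICATES = 2

_WELL_RE = re.compile(r"^([A-P])(\d{1,2})$")


class DrugStatus(str, Enum):
    APPROVED = "approved"
    CLINICAL_TRIAL = "clinical_trial"
    INVESTIGATIONAL = "investigational"

    @property
    def reportable(self) -> bool:
        """Only approved drugs and drugs in clinical studies are reported."""
        return self is not DrugStatus.INVESTIGATIONAL


class WellRole(str, Enum):
    DRUG = "drug"
    POS_CONTROL = "pos_control"  # benzethonium chloride, maximum effect
    NEG_CONTROL = "neg_control"  # DMSO vehicle, minimum effect
    MID_CONTROL = "mid_control"  # 250 nM staurosporine, intermediate effect
    EMPTY = "empty"


@dataclass(frozen=True, order=True)
class WellAddress:
    """A 384-well coordinate: row letter A-P, column 1-24."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise ValidationError(f"invalid well row {self.row!r} (expected A-P)")
        if not 1 <= self.column <= N_COLS:
            raise ValidationError(
                f"invalid well column {self.column} (expected 1-{N_COLS})"
            )

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        m = _WELL_RE.match(str(text).strip().upper())
        if not m:
            raise ValidationError(f"invalid well address {text!r}")
        return cls(m.group(1), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.row}{self.column}"


@dataclass(frozen=True)
class DrugRecord:
    """One library drug: five ascending test concentrations plus its Cmax.

    ``concentrations`` are molar and span five orders of magnitude at 10x
    steps; ``cmax`` is the clinically achievable peak plasma concentration
    used as the potency ceiling in hit calling.
    """

    drug_id: str
    name: str
    drug_class: str
    concentrations: tuple[float, ...]
    cmax: float
    status: DrugStatus

    def __post_init__(self) -> None:
        conc = self.concentrations
        if len(conc) != N_CONCENTRATIONS:
            raise ValidationError(
                f"drug {self.drug_id}: expected {N_CONCENTRATIONS} concentrations, "
                f"got {len(conc)}"
            )
        if any(not (c > 0 and math.isfinite(c)) for c in conc):
            raise ValidationError(f"drug {self.drug_id}: non-positive concentration")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValidationError(
                f"drug {self.drug_id}: concentrations not strictly increasing"
            )
        span = conc[-1] / conc[0]
        if not (0.99e4 <= span <= 1.01e4):
            raise ValidationError(
                f"drug {self.drug_id}: concentration span ratio {span:.4g} "
                "not within 1% of 1e4 (five decades)"
            )
        if not (self.cmax > 0 and math.isfinite(self.cmax)):
            raise ValidationError(f"drug {self.drug_id}: cmax must be positive")

    @property
    def log10_range(self) -> tuple[float, float]:
        return (math.log10(self.concentrations[0]), math.log10(self.concentrations[-1]))


@dataclass(frozen=True)
class DrugLibrary:
    drugs: tuple[DrugRecord, ...]
    library_version: str = "unversioned"

    def __post_init__(self) -> None:
        if not 1 <= len(self.drugs) <= 200:
            raise ValidationError(f"library must hold 1-200 drugs, got {len(self.drugs)}")
        ids = [d.drug_id for d in self.drugs]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValidationError(f"duplicate drug_id(s): {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.drugs)

    def __iter__(self):
        return iter(self.drugs)

    def __getitem__(self, drug_id: str) -> DrugRecord:
        for d in self.drugs:
            if d.drug_id == drug_id:
                return d
        raise KeyError(drug_id)

    @property
    def drug_ids(self) -> list[str]:
        return [d.drug_id for d in self.drugs]


@dataclass(frozen=True)
class WellAssignment:
    well: WellAddress
    role: WellRole
    drug_id: str | None = None
    conc_index: int | None = None
    replicate_index: int | None = None

    def __post_init__(self) -> None:
        if self.role is WellRole.DRUG:
            if self.drug_id is None or self.conc_index is None or self.replicate_index is None:
                raise ValidationError(
                    f"well {self.well}: role=drug requires drug_id, conc_index "
                    "and replicate_index"
                )
            if not 0 <= self.conc_index < N_CONCENTRATIONS:
                raise ValidationError(
                    f"well {self.well}: conc_index {self.conc_index} out of range 0-4"
                )
            if not 0 <= self.replicate_index < N_REPLICATES:
                raise ValidationError(
                    f"well {self.well}: replicate_index {self.replicate_index} "
                    "out of range 0-1"
                )
        elif self.drug_id is not None or self.conc_index is not None or self.replicate_index is not None:
            raise ValidationError(
                f"well {self.well}: control/empty wells carry no drug fields"
            )


@dataclass(frozen=True)
class PlateLayout:
    plate_id: str
    assignments: tuple[WellAssignment, ...]

    def __post_init__(self) -> None:
        seen: set[WellAddress] = set()
        for a in self.assignments:
            if a.well in seen:
                raise ValidationError(f"plate {self.plate_id}: duplicate well {a.well}")
            seen.add(a.well)
        conditions: set[tuple[str, int, int]] = set()
        for a in self.drug_wells():
            key = (a.drug_id, a.conc_index, a.replicate_index)  # type: ignore[arg-type]
            if key in conditions:
                raise ValidationError(
                    f"plate {self.plate_id}: condition {key} assigned twice"
                )
            conditions.add(key)

    def wells_by_role(self, role: WellRole) -> list[WellAssignment]:
        return [a for a in self.assignments if a.role is role]

    def drug_wells(self) -> list[WellAssignment]:
        return self.wells_by_role(WellRole.DRUG)

    @property
    def drug_ids(self) -> list[str]:
        return sorted({a.drug_id for a in self.drug_wells()})  # type: ignore[arg-type]


@dataclass(frozen=True)
class RawPlate:
    """Raw per-well luminescence counts (CellTiter-Glo-style readout)."""

    plate_id: str
    counts: Mapping[WellAddress, float]
    layout_ref: str

    def __post_init__(self) -> None:
        for well, c in self.counts.items():
            if not (math.isfinite(c) and c >= 0):
                raise ValidationError(
                    f"plate {self.plate_id}: count at {well} must be finite and >= 0"
                )

    def check_against_layout(self, layout: PlateLayout) -> None:
        if layout.plate_id != self.layout_ref:
            raise ValidationError(
                f"plate {self.plate_id}: layout_ref {self.layout_ref!r} does not "
                f"match layout {layout.plate_id!r}"
            )
        known = {a.well for a in layout.assignments}
        extra = set(self.counts) - known
        if extra:
            raise ValidationError(
                f"plate {self.plate_id}: counts for wells absent from layout: "
                f"{sorted(str(w) for w in extra)[:5]}"
            )


@dataclass
class DrugCoverage:
    drug_id: str
    n_conditions_present: int
    complete: bool
    missing: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class ScreenManifest:
    """Which drugs of the library have their full 5x2 condition grid measured.

    A full screen comprises three plates; with 1-2 plates the screen is
    partial and the manifest flags the uncovered drugs.
    """

    sample_id: str
    diagnosis: str
    plates: list[RawPlate]
    coverage: dict[str, DrugCoverage]
    seeded_cells_per_well: int = 1000
    viability_pct: float = 100.0

    def __post_init__(self) -> None:
        if not 1 <= len(self.plates) <= 3:
            raise ValidationError("a screen holds 1-3 plates")
        if not 0 <= self.viability_pct <= 100:
            raise ValidationError("viability_pct must lie in [0, 100]")

    @property
    def covered_drugs(self) -> list[str]:
        return sorted(d for d, c in self.coverage.items() if c.complete)

    @property
    def incomplete_drugs(self) -> list[str]:
        return sorted(d for d, c in self.coverage.items() if not c.complete)

    @property
    def n_drug_wells(self) -> int:
        return sum(c.n_conditions_present for c in self.coverage.values())


# ---------------------------------------------------------------------------
# File IO

_LIBRARY_COLUMNS = ["drug_id", "name", "class", "conc_1", "conc_2", "conc_3",
                    "conc_4", "conc_5", "cmax", "status"]


def load_drug_library(path: str | Path, library_version: str | None = None) -> DrugLibrary:
    """Read a drug library CSV (columns drug_id, name, class, conc_1..5, cmax, status)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    drugs = []
    for idx, row in df.iterrows():
        try:
            conc = tuple(float(row[f"conc_{i}"]) for i in range(1, 6))
            cmax = float(row["cmax"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path} row {idx + 2}: non-numeric concentration or cmax ({exc})"
            ) from None
        try:
            status = DrugStatus(str(row["status"]).strip())
        except ValueError:
            raise ValidationError(
                f"{path} row {idx + 2}: unknown status {row['status']!r}"
            ) from None
        try:
            drugs.append(
                DrugRecord(
                    drug_id=str(row["drug_id"]).strip(),
                    name=str(row["name"]).strip(),
                    drug_class=str(row["class"]).strip(),
                    concentrations=conc,
                    cmax=cmax,
                    status=status,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {idx + 2}: {exc}") from None
    version = library_version if library_version is not None else Path(path).stem
    return DrugLibrary(drugs=tuple(drugs), library_version=version)


def write_drug_library(library: DrugLibrary, path: str | Path) -> None:
    rows = []
    for d in library:
        row = {"drug_id": d.drug_id, "name": d.name, "class": d.drug_class}
        for i, c in enumerate(d.concentrations, start=1):
            row[f"conc_{i}"] = repr(c)
        row["cmax"] = repr(d.cmax)
        row["status"] = d.status.value
        rows.append(row)
    pd.DataFrame(rows, columns=_LIBRARY_COLUMNS).to_csv(path, index=False)


_LAYOUT_COLUMNS = ["plate_id", "well", "role", "drug_id", "conc_index", "replicate_index"]


def load_plate_layout(path: str | Path) -> PlateLayout:
    """Read one plate layout CSV (plate_id, well, role, drug fields)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("plate_id", "well", "role") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    plate_ids = sorted(set(df["plate_id"].astype(str)))
    if len(plate_ids) != 1:
        raise ValidationError(f"{path}: expected one plate_id, found {plate_ids}")
    assignments = []
    for idx, row in df.iterrows():
        try:
            well = WellAddress.parse(row["well"])
            role = WellRole(str(row["role"]).strip())

            def _opt_int(col: str) -> int | None:
                v = row.get(col)
                if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
                    return None
                return int(float(v))

            drug_id = row.get("drug_id")
            if drug_id is not None and (not isinstance(drug_id, str) or not drug_id.strip()):
                drug_id = None
            if isinstance(drug_id, float) and math.isnan(drug_id):
                drug_id = None
            assignments.append(
                WellAssignment(
                    well=well,
                    role=role,
                    drug_id=str(drug_id).strip() if drug_id is not None else None,
                    conc_index=_opt_int("conc_index"),
                    replicate_index=_opt_int("replicate_index"),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {idx + 2}: {exc}") from None
    return PlateLayout(plate_id=plate_ids[0], assignments=tuple(assignments))


def write_plate_layout(layout: PlateLayout, path: str | Path) -> None:
    rows = []
    for a in sorted(layout.assignments, key=lambda a: (a.well.row, a.well.column)):
        rows.append(
            {
                "plate_id": layout.plate_id,
                "well": str(a.well),
                "role": a.role.value,
                "drug_id": a.drug_id if a.drug_id is not None else "",
                "conc_index": a.conc_index if a.conc_index is not None else "",
                "replicate_index": a.replicate_index if a.replicate_index is not None else "",
            }
        )
    pd.DataFrame(rows, columns=_LAYOUT_COLUMNS).to_csv(path, index=False)


def load_raw_plate(path: str | Path, layout_ref: str | None = None) -> RawPlate:
    """Read raw counts CSV (plate_id, well, count)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("plate_id", "well", "count") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    plate_ids = sorted(set(df["plate_id"].astype(str)))
    if len(plate_ids) != 1:
        raise ValidationError(f"{path}: expected one plate_id, found {plate_ids}")
    counts: dict[WellAddress, float] = {}
    for idx, row in df.iterrows():
        well = WellAddress.parse(row["well"])
        if well in counts:
            raise ValidationError(f"{path} row {idx + 2}: duplicate well {well}")
        counts[well] = float(row["count"])
    return RawPlate(
        plate_id=plate_ids[0],
        counts=counts,
        layout_ref=layout_ref if layout_ref is not None else plate_ids[0],
    )


def write_raw_plate(plate: RawPlate, path: str | Path) -> None:
    rows = [
        {"plate_id": plate.plate_id, "well": str(w), "count": repr(c)}
        for w, c in sorted(plate.counts.items())
    ]
    pd.DataFrame(rows, columns=["plate_id", "well", "count"]).to_csv(path, index=False)


def validate_screen(
    plates: Iterable[RawPlate],
    layouts: Mapping[str, PlateLayout],
    library: DrugLibrary,
    sample_id: str = "sample",
    diagnosis: str = "unspecified",
    **manifest_kwargs,
) -> ScreenManifest:
    """Cross-check raw plates against their layouts and account per-drug coverage.

    Each library drug needs all 5 concentrations x 2 replicates measured
    somewhere across the provided plates to count as complete; drugs that are
    only partially measured (missing plate, deleted well) are flagged.
    """
    plates = list(plates)
    if not plates:
        raise ValidationError("a screen requires at least one plate")
    present: dict[str, set[tuple[int, int]]] = {}
    for plate in plates:
        layout = layouts.get(plate.layout_ref)
        if layout is None:
            raise ValidationError(
                f"plate {plate.plate_id}: no layout {plate.layout_ref!r} provided"
            )
        plate.check_against_layout(layout)
        for a in layout.drug_wells():
            if a.well in plate.counts:
                present.setdefault(a.drug_id, set()).add(  # type: ignore[arg-type]
                    (a.conc_index, a.replicate_index)  # type: ignore[arg-type]
                )
    full_grid = {
        (ci, ri) for ci in range(N_CONCENTRATIONS) for ri in range(N_REPLICATES)
    }
    coverage: dict[str, DrugCoverage] = {}
    for drug in library:
        have = present.get(drug.drug_id, set())
        coverage[drug.drug_id] = DrugCoverage(
            drug_id=drug.drug_id,
            n_conditions_present=len(have),
            complete=have == full_grid,
            missing=sorted(full_grid - have),
        )
    return ScreenManifest(
        sample_id=sample_id,
        diagnosis=diagnosis,
        plates=plates,
        coverage=coverage,
        **manifest_kwargs,
    )


def write_manifest(manifest: ScreenManifest, path: str | Path) -> None:
    doc = {
        "sample_id": manifest.sample_id,
        "diagnosis": manifest.diagnosis,
        "plates": [p.plate_id for p in manifest.plates],
        "seeded_cells_per_well": manifest.seeded_cells_per_well,
        "viability_pct": manifest.viability_pct,
        "covered_drugs": manifest.covered_drugs,
        "incomplete_drugs": manifest.incomplete_drugs,
        "n_drug_wells": manifest.n_drug_wells,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
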