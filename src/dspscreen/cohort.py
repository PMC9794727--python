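"""Cohort ranking, hit calling, agreement statistics and report artifacts.

A sample's response to each drug is placed in the context of the screened
cohort as a quantile: the percentage of other samples with strictly lower
DSS for that drug.  A quantile of 75% or more marks an above-average
response.

A drug is called a hit when every criterion holds:

  (i)    sDSS > 0 (more active on the tumor than on healthy controls),
  (ii)   maximal fitted effect >= 75% inhibition,
  (iii)  absolute IC50 below the clinical Cmax,
  (iii') predicted inhibition at Cmax >= 50%,
  (iv)   curve-fit R^2 >= 0.8,
  (v)    cohort quantile >= 75% (configurable to advisory),
  (vi)   drug approved or in clinical studies (investigational drugs are
         never reported as hits but corroborate in-class effects).

Paired screens (e.g. a fresh-tissue culture vs the long-term culture of
the same tumor) are compared with Bland-Altman limits of agreement:
mean paired difference +/- 1.96 SD of the differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .errors import ScoringError
from .model import DrugLibrary, DrugStatus
from .scoring import DrugMetrics

QUANTILE_HIT_THRESHOLD = 75.0
MAX_EFFECT_THRESHOLD = 75.0
CMAX_INHIBITION_THRESHOLD = 50.0
R2_THRESHOLD = 0.8
MIN_COHORT_FOR_QUANTILES = 10
LOW_DSS_FOOTNOTE_THRESHOLD = 5.0


@dataclass
class HitCallConfig:
    quantile_required: bool = True
    quantile_threshold: float = QUANTILE_HIT_THRESHOLD
    max_effect_threshold: float = MAX_EFFECT_THRESHOLD
    cmax_inhibition_threshold: float = CMAX_INHIBITION_THRESHOLD
    r2_threshold: float = R2_THRESHOLD
    min_cohort: int = MIN_COHORT_FOR_QUANTILES


@dataclass
class QuantileRank:
    drug_id: str
    quantile_pct: float
    n_compared: int


@dataclass
class HitCall:
    drug_id: str
    flags: dict[str, bool]
    is_hit: bool
    quantile_pct: float | None = None
    in_class_support: list[str] = field(default_factory=list)
    drug_name: str | None = None


@dataclass
class AgreementStats:
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n_pairs: int
    means: np.ndarray | None = None
    differences: np.ndarray | None = None
    outlier_indices: list[int] = field(default_factory=list)


class CohortTable:
    """Samples x drugs DSS matrix with missing values allowed."""

    def __init__(self, dss: pd.DataFrame, diagnoses: dict[str, str] | None = None):
        if dss.index.has_duplicates:
            raise ScoringError("cohort sample_ids must be unique")
        empty = [c for c in dss.columns if dss[c].notna().sum() == 0]
        if empty:
            raise ScoringError(f"cohort columns with no data: {empty}")
        self.dss = dss.astype(float)
        self.diagnoses = diagnoses or {}

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dss.index)

    @property
    def drug_ids(self) -> list[str]:
        return list(self.dss.columns)

    def comparison_values(self, drug_id: str, exclude_sample: str | None = None) -> list[float]:
        col = self.dss[drug_id]
        if exclude_sample is not None and exclude_sample in col.index:
            col = col.drop(exclude_sample)
        return [float(v) for v in col.dropna()]

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.dss.to_csv(path, index_label="sample_id")


def cohort_quantile(value: float, comparison: list[float], drug_id: str = "") -> QuantileRank:
    """Percentage of comparison samples with strictly lower DSS (ties do not
    count as lower); the sample of interest must not be in ``comparison``."""
    if not comparison:
        raise ScoringError("empty comparison set for cohort quantile")
    lower = sum(1 for v in comparison if v < value)
    return QuantileRank(
        drug_id=drug_id,
        quantile_pct=100.0 * lower / len(comparison),
        n_compared=len(comparison),
    )


def _effect_flags(m: DrugMetrics, cmax: float | None, config: HitCallConfig) -> dict[str, bool]:
    return {
        "sdss_positive": m.sdss > 0,
        "max_effect_ge_75": m.max_effect >= config.max_effect_threshold,
        "ic50_below_cmax": (cmax is not None and m.ic50_abs is not None
                            and m.ic50_abs < cmax),
        "inhibition_at_cmax_ge_50": m.inhibition_at_cmax >= config.cmax_inhibition_threshold,
        "r2_ge_080": m.r2 >= config.r2_threshold,
    }


def call_hits(
    sample_metrics: list[DrugMetrics],
    cohort: CohortTable | None,
    library: DrugLibrary,
    sample_id: str | None = None,
    config: HitCallConfig | None = None,
) -> list[HitCall]:
    """Evaluate the hit criteria for every drug of one sample screen.

    Flags are evaluated independently, then conjoined.  Investigational
    drugs can never be hits; when such a drug passes all effect criteria it
    is recorded as in-class support on reportable hits of the same class.
    """
    config = config or HitCallConfig()
    by_id = {d.drug_id: d for d in library}

    calls: list[HitCall] = []
    effect_pass_by_class: dict[str, list[str]] = {}
    for m in sample_metrics:
        drug = by_id.get(m.drug_id)
        cmax = drug.cmax if drug is not None else None
        flags = _effect_flags(m, cmax, config)
        if (drug is not None and not drug.status.reportable
                and all(flags.values())):
            effect_pass_by_class.setdefault(drug.drug_class, []).append(drug.name)

    for m in sorted(sample_metrics, key=lambda m: m.drug_id):
        drug = by_id.get(m.drug_id)
        cmax = drug.cmax if drug is not None else None
        flags = _effect_flags(m, cmax, config)
        flags["reportable_status"] = drug is not None and drug.status.reportable

        quantile_pct: float | None = None
        if cohort is not None and m.drug_id in cohort.drug_ids:
            comparison = cohort.comparison_values(m.drug_id, exclude_sample=sample_id)
            if len(comparison) + (1 if sample_id in cohort.sample_ids else 0) >= config.min_cohort:
                quantile_pct = cohort_quantile(m.dss_asym, comparison, m.drug_id).quantile_pct
        if config.quantile_required:
            flags["quantile_ge_75"] = (
                quantile_pct is not None and quantile_pct >= config.quantile_threshold
            )

        is_hit = all(flags.values())
        support: list[str] = []
        if is_hit and drug is not None:
            support = sorted(effect_pass_by_class.get(drug.drug_class, []))
        calls.append(
            HitCall(
                drug_id=m.drug_id,
                flags=flags,
                is_hit=is_hit,
                quantile_pct=quantile_pct,
                in_class_support=support,
                drug_name=drug.name if drug is not None else m.drug_id,
            )
        )
    return calls


def waterfall_order(values: list[tuple[str, float]]) -> list[tuple[str, float]]:
    """Drugs sorted by descending score, ties broken alphabetically by name.

    This is the ordering of the report's waterfall plot (strongest response
    on the left).
    """
    if not values:
        raise ScoringError("waterfall_order needs at least one drug")
    return sorted(values, key=lambda kv: (-kv[1], kv[0]))


def quantile_heatmap_order(matrix: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Row and column orderings from agglomerative hierarchical clustering
    (Euclidean distance, complete linkage, deterministic leaf order)."""
    if matrix.isna().any().any():
        raise ScoringError(
            "clustering sub-matrix contains missing values; restrict the "
            "drug/sample selection to fully observed entries"
        )

    def _order(df: pd.DataFrame) -> list[str]:
        if len(df) < 2:
            return list(df.index)
        Z = linkage(df.to_numpy(dtype=float), method="complete", metric="euclidean")
        return [df.index[i] for i in leaves_list(Z)]

    return _order(matrix), _order(matrix.T)


def bland_altman(paired: list[tuple[float, float]]) -> AgreementStats:
    """Limits of agreement for paired screens: bias = mean(a - b) and
    LoA = bias +/- 1.96 * SD(a - b) (sample SD, n-1 denominator)."""
    if len(paired) < 2:
        raise ScoringError("Bland-Altman needs at least 2 pairs")
    a = np.array([p[0] for p in paired], dtype=float)
    b = np.array([p[1] for p in paired], dtype=float)
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    outliers = [i for i, d in enumerate(diff) if d < lo or d > hi]
    return AgreementStats(
        bias=bias, sd_diff=sd, loa_lower=lo, loa_upper=hi,
        n_pairs=len(paired), means=(a + b) / 2.0, differences=diff,
        outlier_indices=outliers,
    )


def build_report(
    sample_id: str,
    hit_calls: list[HitCall],
    metrics: list[DrugMetrics],
    qc_summary: dict,
    diagnosis: str = "unspecified",
) -> dict:
    """Assemble the tumor-board style report document.

    Hits are ranked by cohort quantile descending (alphabetical on ties);
    drugs scoring DSS < 5 carry a low-DSS footnote flag; a screen with no
    qualifying drug states so explicitly.
    """
    m_by_id = {m.drug_id: m for m in metrics}
    hits = [h for h in hit_calls if h.is_hit]
    hits.sort(key=lambda h: (-(h.quantile_pct if h.quantile_pct is not None else -1.0),
                             h.drug_name or h.drug_id))
    hit_rows = []
    for rank, h in enumerate(hits, start=1):
        m = m_by_id[h.drug_id]
        hit_rows.append(
            {
                "ranking": rank,
                "drug_id": h.drug_id,
                "drug_name": h.drug_name or h.drug_id,
                "dss_asym": round(m.dss_asym, 3),
                "sdss": round(m.sdss, 3),
                "quantile_pct": round(h.quantile_pct, 1) if h.quantile_pct is not None else None,
                "low_dss_flag": m.dss_asym < LOW_DSS_FOOTNOTE_THRESHOLD,
                "in_class_support": h.in_class_support,
            }
        )
    waterfall = waterfall_order(
        [(m.drug_name or m.drug_id, m.dss_asym) for m in metrics]
    )
    report = {
        "sample_id": sample_id,
        "diagnosis": diagnosis,
        "qc": qc_summary,
        "n_drugs_evaluated": len(metrics),
        "n_hits": len(hits),
        "hits": hit_rows,
        "no_hits_statement": "no drug hits identified" if not hits else None,
        "waterfall": [{"drug": d, "dss_asym": round(v, 3)} for d, v in waterfall],
        "all_drugs": [
            {
                "drug_id": m.drug_id,
                "drug_name": m.drug_name or m.drug_id,
                "dss_asym": round(m.dss_asym, 3),
                "sdss": round(m.sdss, 3),
                "ic50_abs": m.ic50_abs,
                "inhibition_at_cmax": round(m.inhibition_at_cmax, 3),
                "max_effect": round(m.max_effect, 3),
                "r2": round(m.r2, 4),
                "cmax_outside_range": m.cmax_outside_range,
            }
            for m in sorted(metrics, key=lambda m: m.drug_id)
        ],
    }
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
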