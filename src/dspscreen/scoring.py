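"""Drug sensitivity scores: DSS, healthy-control-adjusted sDSS and
combination dcDSS.

DSS integrates the fitted inhibition curve above an activity threshold t
(default 10%) over the tested log10 concentration range and normalizes by
the maximal attainable area:

    DSS = 100 * integral max(min(y(x), 100) - t, 0) dx
              / ((100 - t) * (x_max - x_min))

so a flat 0% curve scores 0 and a flat 100% curve scores 100.  The
integrand is capped at 100% inhibition so scores stay on a 0-100 scale
even when the fitted upper asymptote overshoots.

sDSS subtracts the mean DSS of a healthy/nonmalignant control panel for
the same drug (negative values mark drugs more toxic to normal cells than
to the tumor).  dcDSS is the DSS of a drug in the presence of a fixed
anchor (dispensed at the anchor's own IC25) minus its monotherapy DSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .curves import ConcRange, CurveFit, invert_icx
from .errors import ScoringError

DEFAULT_DSS_THRESHOLD = 10.0


@dataclass
class DrugMetrics:
    """All per-drug readouts for one sample screen."""

    drug_id: str
    dss_asym: float
    sdss: float
    inhibition_at_cmax: float
    ic50_abs: float | None
    max_effect: float
    r2: float
    cmax_outside_range: bool = False
    sdss_unadjusted: bool = False
    max_effect_observed: float | None = None
    drug_name: str | None = None


@dataclass
class ControlPanel:
    """Per-drug DSS values from healthy bone-marrow / nonmalignant controls."""

    entries: dict[str, list[float]] = field(default_factory=dict)

    def values_for(self, drug_id: str) -> list[float]:
        return self.entries.get(drug_id, [])

    def mean_for(self, drug_id: str) -> float | None:
        vals = self.values_for(drug_id)
        return float(np.mean(vals)) if vals else None

    def median_for(self, drug_id: str) -> float | None:
        vals = self.values_for(drug_id)
        return float(np.median(vals)) if vals else None


@dataclass
class CombinationMetrics:
    drug_id: str
    anchor_drug_id: str
    anchor_conc: float
    dss_mono: float
    dss_combo: float
    dcdss: float
    drug_name: str | None = None


def _clipped_excess(fit: CurveFit, x: np.ndarray | float, threshold: float):
    y = fit.predict_log10(x)
    return np.clip(y, threshold, 100.0) - threshold


def _level_crossing_log10(fit: CurveFit, level: float) -> float | None:
    """log10 concentration where the fitted curve equals ``level``, if the
    level lies strictly between the asymptotes."""
    span = fit.y_max - fit.y_min
    if span <= 0 or not fit.y_min < level < fit.y_max:
        return None
    a = ((level - fit.y_min) / span) ** (-1.0 / fit.asym) - 1.0
    if a <= 0:
        return None
    return fit.log10_ec50 - float(np.log10(a)) / fit.slope


def dss_asym(fit: CurveFit, conc_range: ConcRange,
             threshold_t: float = DEFAULT_DSS_THRESHOLD) -> float:
    """Normalized area of the fitted inhibition curve above threshold t."""
    if not 0 <= threshold_t < 100:
        raise ScoringError(f"threshold must lie in [0, 100), got {threshold_t}")
    x_min, x_max = conc_range.x_min, conc_range.x_max  # ConcRange rejects x_max <= x_min
    # split the quadrature at the t / 100% crossings, where the integrand kinks
    pts = []
    for level in (threshold_t, 100.0):
        xc = _level_crossing_log10(fit, level)
        if xc is not None and x_min < xc < x_max:
            pts.append(xc)
    area, _ = quad(lambda x: _clipped_excess(fit, x, threshold_t), x_min, x_max,
                   points=sorted(pts) or None, limit=200, epsabs=1e-10, epsrel=1e-10)
    return 100.0 * area / ((100.0 - threshold_t) * (x_max - x_min))


def adjusted_dss(dss: float, panel: ControlPanel, drug_id: str,
                 aggregate: str = "mean") -> tuple[float, bool]:
    """sDSS = DSS minus the control-panel aggregate for the drug.

    Returns (sdss, unadjusted_flag); drugs without panel data pass through
    unchanged with the flag set.
    """
    agg = panel.mean_for(drug_id) if aggregate == "mean" else panel.median_for(drug_id)
    if agg is None:
        return dss, True
    return dss - agg, False


def dcdss(mono_fit: CurveFit, combo_fit: CurveFit, conc_range: ConcRange,
          anchor_drug_id: str, anchor_conc: float, drug_id: str,
          threshold_t: float = DEFAULT_DSS_THRESHOLD) -> CombinationMetrics:
    """Differential combination DSS over the drug's monotherapy range."""
    mono = dss_asym(mono_fit, conc_range, threshold_t)
    combo = dss_asym(combo_fit, conc_range, threshold_t)
    return CombinationMetrics(
        drug_id=drug_id,
        anchor_drug_id=anchor_drug_id,
        anchor_conc=anchor_conc,
        dss_mono=mono,
        dss_combo=combo,
        dcdss=combo - mono,
    )


def anchor_concentration(anchor_fit: CurveFit, conc_range: ConcRange,
                         x_pct: float = 25.0) -> float:
    """The anchor drug's ICx (default IC25) from its monotherapy curve."""
    conc = invert_icx(anchor_fit, x_pct, conc_range)
    if conc is None:
        raise ScoringError(
            f"anchor IC{x_pct:g} unreachable: monotherapy curve never reaches "
            f"{x_pct:g}% inhibition within the tested range"
        )
    return conc


def compute_drug_metrics(
    fit: CurveFit,
    conc_range: ConcRange,
    cmax: float,
    panel: ControlPanel | None = None,
    drug_id: str = "",
    drug_name: str | None = None,
    threshold_t: float = DEFAULT_DSS_THRESHOLD,
    max_effect_observed: float | None = None,
) -> DrugMetrics:
    """Bundle DSS, sDSS, IC50, Cmax inhibition and max effect for one drug."""
    from .curves import max_effect as _max_effect, predict_inhibition

    dss = dss_asym(fit, conc_range, threshold_t)
    if panel is not None and drug_id:
        sdss, unadj = adjusted_dss(dss, panel, drug_id)
    else:
        sdss, unadj = dss, True
    fitted_max, _ = _max_effect(fit, conc_range=conc_range)
    cmax_log10 = float(np.log10(cmax))
    return DrugMetrics(
        drug_id=drug_id,
        dss_asym=dss,
        sdss=sdss,
        inhibition_at_cmax=predict_inhibition(fit, cmax),
        ic50_abs=invert_icx(fit, 50.0, conc_range),
        max_effect=fitted_max,
        r2=fit.r2,
        cmax_outside_range=not conc_range.x_min <= cmax_log10 <= conc_range.x_max,
        sdss_unadjusted=unadj,
        max_effect_observed=max_effect_observed,
        drug_name=drug_name,
    )
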