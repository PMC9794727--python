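"""Asymmetric logistic dose-response fitting.

The response model is the five-parameter asymmetric logistic (5PL) on the
log10 concentration axis,

    y(x) = y_min + (y_max - y_min) / (1 + 10^(slope * (log10_ec50 - x)))^asym

with slope > 0 (inhibition grows with dose) and asymmetry exponent
asym > 0; asym = 1 recovers the familiar symmetric 4PL.  Fits are
least-squares over all replicate points with box bounds and deterministic
multi-start initialization; goodness of fit is R^2 against the replicate
points themselves.

Derived per-drug quantities: predicted inhibition at any concentration
(e.g. the clinical Cmax), absolute ICx by closed-form inversion of the
model, and the maximal fitted effect over the tested range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import FitError
from .model import N_CONCENTRATIONS
from .qc import NormalizedPlate
from .model import PlateLayout, WellRole

LN10 = math.log(10.0)

# box bounds for (y_min, y_max, log10_ec50, slope, asym); log10_ec50 bounds
# are range-dependent and filled in at fit time
YMIN_BOUNDS = (-30.0, 30.0)
YMAX_BOUNDS = (0.0, 120.0)
SLOPE_BOUNDS = (0.1, 10.0)
ASYM_BOUNDS = (0.2, 5.0)
EC50_MARGIN_DECADES = 2.0

#: replicate-point spread below which data are treated as exactly flat
_FLAT_TOL = 1e-9


@dataclass(frozen=True)
class ConcRange:
    """log10 molar bounds of a drug's tested concentration range."""

    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        if not self.x_max > self.x_min:
            raise FitError(f"degenerate concentration range [{self.x_min}, {self.x_max}]")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min


@dataclass
class DoseResponsePoints:
    """Replicate (log10 concentration, inhibition) points for one drug."""

    drug_id: str
    log10_conc: np.ndarray        # one entry per replicate point
    inhibition: np.ndarray
    replicate_index: np.ndarray
    plate_ids: list[str]
    conc_means: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        order = np.lexsort((self.replicate_index, self.log10_conc))
        self.log10_conc = np.asarray(self.log10_conc, dtype=float)[order]
        self.inhibition = np.asarray(self.inhibition, dtype=float)[order]
        self.replicate_index = np.asarray(self.replicate_index, dtype=int)[order]
        self.plate_ids = [self.plate_ids[i] for i in order]
        self.conc_means = {
            float(x): float(self.inhibition[self.log10_conc == x].mean())
            for x in np.unique(self.log10_conc)
        }

    @property
    def n_distinct_concentrations(self) -> int:
        return len(self.conc_means)

    @property
    def conc_range(self) -> ConcRange:
        return ConcRange(float(self.log10_conc.min()), float(self.log10_conc.max()))


@dataclass(frozen=True)
class CurveFit:
    """Fitted asymmetric-logistic parameters for one sample x drug."""

    y_min: float
    y_max: float
    log10_ec50: float
    slope: float
    asym: float
    r2: float
    converged: bool
    n_points: int
    asym_fixed: bool = False

    def predict_log10(self, x: np.ndarray | float) -> np.ndarray | float:
        return _model(np.asarray(x, dtype=float), self.y_min, self.y_max,
                      self.log10_ec50, self.slope, self.asym)


def _model(x, y_min, y_max, log10_ec50, slope, asym):
    # overflow-safe: 10^(slope*(e-x)) can explode far below the EC50
    z = slope * (log10_ec50 - x) * LN10
    z = np.clip(z, -500.0, 500.0)
    return y_min + (y_max - y_min) * np.exp(-asym * np.log1p(np.exp(z)))


def _jacobian(x, y_min, y_max, log10_ec50, slope, asym):
    z = slope * (log10_ec50 - x) * LN10
    z = np.clip(z, -500.0, 500.0)
    ez = np.exp(z)
    log1p_ez = np.log1p(ez)
    u = np.exp(-asym * log1p_ez)            # (1 + 10^(b(e-x)))^(-s)
    span = y_max - y_min
    sig = ez / (1.0 + ez)                   # d log1p(e^z) / dz
    du_dz = -asym * u * sig
    J = np.empty((x.size, 5))
    J[:, 0] = 1.0 - u
    J[:, 1] = u
    J[:, 2] = span * du_dz * slope * LN10        # d/d log10_ec50
    J[:, 3] = span * du_dz * (log10_ec50 - x) * LN10  # d/d slope
    J[:, 4] = span * (-log1p_ez) * u             # d/d asym
    return J


def _model_b(x: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Model evaluated for a batch of parameter vectors: P (k,5) -> (k,n)."""
    return _model(x[None, :], P[:, 0:1], P[:, 1:2], P[:, 2:3], P[:, 3:4], P[:, 4:5])


def _jac_b(x: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Batched jacobian: (k, n, 5)."""
    y_min, y_max = P[:, 0:1], P[:, 1:2]
    e, b, s = P[:, 2:3], P[:, 3:4], P[:, 4:5]
    z = np.clip(b * (e - x[None, :]) * LN10, -500.0, 500.0)
    ez = np.exp(z)
    log1p_ez = np.log1p(ez)
    u = np.exp(-s * log1p_ez)
    span = y_max - y_min
    du_dz = -s * u * ez / (1.0 + ez)
    J = np.empty((P.shape[0], x.size, 5))
    J[:, :, 0] = 1.0 - u
    J[:, :, 1] = u
    J[:, :, 2] = span * du_dz * b * LN10
    J[:, :, 3] = span * du_dz * (e - x[None, :]) * LN10
    J[:, :, 4] = span * (-log1p_ez) * u
    return J


def _lm_fit_batch(
    x: np.ndarray,
    Y: np.ndarray,
    P0: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Levenberg-Marquardt with box projection, vectorized over problems.

    Solves ``min ||model(x; p) - Y_j||^2`` for every row j of ``Y``
    simultaneously; parameters whose lower and upper bound coincide are held
    fixed.  Problems that have converged are dropped from the working set so
    slow valley-followers do not pay for the whole batch.  Returns
    (P, cost, converged) with cost = 0.5 * SSE per problem.  All-numpy and
    deterministic.
    """
    k = P0.shape[0]
    P = np.clip(np.array(P0, dtype=float), lo, hi)
    free = (hi - lo) > 0  # (k,5); frozen parameters get zeroed jacobian columns
    R = _model_b(x, P) - Y
    cost = 0.5 * np.einsum("kn,kn->k", R, R)
    lam = np.full(k, 1e-3)
    done = np.zeros(k, dtype=bool)
    eye5 = np.eye(5)
    cost_floor = Y.shape[1] * 1e-22
    active = np.arange(k)
    for _ in range(max_iter):
        a = active
        J = _jac_b(x, P[a])
        J = np.where(free[a][:, None, :], J, 0.0)
        g = np.einsum("kni,kn->ki", J, R[a])
        H = np.einsum("kni,knj->kij", J, J)
        diag = np.einsum("kii->ki", H)
        A = H + lam[a][:, None, None] * (diag[:, :, None] * eye5) + 1e-12 * eye5
        try:
            delta = np.linalg.solve(A, -g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            A = A + 1e-8 * eye5
            delta = np.linalg.solve(A, -g[:, :, None])[:, :, 0]
        P_trial = np.clip(P[a] + delta, lo[a], hi[a])
        R_trial = _model_b(x, P_trial) - Y[a]
        cost_trial = 0.5 * np.einsum("kn,kn->k", R_trial, R_trial)
        improved = cost_trial < cost[a]
        rel_gain = np.where(improved, (cost[a] - cost_trial) / (cost[a] + 1e-300), 0.0)
        idx_imp = a[improved]
        P[idx_imp] = P_trial[improved]
        R[idx_imp] = R_trial[improved]
        cost[idx_imp] = cost_trial[improved]
        lam[a] = np.where(improved, np.maximum(lam[a] / 5.0, 1e-14),
                          np.minimum(lam[a] * 3.0, 1e14))
        finished = (improved & (rel_gain < 1e-15)) | (~improved & (lam[a] >= 1e10))
        finished |= cost[a] <= cost_floor
        done[a[finished]] = True
        active = a[~finished]
        if active.size == 0:
            break
    return P, cost, done


def assemble_dose_points(
    normalized_plates: list[NormalizedPlate],
    layouts: dict[str, PlateLayout],
    drug_id: str,
    concentrations: tuple[float, ...] | None = None,
    min_concentrations: int = 4,
) -> DoseResponsePoints:
    """Collect a drug's replicate inhibition values across QC-passing plates.

    ``concentrations`` maps conc_index -> molar value (the library row);
    required because layouts store indices, not molar values.
    """
    if concentrations is None:
        raise FitError("assemble_dose_points requires the drug's concentration grid")
    xs: list[float] = []
    ys: list[float] = []
    reps: list[int] = []
    plate_ids: list[str] = []
    for nplate in normalized_plates:
        if not nplate.qc.passed:
            continue
        layout = layouts[nplate.layout_ref]
        for a in layout.wells_by_role(WellRole.DRUG):
            if a.drug_id != drug_id or a.well not in nplate.inhibition:
                continue
            xs.append(math.log10(concentrations[a.conc_index]))  # type: ignore[index]
            ys.append(nplate.inhibition[a.well])
            reps.append(a.replicate_index)  # type: ignore[arg-type]
            plate_ids.append(nplate.plate_id)
    n_distinct = len(set(xs))
    if n_distinct < min_concentrations:
        raise FitError(
            f"drug {drug_id}: insufficient dose range "
            f"({n_distinct} distinct concentrations, need >= {min_concentrations})"
        )
    return DoseResponsePoints(
        drug_id=drug_id,
        log10_conc=np.array(xs),
        inhibition=np.array(ys),
        replicate_index=np.array(reps),
        plate_ids=plate_ids,
    )


def _r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-12 else 0.0
    return 1.0 - ss_res / ss_tot


N_STARTS = 4


def _ec50_start_matrix(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Deterministic EC50 start candidates per problem row: the tested
    concentration whose mean response is nearest 50%, the range midpoint,
    and the midpoint shifted one decade either way.  Returns (m, 4)."""
    ux = np.unique(x)
    means = np.stack([Y[:, x == v].mean(axis=1) for v in ux], axis=1)  # (m, u)
    # tie on |mean-50| resolved toward the lower concentration
    score = np.abs(means - 50.0) + 1e-9 * np.arange(ux.size)[None, :]
    nearest50 = ux[np.argmin(score, axis=1)]
    mid = 0.5 * (x.min() + x.max())
    m = Y.shape[0]
    return np.stack(
        [nearest50, np.full(m, mid), np.full(m, mid - 1.0), np.full(m, mid + 1.0)],
        axis=1,
    )


def _fit_rows(x: np.ndarray, Y: np.ndarray, fix_asym: bool) -> np.ndarray:
    """Fit every row of Y to the asymmetric logistic; returns (m, 5) params.

    Multi-start (4 deterministic EC50 candidates per row) batched through
    the projected LM solver; per row the lowest SSE wins, ties broken by
    the asymmetry exponent closest to 1.
    """
    m, n = Y.shape
    ec50_lo = float(x.min()) - EC50_MARGIN_DECADES
    ec50_hi = float(x.max()) + EC50_MARGIN_DECADES
    lo = np.array([YMIN_BOUNDS[0], YMAX_BOUNDS[0], ec50_lo, SLOPE_BOUNDS[0], ASYM_BOUNDS[0]])
    hi = np.array([YMIN_BOUNDS[1], YMAX_BOUNDS[1], ec50_hi, SLOPE_BOUNDS[1], ASYM_BOUNDS[1]])
    if fix_asym:
        lo = lo.copy()
        hi = hi.copy()
        lo[4] = hi[4] = 1.0

    y_min0 = np.clip(Y.min(axis=1), *YMIN_BOUNDS)
    y_max0 = np.clip(Y.max(axis=1), *YMAX_BOUNDS)
    y_max0 = np.where(y_max0 <= y_min0 + 1.0,
                      np.minimum(y_min0 + 5.0, YMAX_BOUNDS[1]), y_max0)

    starts = np.clip(_ec50_start_matrix(x, Y), ec50_lo, ec50_hi)  # (m, 4)
    K = m * N_STARTS
    P0 = np.empty((K, 5))
    P0[:, 0] = np.repeat(y_min0, N_STARTS)
    P0[:, 1] = np.repeat(y_max0, N_STARTS)
    P0[:, 2] = starts.reshape(-1)
    P0[:, 3] = 1.0
    P0[:, 4] = 1.0
    Yrep = np.repeat(Y, N_STARTS, axis=0)
    P, cost, _ = _lm_fit_batch(
        x, Yrep, P0, np.broadcast_to(lo, (K, 5)), np.broadcast_to(hi, (K, 5))
    )
    P = P.reshape(m, N_STARTS, 5)
    cost = cost.reshape(m, N_STARTS)
    out = np.empty((m, 5))
    for i in range(m):
        order = np.lexsort((np.abs(P[i, :, 4] - 1.0), np.round(cost[i], 10)))
        out[i] = P[i, order[0]]
    return out


def _flat_fit(y: np.ndarray, x: np.ndarray) -> CurveFit:
    level = float(y.mean())
    return CurveFit(
        y_min=level, y_max=level, log10_ec50=float(x.mean()),
        slope=1.0, asym=1.0, r2=1.0, converged=True, n_points=int(y.size),
        asym_fixed=True,
    )


def _params_to_fit(p: np.ndarray, x: np.ndarray, y: np.ndarray,
                   fix_asym: bool, drug_id: str) -> CurveFit:
    if not np.all(np.isfinite(p)):
        raise FitError(f"drug {drug_id}: curve fit did not converge")
    y_hat = np.asarray(_model(x, *p))
    return CurveFit(
        y_min=float(min(p[0], p[1])), y_max=float(max(p[0], p[1])),
        log10_ec50=float(p[2]), slope=float(p[3]), asym=float(p[4]),
        r2=_r2(y, y_hat),
        converged=True, n_points=int(x.size),
        asym_fixed=bool(fix_asym),
    )


def fit_asym_logistic(points: DoseResponsePoints, fix_asym: bool | None = None) -> CurveFit:
    """Bounded least-squares 5PL fit with deterministic multi-start.

    Flat data (zero spread) short-circuit to a degenerate constant fit with
    R^2 = 1 by convention.  With only four distinct concentrations the
    asymmetry exponent is fixed at 1 (symmetric 4PL) and flagged.
    """
    x = points.log10_conc
    y = points.inhibition
    if x.size == 0:
        raise FitError(f"drug {points.drug_id}: no points to fit")
    if float(y.max() - y.min()) <= _FLAT_TOL:
        return _flat_fit(y, x)
    if fix_asym is None:
        fix_asym = points.n_distinct_concentrations <= 4
    p = _fit_rows(x, y[None, :], fix_asym)[0]
    return _params_to_fit(p, x, y, fix_asym, points.drug_id)


def fit_asym_logistic_many(points_list: list[DoseResponsePoints]) -> dict[str, CurveFit]:
    """Fit many drugs at once, batching those that share a concentration/
    replicate grid through one vectorized solve.  Results are identical to
    calling :func:`fit_asym_logistic` per drug."""
    results: dict[str, CurveFit] = {}
    groups: dict[tuple, list[DoseResponsePoints]] = {}
    for pts in points_list:
        if pts.log10_conc.size == 0:
            raise FitError(f"drug {pts.drug_id}: no points to fit")
        if float(pts.inhibition.max() - pts.inhibition.min()) <= _FLAT_TOL:
            results[pts.drug_id] = _flat_fit(pts.inhibition, pts.log10_conc)
            continue
        fix = pts.n_distinct_concentrations <= 4
        groups.setdefault((pts.log10_conc.tobytes(), fix), []).append(pts)
    for (_, fix), grp in groups.items():
        x = grp[0].log10_conc
        Y = np.stack([g.inhibition for g in grp])
        P = _fit_rows(x, Y, fix)
        for g, p in zip(grp, P):
            results[g.drug_id] = _params_to_fit(p, x, g.inhibition, fix, g.drug_id)
    return results


def predict_inhibition(fit: CurveFit, conc: float) -> float:
    """Fitted inhibition (percent) at a molar concentration; extrapolates
    freely outside the tested range."""
    if conc <= 0:
        raise FitError(f"concentration must be positive, got {conc}")
    return float(fit.predict_log10(math.log10(conc)))


def invert_icx(fit: CurveFit, x_pct: float, conc_range: ConcRange) -> float | None:
    """Absolute ICx: the molar concentration inside the tested range where
    the fitted curve crosses ``x_pct`` percent inhibition; None if the curve
    never reaches it there.  Closed-form inversion of the logistic model.

    A curve sitting above ``x_pct`` over the whole tested range attains the
    target below the lowest tested concentration; the lowest tested
    concentration is returned as the (censored) ICx in that case.
    """
    if not 0 < x_pct < 100:
        raise FitError(f"x_pct must lie strictly between 0 and 100, got {x_pct}")
    span = fit.y_max - fit.y_min
    if span <= 0:  # flat curve
        return 10.0 ** conc_range.x_min if fit.y_max >= x_pct else None
    frac = (x_pct - fit.y_min) / span
    if frac <= 0:  # lower asymptote already above x_pct
        return 10.0 ** conc_range.x_min
    if frac >= 1:  # upper asymptote below x_pct: never reached
        return None
    a = frac ** (-1.0 / fit.asym) - 1.0
    if a <= 0:
        return None
    x = fit.log10_ec50 - math.log10(a) / fit.slope
    if x > conc_range.x_max + 1e-9:  # not reached within the tested range
        return None
    if x < conc_range.x_min:  # attained below the range: censor at the floor
        return 10.0 ** conc_range.x_min
    return 10.0 ** x


def max_effect(fit: CurveFit, points: DoseResponsePoints | None = None,
               conc_range: ConcRange | None = None) -> tuple[float, float | None]:
    """Maximal fitted inhibition over the tested range (the value at the top
    concentration for this monotone model), paired with the maximal observed
    per-concentration mean when points are given."""
    if conc_range is None:
        if points is None:
            raise FitError("max_effect needs points or an explicit range")
        conc_range = points.conc_range
    fitted = float(fit.predict_log10(conc_range.x_max))
    observed = max(points.conc_means.values()) if points is not None else None
    return fitted, observed
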