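import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dspscreen import (
    SimConfig,
    build_layouts,
    control_panel_from_truth,
    sample_ground_truth,
    simulate_raw_plates,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Reduced screen (12 drugs, 6 samples) for fast structural tests."""
    return SimConfig(n_drugs=12, n_samples=6, planted_hits_per_sample=2,
                     n_control_samples=3, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return sample_ground_truth(small_config)


@pytest.fixture(scope="session")
def small_layouts(small_config, small_truth):
    return build_layouts(small_config, small_truth.library)


@pytest.fixture(scope="session")
def small_plates(small_truth, small_layouts):
    plates, _ = simulate_raw_plates(small_truth, "s001", layouts=small_layouts)
    return plates


@pytest.fixture(scope="session")
def small_panel(small_truth):
    return control_panel_from_truth(small_truth)


# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementation paths they check)

def trapezoid_dss(fit, x_min: float, x_max: float, threshold: float,
                  n_grid: int = 100_000) -> float:
    """Dense-grid trapezoid evaluation of the DSS integral."""
    x = np.linspace(x_min, x_max, n_grid)
    y = np.clip(np.asarray(fit.predict_log10(x)), threshold, 100.0) - threshold
    area = np.trapezoid(y, x)
    return 100.0 * area / ((100.0 - threshold) * (x_max - x_min))


def bisect_icx(fit, target: float, x_min: float, x_max: float,
               tol: float = 1e-12) -> float | None:
    """Bisection for the log10 concentration where the monotone fitted curve
    crosses ``target``; None when no crossing exists inside the range."""
    f_lo = float(fit.predict_log10(x_min)) - target
    f_hi = float(fit.predict_log10(x_max)) - target
    if f_lo > 0:  # already above target at the lowest dose
        return 10.0 ** x_min
    if f_hi < 0:
        return None
    a, b = x_min, x_max
    while b - a > tol:
        m = 0.5 * (a + b)
        if float(fit.predict_log10(m)) - target <= 0:
            a = m
        else:
            b = m
    return 10.0 ** (0.5 * (a + b))


def random_fit(rng: np.random.Generator, x_min: float = -9.0, x_max: float = -5.0):
    """A random plausible curve as a CurveFit (for oracle comparisons)."""
    from dspscreen import CurveFit

    return CurveFit(
        y_min=float(rng.uniform(-10.0, 10.0)),
        y_max=float(rng.uniform(20.0, 110.0)),
        log10_ec50=float(rng.uniform(x_min - 1.0, x_max + 1.0)),
        slope=float(rng.uniform(0.3, 4.0)),
        asym=float(rng.uniform(0.3, 3.0)),
        r2=1.0,
        converged=True,
        n_points=10,
    )
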