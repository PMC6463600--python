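import numpy as np
import pandas as pd
import pytest

from bbocox.simulate import CovariateSpec, GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def worked_cox_cohort() -> pd.DataFrame:
    """Four uncensored patients, one binary covariate; the partial-likelihood
    score has the closed-form root beta = ln((1 + sqrt(17)) / 2)."""
    return pd.DataFrame({
        "time": [1.0, 2.0, 3.0, 4.0],
        "event": [1, 1, 1, 1],
        "x": [1, 0, 1, 0],
    })


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One cohort from the default generator configuration (n = 1896,
    15 covariates, ~3.5% events)."""
    return generate_cohort(GeneratorConfig(seed=424242))


def planted_benchmark_config(seed: int, d: int = 10, n: int = 400,
                             n_active: int = 4,
                             log_hazard: float = 1.0) -> GeneratorConfig:
    """Well-powered planted-signal benchmark: d balanced covariates, the
    first ``n_active`` with log-hazard ``log_hazard``, half the cohort
    experiencing the event."""
    specs = tuple(
        CovariateSpec(f"x{j}", "high", "low", 0.5,
                      log_hazard if j < n_active else 0.0)
        for j in range(d)
    )
    return GeneratorConfig(n_patients=n, covariates=specs,
                           target_event_fraction=0.5, seed=seed)


@pytest.fixture(scope="session")
def planted_small_cohort() -> pd.DataFrame:
    """d = 6 planted benchmark cohort, small enough for exhaustive search."""
    return generate_cohort(planted_benchmark_config(seed=99, d=6, n=250))


def random_survival_fixture(rng: np.random.Generator, n: int):
    """Random times/events/risks with deliberate ties in all three."""
    time = rng.integers(1, max(3, n // 2), n).astype(float)
    event = rng.integers(0, 2, n)
    risk = rng.integers(-3, 4, n).astype(float)
    return time, event, risk


def brute_force_concordance(time, event, risk, mode="harrell"):
    """Independent oracle: direct double loop over all ordered pairs."""
    n = len(time)
    usable = conc = disc = tied = 0
    for i in range(n):
        for j in range(n):
            if i == j or time[i] >= time[j]:
                continue
            if event[i] != 1:
                continue
            usable += 1
            if risk[i] > risk[j]:
                conc += 1
            elif risk[i] < risk[j]:
                disc += 1
            else:
                tied += 1
    credit = conc + (0.5 * tied if mode == "harrell" else 0.0)
    c = credit / usable if usable else float("nan")
    return c, conc, disc, tied, usable
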