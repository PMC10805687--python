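import numpy as np
import pytest

from survrank.clinical_io import FeatureSpec, SurvivalTable
from survrank.synthetic import (
    Censoring,
    CohortSpec,
    generate,
    truncated_normal,
)


@pytest.fixture
def toy_table() -> SurvivalTable:
    """Six subjects, one binary covariate, all events observed."""
    feats = [FeatureSpec("treated", "binary", coding={"no": 0, "yes": 1})]
    X = {"treated": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]}
    return SurvivalTable(feats, X, [1.0, 3.0, 5.0, 2.0, 4.0, 6.0],
                         [1, 1, 1, 1, 1, 1])


def gaussian_cohort_spec(n, beta, seed, censoring_rate=0.02, p=None):
    """Standard-normal covariates with a Weibull PH outcome."""
    if p is None:
        p = max(len(beta), 2)
    marginals = tuple(
        truncated_normal(f"f{i}", 0.0, 1.0, -4.0, 4.0) for i in range(p)
    )
    return CohortSpec(
        n=n,
        marginals=marginals,
        beta={f"f{i}": b for i, b in enumerate(beta)},
        baseline_shape=1.2,
        baseline_scale=12.0,
        censoring=Censoring("exponential", censoring_rate),
        seed=seed,
    )


@pytest.fixture(scope="session")
def signal_table() -> SurvivalTable:
    """n=600 cohort with effect sizes (1.5, 0.75, 0, 0)."""
    return generate(gaussian_cohort_spec(600, [1.5, 0.75, 0.0, 0.0], seed=11))


@pytest.fixture(scope="session")
def null_table() -> SurvivalTable:
    """n=300 cohort whose survival is independent of every covariate."""
    return generate(gaussian_cohort_spec(300, [0.0, 0.0, 0.0, 0.0], seed=2,
                                         censoring_rate=0.03))


@pytest.fixture(scope="session")
def recovery_table() -> SurvivalTable:
    """n=2000 Weibull-PH cohort with beta = (1.0, -0.5), light censoring."""
    spec = gaussian_cohort_spec(2000, [1.0, -0.5], seed=3, censoring_rate=0.01)
    return generate(spec.with_(baseline_shape=1.5, baseline_scale=10.0))


def random_censored_fixture(rng, n=60, tied=False):
    """(time, event, risk) with continuous times; optionally a few exact ties."""
    t = rng.exponential(10.0, n) + 0.01
    if tied:
        dup = rng.integers(0, n, 3)
        t[dup] = t[rng.integers(0, n, 3)]
    e = (rng.random(n) < 0.7).astype(int)
    if e.sum() < 3:
        e[:3] = 1
    risk = rng.normal(size=n)
    return t, e, risk
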