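import numpy as np
import pandas as pd
import pytest

from dietcohort import CohortConfig, Law, generate_cohort


def mixed_config(seed: int = 42, scale: int = 1, **overrides) -> CohortConfig:
    """A small cohort with every archetype represented."""
    n = {
        "NonUser": 30 * scale,
        "NonActive": 25 * scale,
        "SemiActive": 20 * scale,
        "Active": 10 * scale,
        "ActiveImprover": 5 * scale,
        "ActiveDecliner": 5 * scale,
    }
    return CohortConfig(n_per_archetype=n, seed=seed, **overrides)


def no_interference_config(seed: int = 7, scale: int = 1) -> CohortConfig:
    """Archetype labels are exactly recoverable: the validity rule never
    fires (every picture has >= 10 ratings, no test first pictures)."""
    cfg = mixed_config(seed=seed, scale=scale)
    return CohortConfig(
        n_per_archetype=cfg.n_per_archetype,
        seed=seed,
        p_test_first_picture=0.0,
        rating_count=Law("poisson", 15.0, offset=10),
    )


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(mixed_config(seed=42))


@pytest.fixture(scope="session")
def clean_cohort():
    return generate_cohort(no_interference_config(seed=7))


@pytest.fixture()
def cohort_dir(tmp_path, small_cohort):
    from dietcohort import write_cohort

    d = tmp_path / "cohort"
    write_cohort(small_cohort, d)
    return d
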