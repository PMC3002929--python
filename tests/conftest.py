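import numpy as np
import pandas as pd
import pytest

from cghcompare import synthetic as syn
from cghcompare.core import AcghCohort, ProbeMap


@pytest.fixture(scope="session")
def small_map() -> ProbeMap:
    """Two 150 Mb chromosomes at 1 Mb probe spacing (300 probes)."""
    return syn.make_probe_map(
        {"1": 150_000_000, "2": 150_000_000}, spacing_bp=1_000_000, seed=11
    )


@pytest.fixture(scope="session")
def quad_map() -> ProbeMap:
    """Four 150 Mb chromosomes (600 probes), room for many segments."""
    lengths = {str(c): 150_000_000 for c in range(1, 5)}
    return syn.make_probe_map(lengths, spacing_bp=1_000_000, seed=12)


def make_two_group_cohort(
    probe_map: ProbeMap,
    segments=(),
    n_a: int = 20,
    n_b: int = 20,
    noise_sd: float = 0.2,
    seed: int = 0,
    tumor_fraction=(1.0, 1.0),
):
    spec = syn.CohortSpec(
        n_per_group={"A": n_a, "B": n_b},
        segments=segments,
        probe_noise_sd=noise_sd,
        tumor_fraction_range=tumor_fraction,
        seed=seed,
    )
    return syn.simulate_cohort(probe_map, spec)


@pytest.fixture()
def noise_cohort(small_map) -> AcghCohort:
    cohort, _ = make_two_group_cohort(small_map, n_a=10, n_b=10, seed=5)
    return cohort
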