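"""Shared fixtures: small deterministic datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gras2qtl.simulate import QTLEffect, SimConfig, simulate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


SMALL_CONFIG = SimConfig(
    n_individuals=80,
    n_linkage_groups=3,
    markers_per_group=10,
    marker_spacing=5.0,
    qtl_spec=(QTLEffect(2, 22.5, -7.19, -3.28),),
    flowering_qtl_spec=(QTLEffect(1, 12.5, -6.52, -0.03),),
    seed=5,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A 30-marker, 80-individual dataset: fast enough for most unit tests."""
    return simulate_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study-condition dataset (160 markers, 150 individuals)."""
    return simulate_dataset(SimConfig(seed=5))


def genotype_frame(rows: dict[str, str], individuals: list[str] | None = None):
    """Build a small call matrix from strings of genotype codes."""
    data = {m: list(s) for m, s in rows.items()}
    n = len(next(iter(data.values())))
    cols = individuals or [f"F2_{i + 1:03d}" for i in range(n)]
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)


def random_f2_codes(rng: np.random.Generator, n_markers: int, n_ind: int):
    """Null 1:2:1 co-dominant codes with no linkage."""
    draws = rng.choice(3, size=(n_markers, n_ind), p=[0.25, 0.5, 0.25])
    return pd.DataFrame(
        np.array(["B", "H", "A"])[draws],
        index=[f"M{i + 1:04d}" for i in range(n_markers)],
        columns=[f"F2_{j + 1:03d}" for j in range(n_ind)],
    )
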