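"""Shared fixtures: hand-built forests and seeded synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oct4lineage.lineage import build_forest
from oct4lineage.simulate import (
    GeneratorConfig,
    simulate_lineages,
    tiny_forest_table,
)

DEFAULT_SEED = 1


def make_track_df(cells: dict[str, tuple]) -> pd.DataFrame:
    """Build a track table from {cell_id: (parent, first_frame, levels)}."""
    rows = []
    for cid, (parent, f0, levels) in cells.items():
        for k, lvl in enumerate(levels):
            rows.append(
                {
                    "cell_id": cid,
                    "parent_id": parent or "",
                    "frame": f0 + k,
                    "time_min": (f0 + k) * 5.0,
                    "level_afu": float(lvl),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def tiny_forest():
    df, meta = tiny_forest_table()
    return build_forest(df), meta


@pytest.fixture(scope="session")
def undisturbed_dataset():
    """Default undisturbed synthetic run: 50 founders, 72 h, seed 1."""
    return simulate_lineages(GeneratorConfig(), 50, seed=DEFAULT_SEED, design="undisturbed")


@pytest.fixture(scope="session")
def undisturbed_forest(undisturbed_dataset):
    return undisturbed_dataset.forest()


@pytest.fixture(scope="session")
def stimulus_dataset():
    """Default differentiation synthetic run: 40 founders, 42 + 24 h, seed 1."""
    return simulate_lineages(GeneratorConfig(), 40, seed=DEFAULT_SEED, design="stimulus")


@pytest.fixture(scope="session")
def stimulus_forest(stimulus_dataset):
    return stimulus_dataset.forest()


@pytest.fixture(scope="session")
def aligned_pairs(undisturbed_forest):
    from oct4lineage.inheritance import align_mother_daughter

    return align_mother_daughter(undisturbed_forest)


@pytest.fixture()
def rng():
    return np.random.default_rng(DEFAULT_SEED)
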