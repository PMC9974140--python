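"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from phenonas import dataprep as dp
from phenonas import synthetic as syn


def load_dataset(root, n_plants, seed):
    """Generate a dataset on disk and return (rows, annotations)."""
    rows = syn.generate_dataset(root, n_plants, seed=seed)
    annotations = []
    for row in rows:
        label = syn.load_label_png(root / f"{row['image_id']}_label.png")
        annotations.append(
            dp.annotate_plant(
                row["image_id"],
                root / f"{row['image_id']}_rgb.png",
                label,
                row["genotype"],
                row["declared_leaf_count"],
            )
        )
    return rows, annotations


@pytest.fixture(scope="session")
def dataset50(tmp_path_factory):
    root = tmp_path_factory.mktemp("plants50")
    rows, annotations = load_dataset(root, 50, seed=123)
    return root, rows, annotations


@pytest.fixture(scope="session")
def arrays50(dataset50):
    _, _, annotations = dataset50
    return dp.build_training_arrays(annotations)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
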