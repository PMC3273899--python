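"""Shared fixtures: analytic meshes and a simulated study cohort.

The cohort fixture is session-scoped because full image simulation plus
feature extraction costs a few seconds per cell; every end-to-end test reads
from the same frozen-seed cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from laminaq.classification import PopulationDataset
from laminaq.features import FeatureParams, SegmentationFailure, compute_features
from laminaq.segmentation import SegmentationParams
from laminaq.synthetic import (
    PHENOTYPE_TEMPLATES,
    NucleusPhenotype,
    make_surface,
    simulate_population,
)

#: segmentation settings for the scaled-down synthetic nuclei (volumes 7-35 um^3)
SYNTH_SEG = SegmentationParams(min_volume_nm3=5e9)
SYNTH_FEATURES = FeatureParams(segmentation=SYNTH_SEG)


@pytest.fixture(scope="session")
def sphere_truth():
    return make_surface(NucleusPhenotype(semiaxes=(2000.0, 2000.0, 2000.0)), seed=1)


@pytest.fixture(scope="session")
def ellipsoid_truth():
    return make_surface(NucleusPhenotype(semiaxes=(2200.0, 1900.0, 1400.0)), seed=2)


@pytest.fixture(scope="session")
def sphere_mesh(sphere_truth):
    mesh, k = sphere_truth.to_mesh(subdivisions=5)
    return mesh, k


@pytest.fixture(scope="session")
def ellipsoid_mesh(ellipsoid_truth):
    mesh, k = ellipsoid_truth.to_mesh(subdivisions=5)
    return mesh, k


@pytest.fixture(scope="session")
def cohort():
    """Simulated study cohort with features computed end to end.

    fresh n=14, senescent n=31, apoptotic n=14, plus 2 apoptotic-template
    cells planted into the senescent cohort (cell_id prefix ``planted``);
    mirrors a senescent population of 33 carrying ~6% apoptotic-like cells.
    Returns (DataFrame, n_segmentation_failures, n_cells_total).
    """
    rows, n_fail = [], 0

    def harvest(cells, label_override=None, prefix=""):
        nonlocal n_fail
        for i, (stack, truth) in enumerate(cells):
            label = label_override or truth.label
            try:
                f = compute_features(
                    stack, SYNTH_FEATURES, cell_id=f"{prefix}{label}_{i:02d}", label=label
                )
                rows.append(f.as_dict())
            except SegmentationFailure:
                n_fail += 1

    harvest(simulate_population(PHENOTYPE_TEMPLATES, n_per_label=14, jitter=0.1, seed=101))
    harvest(
        simulate_population(
            {"senescent": PHENOTYPE_TEMPLATES["senescent"]}, n_per_label=17, jitter=0.1, seed=202
        )
    )
    harvest(
        simulate_population(
            {"apoptotic": PHENOTYPE_TEMPLATES["apoptotic"]}, n_per_label=2, jitter=0.1, seed=303
        ),
        label_override="senescent",
        prefix="planted_",
    )
    df = pd.DataFrame(rows)
    return df, n_fail, len(rows) + n_fail


@pytest.fixture(scope="session")
def fresh_vs_senescent(cohort):
    """Two-population dataset: fresh vs true (unplanted) senescent cells."""
    df, _, _ = cohort
    sub = df[
        (df.label == "fresh")
        | ((df.label == "senescent") & ~df.cell_id.str.startswith("planted"))
    ]
    return PopulationDataset(sub.reset_index(drop=True), ("intensity", "skewness", "curvature"))
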