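"""Shared fixtures: mesh hierarchy, synthetic study cohort, trained models.

Expensive objects (the 40,962-node mesh and its sampling map, the trained
reference model on the synthetic cohort) are session-scoped so the shape
tests, the transfer-learning test and the saliency test reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.model_selection import train_test_split

from spherecnn.icosphere import base_icosahedron, subdivide
from spherecnn.network import ModelSpec, TrainConfig, build_model, evaluate, train
from spherecnn.synthetic_data import CohortSpec, generate_cohort

# Reference study conditions for the synthetic experiments: 200 subjects per
# class on the 642-node mesh, one 0.5 rad effect region with a 0.3 mm class
# shift, 0.1 mm correlated noise.
STUDY_SEED = 42


@pytest.fixture(scope="session")
def hierarchy():
    """Icosphere levels 0..6 built by successive subdivision."""
    meshes = [base_icosahedron()]
    for _ in range(6):
        meshes.append(subdivide(meshes[-1]))
    return meshes


@pytest.fixture(scope="session")
def full_model(hierarchy):
    """The default five-complex model on the 40,962-node input mesh."""
    meshes = list(reversed(hierarchy[1:7]))  # levels 6 .. 1
    return build_model(ModelSpec(), meshes=meshes)


@pytest.fixture(scope="session")
def study_cohort():
    """The reference synthetic cohort with a stratified test split."""
    cohort = generate_cohort(CohortSpec(seed=STUDY_SEED))
    X = cohort.network_inputs()
    idx = np.arange(cohort.n_subjects)
    tv, te = train_test_split(
        idx, test_size=40, stratify=cohort.y, random_state=0
    )
    return {
        "cohort": cohort,
        "X": X,
        "y": cohort.y,
        "tv": tv,
        "test": te,
    }


def small_model_spec(level: int = 3, filters: int = 16, seed: int = 0) -> ModelSpec:
    """Level-3 analogue of the full architecture used for training tests."""
    return ModelSpec(
        input_level=level,
        n_complexes=level,
        filters_per_layer=(filters,) * level,
        seed=seed,
    )


@pytest.fixture(scope="session")
def trained_model(study_cohort):
    """One model trained on the reference cohort (train/val split of the
    train-validation pool), with its held-out test accuracy."""
    X, y = study_cohort["X"], study_cohort["y"]
    tv, te = study_cohort["tv"], study_cohort["test"]
    tr, va = train_test_split(tv, test_size=60, stratify=y[tv], random_state=1)
    model = build_model(small_model_spec())
    cfg = TrainConfig(seed=0, stop_patience=6)
    result = train(model, (X[tr], y[tr], X[va], y[va]), cfg)
    test_acc, _ = evaluate(model, X[te], y[te])
    return {"model": model, "result": result, "test_accuracy": test_acc}
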