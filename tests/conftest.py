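"""Shared fixtures: synthetic deployments and a trained patch classifier.

Everything is generated at test time from fixed seeds; the expensive
pieces (patch dataset, CNN training) are session-scoped so the whole
suite trains exactly once.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pytest

from trapscan import patch_classifier as pc
from trapscan import synthetic_fixtures as sf

TRAIN_SEED = 0
N_PER_CLASS = 600
N_TEST_PER_CLASS = 200
EPOCHS = 6


@pytest.fixture(scope="session")
def patch_tree(tmp_path_factory) -> Path:
    root = tmp_path_factory.mktemp("patches")
    sf.gen_patch_dataset(
        root, n_per_class=N_PER_CLASS, n_test_per_class=N_TEST_PER_CLASS, seed=TRAIN_SEED
    )
    return root


@pytest.fixture(scope="session")
def patch_data(patch_tree):
    xtr, ytr = pc.load_patch_dataset(patch_tree / "train")
    xte, yte = pc.load_patch_dataset(patch_tree / "test")
    return xtr, ytr, xte, yte


@pytest.fixture(scope="session")
def trained(patch_data):
    """(model, held-out accuracy) trained once for the whole session."""
    xtr, ytr, xte, yte = patch_data
    model, acc = pc.train(
        xtr, ytr, seed=TRAIN_SEED, epochs=EPOCHS, val_patches=xte, val_labels=yte
    )
    return model, acc


@pytest.fixture(scope="session")
def checkpoint(trained, tmp_path_factory) -> Path:
    path = tmp_path_factory.mktemp("ckpt") / "model.npz"
    pc.save_model(trained[0], path)
    return path


@pytest.fixture(scope="session")
def deployment(tmp_path_factory):
    """The 6-sequence demo deployment (2 animal, 1 human, 3 background)."""
    root = tmp_path_factory.mktemp("deployment") / "dep"
    manifest = sf.gen_deployment(root, sf.SceneConfig(seed=0))
    return root, manifest


@pytest.fixture(scope="session")
def static_deployment(tmp_path_factory):
    """One sequence of identical frames + sensor noise, no objects."""
    root = tmp_path_factory.mktemp("static") / "dep"
    plan = ({"cls": "none", "nuisance": "none", "night": False},)
    manifest = sf.gen_deployment(root, sf.SceneConfig(seed=5, plan=plan))
    return root, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def load_manifest(folder: Path) -> dict:
    return json.loads((Path(folder) / "manifest.json").read_text())
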