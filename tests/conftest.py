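"""Shared fixtures: every input is generated in code at test time."""

from __future__ import annotations

import numpy as np
import pytest

from foodvs.fixtures import (FixtureSpec, make_decoys,
                             make_feature_triad_ligands, make_toy_pocket,
                             make_training_ligands, triad_template)
from foodvs.pharmacophore import generate_common_feature_models


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    return FixtureSpec(seed=7, n_actives=12, n_decoys_per_active=3, noise=0.0)


@pytest.fixture(scope="session")
def template():
    return triad_template(seed=7)


@pytest.fixture(scope="session")
def triad_model(small_spec):
    train = make_training_ligands(small_spec, n=4)
    models = generate_common_feature_models(train, k_features=3)
    assert models, "triad model induction failed"
    return models[0]


@pytest.fixture(scope="session")
def actives(small_spec):
    return make_feature_triad_ligands(small_spec)


@pytest.fixture(scope="session")
def decoys(small_spec):
    return make_decoys(small_spec)


@pytest.fixture(scope="session")
def pocket_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("pocket") / "pocket.pdb"
    make_toy_pocket(path)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(20170310)
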