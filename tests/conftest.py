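"""Shared fixtures: small synthetic ensembles and a session-scoped model.

Everything is generated programmatically and seeded, so the suite needs no
stored data files.
"""

from __future__ import annotations

import numpy as np
import pytest

import ccsfocus as cf

#: Feature mask for synthetic fatty-acid studies: free fatty acids all have
#: exactly two heteroatoms (the carboxylate oxygens), so n_het is
#: zero-variance by construction and is dropped.
FA_MASK = ("mz", "d_het_max", "d_atom_max", "msa")


@pytest.fixture(scope="session")
def training_specs():
    return [
        cf.SyntheticSpec(18, (9,), n_conformers=100, seed=21),
        cf.SyntheticSpec(18, (), n_conformers=100, seed=22),
        cf.SyntheticSpec(20, (11, 14, 17), n_conformers=100, seed=23),
    ]


@pytest.fixture(scope="session")
def training_data(training_specs):
    """(features, labels) for a small multi-species synthetic training set."""
    feats, labels = [], []
    for spec in training_specs:
        ens = cf.generate_ensemble(spec)
        feats.extend(cf.featurize_ensemble(ens))
        labels.extend(c.label_ccs for c in ens)
    return feats, np.asarray(labels)


@pytest.fixture(scope="session")
def small_model(training_data):
    """A quick CCS regressor trained on the small synthetic set."""
    feats, labels = training_data
    config = cf.RegressorConfig(seed=5, feature_mask=FA_MASK, epochs=200)
    return cf.train(feats, labels, config)


@pytest.fixture(scope="session")
def query_ensemble():
    """A labelled, energy-annotated ensemble unseen by ``small_model``."""
    spec = cf.SyntheticSpec(18, (9,), n_conformers=150, seed=99)
    return cf.generate_ensemble(spec, assign_energies=True)


@pytest.fixture()
def methane():
    return cf.Conformer(
        "ch4",
        [
            cf.Atom("C", 0.0, 0.0, 0.0),
            cf.Atom("H", 0.629, 0.629, 0.629),
            cf.Atom("H", -0.629, -0.629, 0.629),
            cf.Atom("H", -0.629, 0.629, -0.629),
            cf.Atom("H", 0.629, -0.629, -0.629),
        ],
        formal_charge=0,
    )
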