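"""Shared fixtures: small synthetic meshes built once per session."""

import numpy as np
import pytest

from aneupoint import synthgeom as sg


@pytest.fixture(scope="session")
def default_params():
    return sg.ShapeParams()


@pytest.fixture(scope="session")
def fused_model(default_params):
    """Default aneurysm+vessel model (watertight, mm units)."""
    return sg.make_aneurysm_model(default_params)


@pytest.fixture(scope="session")
def straight_vessel(default_params):
    """Parametric straight tube, radius 1.5 mm, length 20 mm."""
    return sg.make_vessel(default_params)


@pytest.fixture(scope="session")
def curved_vessel():
    return sg.make_vessel(sg.ShapeParams(vessel_curvature=0.03))


@pytest.fixture(scope="session")
def branch_model():
    """Fused model carrying one 0.4 mm-radius side branch."""
    return sg.make_aneurysm_model(sg.ShapeParams(branch_radius=0.4))


def pair_counting_auc(scores, labels):
    """Exhaustive Mann-Whitney AUC oracle: wins + half-ties over all
    positive x negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))
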