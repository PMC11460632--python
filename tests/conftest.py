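"""Shared fixtures: topologies, dynamic models, ensembles and the pocket.

Everything is generated programmatically at test time; session scope keeps
the expensive objects (250-member ensembles, per-mode observable tables)
to one construction each.
"""

from __future__ import annotations

import pytest

from hyalodyn.conformer_builder import generate_ensemble
from hyalodyn.synthetic_data import make_pocket_fixture
from hyalodyn.topologies import (
    dynamic_model_for,
    ha4_2aa_topology,
    ha6_2aa_topology,
)

#: Joint-mode occupancies of the measured codependent group.
TRUE_POPULATIONS = (0.35, 0.35, 0.22, 0.06, 0.02)


@pytest.fixture(scope="session")
def ha4_topology():
    return ha4_2aa_topology()


@pytest.fixture(scope="session")
def ha6_topology():
    return ha6_2aa_topology()


@pytest.fixture(scope="session")
def ha4_model(ha4_topology):
    return dynamic_model_for(ha4_topology)


@pytest.fixture(scope="session")
def ha6_model(ha6_topology):
    return dynamic_model_for(ha6_topology)


@pytest.fixture(scope="session")
def small_ensemble(ha4_model, ha4_topology):
    return generate_ensemble(ha4_model, ha4_topology, 50, seed=11)


@pytest.fixture(scope="session")
def docking_ensemble(ha6_model, ha6_topology):
    """The production-size ensemble (250 conformers) used for docking."""
    return generate_ensemble(ha6_model, ha6_topology, 250, seed=2024)


@pytest.fixture(scope="session")
def groove_pocket():
    pocket, _ = make_pocket_fixture("link_tsg6_groove")
    return pocket
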