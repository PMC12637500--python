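"""Shared fixtures: toy RNA references, planted-site ensembles and maps.

Everything is generated programmatically with frozen seeds; the larger
renders are session-scoped so several tests can share one build.
"""

import numpy as np
import pytest

from cryoshell.density_builder import DensityConfig, ensemble_to_map
from cryoshell.shell_mask import compute_shell
from cryoshell.synthetic_fixtures import (
    FixtureSpec,
    ground_truth_ensemble,
    make_clean_map,
    make_reference_map,
    make_solvent_ensemble,
    make_toy_rna,
)


@pytest.fixture(scope="session")
def ref12():
    return make_toy_rna(12, seed=1)


@pytest.fixture(scope="session")
def spec12():
    return FixtureSpec(n_residues=12, seed=1)


@pytest.fixture(scope="session")
def truth12(ref12, spec12):
    return ground_truth_ensemble(ref12, spec12)


@pytest.fixture(scope="session")
def clean12(ref12, spec12):
    """Noise-free map of the ground-truth ensemble (the expensive build)."""
    return make_clean_map(ref12, spec12)


@pytest.fixture(scope="session")
def refmap12(ref12, spec12, clean12):
    return make_reference_map(ref12, spec12, seed=1001, clean=clean12.total)


@pytest.fixture(scope="session")
def indepmap12(ref12, spec12, clean12):
    return make_reference_map(ref12, spec12, seed=1002, clean=clean12.total)


@pytest.fixture(scope="session")
def mask12(ref12, clean12):
    return compute_shell(ref12, clean12.total.lattice, excluded=())


@pytest.fixture(scope="session")
def density_cfg12(clean12):
    return DensityConfig(lattice=clean12.total.lattice)


@pytest.fixture(scope="session")
def ref4():
    return make_toy_rna(4, seed=7)


@pytest.fixture(scope="session")
def small_ensemble(ref4):
    spec = FixtureSpec(n_residues=4, n_models=5, seed=7)
    return make_solvent_ensemble(ref4, spec)


@pytest.fixture(scope="session")
def small_maps(ref4, small_ensemble):
    return ensemble_to_map(small_ensemble, ref4)
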