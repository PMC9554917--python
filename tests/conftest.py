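"""Shared fixtures: all test systems are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from lipsite.core import AtomRecord, SegmentClass, Topology
from lipsite.synth import ToySystemSpec, build_toy_system


@pytest.fixture(scope="session")
def toy_system():
    """Default-sized membrane-protein-ligand system (shared, read-only)."""
    return build_toy_system(ToySystemSpec(seed=3))


@pytest.fixture(scope="session")
def small_system():
    """Small variant for fast per-test trajectories."""
    return build_toy_system(
        ToySystemSpec(
            seed=11,
            n_helices=3,
            beads_per_helix=6,
            n_lipids_per_leaflet=6,
            lipid_tail_length=4,
            n_waters=8,
            box=(48.0, 48.0, 56.0),
        )
    )


def make_atoms(specs):
    """Build a Topology from (name, element, charge, rmin_half, eps) tuples,
    one residue per atom, all protein class."""
    atoms = [
        AtomRecord(i, name, element, i, "RES", "A", SegmentClass.PROTEIN,
                   charge, rmin, eps)
        for i, (name, element, charge, rmin, eps) in enumerate(specs)
    ]
    return Topology(atoms=atoms)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
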