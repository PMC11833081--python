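"""Shared fixtures: hand-built miniature topologies and cached ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from loopscape.elements import is_hydrogen, mass_of
from loopscape.ensemble_io import AtomRecord, StructureEnsemble, Topology
from loopscape.synthetic import (
    SyntheticSpec,
    generate_binding_ensemble,
    generate_two_state_enzyme,
    two_pose_spec,
)


def make_topology(atom_spec):
    """Build a Topology from (chain, residue_number, element, name) tuples."""
    atoms = [
        AtomRecord(
            atom_index=i,
            atom_name=name,
            element=element,
            chain_id=chain,
            residue_number=resnum,
            residue_name="ALA",
            mass=mass_of(element),
            is_heavy=not is_hydrogen(element),
        )
        for i, (chain, resnum, element, name) in enumerate(atom_spec)
    ]
    return Topology(atoms=atoms)


def make_ensemble(atom_spec, frames):
    """StructureEnsemble from an atom spec and a list of coordinate frames."""
    return StructureEnsemble(
        topology=make_topology(atom_spec),
        coordinates=np.asarray(frames, dtype=float),
        frame_ids=np.arange(1, len(frames) + 1),
    )


@pytest.fixture(scope="session")
def two_state_ensemble():
    """Canonical two-state enzyme: f_open 0.25, n 2000, seed 42."""
    spec = SyntheticSpec(n_frames=2000, f_open=0.25, seed=42)
    return generate_two_state_enzyme(spec)


@pytest.fixture(scope="session")
def binding_ensemble():
    """Two-pose binding ensemble (0.7/0.3, 10 A apart, n 1000, seed 7)."""
    return generate_binding_ensemble(two_pose_spec())


@pytest.fixture(scope="session")
def binding_ensemble_loop_closed():
    """Same poses with the loop held closed, isolating the pose signal."""
    return generate_binding_ensemble(two_pose_spec(pose_open_fractions=(0.0, 0.0)))
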