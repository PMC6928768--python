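"""Shared fixtures: the symmetry group and seeded toy capsid families."""

import numpy as np
import pytest

from capsidhs.symmetry import generate_group
from capsidhs.synthetic import ToyFamilySpec, make_toy_family


@pytest.fixture(scope="session")
def icosa_group():
    return generate_group()


@pytest.fixture(scope="session")
def toy_family():
    """Default 4-member T=3 family with planted conservation structure."""
    spec = ToyFamilySpec(seed=1)
    members, truth = make_toy_family(spec)
    return spec, members, truth


@pytest.fixture(scope="session")
def toy_family_small():
    """A lighter single-chain family for I/O and CLI tests."""
    spec = ToyFamilySpec(
        n_members=2, t_number=1, residues_per_chain=14,
        planted_interface=frozenset({2, 5, 9}),
        planted_seq_conserved=frozenset({2, 9, 12}),
        planted_space_conserved=frozenset({2, 9}),
        seed=3,
    )
    members, truth = make_toy_family(spec)
    return spec, members, truth


def random_bead_subunits(rng, n_subunits=3, n_residues=8, box=25.0):
    """Random single-atom-bead subunits for contact-search property tests."""
    from capsidhs.structures import Atom, Residue, Subunit

    subs = []
    for si in range(n_subunits):
        residues = []
        for ri in range(n_residues):
            xyz = rng.uniform(-box, box, size=3)
            residues.append(Residue(
                chain_id=chr(65 + si), seq_number=ri + 1, res_name="ALA",
                atoms=[Atom(serial=ri + 1, name="CA", element="C", coords=xyz)],
            ))
        subs.append(Subunit(label=chr(65 + si), residues=residues))
    return subs
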