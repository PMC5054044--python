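"""Shared fixtures: small hand-built residues and an independent pairwise
energy oracle used to cross-check the surrogate backend and the protocol."""

from __future__ import annotations

import math

import numpy as np
import pytest

from pocketscan.structure import Atom, MolecularSystem, ResidueKey


def make_atom(serial, name, element, key, xyz, q=0, het=False):
    return Atom(serial, name, element, key, np.array(xyz, dtype=float),
                formal_charge=q, is_hetero=het)


@pytest.fixture
def leu_residue():
    """A leucine with full side chain (no CB hydrogens modelled)."""
    key = ResidueKey("A", 9, "", "LEU")
    atoms = [
        make_atom(1, "N", "N", key, [0, 1.4, 0]),
        make_atom(2, "CA", "C", key, [0, 0, 0]),
        make_atom(3, "C", "C", key, [1.3, -0.7, 0]),
        make_atom(4, "O", "O", key, [2.4, -0.2, 0]),
        make_atom(5, "CB", "C", key, [-1.2, -0.8, 0]),
        make_atom(6, "CG", "C", key, [-1.2, -2.3, 0]),
        make_atom(7, "HG", "H", key, [-0.5, -2.7, 0.7]),
        make_atom(8, "CD1", "C", key, [-2.6, -2.9, 0]),
        make_atom(9, "HD11", "H", key, [-2.6, -3.9, 0.3]),
        make_atom(10, "HD12", "H", key, [-3.0, -2.9, -1.0]),
        make_atom(11, "HD13", "H", key, [-3.2, -2.3, 0.7]),
        make_atom(12, "CD2", "C", key, [-0.4, -2.9, 1.1]),
        make_atom(13, "HD21", "H", key, [-0.4, -4.0, 1.0]),
        make_atom(14, "HD22", "H", key, [-0.9, -2.6, 2.0]),
        make_atom(15, "HD23", "H", key, [0.6, -2.5, 1.2]),
    ]
    return MolecularSystem("leu-fixture", atoms, 0), key


@pytest.fixture
def lys_residue():
    """A protonated lysine terminus (NZ+ with three hydrogens)."""
    key = ResidueKey("A", 23, "", "LYS")
    atoms = [
        make_atom(1, "CD", "C", key, [-1.5, 0, 0]),
        make_atom(2, "CE", "C", key, [0, 0, 0]),
        make_atom(3, "NZ", "N", key, [1.5, 0, 0], q=1),
        make_atom(4, "HZ1", "H", key, [2.0, 0.9, 0]),
        make_atom(5, "HZ2", "H", key, [2.0, -0.9, 0]),
        make_atom(6, "HZ3", "H", key, [1.6, 0, 1.0]),
    ]
    return MolecularSystem("lys-fixture", atoms, 1), key


@pytest.fixture
def oxo_substrate():
    """A minimal oxidized-guanine fragment carrying C8/O8/N7/H7."""
    key = ResidueKey("A", 1157, "", "8OG")
    atoms = [
        make_atom(1, "C8", "C", key, [0, 0, 0], het=True),
        make_atom(2, "O8", "O", key, [1.25, 0, 0], het=True),
        make_atom(3, "N7", "N", key, [-0.7, 1.1, 0], het=True),
        make_atom(4, "H7", "H", key, [-0.4, 2.0, 0], het=True),
        make_atom(5, "N9", "N", key, [-0.7, -1.1, 0], het=True),
    ]
    return MolecularSystem("8og-fixture", atoms, 0), key


# -- independent pairwise oracle ------------------------------------------
# Deliberately re-derived with scalar math: the tests that use it must not
# share code paths with pocketscan.backend.


def oracle_pair_energy(depth, r_eq, r, cutoff=None):
    if cutoff is not None and r > cutoff:
        return 0.0
    q = (r_eq / r) ** 6
    return depth * (2.0 * q - q * q)


def oracle_total_energy(system, params):
    """Plain double-loop sum over all atom pairs."""
    e = 0.0
    atoms = system.atoms
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            e += _oracle_terms(atoms[i], atoms[j], params)
            if params.coulomb_scale and atoms[i].formal_charge and atoms[j].formal_charge:
                r = math.dist(atoms[i].coords, atoms[j].coords)
                e += (332.0637 * params.coulomb_scale
                      * atoms[i].formal_charge * atoms[j].formal_charge / r)
    return e


def oracle_cross_energy(atoms_a, atoms_b, params):
    """Cross-interaction between two disjoint atom groups."""
    e = 0.0
    for a in atoms_a:
        for b in atoms_b:
            e += _oracle_terms(a, b, params)
            if params.coulomb_scale and a.formal_charge and b.formal_charge:
                r = math.dist(a.coords, b.coords)
                e += 332.0637 * params.coulomb_scale * a.formal_charge * b.formal_charge / r
    return e


def _oracle_terms(a, b, params):
    ca, cb = params.atom_class(a), params.atom_class(b)
    key = (ca, cb) if ca <= cb else (cb, ca)
    e = 0.0
    r = math.dist(a.coords, b.coords)
    for table in (params.pair_terms, params.hbond_terms):
        if key in table:
            depth, r_eq = table[key]
            e += oracle_pair_energy(depth, r_eq, r, params.cutoff)
    return e
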