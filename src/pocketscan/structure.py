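"""Molecular structure model, PDB I/O, atom selection and geometry measures.

Coordinates are in Angstroms throughout, in the crystal frame of the source
PDB file.  Serials are 1-based and preserved on load; residue numbering and
insertion codes are honoured.  Formal charges are never inferred from the
structure -- they are supplied externally through a charge map.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "MolecularSystem",
    "RegionSelection",
    "ResidueKey",
    "load_system",
    "write_system",
    "select_region",
    "select_region_by_coords",
    "rmsd",
    "min_distance",
]

WATER_NAMES = {"HOH", "WAT"}

#: Elements gemmi is allowed to guess from the atom name when the PDB file
#: carries no element column.
_VALID_ELEMENTS = {
    gemmi.Element(i).name.upper() for i in range(1, 104)
}


class ResidueKey(NamedTuple):
    """Identity of one residue: chain, number, insertion code, name."""

    chain: str
    seqid: int
    icode: str
    resname: str


@dataclass
class Atom:
    """A single atom with PDB-style identity and a formal point charge."""

    serial: int
    name: str
    element: str
    residue_key: ResidueKey
    coords: np.ndarray
    formal_charge: int = 0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.serial < 1:
            raise ValueError(f"serial must be positive, got {self.serial}")
        if self.element.upper() not in _VALID_ELEMENTS:
            raise ValueError(f"invalid element symbol {self.element!r}")

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class MolecularSystem:
    """An ordered collection of atoms forming one model system.

    ``net_charge`` always equals the sum of the atoms' formal charges; the
    constructor enforces this, so operators that change charges must keep
    the two in step.
    """

    label: str
    atoms: list[Atom]
    net_charge: int = 0
    provenance: str = ""

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(serials) != len(set(serials)):
            raise ValueError(f"duplicate atom serials in system {self.label!r}")
        total = sum(a.formal_charge for a in self.atoms)
        if total != self.net_charge:
            raise ValueError(
                f"net_charge {self.net_charge} != sum of formal charges {total}"
            )

    # -- lookups ---------------------------------------------------------

    @property
    def waters(self) -> set[ResidueKey]:
        return {a.residue_key for a in self.atoms if a.residue_key.resname in WATER_NAMES}

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def residue_keys(self) -> list[ResidueKey]:
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)

    def residue_atoms(self, key: ResidueKey) -> list[Atom]:
        found = [a for a in self.atoms if a.residue_key == key]
        if not found:
            raise KeyError(f"residue {key} not in system {self.label!r}")
        return found

    def atom(self, key: ResidueKey, name: str) -> Atom:
        for a in self.atoms:
            if a.residue_key == key and a.name == name:
                return a
        raise KeyError(f"atom {name!r} of residue {key} not found")

    def by_serial(self, serial: int) -> Atom:
        for a in self.atoms:
            if a.serial == serial:
                return a
        raise KeyError(f"serial {serial} not found")

    def copy(self, label: str | None = None) -> "MolecularSystem":
        return MolecularSystem(
            label=self.label if label is None else label,
            atoms=[a.copy() for a in self.atoms],
            net_charge=self.net_charge,
            provenance=self.provenance,
        )


@dataclass
class RegionSelection:
    """Atom-granular selection around an anchor (distance-cutoff pocket)."""

    atom_ids: set[int]
    cutoff: float
    anchor_residue: ResidueKey | None = None

    def to_serial_list(self) -> str:
        """Whitespace-separated serial list, for frozen-atom masks."""
        return " ".join(str(s) for s in sorted(self.atom_ids))


# -- PDB I/O ---------------------------------------------------------------


def load_system(
    path: str | os.PathLike,
    charge_map: Mapping | None = None,
    label: str | None = None,
) -> MolecularSystem:
    """Read a (pre-hydrogenated) PDB file into a :class:`MolecularSystem`.

    ``charge_map`` assigns integer formal charges to residues; keys may be
    full :class:`ResidueKey` tuples, ``(chain, seqid)`` pairs, or bare
    residue-name strings (applied to every matching residue).  The charge is
    attached to the first atom of each matched residue, and the system net
    charge is their sum.  A key that matches no residue is an error.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    atoms: list[Atom] = []
    if len(st) == 0:
        raise ValueError(f"zero atoms in {path}")
    model = st[0]
    for chain in model:
        for res in chain:
            key = ResidueKey(
                chain.name,
                res.seqid.num,
                res.seqid.icode.strip(),
                res.name,
            )
            for at in res:
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name,
                        residue_key=key,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        is_hetero=res.het_flag == "H",
                    )
                )
    if not atoms:
        raise ValueError(f"zero atoms in {path}")
    serials = [a.serial for a in atoms]
    if len(serials) != len(set(serials)):
        raise ValueError(f"duplicate atom serials in {path}")

    charge_map = dict(charge_map or {})
    residue_first: dict[ResidueKey, Atom] = {}
    for a in atoms:
        residue_first.setdefault(a.residue_key, a)
    for mkey, q in charge_map.items():
        matched = [
            k for k in residue_first
            if k == mkey
            or (isinstance(mkey, str) and k.resname == mkey)
            or (isinstance(mkey, tuple) and len(mkey) == 2 and (k.chain, k.seqid) == tuple(mkey))
        ]
        if not matched:
            raise KeyError(f"charge_map entry {mkey!r} matches no residue")
        for k in matched:
            residue_first[k].formal_charge += int(q)

    net = sum(a.formal_charge for a in atoms)
    return MolecularSystem(
        label=label or os.path.splitext(os.path.basename(path))[0],
        atoms=atoms,
        net_charge=net,
        provenance=f"loaded from {path}",
    )


def write_system(system: MolecularSystem, path: str | os.PathLike) -> None:
    """Write to PDB.  Round-trips names, serials, residues and coordinates
    to the format's 3-decimal precision."""
    if any(a.serial > 99999 for a in system.atoms):
        raise ValueError("serial overflow: PDB serial field is limited to 99999")
    st = gemmi.Structure()
    st.name = system.label
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    current: tuple[str, ResidueKey] | None = None
    for a in system.atoms:
        key = a.residue_key
        if key.chain not in chains:
            chains[key.chain] = gemmi.Chain(key.chain)
        chain = chains[key.chain]
        if current != (key.chain, key):
            res = gemmi.Residue()
            res.name = key.resname
            res.seqid = gemmi.SeqId(key.seqid, key.icode or " ")
            res.het_flag = "H" if a.is_hetero else "A"
            chain.add_residue(res)
            current = (key.chain, key)
        res = chain[-1]
        at = gemmi.Atom()
        at.name = a.name
        at.serial = a.serial
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.coords)
        res.add_atom(at)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    opts = gemmi.PdbWriteOptions()
    opts.preserve_serial = True
    opts.numbered_ter = False
    doc = st.make_pdb_string(opts)
    with open(path, "w") as fh:
        fh.write(doc)


# -- selection & geometry --------------------------------------------------


def select_region_by_coords(
    system: MolecularSystem, anchor_coords: np.ndarray, cutoff: float,
    anchor_residue: ResidueKey | None = None,
    whole_residues: bool = False,
) -> RegionSelection:
    """Atoms whose minimum distance to any anchor coordinate is <= cutoff.

    Used directly for apo systems where the pocket is defined around the
    recorded position of a departed ligand.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    anchor_coords = np.atleast_2d(np.asarray(anchor_coords, dtype=float))
    coords = system.coords_array()
    tree = cKDTree(anchor_coords)
    dmin, _ = tree.query(coords)
    ids = {a.serial for a, d in zip(system.atoms, dmin) if d <= cutoff}
    if whole_residues:
        hit_res = {a.residue_key for a in system.atoms if a.serial in ids}
        ids = {a.serial for a in system.atoms if a.residue_key in hit_res}
    return RegionSelection(atom_ids=ids, cutoff=cutoff, anchor_residue=anchor_residue)


def select_region(
    system: MolecularSystem, anchor: ResidueKey, cutoff: float,
    whole_residues: bool = False,
) -> RegionSelection:
    """All atoms within ``cutoff`` of any atom of the anchor residue.

    Atom-granular by default (an atom is in or out on its own distance);
    ``whole_residues=True`` expands each hit to its full residue, which the
    mutation-relaxation step uses.
    """
    anchor_atoms = system.residue_atoms(anchor)  # raises KeyError if absent
    anchor_coords = np.array([a.coords for a in anchor_atoms])
    sel = select_region_by_coords(
        system, anchor_coords, cutoff, anchor_residue=anchor,
        whole_residues=whole_residues,
    )
    return sel


def rmsd(
    reference: MolecularSystem,
    other: MolecularSystem,
    atom_ids: Iterable[int] | None = None,
) -> float:
    """Root-mean-square deviation over matched atoms, in Angstroms.

    Atoms are matched by (residue_key, atom name).  No re-superposition is
    performed: both geometries live in the shared crystal frame and the
    protocol restrains toward it, so a fit would hide exactly the drift
    being measured.
    """
    if atom_ids is None:
        ref_atoms = reference.atoms
    else:
        wanted = set(atom_ids)
        ref_atoms = [a for a in reference.atoms if a.serial in wanted]
        missing = wanted - {a.serial for a in ref_atoms}
        if missing:
            raise KeyError(f"atom ids {sorted(missing)} not in reference")
    if not ref_atoms:
        raise ValueError("empty atom selection for RMSD")
    other_index = {(a.residue_key, a.name): a for a in other.atoms}
    sq = 0.0
    for a in ref_atoms:
        mate = other_index.get((a.residue_key, a.name))
        if mate is None:
            raise KeyError(f"atom {(a.residue_key, a.name)} unmatched in {other.label!r}")
        d = a.coords - mate.coords
        sq += float(d @ d)
    return float(np.sqrt(sq / len(ref_atoms)))


def min_distance(
    system: MolecularSystem,
    key_a: tuple[ResidueKey, str],
    key_b: tuple[ResidueKey, str],
) -> float:
    """Euclidean distance between two named atoms, Angstroms."""
    a = system.atom(*key_a)
    b = system.atom(*key_b)
    return float(np.linalg.norm(a.coords - b.coords))
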