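"""Structural edit operators: the mutation set of the scanning protocol.

Every operator is deterministic (no randomness in hydrogen placement), is
charge-aware, and returns a :class:`MutationRecord` whose bookkeeping
(atoms removed / added, charge delta) exactly reproduces the change it made.
The operator set is intentionally closed: side-chain truncation to a methyl
group, excision of the lysine ammonium terminus, interconversion of the
oxidized and normal guanine substrates, substrate deletion under an explicit
charge policy, and water addition/removal.  General point mutation with
rotamer libraries is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .structure import Atom, MolecularSystem, ResidueKey

__all__ = [
    "MutationOperator",
    "ChargePolicy",
    "MutationRecord",
    "FragmentGeometry",
    "to_alanine",
    "lys_terminal_excision",
    "oxo_to_normal",
    "delete_substrate",
    "add_water",
    "delete_water",
    "transplant_fragment",
]

#: Standard C-H bond length used for every hydrogen this module places.
CH_BOND = 1.09
TETRAHEDRAL = np.deg2rad(109.471)

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HXT"}


class MutationOperator(str, Enum):
    TO_ALANINE = "to_alanine"
    LYS_TERMINAL_EXCISION = "lys_terminal_excision"
    OXO_TO_NORMAL = "oxo_to_normal"
    NORMAL_TO_OXO = "normal_to_oxo"
    ADD_WATER = "add_water"
    DELETE_WATER = "delete_water"
    DELETE_SUBSTRATE = "delete_substrate"
    IDENTITY = "identity"


class ChargePolicy(str, Enum):
    """Where the charge goes when the substrate leaves the binding site.

    ``ANIONIC_SUBSTRATE`` (default): the substrate departs with the formal
    charge modelled on it, and the guanine-site anion relocalizes onto the
    aspartate pair -- a -1 complex yields a neutral apo system.
    ``PROTON_RETAINED``: the ionizable proton stays on the aspartate, so the
    substrate departs doubly charged and the apo system keeps +1 (the lysine
    cation).  Used as the alternative apo reference for the two aspartates.
    """

    ANIONIC_SUBSTRATE = "anionic_substrate"
    PROTON_RETAINED = "proton_retained"


@dataclass
class MutationRecord:
    """Reproducible description of one structural edit."""

    operator: MutationOperator
    target: ResidueKey
    atoms_removed: list[tuple[ResidueKey, str]] = field(default_factory=list)
    atoms_added: list[Atom] = field(default_factory=list)
    charge_delta: int = 0
    fragment_geometry_id: str | None = None

    def to_line(self) -> str:
        t = self.target
        return "\t".join(
            [
                self.operator.value,
                f"{t.chain}/{t.seqid}{t.icode}/{t.resname}",
                str(len(self.atoms_removed)),
                str(len(self.atoms_added)),
                str(self.charge_delta),
                self.fragment_geometry_id or "-",
            ]
        )


@dataclass
class FragmentGeometry:
    """A rigid mutated-residue geometry, shared across one chain family."""

    fragment_id: str
    chain_family: str
    residue_key: ResidueKey
    atoms: list[Atom]  # may be empty (deleted-water fragment)

    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]


# -- internal helpers ------------------------------------------------------


def _next_serial(system: MolecularSystem) -> int:
    return max((a.serial for a in system.atoms), default=0) + 1


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("degenerate geometry: zero-length bond vector")
    return v / n


def _methyl_hydrogens(
    ca: np.ndarray, cb: np.ndarray, ref: np.ndarray, n_needed: int
) -> list[np.ndarray]:
    """Positions for up to three methyl hydrogens on CB.

    Tetrahedral about the CA->CB axis at 1.09 A, staggered with respect to
    the reference substituent on CA (the backbone nitrogen): azimuths 60,
    180 and 300 degrees from the N's azimuthal direction.  Fully
    deterministic.
    """
    axis = _unit(cb - ca)
    ref_dir = ref - ca
    perp = ref_dir - (ref_dir @ axis) * axis
    if np.linalg.norm(perp) < 1e-6:
        # reference collinear with the axis; fall back to an arbitrary but
        # deterministic perpendicular
        trial = np.array([1.0, 0.0, 0.0])
        if abs(trial @ axis) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        perp = trial - (trial @ axis) * axis
    e1 = _unit(perp)
    e2 = np.cross(axis, e1)
    out: list[np.ndarray] = []
    for k in range(n_needed):
        az = np.deg2rad(60.0 + 120.0 * k)  # staggered w.r.t. the reference
        direction = (
            np.cos(TETRAHEDRAL) * axis
            + np.sin(TETRAHEDRAL) * (np.cos(az) * e1 + np.sin(az) * e2)
        )
        out.append(cb + CH_BOND * direction)
    return out


def _attached_hydrogens(
    system: MolecularSystem, heavy: Atom, hbond_max: float = 1.3
) -> list[Atom]:
    """Hydrogens of the same residue within covalent range of a heavy atom."""
    out = []
    for a in system.residue_atoms(heavy.residue_key):
        if a.element == "H" and np.linalg.norm(a.coords - heavy.coords) <= hbond_max:
            out.append(a)
    return out


def _remove_and_add(
    system: MolecularSystem,
    remove: list[Atom],
    add: list[Atom],
    charge_delta: int,
    label_suffix: str,
) -> MolecularSystem:
    removed_ids = {id(a) for a in remove}
    atoms = [a.copy() for a in system.atoms if id(a) not in removed_ids]
    atoms.extend(a.copy() for a in add)
    return MolecularSystem(
        label=f"{system.label}{label_suffix}",
        atoms=atoms,
        net_charge=system.net_charge + charge_delta,
        provenance=system.provenance,
    )


# -- operators -------------------------------------------------------------


def to_alanine(
    system: MolecularSystem, target: ResidueKey
) -> tuple[MolecularSystem, MutationRecord]:
    """Truncate a side chain to a methyl group (in-silico alanine scan).

    All side-chain atoms beyond CB are removed, CB is retained, and the
    methyl is completed to exactly three hydrogens placed tetrahedrally at
    1.09 A, staggered about the CA-CB bond relative to the backbone N.  The
    backbone is untouched.  Any formal charge carried by a removed atom is
    cancelled, so the record's charge_delta keeps the net charge consistent.
    """
    res_atoms = system.residue_atoms(target)
    names = {a.name for a in res_atoms}
    if target.resname == "GLY":
        raise ValueError("cannot truncate Gly: no CB atom")
    if target.resname == "PRO":
        raise ValueError("cannot truncate Pro: side chain is part of the backbone ring")
    if target.resname == "ALA":
        raise ValueError(f"residue {target} is already alanine")
    if "CB" not in names or "CA" not in names or "N" not in names:
        raise ValueError(f"residue {target} lacks N/CA/CB; not a truncatable amino acid")

    ca = system.atom(target, "CA")
    cb = system.atom(target, "CB")
    n = system.atom(target, "N")
    keep = BACKBONE_NAMES | {"CB"}
    removed = [a for a in res_atoms if a.name not in keep and not a.name.startswith("HB")]
    existing_hb = [a for a in res_atoms if a.name.startswith("HB")]
    if not removed:
        raise ValueError(f"residue {target} has no side-chain atoms beyond CB")

    n_new = max(0, 3 - len(existing_hb))
    new_positions = _methyl_hydrogens(ca.coords, cb.coords, n.coords, n_new)
    serial = _next_serial(system)
    added = []
    for k, pos in enumerate(new_positions):
        added.append(
            Atom(
                serial=serial + k,
                name=f"HB{k + 1}",
                element="H",
                residue_key=target,
                coords=pos,
                is_hetero=cb.is_hetero,
            )
        )
    charge_delta = -sum(a.formal_charge for a in removed)
    mutated = _remove_and_add(system, removed, added, charge_delta, label_suffix="")
    record = MutationRecord(
        operator=MutationOperator.TO_ALANINE,
        target=target,
        atoms_removed=[(a.residue_key, a.name) for a in removed],
        atoms_added=[a.copy() for a in added],
        charge_delta=charge_delta,
    )
    return mutated, record


def lys_terminal_excision(
    system: MolecularSystem, target: ResidueKey
) -> tuple[MolecularSystem, MutationRecord]:
    """Replace the lysine terminal ammonium (-NH3+) with a hydrogen atom.

    The smallest edit that severs the salt bridge: NZ and its three
    hydrogens are removed and one hydrogen is placed on CE along the former
    CE->NZ direction at 1.09 A.  charge_delta is -1.
    """
    if target.resname != "LYS":
        raise ValueError(f"terminal excision only defined for Lys, got {target.resname}")
    try:
        nz = system.atom(target, "NZ")
    except KeyError:
        raise ValueError(f"residue {target} has no NZ atom") from None
    ce = system.atom(target, "CE")
    hz = _attached_hydrogens(system, nz)
    if len(hz) != 3 or nz.formal_charge != 1:
        raise ValueError(
            f"unexpected protonation of {target}: expected NZ(+1) with three "
            f"hydrogens, found charge {nz.formal_charge} with {len(hz)}"
        )
    removed = [nz, *hz]
    h_new = Atom(
        serial=_next_serial(system),
        name="HE3",
        element="H",
        residue_key=target,
        coords=ce.coords + CH_BOND * _unit(nz.coords - ce.coords),
        is_hetero=ce.is_hetero,
    )
    mutated = _remove_and_add(system, removed, [h_new], charge_delta=-1, label_suffix="")
    record = MutationRecord(
        operator=MutationOperator.LYS_TERMINAL_EXCISION,
        target=target,
        atoms_removed=[(a.residue_key, a.name) for a in removed],
        atoms_added=[h_new.copy()],
        charge_delta=-1,
    )
    return mutated, record


def oxo_to_normal(
    system: MolecularSystem, substrate: ResidueKey
) -> tuple[MolecularSystem, MutationRecord]:
    """Convert the oxidized guanine substrate to the normal one.

    H7 is deleted and O8 is converted to a hydrogen named H8, repositioned
    along the former C8->O8 direction at 1.09 A.  The net charge is
    unchanged.  Reusing the C8->O8 direction (rather than rebuilding ideal
    sp2 geometry) minimizes the perturbation; the protocol re-optimizes the
    pocket afterwards anyway.
    """
    names = {a.name for a in system.residue_atoms(substrate)}
    if "H7" not in names or "O8" not in names:
        raise ValueError(
            f"substrate {substrate} has no H7/O8: already the normal form?"
        )
    h7 = system.atom(substrate, "H7")
    o8 = system.atom(substrate, "O8")
    c8 = system.atom(substrate, "C8")
    h8 = Atom(
        serial=_next_serial(system),
        name="H8",
        element="H",
        residue_key=substrate,
        coords=c8.coords + CH_BOND * _unit(o8.coords - c8.coords),
        formal_charge=o8.formal_charge,
        is_hetero=o8.is_hetero,
    )
    mutated = _remove_and_add(system, [h7, o8], [h8], charge_delta=0, label_suffix="")
    record = MutationRecord(
        operator=MutationOperator.OXO_TO_NORMAL,
        target=substrate,
        atoms_removed=[(substrate, "H7"), (substrate, "O8")],
        atoms_added=[h8.copy()],
        charge_delta=0,
    )
    return mutated, record


def delete_substrate(
    system: MolecularSystem,
    substrate: ResidueKey,
    charge_policy: ChargePolicy = ChargePolicy.ANIONIC_SUBSTRATE,
) -> tuple[MolecularSystem, MutationRecord]:
    """Remove the substrate, producing the apo (NUL) reference system.

    The departing charge is assigned by the explicit policy (see
    :class:`ChargePolicy`); the resulting net charge is recorded so both
    apo reference states used by the ledger are reproducible.
    """
    charge_policy = ChargePolicy(charge_policy)
    sub_atoms = system.residue_atoms(substrate)  # KeyError if absent
    sub_charge = sum(a.formal_charge for a in sub_atoms)
    if charge_policy is ChargePolicy.ANIONIC_SUBSTRATE:
        charge_delta = -sub_charge
    else:  # PROTON_RETAINED: substrate departs with one extra negative charge
        charge_delta = -sub_charge + 1
    removed_ids = {id(a) for a in sub_atoms}
    atoms = [a.copy() for a in system.atoms if id(a) not in removed_ids]
    if not atoms:
        raise ValueError("deleting the substrate would leave an empty system")
    # park any retained charge on the first remaining atom so the
    # formal-charge sum stays consistent with the net charge
    atoms[0].formal_charge += charge_delta + sub_charge
    apo = MolecularSystem(
        label=system.label,
        atoms=atoms,
        net_charge=system.net_charge + charge_delta,
        provenance=system.provenance,
    )
    record = MutationRecord(
        operator=MutationOperator.DELETE_SUBSTRATE,
        target=substrate,
        atoms_removed=[(a.residue_key, a.name) for a in sub_atoms],
        atoms_added=[],
        charge_delta=charge_delta,
        fragment_geometry_id=charge_policy.value,
    )
    return apo, record


def add_water(
    system: MolecularSystem,
    template: list[Atom],
    label: ResidueKey,
) -> tuple[MolecularSystem, MutationRecord]:
    """Append a water molecule (one O, two H within covalent range of O)."""
    if label in {a.residue_key for a in system.atoms}:
        raise ValueError(f"residue label {label} already used")
    if label.resname not in {"HOH", "WAT"}:
        raise ValueError(f"water label must be HOH/WAT, got {label.resname}")
    elements = sorted(a.element for a in template)
    if elements != ["H", "H", "O"]:
        raise ValueError(f"malformed water template: elements {elements}")
    o = next(a for a in template if a.element == "O")
    for h in (a for a in template if a.element == "H"):
        if np.linalg.norm(h.coords - o.coords) > 1.2:
            raise ValueError("malformed water: O-H distance exceeds 1.2 A")
    serial = _next_serial(system)
    added = []
    for k, a in enumerate(template):
        added.append(
            Atom(
                serial=serial + k,
                name=a.name,
                element=a.element,
                residue_key=label,
                coords=np.asarray(a.coords, dtype=float).copy(),
                is_hetero=True,
            )
        )
    out = _remove_and_add(system, [], added, charge_delta=0, label_suffix="")
    record = MutationRecord(
        operator=MutationOperator.ADD_WATER,
        target=label,
        atoms_removed=[],
        atoms_added=[a.copy() for a in added],
        charge_delta=0,
    )
    return out, record


def delete_water(
    system: MolecularSystem, label: ResidueKey
) -> tuple[MolecularSystem, MutationRecord]:
    """Remove one water molecule."""
    if label.resname not in {"HOH", "WAT"}:
        raise ValueError(f"{label} is not a water residue")
    atoms = system.residue_atoms(label)
    out = _remove_and_add(system, list(atoms), [], charge_delta=0, label_suffix="")
    record = MutationRecord(
        operator=MutationOperator.DELETE_WATER,
        target=label,
        atoms_removed=[(a.residue_key, a.name) for a in atoms],
        atoms_added=[],
        charge_delta=0,
    )
    return out, record


def transplant_fragment(
    host: MolecularSystem,
    fragment: FragmentGeometry,
    target: ResidueKey,
    allow_cross_chain: bool = False,
) -> MolecularSystem:
    """Replace a residue by a stored rigid fragment, bit-identically.

    The target residue's atoms are swapped for the fragment's (which may be
    a truncated mutant, or empty for a deleted water); no other atom moves.
    Transplants across chain families are refused unless explicitly
    overridden, because rigid fragments are only exact within the family
    they were optimized in.
    """
    if fragment.chain_family != target.chain and not allow_cross_chain:
        raise ValueError(
            f"cross-chain transplant of fragment {fragment.fragment_id!r} "
            f"(family {fragment.chain_family!r}) into chain {target.chain!r} "
            "requires allow_cross_chain=True"
        )
    old_atoms = host.residue_atoms(target)  # KeyError if absent
    if fragment.atoms and fragment.residue_key.resname != target.resname:
        raise ValueError(
            f"fragment residue {fragment.residue_key.resname} does not match "
            f"target {target.resname}"
        )
    # identity transplant must preserve atom names one-for-one
    old_names = {a.name for a in old_atoms}
    frag_names = fragment.atom_names()
    if len(frag_names) != len(set(frag_names)):
        raise ValueError("fragment has duplicate atom names")
    extra = [n for n in frag_names if n not in old_names and not n.startswith("HB")
             and n != "HE3"]
    if extra and len(frag_names) >= len(old_names):
        raise ValueError(f"fragment atoms {extra} missing from host residue {target}")

    serial = 1
    atoms: list[Atom] = []
    inserted = False
    for a in host.atoms:
        if a.residue_key == target:
            if not inserted:
                for fa in fragment.atoms:
                    na = fa.copy()
                    na.residue_key = target
                    na.serial = serial
                    serial += 1
                    atoms.append(na)
                inserted = True
            continue
        na = a.copy()
        na.serial = serial
        serial += 1
        atoms.append(na)
    removed_charge = sum(a.formal_charge for a in old_atoms)
    added_charge = sum(a.formal_charge for a in fragment.atoms)
    return MolecularSystem(
        label=host.label,
        atoms=atoms,
        net_charge=host.net_charge - removed_charge + added_charge,
        provenance=host.provenance,
    )
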