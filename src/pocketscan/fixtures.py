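"""Synthetic toy-pocket systems with known ground truth, and the MTH1
reference ledger.

``generate_pocket`` builds a small ligand surrounded by truncatable
mini-residues whose side-chain/ligand cross-interaction energies are
planted: each residue's interaction atom carries its own surrogate atom
class, and the pair term between that class and the ligand hub is
calibrated by direct evaluation so the cross-interaction equals the planted
value.  Because every interacting pair sits exactly at its equilibrium
distance, the generated geometry is a stationary point of the surrogate,
which keeps the four-stage protocol deterministic down to the last bit.
Seeded pseudo-randomness lives only here; the production protocol itself
contains none.

``mth1_reference_ledger`` loads the published PM7 heats of formation for
the MTH1 / 8-oxo-dGMP system (chains A and B of PDB 3ZR0): the intact
complexes, the apo references under both charge policies, every
single-entity mutant, and the solution-phase substrate conformers.  It is
the desk-scale regression fixture for all ledger arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .backend import SurrogateParams, pair_energy
from .ledger import ScanLedger
from .mutations import ChargePolicy, MutationOperator, delete_substrate
from .protocol import ScanPlan, ScanTarget
from .structure import Atom, MolecularSystem, ResidueKey

__all__ = [
    "ToyPocketSpec",
    "ToyPocket",
    "generate_pocket",
    "mth1_reference_ledger",
    "ASP_PROXY_CORRECTION",
    "MTH1_PLAN_RESIDUES",
]


@dataclass
class ToyPocketSpec:
    """Recipe for one toy pocket.

    ``planted_energies`` maps residue index to the target side-chain/ligand
    interaction energy (kcal/mol, negative = attractive); unspecified
    residues draw from a moderate attractive range.  ``two_ligand_mode``
    additionally generates a sibling "normal" ligand differing at a single
    site, with planted per-residue specificities.  Generation is
    bit-reproducible for a fixed seed.
    """

    n_residues: int = 5
    ligand_size: int = 4
    planted_energies: dict[int, float] = field(default_factory=dict)
    planted_specificities: dict[int, float] = field(default_factory=dict)
    two_ligand_mode: bool = False
    include_water: bool = False
    planted_water_energy: float | None = None
    n_far_residues: int = 2
    chain: str = "T"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1 or self.ligand_size < 2:
            raise ValueError("need at least one residue and a two-atom ligand")
        for v in list(self.planted_energies.values()) + list(
            self.planted_specificities.values()
        ):
            if not math.isfinite(v):
                raise ValueError(f"infeasible planted energy {v!r}")


@dataclass
class ToyPocket:
    spec: ToyPocketSpec
    params: SurrogateParams
    systems: dict[str, MolecularSystem]
    plan: ScanPlan
    ground_truth_binding_oxidized: dict[str, float]
    ground_truth_binding_normal: dict[str, float]
    ground_truth_specificity: dict[str, float]
    far_residues: list[ResidueKey]


def _fibonacci_directions(n: int) -> np.ndarray:
    """n well-separated unit vectors (deterministic spherical lattice)."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def generate_pocket(spec: ToyPocketSpec) -> ToyPocket:
    """Build the toy systems, surrogate parameters and ground truth.

    The planted value is verified against the directly evaluated
    cross-interaction (to 1e-3 kcal/mol) before the pocket is returned.
    """
    rng = np.random.default_rng(spec.seed)
    chain = spec.chain
    lig_key = ResidueKey(chain, 900, "", "LIG")
    n_total = spec.n_residues + spec.n_far_residues + 2
    directions = _fibonacci_directions(max(n_total, 4))

    # -- ligand ----------------------------------------------------------
    hub = Atom(1, "L1", "C", lig_key, np.zeros(3), is_hetero=True)
    lig_atoms = [hub]
    for k in range(spec.ligand_size - 2):
        pos = 1.45 * directions[spec.n_residues + spec.n_far_residues + (k % 2)]
        lig_atoms.append(
            Atom(2 + k, f"L{2 + k}", "C", lig_key,
                 pos * (1.0 + 0.35 * k), is_hetero=True)
        )
    site_pos = np.array([0.0, 0.0, 1.30])
    site_index = len(lig_atoms) + 1

    class_map: dict[tuple[ResidueKey, str], str] = {(lig_key, "L1"): "LIG_HUB"}
    pair_terms: dict[tuple[str, str], tuple[float, float]] = {}

    # -- residues with planted interactions ------------------------------
    serial = 100
    residues: list[tuple[ResidueKey, str]] = []
    res_atoms: list[Atom] = []
    planted_bind: dict[str, float] = {}
    planted_spec: dict[str, float] = {}
    targets: list[ScanTarget] = []
    cg_positions: dict[str, np.ndarray] = {}
    for i in range(spec.n_residues):
        key = ResidueKey(chain, i + 1, "", "LEU")
        mid = f"Leu{i + 1}"
        d = directions[i]
        r_i = float(rng.uniform(3.2, 4.6))
        bind = spec.planted_energies.get(i, float(rng.uniform(-8.0, -0.5)))
        cg = r_i * d
        for name, dist in (("N", r_i + 4.5), ("CA", r_i + 3.0), ("CB", r_i + 1.5)):
            res_atoms.append(Atom(serial, name, name[0], key, dist * d))
            serial += 1
        res_atoms.append(Atom(serial, "CG", "C", key, cg))
        serial += 1
        cls = f"SC{i}"
        class_map[(key, "CG")] = cls
        pair_terms[("LIG_HUB", cls)] = (bind, r_i)
        planted_bind[mid] = bind
        cg_positions[mid] = cg
        if spec.two_ligand_mode:
            s_i = spec.planted_specificities.get(
                i, float(rng.uniform(-3.0, 0.5))
            )
            r_site = float(np.linalg.norm(cg - site_pos))
            pair_terms[("OXO_SITE", cls)] = (s_i, r_site)
            planted_spec[mid] = s_i
        residues.append((key, mid))
        targets.append(ScanTarget(key, MutationOperator.TO_ALANINE, mid))

    # -- optional pocket water with a planted contribution ---------------
    if spec.include_water:
        wkey = ResidueKey(chain, 501, "", "HOH")
        wmid = "H2O-501"
        d = directions[(spec.n_residues + spec.n_far_residues + 1) % len(directions)]
        rw = float(rng.uniform(3.0, 4.0))
        wbind = (
            spec.planted_water_energy
            if spec.planted_water_energy is not None
            else float(rng.uniform(-6.0, -1.0))
        )
        o_pos = rw * d
        res_atoms.append(Atom(serial, "O", "O", wkey, o_pos, is_hetero=True))
        serial += 1
        for j, off in enumerate(
            (np.array([0.76, 0.59, 0.0]), np.array([-0.76, 0.59, 0.0]))
        ):
            res_atoms.append(
                Atom(serial, f"H{j + 1}", "H", wkey, o_pos + off, is_hetero=True)
            )
            serial += 1
        class_map[(wkey, "O")] = "WSC"
        pair_terms[("LIG_HUB", "WSC")] = (wbind, rw)
        planted_bind[wmid] = wbind
        if spec.two_ligand_mode:
            planted_spec[wmid] = 0.0
        targets.append(ScanTarget(wkey, MutationOperator.DELETE_WATER, wmid))

    # -- far control residues (beyond every interaction) -----------------
    far_keys: list[ResidueKey] = []
    for j in range(spec.n_far_residues):
        key = ResidueKey(chain, 101 + j, "", "LEU")
        d = directions[spec.n_residues + j]
        base = 20.0 + 2.0 * j
        for name, dist in (
            ("N", base + 4.5), ("CA", base + 3.0), ("CB", base + 1.5), ("CG", base)
        ):
            res_atoms.append(Atom(serial, name, name[0], key, dist * d))
            serial += 1
        far_keys.append(key)

    if spec.two_ligand_mode:
        class_map[(lig_key, "O8")] = "OXO_SITE"
        class_map[(lig_key, "H8")] = "SITE_INERT"
    params = SurrogateParams(
        pair_terms=pair_terms, class_map=class_map, seed=spec.seed
    )

    def build(label: str, site_atom: Atom | None) -> MolecularSystem:
        atoms = [a.copy() for a in lig_atoms]
        if site_atom is not None:
            atoms.append(site_atom.copy())
        atoms.extend(a.copy() for a in res_atoms)
        return MolecularSystem(label=label, atoms=atoms, net_charge=0,
                               provenance=f"toy pocket seed={spec.seed}")

    oxi_site = Atom(site_index, "O8", "O", lig_key, site_pos, is_hetero=True)
    systems: dict[str, MolecularSystem] = {}
    label_oxi, label_nor, label_nul = "TOY-OXI", "TOY-NOR", "TOY-NUL"
    if spec.two_ligand_mode:
        nor_site = Atom(site_index, "H8", "H", lig_key, site_pos, is_hetero=True)
        systems[label_oxi] = build(label_oxi, oxi_site)
        systems[label_nor] = build(label_nor, nor_site)
    else:
        systems[label_oxi] = build(label_oxi, oxi_site)
    apo, _ = delete_substrate(
        systems[label_oxi], lig_key, ChargePolicy.ANIONIC_SUBSTRATE
    )
    systems[label_nul] = apo.copy(label=label_nul)
    systems[label_nul].label = label_nul

    plan = ScanPlan(
        chain_family=chain,
        label_oxidized=label_oxi,
        label_normal=label_nor if spec.two_ligand_mode else None,
        label_null=label_nul,
        substrate=lig_key,
        targets=targets,
    )

    _verify_planted(systems[label_oxi], params, plan, planted_bind, planted_spec,
                    spec.two_ligand_mode)

    gt_nor = {
        mid: (planted_bind[mid] if not spec.two_ligand_mode else planted_bind[mid])
        for mid in planted_bind
    }
    gt_oxi = {
        mid: planted_bind[mid] + planted_spec.get(mid, 0.0) for mid in planted_bind
    }
    return ToyPocket(
        spec=spec,
        params=params,
        systems=systems,
        plan=plan,
        ground_truth_binding_oxidized=gt_oxi,
        ground_truth_binding_normal=gt_nor,
        ground_truth_specificity=dict(planted_spec),
        far_residues=far_keys,
    )


def _verify_planted(
    complex_system: MolecularSystem,
    params: SurrogateParams,
    plan: ScanPlan,
    planted_bind: dict[str, float],
    planted_spec: dict[str, float],
    two_ligand: bool,
    tol: float = 1e-3,
) -> None:
    """Direct evaluation of every planted cross-interaction.

    Sums the surrogate pair terms between each scanned entity's interacting
    atoms and the ligand, atom by atom, and insists the result matches the
    planted value.  Raises if a planted energy is unreachable.
    """
    lig_atoms = complex_system.residue_atoms(plan.substrate)
    for target in plan.targets:
        mid = target.mutation_id
        ent_atoms = complex_system.residue_atoms(target.residue)
        total = 0.0
        site = 0.0
        for a in ent_atoms:
            ca = params.atom_class(a)
            for b in lig_atoms:
                cb = params.atom_class(b)
                r = float(np.linalg.norm(a.coords - b.coords))
                for depth, r_eq in params.terms_for(ca, cb):
                    e = pair_energy(depth, r_eq, r, params.cutoff)
                    total += e
                    if cb == "OXO_SITE":
                        site += e
        want = planted_bind[mid] + (planted_spec.get(mid, 0.0) if two_ligand else 0.0)
        if abs(total - want) > tol:
            raise ValueError(
                f"infeasible planted energy for {mid}: requested {want}, "
                f"directly evaluated {total:.6f}"
            )
        if two_ligand and abs(site - planted_spec.get(mid, 0.0)) > tol:
            raise ValueError(f"planted specificity for {mid} not realized")


# -- MTH1 reference ledger -------------------------------------------------

#: Extra stabilization of the intact carboxylate/carboxylic-acid pair,
#: estimated from the surface-aspartate (D99A) proxy mutation, kcal/mol.
ASP_PROXY_CORRECTION = 10.25

#: The 13 scanned binding-site entities, in table order.
MTH1_PLAN_RESIDUES = [
    "Asp119", "Asp120", "Asn33", "Leu9", "Lys23", "Met81", "Trp117",
    "Phe27", "Val83", "Phe72", "H2O-2134", "Trp123", "Phe139",
]

# (residue, dHf(A-NUL)_R, dHf(A-8OG)_R, dHf(A-GMP)_R); the two aspartates
# use the proton-retained apo reference (see ChargePolicy.PROTON_RETAINED).
_TABLE_A = [
    ("Asp119", -23644.90, -24328.99, -24262.90),
    ("Asp120", -23655.84, -24330.10, -24263.40),
    ("Asn33", -23773.56, -24365.65, -24300.19),
    ("Leu9", -23814.97, -24415.26, -24349.13),
    ("Lys23", -23893.82, -24492.09, -24426.03),
    ("Met81", -23828.01, -24434.66, -24369.51),
    ("Trp117", -23847.76, -24449.51, -24385.23),
    ("Phe27", -23854.25, -24457.49, -24392.04),
    ("Val83", -23821.84, -24425.62, -24359.08),
    ("Phe72", -23847.94, -24449.37, -24385.15),
    ("H2O-2134", -23765.50, -24366.34, -24301.07),
    ("Trp123", -23845.34, -24450.28, -24382.71),
    ("Phe139", -23842.76, -24448.58, -24383.16),
]

# (residue, dHf(B-8OG)_R, dHf(B-GMP)_R)
_TABLE_B = [
    ("Asp119", -19307.03, -19240.04),
    ("Asp120", -19298.65, -19231.54),
    ("Asn33", -19351.29, -19285.08),
    ("Leu9", -19392.44, -19325.05),
    ("Lys23", -19471.20, -19404.28),
    ("Met81", -19408.82, -19342.78),
    ("Trp117", -19436.33, -19371.44),
    ("Phe27", -19434.35, -19366.94),
    ("Val83", -19400.40, -19333.20),
    ("Phe72", -19424.21, -19360.74),
    ("H2O-2134", -19342.02, -19275.74),
    ("Trp123", -19424.93, -19357.47),
    ("Phe139", -19424.55, -19358.75),
]

# solution-phase substrate anion conformers/tautomers, kcal/mol
_SOLUTION = {
    ("8-oxo-dGMP", "syn-keto-keto"): -517.99,
    ("8-oxo-dGMP", "anti-keto-keto"): -515.65,
    ("8-oxo-dGMP", "syn-enol-keto"): -509.38,
    ("8-oxo-dGMP", "anti-enol-keto"): -506.35,
    ("8-oxo-dGMP", "syn-keto-enol"): -500.09,
    ("8-oxo-dGMP", "anti-keto-enol"): -508.91,
    ("8-oxo-dGMP", "syn-enol-enol"): -490.55,
    ("8-oxo-dGMP", "anti-enol-enol"): -509.05,
    ("dGMP", "syn-keto"): -459.71,
    ("dGMP", "anti-keto"): -459.39,
    ("dGMP", "syn-enol"): -449.84,
    ("dGMP", "anti-enol"): -449.42,
}

#: Residues whose apo reference is the proton-retained preparation.
MTH1_NULL_OVERRIDES = {"Asp119": "A-NUL+", "Asp120": "A-NUL+"}


def mth1_reference_ledger() -> ScanLedger:
    """The published PM7 ledger for MTH1 (PDB 3ZR0, chains A and B).

    Unmutated labels: A-8OG, A-GMP, A-NUL (and the proton-retained
    alternative A-NUL+ used for the two aspartates), B-8OG, B-GMP.  Mutated
    entries carry one cell per scanned entity per system.  Uncorrected
    pharmacophore stabilizations (prior to the acid-pair correction) are
    attached for the two aspartates.
    """
    ledger = ScanLedger()
    ledger.unmutated.update(
        {
            "A-8OG": -24446.41,
            "A-GMP": -24380.00,
            "A-NUL": -23840.25,
            "A-NUL+": -23756.26,
            "B-8OG": -19421.98,
            "B-GMP": -19354.72,
        }
    )
    for residue, nul_r, oxi_r, gmp_r in _TABLE_A:
        null_label = MTH1_NULL_OVERRIDES.get(residue, "A-NUL")
        ledger.record(null_label, residue, nul_r)
        ledger.record("A-8OG", residue, oxi_r)
        ledger.record("A-GMP", residue, gmp_r)
    for residue, oxi_r, gmp_r in _TABLE_B:
        ledger.record("B-8OG", residue, oxi_r)
        ledger.record("B-GMP", residue, gmp_r)
    ledger.substrate_solution.update(_SOLUTION)
    ledger.uncorrected_pharmacophore.update({"Asp119": 5.02, "Asp120": -8.52})
    return ledger
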