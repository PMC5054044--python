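"""Energy backends: a uniform contract for heat-of-formation evaluation.

Two backends implement the contract.  The :class:`SurrogateBackend` is a
deterministic, strictly pairwise-additive potential used for engine-free
testing of the whole protocol; pairwise additivity is the property every
protocol oracle rests on.  The :class:`MopacBackend` adapter treats an
external semiempirical engine (PM7-style, localized orbitals, implicit
solvation) as a black box: it emits an input deck, shells out, and parses
the result.  No quantum chemistry is reimplemented here.

All energies are heats of formation in kcal/mol.  Restrained optimization
uses a harmonic per-atom penalty 0.5*k*d^2 toward a reference geometry,
whose gradient magnitude equals the nominal restraining force k at 1 A
displacement.
"""

from __future__ import annotations

import math
import os
import re
import subprocess
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .structure import Atom, MolecularSystem, ResidueKey, write_system

__all__ = [
    "EnergyResult",
    "RestraintSpec",
    "SurrogateParams",
    "SurrogateBackend",
    "MopacBackend",
    "emit_engine_input",
    "parse_engine_output",
    "render_engine_output",
    "pair_energy",
    "COULOMB_CONSTANT",
    "DEFAULT_EPSILON",
]

COULOMB_CONSTANT = 332.0637  # kcal A / (mol e^2)
#: Dielectric constant of bulk water, the default implicit solvent.
DEFAULT_EPSILON = 78.4


@dataclass
class EnergyResult:
    heat_of_formation: float
    backend_id: str
    converged: bool
    geometry: MolecularSystem | None
    wall_notes: str = ""

    def __post_init__(self) -> None:
        if self.converged and not math.isfinite(self.heat_of_formation):
            raise ValueError("converged result with non-finite heat of formation")


@dataclass
class RestraintSpec:
    """Harmonic bias of selected atoms toward a reference geometry."""

    reference: MolecularSystem
    force_constant: float  # kcal/mol/A of gradient at 1 A displacement
    restrained_atom_ids: set[int]

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        ref_serials = {a.serial for a in self.reference.atoms}
        missing = set(self.restrained_atom_ids) - ref_serials
        if missing:
            raise ValueError(f"restrained atoms {sorted(missing)} absent from reference")


@dataclass
class SurrogateParams:
    """Parameters of the deterministic pairwise surrogate potential.

    ``pair_terms`` maps an unordered pair of atom classes to a
    (well depth, equilibrium distance) Lennard-Jones-style term

        E(r) = depth * (2 (re/r)^6 - (re/r)^12)

    whose value at r = re is exactly ``depth`` (negative = attractive well).
    ``hbond_terms`` are additional terms of the same form between donor-H
    and acceptor classes.  ``coulomb_scale`` scales a point-charge Coulomb
    term over formal charges (0 disables it).  ``class_map`` pins explicit
    classes onto named atoms; everything else is typed from the element with
    simple donor/acceptor flavouring.  Energies are strictly pairwise
    additive; ``cutoff`` (if set) truncates every pair term to zero beyond
    that separation.
    """

    pair_terms: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    hbond_terms: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    coulomb_scale: float = 0.0
    cutoff: float | None = None
    class_map: dict[tuple[ResidueKey, str], str] = field(default_factory=dict)
    seed: int = 0  # fixture-generation bookkeeping only

    def __post_init__(self) -> None:
        self.pair_terms = {_norm_pair(k): v for k, v in self.pair_terms.items()}
        self.hbond_terms = {_norm_pair(k): v for k, v in self.hbond_terms.items()}
        for (d, re_) in list(self.pair_terms.values()) + list(self.hbond_terms.values()):
            if re_ <= 0:
                raise ValueError("equilibrium distances must be positive")

    def atom_class(self, atom: Atom) -> str:
        explicit = self.class_map.get((atom.residue_key, atom.name))
        if explicit is not None:
            return explicit
        if atom.element == "H":
            return "H"
        if atom.element == "N":
            return "N_acc"
        if atom.element == "O":
            return "O_acc"
        return atom.element

    def set_pair_term(
        self, class_a: str, class_b: str, depth: float, r_eq: float
    ) -> None:
        """Insert or replace a pair term with the key properly normalized."""
        if r_eq <= 0:
            raise ValueError("equilibrium distances must be positive")
        self.pair_terms[_norm_pair((class_a, class_b))] = (depth, r_eq)

    def terms_for(self, class_a: str, class_b: str) -> list[tuple[float, float]]:
        """All additive terms acting between two classes (pair + H-bond)."""
        key = _norm_pair((class_a, class_b))
        out = []
        for table in (self.pair_terms, self.hbond_terms):
            if key in table:
                out.append(table[key])
        return out


def _norm_pair(pair: Iterable[str]) -> tuple[str, str]:
    a, b = tuple(pair)
    return (a, b) if a <= b else (b, a)


def pair_energy(depth: float, r_eq: float, r: float, cutoff: float | None = None) -> float:
    """Single pair term; exactly the surrogate's functional form."""
    if cutoff is not None and r > cutoff:
        return 0.0
    s6 = (r_eq / r) ** 6
    return depth * (2.0 * s6 - s6 * s6)


def _pair_gradient_factor(depth: float, r_eq: float, r: float,
                          cutoff: float | None = None) -> float:
    """dE/dr for the pair term."""
    if cutoff is not None and r > cutoff:
        return 0.0
    return 12.0 * depth * (r_eq**12 / r**13 - r_eq**6 / r**7)


class SurrogateBackend:
    """Engine-free backend with analytic gradients.

    Deterministic: identical systems give bit-identical energies, and the
    quasi-Newton optimizer is run with fixed settings and no randomness.
    """

    backend_id = "surrogate"

    def __init__(self, params: SurrogateParams):
        self.params = params

    # -- core evaluation -------------------------------------------------

    def _energy_and_gradient(
        self, atoms: Sequence[Atom], coords: np.ndarray
    ) -> tuple[float, np.ndarray]:
        p = self.params
        n = len(atoms)
        grad = np.zeros((n, 3))
        energy = 0.0
        classes = [p.atom_class(a) for a in atoms]
        charges = [a.formal_charge for a in atoms]
        for i in range(n):
            for j in range(i + 1, n):
                rij = coords[j] - coords[i]
                r = float(np.linalg.norm(rij))
                if r < 1e-12:
                    raise ValueError(
                        f"coincident atoms {atoms[i].name}/{atoms[j].name}"
                    )
                de_dr = 0.0
                key = _norm_pair((classes[i], classes[j]))
                for table in (p.pair_terms, p.hbond_terms):
                    term = table.get(key)
                    if term is not None:
                        depth, r_eq = term
                        energy += pair_energy(depth, r_eq, r, p.cutoff)
                        de_dr += _pair_gradient_factor(depth, r_eq, r, p.cutoff)
                if p.coulomb_scale and charges[i] and charges[j]:
                    qq = COULOMB_CONSTANT * p.coulomb_scale * charges[i] * charges[j]
                    energy += qq / r
                    de_dr += -qq / r**2
                if de_dr != 0.0:
                    g = de_dr * rij / r
                    grad[i] -= g
                    grad[j] += g
        return energy, grad

    def _restraint_energy_and_gradient(
        self,
        atoms: Sequence[Atom],
        coords: np.ndarray,
        restraint: RestraintSpec,
    ) -> tuple[float, np.ndarray]:
        ref_pos = {a.serial: a.coords for a in restraint.reference.atoms}
        k = restraint.force_constant
        e = 0.0
        grad = np.zeros_like(coords)
        for idx, a in enumerate(atoms):
            if a.serial in restraint.restrained_atom_ids:
                d = coords[idx] - ref_pos[a.serial]
                e += 0.5 * k * float(d @ d)
                grad[idx] += k * d
        return e, grad

    # -- contract --------------------------------------------------------

    def single_point(
        self, system: MolecularSystem, solvent_epsilon: float = DEFAULT_EPSILON
    ) -> EnergyResult:
        """Heat of formation at fixed geometry (solvent epsilon is carried
        for interface parity; the surrogate has no explicit solvent)."""
        if not system.atoms:
            return EnergyResult(0.0, self.backend_id, True, system.copy())
        e, _ = self._energy_and_gradient(system.atoms, system.coords_array())
        return EnergyResult(e, self.backend_id, True, system.copy())

    def optimize(
        self,
        system: MolecularSystem,
        movable_atom_ids: set[int],
        restraint: RestraintSpec | None = None,
        solvent_epsilon: float = DEFAULT_EPSILON,
    ) -> EnergyResult:
        """Constrained minimization; frozen atoms stay bit-identical.

        Only movable atoms enter the optimization variables, so the frozen
        complement cannot drift even by round-off.  The reported heat of
        formation is the potential energy of the final geometry, without
        the restraint penalty.
        """
        if not movable_atom_ids:
            raise ValueError("movable set is empty; use single_point instead")
        atoms = system.atoms
        serial_to_idx = {a.serial: i for i, a in enumerate(atoms)}
        missing = set(movable_atom_ids) - set(serial_to_idx)
        if missing:
            raise KeyError(f"movable atoms {sorted(missing)} absent from system")
        movable_idx = np.array(sorted(serial_to_idx[s] for s in movable_atom_ids))
        base = system.coords_array()

        def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
            coords = base.copy()
            coords[movable_idx] = x.reshape(-1, 3)
            e, g = self._energy_and_gradient(atoms, coords)
            if restraint is not None:
                er, gr = self._restraint_energy_and_gradient(atoms, coords, restraint)
                e += er
                g = g + gr
            return e, g[movable_idx].ravel()

        x0 = base[movable_idx].ravel()
        res = minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"gtol": 1e-10, "ftol": 1e-15, "maxiter": 1000},
        )
        final = system.copy()
        new_coords = base.copy()
        new_coords[movable_idx] = res.x.reshape(-1, 3)
        for i in movable_idx:
            final.atoms[int(i)].coords = new_coords[int(i)].copy()
        e_final, _ = self._energy_and_gradient(final.atoms, new_coords)
        return EnergyResult(
            heat_of_formation=float(e_final),
            backend_id=self.backend_id,
            converged=bool(res.success),
            geometry=final,
            wall_notes=str(res.message),
        )


# -- engine adapter --------------------------------------------------------


def emit_engine_input(
    system: MolecularSystem,
    movable_atom_ids: set[int],
    restraint: RestraintSpec | None = None,
    solvent_epsilon: float = DEFAULT_EPSILON,
    charge: int | None = None,
    restraint_path: str = "geo_ref.pdb",
) -> str:
    """Deterministic input deck for a PM7-class semiempirical engine.

    Keyword line: Hamiltonian, localized-orbital mode, implicit-solvent
    epsilon and total charge; then one atom per line with element,
    Cartesian coordinates and per-coordinate optimization flags (1 =
    movable, 0 = frozen).  A reference-geometry restraint is passed as a
    file path plus the stated force constant.  With no movable atoms the
    deck requests a single-point (1SCF) run.
    """
    if charge is None:
        charge = system.net_charge
    if charge != system.net_charge:
        raise ValueError(
            f"requested charge {charge} inconsistent with system net charge "
            f"{system.net_charge}"
        )
    keywords = ["PM7", "MOZYME", f"EPS={solvent_epsilon:.2f}", f"CHARGE={charge}"]
    if not movable_atom_ids:
        keywords.append("1SCF")
    if restraint is not None:
        keywords.append(f'GEO_REF="{restraint_path}"')
        keywords.append(f"GEO_FORCE={restraint.force_constant:.2f}")
    lines = [" ".join(keywords), system.label, ""]
    for a in system.atoms:
        flag = 1 if a.serial in movable_atom_ids else 0
        x, y, z = a.coords
        lines.append(
            f" {a.element:<2s} {x:14.8f} {flag} {y:14.8f} {flag} {z:14.8f} {flag}"
        )
    return "\n".join(lines) + "\n"


_FINAL_HOF = re.compile(r"FINAL HEAT OF FORMATION\s*=\s*(-?\d+(?:\.\d+)?)\s*KCAL")
_CYCLE_HOF = re.compile(r"HEAT:?\s*(-?\d+(?:\.\d+)?)")
_COORD_LINE = re.compile(
    r"^\s*\d+\s+([A-Z][a-z]?)\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s*$"
)


def parse_engine_output(text: str, backend_id: str = "engine") -> EnergyResult:
    """Extract the final heat of formation, geometry and convergence status.

    A truncated run (cycle heats but no final energy) is returned with
    ``converged=False`` and the last cycle energy; output with no energy at
    all is an error -- a number is never silently invented.
    """
    if not text.strip():
        raise ValueError("no energy found: empty engine output")
    geometry = _parse_geometry_block(text)
    m = _FINAL_HOF.search(text)
    if m:
        heat = float(m.group(1))
        failed = "EXCESS NUMBER OF OPTIMIZATION CYCLES" in text
        return EnergyResult(
            heat_of_formation=heat,
            backend_id=backend_id,
            converged=not failed,
            geometry=geometry,
            wall_notes="" if not failed else "optimization cycle limit reached",
        )
    cycles = _CYCLE_HOF.findall(text)
    if cycles:
        return EnergyResult(
            heat_of_formation=float(cycles[-1]),
            backend_id=backend_id,
            converged=False,
            geometry=geometry,
            wall_notes="truncated output: no final energy line",
        )
    raise ValueError("no energy found in engine output")


def _parse_geometry_block(text: str) -> MolecularSystem | None:
    blocks: list[list[Atom]] = []
    current: list[Atom] = []
    in_block = False
    for line in text.splitlines():
        if "CARTESIAN COORDINATES" in line:
            if current:
                blocks.append(current)
            current = []
            in_block = True
            continue
        if in_block:
            m = _COORD_LINE.match(line)
            if m:
                el, x, y, z = m.groups()
                current.append(
                    Atom(
                        serial=len(current) + 1,
                        name=f"{el}{len(current) + 1}",
                        element=el,
                        residue_key=ResidueKey("X", 1, "", "UNK"),
                        coords=np.array([float(x), float(y), float(z)]),
                    )
                )
            elif current:
                in_block = False
    if current:
        blocks.append(current)
    if not blocks:
        return None
    atoms = blocks[-1]  # final geometry
    return MolecularSystem(label="parsed", atoms=atoms, net_charge=0)


def render_engine_output(result: EnergyResult) -> str:
    """Serialize a result in the dialect :func:`parse_engine_output` reads.

    emit->parse on this serialization is the identity on the heat of
    formation and the geometry (coordinates kept to 10 decimals).
    """
    lines = []
    if result.geometry is not None:
        lines.append("          CARTESIAN COORDINATES")
        for i, a in enumerate(result.geometry.atoms, start=1):
            x, y, z = a.coords
            lines.append(f"   {i}   {a.element:<2s}  {x:.10f}  {y:.10f}  {z:.10f}")
        lines.append("")
    lines.append(
        f" FINAL HEAT OF FORMATION = {result.heat_of_formation:.10f} KCAL/MOL"
    )
    if not result.converged:
        lines.append(" EXCESS NUMBER OF OPTIMIZATION CYCLES")
    return "\n".join(lines) + "\n"


class MopacBackend:
    """Adapter that shells out to an external PM7-class engine per call.

    The engine executable is located from ``executable`` or the
    ``POCKETSCAN_ENGINE`` environment variable.  Each evaluation writes a
    deck in a scratch directory, runs the engine, and parses its output;
    engine failures surface with the engine's own message.
    """

    backend_id = "pm7-engine"

    def __init__(self, executable: str | None = None, workdir: str | None = None):
        self.executable = executable or os.environ.get("POCKETSCAN_ENGINE")
        if not self.executable:
            raise ValueError(
                "no engine executable configured (set POCKETSCAN_ENGINE or "
                "pass executable=...)"
            )
        self.workdir = workdir

    def _run(
        self,
        system: MolecularSystem,
        movable_atom_ids: set[int],
        restraint: RestraintSpec | None,
        solvent_epsilon: float,
    ) -> EnergyResult:
        with tempfile.TemporaryDirectory(dir=self.workdir) as tmp:
            ref_path = os.path.join(tmp, "geo_ref.pdb")
            if restraint is not None:
                write_system(restraint.reference, ref_path)
            deck = emit_engine_input(
                system, movable_atom_ids, restraint, solvent_epsilon,
                restraint_path=ref_path,
            )
            inp = os.path.join(tmp, "job.mop")
            with open(inp, "w") as fh:
                fh.write(deck)
            proc = subprocess.run(
                [self.executable, inp], capture_output=True, text=True
            )
            out_path = os.path.join(tmp, "job.out")
            if not os.path.exists(out_path):
                raise RuntimeError(
                    f"engine produced no output (exit {proc.returncode}): "
                    f"{proc.stderr.strip() or proc.stdout.strip()}"
                )
            with open(out_path) as fh:
                return parse_engine_output(fh.read(), backend_id=self.backend_id)

    def single_point(
        self, system: MolecularSystem, solvent_epsilon: float = DEFAULT_EPSILON
    ) -> EnergyResult:
        return self._run(system, set(), None, solvent_epsilon)

    def optimize(
        self,
        system: MolecularSystem,
        movable_atom_ids: set[int],
        restraint: RestraintSpec | None = None,
        solvent_epsilon: float = DEFAULT_EPSILON,
    ) -> EnergyResult:
        if not movable_atom_ids:
            raise ValueError("movable set is empty; use single_point instead")
        return self._run(system, movable_atom_ids, restraint, solvent_epsilon)
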