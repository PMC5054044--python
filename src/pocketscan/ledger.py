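"""Energy bookkeeping: per-residue binding and specificity decomposition.

Every quantity here is pure arithmetic on recorded heats of formation
(kcal/mol).  The binding contribution of a residue R is

    B_R = (dHf(complex) - dHf(apo)) - (dHf(complex)_R - dHf(apo)_R)

where the subscript R marks the systems in which R was mutated; negative
values are stabilizing.  The specificity contribution replaces the apo
system with the complex of the competing substrate:

    S_R = (dHf(oxi) - dHf(nor)) - (dHf(oxi)_R - dHf(nor)_R)

so a negative S_R means R binds the oxidized substrate more strongly.
Reference constants (the footnote-style shortcut forms) are always derived
from the stored unmutated entries, never hard-coded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "LedgerCell",
    "ScanLedger",
    "reference_constant",
    "binding_contribution",
    "specificity_contribution",
    "heat_of_reaction",
    "total_specificity",
    "corrected_asp_contributions",
    "conformer_diffs",
    "render_tables",
]


@dataclass
class LedgerCell:
    value: float
    valid: bool = True
    note: str = ""


@dataclass
class ScanLedger:
    """Map of (system label, mutation id) -> heat of formation.

    ``unmutated`` holds the intact systems, keyed by label; alternative apo
    reference states (e.g. the proton-retained preparation used for the
    aspartate pair) are simply additional labels.  ``substrate_solution``
    holds solution-phase substrate conformers keyed by
    (substrate, conformer id).  Cells marked invalid poison every derived
    quantity that touches them.  Cells are immutable once written: a second
    ``record`` on the same key is an error, so re-runs cannot silently
    overwrite the precision bookkeeping.
    """

    entries: dict[tuple[str, str], LedgerCell] = field(default_factory=dict)
    unmutated: dict[str, float] = field(default_factory=dict)
    substrate_solution: dict[tuple[str, str], float] = field(default_factory=dict)
    uncorrected_pharmacophore: dict[str, float] = field(default_factory=dict)
    tolerance: float = 0.02  # kcal/mol, single-cell comparisons
    sum_tolerance: float = 0.03  # kcal/mol, column sums (tables carry rounding)

    # -- recording -------------------------------------------------------

    def record(self, label: str, mutation_id: str, value: float,
               valid: bool = True, note: str = "") -> None:
        key = (label, mutation_id)
        if key in self.entries:
            raise ValueError(f"ledger cell {key} already written (cells are immutable)")
        self.entries[key] = LedgerCell(value=value, valid=valid, note=note)

    def cell(self, label: str, mutation_id: str) -> float:
        try:
            c = self.entries[(label, mutation_id)]
        except KeyError:
            raise KeyError(f"no ledger entry for system {label!r}, mutation "
                           f"{mutation_id!r}") from None
        if not c.valid:
            raise ValueError(
                f"ledger cell ({label}, {mutation_id}) is invalid: {c.note}"
            )
        return c.value

    def base(self, label: str) -> float:
        try:
            return self.unmutated[label]
        except KeyError:
            raise KeyError(f"no unmutated entry for system {label!r}") from None

    def mutation_ids(self, label: str) -> list[str]:
        return [m for (lbl, m) in self.entries if lbl == label]


# -- derived quantities ----------------------------------------------------


def reference_constant(ledger: ScanLedger, complex_label: str, null_label: str) -> float:
    """dHf(apo) - dHf(complex): the constant of the shortcut form of B_R."""
    return ledger.base(null_label) - ledger.base(complex_label)


def binding_contribution(
    ledger: ScanLedger, residue: str, complex_label: str, null_label: str
) -> float:
    """B_R for one residue, from the four heats of formation."""
    unmut = ledger.base(complex_label) - ledger.base(null_label)
    mut = ledger.cell(complex_label, residue) - ledger.cell(null_label, residue)
    return unmut - mut


def specificity_contribution(
    ledger: ScanLedger, residue: str, label_oxi: str, label_nor: str
) -> float:
    """S_R for one residue: B_R with the competing complex as reference."""
    unmut = ledger.base(label_oxi) - ledger.base(label_nor)
    mut = ledger.cell(label_oxi, residue) - ledger.cell(label_nor, residue)
    return unmut - mut


def heat_of_reaction(
    ledger: ScanLedger,
    complex_label: str,
    null_label: str,
    substrate_solution_key: tuple[str, str],
) -> float:
    """dH_r = dHf(complex) - (dHf(substrate, aq) + dHf(apo))."""
    try:
        sol = ledger.substrate_solution[substrate_solution_key]
    except KeyError:
        raise KeyError(
            f"no solution-phase entry {substrate_solution_key}"
        ) from None
    return ledger.base(complex_label) - (sol + ledger.base(null_label))


def total_specificity(
    ledger: ScanLedger,
    labels: tuple[str, str],
    substrate_solution_keys: tuple[tuple[str, str], tuple[str, str]],
) -> float:
    """Whole-system specificity: complex energy gap minus the gap of the
    isolated solvated substrates (conformer choice is the caller's)."""
    label_oxi, label_nor = labels
    key_oxi, key_nor = substrate_solution_keys
    for k in (key_oxi, key_nor):
        if k not in ledger.substrate_solution:
            raise KeyError(f"no solution-phase entry {k}")
    complex_gap = ledger.base(label_oxi) - ledger.base(label_nor)
    solution_gap = (
        ledger.substrate_solution[key_oxi] - ledger.substrate_solution[key_nor]
    )
    return complex_gap - solution_gap


def corrected_asp_contributions(
    ledger: ScanLedger, proxy_residue_delta: float,
    residues: tuple[str, str] = ("Asp119", "Asp120"),
) -> tuple[float, float]:
    """Subtract the carboxylate-carboxylic-acid proxy correction from the
    two pharmacophore residues' uncorrected stabilization energies.

    The correction is the extra stabilization the intact acid pair enjoys
    in the unmutated enzyme, estimated from a surface-aspartate proxy
    mutation; the pairwise difference between the two residues is preserved.
    """
    out = []
    for r in residues:
        if r not in ledger.uncorrected_pharmacophore:
            raise KeyError(f"no uncorrected stabilization recorded for {r}")
        out.append(ledger.uncorrected_pharmacophore[r] - proxy_residue_delta)
    return (out[0], out[1])


def conformer_diffs(ledger: ScanLedger, substrate: str) -> dict[str, float]:
    """Solution-phase conformer energies relative to the lowest one."""
    vals = {
        conf: v
        for (sub, conf), v in ledger.substrate_solution.items()
        if sub == substrate
    }
    if not vals:
        raise ValueError(f"no solution-phase entries for substrate {substrate!r}")
    low = min(vals.values())
    return {conf: v - low for conf, v in vals.items()}


# -- tables & consistency --------------------------------------------------


@dataclass
class ConsistencyCheck:
    name: str
    expected: float | None
    computed: float
    tolerance: float
    passed: bool | None


def render_tables(
    ledger: ScanLedger,
    complex_label: str,
    null_label: str,
    normal_label: str | None = None,
    residues: Sequence[str] | None = None,
    null_overrides: Mapping[str, str] | None = None,
    out_dir: str | None = None,
    expectations: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None, list[ConsistencyCheck]]:
    """Emit per-residue binding (and, optionally, specificity) tables.

    ``null_overrides`` maps residue -> alternative apo label (the
    proton-retained reference used for the aspartate pair).  The returned
    consistency report compares column sums against caller-supplied
    expectations (e.g. an independently computed heat of reaction or total
    specificity) at the ledger's tolerances.  Incomplete ledgers yield
    partial tables with explicit gaps (NaN) and a failed check.
    """
    null_overrides = dict(null_overrides or {})
    if residues is None:
        residues = ledger.mutation_ids(complex_label)
    if not residues:
        raise ValueError(f"ledger holds no mutations for {complex_label!r}")

    rows = []
    checks: list[ConsistencyCheck] = []
    for r in residues:
        nul = null_overrides.get(r, null_label)
        row: dict[str, object] = {
            "residue": r,
            "null_reference": nul,
            "reference_constant": reference_constant(ledger, complex_label, nul),
        }
        try:
            row["B_R"] = binding_contribution(ledger, r, complex_label, nul)
        except (KeyError, ValueError) as exc:
            row["B_R"] = math.nan
            checks.append(ConsistencyCheck(f"B_R[{r}] available", None, math.nan,
                                           ledger.tolerance, False))
        rows.append(row)
    binding_df = pd.DataFrame(rows)

    sum_b = float(binding_df["B_R"].sum(skipna=False))
    checks.append(
        _check("sum(B_R)", expectations, "sum_B_R", sum_b, ledger.sum_tolerance)
    )

    spec_df = None
    if normal_label is not None:
        srows = []
        for r in residues:
            try:
                s = specificity_contribution(ledger, r, complex_label, normal_label)
            except (KeyError, ValueError):
                s = math.nan
            srows.append({"residue": r, "S_R": s})
        spec_df = pd.DataFrame(srows)
        sum_s = float(spec_df["S_R"].sum(skipna=False))
        checks.append(
            _check("sum(S_R)", expectations, "sum_S_R", sum_s, ledger.sum_tolerance)
        )

    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        binding_df.to_csv(os.path.join(out_dir, "binding_contributions.csv"),
                          index=False, float_format="%.4f")
        if spec_df is not None:
            spec_df.to_csv(os.path.join(out_dir, "specificity_contributions.csv"),
                           index=False, float_format="%.4f")
        report = pd.DataFrame([c.__dict__ for c in checks])
        report.to_csv(os.path.join(out_dir, "consistency_report.csv"), index=False)
    return binding_df, spec_df, checks


def _check(
    name: str,
    expectations: Mapping[str, float] | None,
    key: str,
    computed: float,
    tolerance: float,
) -> ConsistencyCheck:
    expected = None if expectations is None else expectations.get(key)
    passed = None
    if expected is not None:
        passed = math.isfinite(computed) and abs(computed - expected) <= tolerance
    return ConsistencyCheck(name, expected, computed, tolerance, passed)
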