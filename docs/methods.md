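# Methods

## Model and assumptions

The package treats per-residue energetics as differences of heats of
formation (ΔH_f, kcal mol⁻¹) between structurally controlled model systems.
The central assumption is *local rigidity*: the binding pocket is stiff
enough that removing one residue's interacting group does not reorganize
the rest of the pocket, so one-at-a-time mutations decompose the binding
energy approximately additively. The method is therefore appropriate for
enzymes with rigid pockets and should not be trusted where substrate
binding triggers large conformational change.

All energies are minimum-energy (0 K) values; the backends are expected to
be parameterized against room-temperature chemistry, so no thermal or
entropic corrections are applied anywhere in the ledger. Solvent is
implicit (dielectric continuum); counterions are deliberately absent, which
shifts absolute heats of reaction but cancels in every per-residue
difference.

A complex, its sibling complex (the competing substrate) and the apo (NUL)
system form one *chain family*. Within a family, every mutated residue has
exactly one geometry — the rigid fragment — transplanted bit-identically
into every system, and all ledgered energies are single points. This is
what eliminates optimizer noise from the differences: two ledger cells can
disagree only through real interactions, not through re-optimization
artifacts.

## Protocol stages

1. *Restrained optimization*: all atoms movable under a harmonic bias
   toward the starting geometry. The penalty is ½·k·d² per atom with
   k = 3 kcal mol⁻¹ Å⁻² (gradient equals the nominal 3 kcal mol⁻¹ Å⁻¹
   restraining force at 1 Å displacement). The harmonic form is a design
   choice — only the force magnitude is standard — and k is a plan
   parameter, not a constant in code.
2. *Free pocket optimization*: movable set = all atoms within the pocket
   cutoff (default 5.0 Å) of any substrate atom, selection atom-granular;
   no restraint. For the apo system the pocket is selected around the
   recorded coordinates of the departed substrate. Pocket waters inside
   the cutoff are movable. Frozen atoms are excluded from the optimization
   variables entirely, so they are bit-identical by construction, not by
   tolerance.
3. *Mutant fragment generation*: each scan target is mutated on the
   family's oxidized-complex stage-2 geometry (the choice of source
   complex is immaterial when the pockets match; the cross-placement check
   measures exactly this) and locally re-optimized with the mutated
   residue plus the pocket movable. The mutated residue's atoms are stored
   as the family's shared rigid fragment. The binding-site water is
   scanned with a deletion operator (empty fragment), through the same
   stage-4 pathway as the residues.
4. *Rigid single points*: fragments transplanted into every system, single
   point energies recorded. Ledger cells are immutable once written;
   re-running the stage must reproduce them bit-for-bit.

### Audits

- *Cross-placement check*: fragments regenerated from (or perturbed
  toward) the sibling complex are substituted and the single-point
  energies compared; the default pass threshold is 0.1 kcal mol⁻¹ per
  residue.
- *Far-residue audit*: residues entirely outside the cutoff are truncated
  to alanine with local re-optimization; the change in the
  oxidized-minus-normal energy difference is reported (max and mean
  absolute). Any sizeable value indicates spurious coupling.
- *Water-distortion probe*: local optimization with and without a
  candidate water; the record reports the pocket RMSD between the two
  outcomes, watched donor–acceptor distance changes, and both energies.
  It renders no verdict — a distortion that vanishes when the water is
  present is evidence for an unresolved water, to be weighed by the user.

## Mutation operators

Side-chain truncation removes every atom beyond Cβ and completes the Cβ
methyl to exactly three hydrogens (1.09 Å, tetrahedral, staggered about the
Cα–Cβ bond relative to the backbone N — fully deterministic). Gly, Pro and
Ala are refused rather than improvised. The lysine operator excises the
terminal –NH₃⁺ and caps Cε with one hydrogen along the former Cε→Nζ
direction (charge delta −1). Substrate interconversion (oxidized↔normal
guanine) deletes H7 and re-types O8 as H8 along the former C8→O8 direction
— reusing that direction rather than idealizing sp² geometry minimizes the
perturbation, and the pocket is re-optimized afterwards anyway. Substrate
deletion takes an explicit charge policy: by default the substrate departs
with its modelled charge and the pocket anion relocalizes (a −1 complex
gives a neutral apo system); the proton-retained alternative leaves the apo
system at +1 and models the substrate as a dianion. Both policies exist
because the two aspartates of the recognition pocket share an ionizable
proton with the substrate, and their contributions are only well defined
against the reference state that keeps that proton fixed.

Every operator returns a record (atoms removed/added, charge delta) whose
bookkeeping is checked against the observed system changes, and serializes
to a line-oriented audit log.

## Energy backends

The backend contract is two operations: `single_point` and `optimize`
(movable set, optional restraint), returning ΔH_f, convergence status and
the final geometry.

**Surrogate.** A strictly pairwise potential: per class-pair terms
E(r) = depth·(2(re/r)⁶ − (re/r)¹²) (value exactly `depth` at r = re),
optional H-bond terms of the same form, and an optional scaled Coulomb term
over formal point charges. Atom classes come from an explicit per-atom map
with an element-based donor/acceptor fallback. Pairwise additivity is
exact, which is what the protocol oracles exploit: the binding contribution
of a residue must equal the brute-force cross-interaction sum between its
removed atoms and the substrate. Optimization is L-BFGS-B with analytic
gradients (gtol 10⁻¹⁰); frozen atoms never enter the variable vector. The
surrogate has no explicit solvent; it accepts the epsilon argument for
interface parity only.

**Engine adapter.** Input decks carry a keyword line (PM7-class
Hamiltonian, localized-orbital mode, implicit-solvent epsilon, total
charge, 1SCF for single points), one atom per line with per-coordinate 0/1
movability flags, and the restraint as a reference-geometry file plus
`GEO_FORCE` keyword. The parser extracts the final heat of formation, the
last Cartesian block and a convergence verdict; truncated output yields
`converged=False` with the last cycle energy, and output with no energy at
all raises — a number is never invented. The adapter shells out per
evaluation and treats the engine as a black box.

### Recipe for engine-backed runs

To reproduce engine-level quantities (binding-site RMSD against the
crystal structure, solution-phase conformer energies, the far-residue
audit on the real enzyme): obtain the hydrogenated, ionized chain-A and
chain-B systems derived from PDB 3ZR0 (net charge −1 each), set
`POCKETSCAN_ENGINE` to the engine executable, select the `mopac` backend
in the run config, and use the same plan defaults (5.0 Å cutoff,
3 kcal mol⁻¹ Å⁻¹ restraint, ε = 78.4). These runs take minutes per single
point on a desktop-class machine and are not part of the test suite.

## Synthetic pockets and what they do (and do not) show

`fixtures.generate_pocket` builds a small ligand (an interaction hub plus
inert atoms, optionally an oxidized/normal site pair) surrounded by
truncatable mini-residues, each with one interacting side-chain atom
carrying its own atom class. The pair term between that class and the
ligand is calibrated by direct evaluation so the residue–ligand
cross-interaction equals the planted energy (a guard of 10⁻³ kcal mol⁻¹ is
enforced at generation time); in two-ligand mode a second term against the
oxidized site plants the per-residue specificity. Far control residues are
placed beyond every interaction. Because each interacting pair sits exactly
at its equilibrium distance, the generated geometry is a stationary point
of the surrogate: the protocol stages are then deterministic to the last
bit, and recovery of planted energies isolates the protocol's bookkeeping
from optimizer behaviour. Planted binding energies default to a moderate
attractive range (−8 to −0.5 kcal mol⁻¹) and specificities to −3 to +0.5,
matching the magnitudes typical of pocket residues; seeds are the only
source of randomness in the package.

Toy pockets deliberately do not emulate: proton transfer / charge
migration (handled instead by explicit charge policies), many-body
polarization, conformational strain, or solvent structure. A passing
recovery test therefore certifies the protocol's arithmetic and its
frozen/rigid contracts — not the physical accuracy of any real-system
prediction, which is inherited entirely from the backend.

## Numerical choices and degenerate inputs

- Comparison tolerances for recorded-table regressions: 0.02 kcal mol⁻¹
  per cell and 0.03 for column sums, because published tables are rounded
  to 0.01 and 13-cell sums accumulate that rounding.
- Pair-term keys are order-normalized; equilibrium distances must be
  positive; well depths are ≤ 0 for attractive classes by convention.
- Coincident atoms (r < 10⁻¹²) raise rather than returning infinities.
- The RMSD is computed in the shared crystal frame without superposition:
  the protocol restrains toward that frame, and a fit would mask exactly
  the drift being measured.
- PDB I/O preserves 1-based serials and insertion codes; serials above
  99999 are refused (format width). Water detection is by residue name
  (HOH/WAT). Formal charges are supplied via the charge map, never
  inferred.
- Empty systems have zero surrogate energy; optimization with an empty
  movable set is an error (use a single point).

## Known limitations

- Additivity is an approximation; the gap between the summed per-residue
  contributions and the full heat of reaction (cooperative terms such as
  the aspartate-pair proton transfer) is reported, not resolved.
- Only the scan operator set is supported — no general point mutations or
  rotamer search.
- No mmCIF input, no protonation-state prediction: structures arrive
  hydrogenated with charges declared.
- The surrogate optimizer is adequate for fixture-scale systems only; real
  systems go through the external engine.
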