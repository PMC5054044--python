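"""Four-stage protocol: stage contracts, audits, determinism."""

import numpy as np
import pytest

from pocketscan.backend import SurrogateBackend
from pocketscan.fixtures import ToyPocketSpec, generate_pocket
from pocketscan.mutations import FragmentGeometry, MutationOperator
from pocketscan.protocol import ResidueScan, ScanPlan, ScanTarget
from pocketscan.structure import ResidueKey, rmsd, select_region

from conftest import make_atom, oracle_cross_energy


@pytest.fixture
def pocket():
    return generate_pocket(
        ToyPocketSpec(n_residues=4, two_ligand_mode=True, include_water=True, seed=42)
    )


@pytest.fixture
def scan(pocket):
    return ResidueScan(SurrogateBackend(pocket.params), pocket.plan)


@pytest.fixture
def result(scan, pocket):
    return scan.run(pocket.systems)


class TestPlanValidation:
    def test_identity_operator_rejected(self, pocket):
        with pytest.raises(ValueError, match="not a scan operator"):
            ScanTarget(
                ResidueKey("T", 1, "", "LEU"), MutationOperator.IDENTITY, "x"
            )

    def test_duplicate_labels_rejected(self, pocket):
        with pytest.raises(ValueError, match="distinct"):
            ScanPlan(
                chain_family="T",
                label_oxidized="X",
                label_null="X",
                substrate=pocket.plan.substrate,
                targets=pocket.plan.targets,
            )


class TestStageContracts:
    def test_stage2_frozen_atoms_bit_identical(self, scan, pocket):
        sys_ = pocket.systems["TOY-OXI"]
        region = select_region(sys_, pocket.plan.substrate, pocket.plan.cutoff)
        res = scan.stage2_free_pocket_optimize(sys_, pocket.plan.substrate)
        for a in sys_.atoms:
            if a.serial not in region.atom_ids:
                assert np.array_equal(
                    res.geometry.by_serial(a.serial).coords, a.coords
                )

    def test_stage2_energy_not_above_stage1_single_point(self, scan, pocket):
        be = scan.backend
        sys_ = pocket.systems["TOY-OXI"]
        e1 = be.single_point(sys_).heat_of_formation
        res = scan.stage2_free_pocket_optimize(sys_, pocket.plan.substrate)
        assert res.heat_of_formation <= e1 + 1e-9

    def test_zero_restraint_equals_plain_optimize(self, pocket):
        plan = pocket.plan
        plan0 = ScanPlan(
            chain_family=plan.chain_family,
            label_oxidized=plan.label_oxidized,
            label_normal=plan.label_normal,
            label_null=plan.label_null,
            substrate=plan.substrate,
            targets=plan.targets,
            restraint_constant=0.0,
        )
        be = SurrogateBackend(pocket.params)
        scan0 = ResidueScan(be, plan0)
        sys_ = pocket.systems["TOY-OXI"]
        res = scan0.stage1_restrained_optimize(sys_, sys_)
        plain = be.optimize(sys_, {a.serial for a in sys_.atoms}, None)
        assert res.heat_of_formation == plain.heat_of_formation
        assert np.array_equal(
            res.geometry.coords_array(), plain.geometry.coords_array()
        )

    def test_restraint_pulls_geometry_toward_reference(self):
        """Starting away from the reference, the restrained optimum stays
        nearer to it than the unrestrained optimum does."""
        pocket = generate_pocket(ToyPocketSpec(n_residues=3, seed=7))
        be = SurrogateBackend(pocket.params)
        scan = ResidueScan(be, pocket.plan)
        reference = pocket.systems["TOY-OXI"]
        displaced = reference.copy()
        rng = np.random.default_rng(0)
        for a in displaced.atoms:
            if pocket.params.atom_class(a).startswith("SC"):
                a.coords = a.coords + rng.normal(0, 0.35, 3)
        restrained = scan.stage1_restrained_optimize(displaced, reference)
        free = be.optimize(displaced, {a.serial for a in displaced.atoms}, None)
        assert rmsd(reference, restrained.geometry) <= rmsd(reference, free.geometry)

    def test_stage3_produces_one_fragment_per_target(self, result, pocket):
        assert set(result.fragments) == {
            t.mutation_id for t in pocket.plan.targets
        }
        assert result.stage_errors == {}

    def test_stage3_regeneration_is_bit_identical(self, scan, result, pocket):
        frags2, _, _ = scan.stage3_generate_mutant_fragments(
            result.stage2_geometries[pocket.plan.label_oxidized]
        )
        for mid, frag in result.fragments.items():
            again = frags2[mid]
            assert [a.name for a in again.atoms] == [a.name for a in frag.atoms]
            for a, b in zip(frag.atoms, again.atoms):
                assert np.array_equal(a.coords, b.coords)

    def test_stage4_ledger_entry_count(self, result, pocket):
        n_targets = len(pocket.plan.targets)
        n_systems = len(pocket.plan.system_labels())
        assert len(result.ledger.entries) == n_targets * n_systems
        assert len(result.ledger.unmutated) == n_systems

    def test_stage4_rerun_is_bit_reproducible(self, scan, result):
        again = scan.stage4_rigid_single_points(
            result.stage2_geometries, result.fragments
        )
        assert again.unmutated == result.ledger.unmutated
        for key, cell in result.ledger.entries.items():
            assert again.entries[key].value == cell.value


class TestCrossPlacement:
    def test_shared_fragments_give_exactly_zero(self, scan, result):
        report = scan.cross_placement_check(
            result.stage2_geometries, result.fragments
        )
        assert report.max_discrepancy == 0.0
        assert report.passed

    def test_perturbed_sibling_fragment_is_flagged(self, scan, result, pocket):
        # let the truncated fragments interact weakly with the ligand so a
        # geometry difference is visible in the single-point energies
        pocket.params.set_pair_term("C", "LIG_HUB", -0.5, 3.5)
        sibling = {}
        for mid, frag in result.fragments.items():
            atoms = [a.copy() for a in frag.atoms]
            for a in atoms:  # plant a 0.5 A displacement
                a.coords = a.coords + np.array([0.5, 0.0, 0.0])
            sibling[mid] = FragmentGeometry(
                frag.fragment_id + "-perturbed", frag.chain_family,
                frag.residue_key, atoms,
            )
        report = scan.cross_placement_check(
            result.stage2_geometries, result.fragments, sibling
        )
        assert report.max_discrepancy > 0.0

    def test_threshold_default_honoured(self, pocket):
        assert pocket.plan.cross_check_threshold == 0.1


class TestFarResidueAudit:
    def test_out_of_range_controls_change_nothing(self, scan, result, pocket):
        audit = scan.far_residue_audit(
            result.stage2_geometries["TOY-OXI"],
            result.stage2_geometries["TOY-NOR"],
            pocket.far_residues,
        )
        assert audit.max_abs_change == 0.0
        assert audit.mean_abs_change == 0.0

    def test_pocket_residue_is_refused(self, scan, result, pocket):
        inside = pocket.plan.targets[0].residue
        with pytest.raises(ValueError, match="within the"):
            scan.far_residue_audit(
                result.stage2_geometries["TOY-OXI"],
                result.stage2_geometries["TOY-NOR"],
                [inside],
            )

    def test_weak_long_range_tail_matches_oracle(self):
        """With a deliberate far-reaching term, the audit equals a direct
        recomputation of the coupling from the pair potential."""
        pocket = generate_pocket(ToyPocketSpec(n_residues=3, two_ligand_mode=True, seed=5))
        # couple one far residue's CG to the oxidized site only, at its
        # current separation so no other atom feels a force
        oxi = pocket.systems["TOY-OXI"]
        far = pocket.far_residues[0]
        d = float(np.linalg.norm(
            oxi.atom(far, "CG").coords
            - oxi.atom(pocket.plan.substrate, "O8").coords
        ))
        pocket.params.class_map[(far, "CG")] = "FARSC"
        pocket.params.pair_terms[("FARSC", "OXO_SITE")] = (-0.4, d)
        be = SurrogateBackend(pocket.params)
        scan = ResidueScan(be, pocket.plan)
        nor = pocket.systems["TOY-NOR"]
        audit = scan.far_residue_audit(oxi, nor, [far])
        cg = [oxi.atom(far, "CG")]
        lig = oxi.residue_atoms(pocket.plan.substrate)
        # truncating the far side chain removes its coupling from the
        # oxidized system only, so the 8OG-GMP difference shifts by -coupling
        expected = oracle_cross_energy(cg, lig, pocket.params)
        assert expected == pytest.approx(-0.4, abs=1e-9)
        name = f"{far.resname}{far.seqid}"
        assert audit.changes[name] == pytest.approx(-expected, abs=1e-6)


class TestWaterProbe:
    def _template(self, origin):
        key = ResidueKey("T", 998, "", "HOH")
        o = np.asarray(origin, dtype=float)
        return [
            make_atom(1, "O", "O", key, o, het=True),
            make_atom(2, "H1", "H", key, o + [0.76, 0.59, 0], het=True),
            make_atom(3, "H2", "H", key, o + [-0.76, 0.59, 0], het=True),
        ], key

    def test_non_interacting_water_changes_nothing(self, scan, pocket):
        template, key = self._template([0.0, 2.5, 0.0])
        record = scan.water_distortion_probe(
            pocket.systems["TOY-OXI"], template, key
        )
        assert record.pocket_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_site_outside_pocket_is_error(self, scan, pocket):
        template, key = self._template([40.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="outside"):
            scan.water_distortion_probe(pocket.systems["TOY-OXI"], template, key)

    def test_water_bridged_minimum_reduces_distortion(self):
        """A planted inward distortion of a pocket side chain persists when
        the pocket is optimized without the water, but the water's contact
        pushes the side chain back toward its undistorted position."""
        pocket = generate_pocket(
            ToyPocketSpec(n_residues=3, planted_energies={0: 0.0}, seed=13)
        )
        sys_ = pocket.systems["TOY-OXI"].copy()
        key0 = pocket.plan.targets[0].residue  # interaction-free residue
        hub = sys_.atom(pocket.plan.substrate, "L1").coords
        cg_atom = sys_.atom(key0, "CG")
        cg0 = cg_atom.coords.copy()
        r0 = float(np.linalg.norm(cg0 - hub))
        # water on the hub-CG axis, in contact with the undistorted CG
        wkey = ResidueKey("T", 998, "", "HOH")
        o_pos = cg0 * (1.0 - 2.8 / r0)
        pocket.params.class_map[(wkey, "O")] = "WPROBE"
        pocket.params.set_pair_term("WPROBE", "SC0", -500.0, 2.8)
        template = [
            make_atom(1, "O", "O", wkey, o_pos, het=True),
            make_atom(2, "H1", "H", wkey, o_pos + [0.76, 0.59, 0], het=True),
            make_atom(3, "H2", "H", wkey, o_pos + [-0.76, 0.59, 0], het=True),
        ]
        # plant the distortion: CG pressed 0.5 A inward, into the water's
        # repulsive wall
        cg_atom.coords = cg0 * (1.0 - 0.5 / r0)
        scan = ResidueScan(SurrogateBackend(pocket.params), pocket.plan)
        record = scan.water_distortion_probe(
            sys_, template, wkey,
            watch_distances={"CG-hub": (
                (key0, "CG"), (pocket.plan.substrate, "L1"),
            )},
        )
        assert record.pocket_rmsd > 0.05  # outcomes genuinely differ
        # with the water present, CG moves back outward; without it, the
        # distortion persists (the residue feels no other force)
        assert record.distance_changes["CG-hub"] > 0.1
        assert record.energy_with < record.energy_without
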