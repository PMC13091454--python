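import numpy as np
import pytest

from fibrilsolv import FibrilRecipe, make_fibril
from fibrilsolv.fibril_geometry import central_chain_ids
from fibrilsolv.solvation_energetics import (
    AspTable,
    ChainEnergySummary,
    ClassificationError,
    CompensationEntry,
    CompensationSpec,
    apply_charge_compensation,
    builtin_compensation_specs,
    chain_summary,
    residue_energies,
)
from fibrilsolv.structure_io import AtomRecord
from fibrilsolv.surface_area import AtomAreas, buried_areas
from fibrilsolv.synthetic_fibrils import RESIDUE_TEMPLATES, make_energy_fixture

N_POINTS = 240  # coarse but deterministic; plenty for bookkeeping tests


def atom(name, element, res_name, res_seq, chain="A"):
    return AtomRecord(1, name, element, "", res_name, chain, res_seq, (0.0, 0.0, 0.0))


def areas_for(atoms, buried):
    buried = np.asarray(buried, dtype=float)
    ref = buried + 5.0
    return AtomAreas(atoms=list(atoms), reference=ref, assembly=ref - buried)


@pytest.fixture(scope="module")
def fixture_stack():
    return make_energy_fixture(n_sphere_points=N_POINTS)


@pytest.fixture(scope="module")
def central_areas(fixture_stack):
    stack, _, _ = fixture_stack
    (cid,) = central_chain_ids(stack)
    return cid, buried_areas(stack, cid, n_sphere_points=N_POINTS)


class TestAspTable:
    def test_default_loads(self):
        asp = AspTable.default()
        assert asp.parameters["apolar_C"] == pytest.approx(0.016)
        assert asp.parameters["charged_N_plus"] == pytest.approx(-0.050)

    def test_sign_invariant_enforced(self):
        with pytest.raises(ValueError, match="opposite"):
            AspTable(parameters={
                "apolar_C": 0.016, "polar_N_O": -0.006,
                "carboxylate_O_minus": -0.024, "charged_N_plus": 0.05, "sulfur": 0.021,
            })

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            AspTable(parameters={"apolar_C": 0.016})

    @pytest.mark.parametrize("res,name,expected", [
        ("ALA", "CB", "apolar_C"),
        ("GLY", "N", "polar_N_O"),
        ("SER", "OG", "polar_N_O"),
        ("ASP", "OD1", "carboxylate_O_minus"),
        ("GLU", "OE2", "carboxylate_O_minus"),
        ("ALA", "OXT", "carboxylate_O_minus"),
        ("LYS", "NZ", "charged_N_plus"),
        ("ARG", "NH1", "charged_N_plus"),
        ("ARG", "NE", "charged_N_plus"),
        ("HIS", "ND1", "polar_N_O"),  # baseline: polar, compensable via spec
        ("MET", "SD", "sulfur"),
        ("CYS", "SG", "sulfur"),
    ])
    def test_classification(self, res, name, expected):
        assert AspTable.default().classify(res, name) == expected

    def test_histidine_charged_option(self):
        asp = AspTable(parameters=AspTable.default().parameters, histidine_charged=True)
        assert asp.classify("HIS", "NE2") == "charged_N_plus"

    def test_every_standard_heavy_atom_classifiable(self):
        asp = AspTable.default()
        for res, side in RESIDUE_TEMPLATES.items():
            for name in ["N", "CA", "C", "O", *side]:
                assert asp.classify(res, name) in asp.parameters

    def test_unclassifiable_atom_raises(self):
        with pytest.raises(ClassificationError):
            AspTable.default().classify("HEM", "FE", element="FE")


class TestResidueEnergies:
    def test_zero_burial_gives_zero(self):
        areas = areas_for([atom("CB", "C", "ALA", 1), atom("NZ", "N", "LYS", 2)], [0.0, 0.0])
        profile = residue_energies(areas)
        assert np.all(profile.energies == 0.0)

    def test_hand_arithmetic_carbon(self):
        areas = areas_for([atom("CB", "C", "ALA", 1)], [10.0])
        profile = residue_energies(areas)
        assert profile.energies[0] == pytest.approx(-0.16, abs=1e-12)

    def test_buried_lysine_nitrogen_is_destabilizing(self):
        areas = areas_for([atom("NZ", "N", "LYS", 1)], [20.0])
        profile = residue_energies(areas)
        assert profile.energies[0] == pytest.approx(1.0, abs=1e-12)
        assert profile.energies[0] > 0

    def test_chain_total_is_residue_sum(self, central_areas):
        cid, areas = central_areas
        profile = residue_energies(areas)
        assert profile.chain_total(cid) == pytest.approx(profile.energies.sum(), abs=1e-9)

    def test_scale_covariance(self, central_areas):
        _, areas = central_areas
        asp = AspTable.default()
        doubled = residue_energies(areas, asp.scaled(2.0))
        assert np.allclose(doubled.energies, 2.0 * residue_energies(areas, asp).energies,
                           atol=1e-12)


class TestChainSummary:
    def test_two_residue_arithmetic(self):
        areas = areas_for(
            [atom("CB", "C", "ALA", 1), atom("NZ", "N", "LYS", 2)],
            [62.5, 5.0],
        )  # -0.016*62.5 = -1.0 ; +0.05*5 = +0.25
        profile = residue_energies(areas)
        summ = chain_summary(profile, "A")
        assert summ.dG_chain == pytest.approx(-0.75, abs=1e-12)
        assert summ.dG_residue == pytest.approx(-0.375, abs=1e-12)
        assert summ.n_ordered_residues == 2

    def test_per_residue_identity(self, central_areas):
        cid, areas = central_areas
        summ = chain_summary(residue_energies(areas), cid)
        assert summ.dG_residue * summ.n_ordered_residues == pytest.approx(
            summ.dG_chain, abs=1e-9)

    def test_polyalanine_fibril_chain_is_stabilized(self):
        stack = make_fibril(FibrilRecipe("AAAAAAAA", n_layers=5))
        (cid,) = central_chain_ids(stack)
        areas = buried_areas(stack, cid, n_sphere_points=N_POINTS)
        summ = chain_summary(residue_energies(areas), cid)
        assert summ.dG_chain < 0

    def test_empty_chain_errors(self, central_areas):
        _, areas = central_areas
        with pytest.raises(KeyError):
            chain_summary(residue_energies(areas), "Z")

    def test_summary_invariant(self):
        with pytest.raises(ValueError):
            ChainEnergySummary(label="x", dG_chain=-1.0, n_ordered_residues=0,
                               compensated=False)


class TestCompensationSpec:
    def test_only_krh_admitted(self):
        with pytest.raises(ValueError, match="Lys/Arg/His"):
            CompensationEntry(res_seq=5, res_name="ALA")

    def test_derived_atom_counts(self):
        assert CompensationEntry(1, "LYS").atom_names == ("NZ",)
        assert CompensationEntry(1, "ARG").atom_names == ("NE", "NH1", "NH2")
        assert CompensationEntry(1, "HIS").atom_names == ("ND1", "NE2")

    def test_builtin_specs(self):
        specs = builtin_compensation_specs()
        assert len(specs["7sp1"]) == 1
        assert specs["7sp1"].n_nitrogens == 3  # one arginine
        assert len(specs["9o8e"]) == 8
        assert {e.res_seq for e in specs["9o8e"].entries} == {
            343, 347, 349, 370, 375, 379, 383, 385}
        assert len(specs["9o8h"]) == 5
        assert specs["9o8h"].n_nitrogens == 3 * 1 + 2 * 2  # 3 Lys NZ + 2 His ring pairs
        assert len(specs["9o8e_density_proximity"]) == 7


class TestApplyChargeCompensation:
    def test_empty_spec_is_identity(self, central_areas):
        _, areas = central_areas
        plain = residue_energies(areas)
        comp = apply_charge_compensation(areas, spec=CompensationSpec())
        assert np.array_equal(comp.energies, plain.energies)
        assert not comp.compensated.any()

    def test_zero_burial_spec_changes_nothing(self):
        areas = areas_for([atom("NZ", "N", "LYS", 7), atom("CB", "C", "LYS", 7)], [0.0, 4.0])
        spec = CompensationSpec.from_residues([(7, "K")])
        comp = apply_charge_compensation(areas, spec=spec)
        plain = residue_energies(areas)
        assert np.allclose(comp.energies, plain.energies, atol=1e-12)
        assert comp.compensated.all()  # flagged even though nothing removed

    def test_delta_equals_independent_resummation(self, fixture_stack, central_areas):
        stack, spec, expected_ddg = fixture_stack
        cid, areas = central_areas
        plain = chain_summary(residue_energies(areas), cid)
        comp = chain_summary(apply_charge_compensation(areas, spec=spec), cid)
        assert comp.dG_chain - plain.dG_chain == pytest.approx(expected_ddg, abs=1e-9)
        assert expected_ddg <= 0
        assert expected_ddg < 0  # the ladder lysines really are buried

    def test_compensation_never_increases_energy(self, central_areas):
        cid, areas = central_areas
        lys = sorted({a.res_seq for a in areas.atoms if a.res_name == "LYS"})
        plain = chain_summary(residue_energies(areas), cid)
        for k in range(len(lys) + 1):
            spec = CompensationSpec.from_residues([(s, "K") for s in lys[:k]])
            comp = chain_summary(apply_charge_compensation(areas, spec=spec), cid)
            assert comp.dG_chain <= plain.dG_chain + 1e-12

    def test_negative_nitrogen_terms_untouched(self):
        # an exposed Arg NE with zero burial plus a buried one: only the
        # positive (penalty) terms may be zeroed
        areas = areas_for(
            [atom("NE", "N", "ARG", 3), atom("NH1", "N", "ARG", 3),
             atom("NH2", "N", "ARG", 3)],
            [8.0, 0.0, 2.0],
        )
        spec = CompensationSpec.from_residues([(3, "R")])
        comp = apply_charge_compensation(areas, spec=spec)
        assert comp.energies[0] == pytest.approx(0.0, abs=1e-12)

    def test_absent_residue_rejected(self, central_areas):
        _, areas = central_areas
        spec = CompensationSpec.from_residues([(999, "K")])
        with pytest.raises(ValueError, match="999"):
            apply_charge_compensation(areas, spec=spec)

    def test_wrong_residue_type_rejected(self, central_areas):
        _, areas = central_areas
        leu_seq = next(a.res_seq for a in areas.atoms if a.res_name == "LEU")
        spec = CompensationSpec.from_residues([(leu_seq, "K")])
        with pytest.raises(ValueError, match="model has LEU"):
            apply_charge_compensation(areas, spec=spec)


class TestParameterSanity:
    def test_lysine_ladder_less_stable_than_leucine(self):
        """A charged ladder destabilizes; compensating it recovers the NZ terms."""
        lys_stack = make_fibril(FibrilRecipe("LKLLKL", n_layers=5))
        leu_stack = make_fibril(FibrilRecipe("LLLLLL", n_layers=5))
        (cid,) = central_chain_ids(lys_stack)
        areas_k = buried_areas(lys_stack, cid, n_sphere_points=N_POINTS)
        areas_l = buried_areas(leu_stack, central_chain_ids(leu_stack)[0],
                               n_sphere_points=N_POINTS)
        dg_k = chain_summary(residue_energies(areas_k), cid).dG_chain
        dg_l = chain_summary(residue_energies(areas_l), cid).dG_chain
        assert dg_k > dg_l  # lysine version less stable
        spec = CompensationSpec.from_residues([(2, "K"), (5, "K")])
        comp = chain_summary(apply_charge_compensation(areas_k, spec=spec), cid)
        # compensation removes exactly the NZ penalty part of the difference
        asp = AspTable.default()
        nz_penalty = sum(
            max(0.0, -asp.parameters["charged_N_plus"] * areas_k.buried[i])
            for i, a in enumerate(areas_k.atoms) if a.name == "NZ"
        )
        assert (chain_summary(residue_energies(areas_k), cid).dG_chain
                - comp.dG_chain) == pytest.approx(nz_penalty, abs=1e-9)
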