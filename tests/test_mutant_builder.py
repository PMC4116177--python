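"""Side-chain rebuilding, clash scoring and aromatic proximity."""

import math

import numpy as np
import pytest

from erdesign.mutant_builder import (
    CHI_COUNT,
    ClashParameters,
    ClashReport,
    RotamerLibrary,
    aromatic_proximity,
    apply_placement,
    best_placement,
    clash_score,
    load_rotamer_library,
    mutate_residue,
    score_placements,
)
from erdesign.structure_io import ResidueKey, StructureModel, read_pdb, select_ligand, write_pdb

from conftest import make_atom


def dihedral(p0, p1, p2, p3):
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    return math.degrees(math.atan2(np.dot(np.cross(b1n, v), w), np.dot(v, w)))


class TestRotamerLibrary:
    def test_chi_counts_match_residue_types(self):
        lib = load_rotamer_library()
        for res, rotamers in lib.rotamers.items():
            for chis in rotamers:
                assert len(chis) == CHI_COUNT[res]

    def test_phe_has_six_rotamers(self):
        lib = load_rotamer_library()
        assert len(lib.for_residue("PHE")) == 6


class TestMutateResidue:
    def test_glycine_target_has_no_side_chain(self, toy_met_complex):
        model, res, _ = toy_met_complex
        placements = mutate_residue(model, res, "G")
        assert len(placements) == 1
        assert placements[0].atoms == []
        assert clash_score(model, placements[0]).total == 0.0

    def test_one_placement_per_library_rotamer(self, toy_met_complex):
        model, res, _ = toy_met_complex
        lib = load_rotamer_library()
        placements = mutate_residue(model, res, "F")
        assert len(placements) == len(lib.for_residue("PHE"))

    def test_rebuilt_phe_geometry(self, toy_met_complex):
        model, res, _ = toy_met_complex
        p = mutate_residue(model, res, "F")[0]
        names = [a.name for a in p.atoms]
        assert names == ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
        ring = np.array([a.coords for a in p.atoms if a.name != "CB"])
        centred = ring - ring.mean(axis=0)
        normal = np.linalg.svd(centred)[2][2]
        assert np.abs(centred @ normal).max() < 0.05  # planar
        pos = {a.name: a.coords for a in p.atoms}
        for bond in (("CG", "CD1"), ("CD1", "CE1"), ("CE1", "CZ"), ("CZ", "CE2")):
            assert np.linalg.norm(pos[bond[0]] - pos[bond[1]]) == pytest.approx(1.39, abs=0.02)

    def test_chi_angles_are_honoured(self, toy_met_complex):
        model, res, _ = toy_met_complex
        p = mutate_residue(model, res, "F", RotamerLibrary({"PHE": [(-65.0, 90.0)]}))[0]
        by_name = {a.name: a.coords for a in model.residues[res]}
        pos = {a.name: a.coords for a in p.atoms}
        chi1 = dihedral(by_name["N"], by_name["CA"], pos["CB"], pos["CG"])
        chi2 = dihedral(by_name["CA"], pos["CB"], pos["CG"], pos["CD1"])
        assert chi1 == pytest.approx(-65.0, abs=0.5)
        assert chi2 == pytest.approx(90.0, abs=0.5)

    def test_self_mutation_with_native_chis_reproduces_side_chain(self, toy_met_complex):
        model, res, _ = toy_met_complex
        by_name = {a.name: a.coords for a in model.residues[res]}
        chis = (
            dihedral(by_name["N"], by_name["CA"], by_name["CB"], by_name["CG"]),
            dihedral(by_name["CA"], by_name["CB"], by_name["CG"], by_name["SD"]),
            dihedral(by_name["CB"], by_name["CG"], by_name["SD"], by_name["CE"]),
        )
        p = mutate_residue(model, res, "M", RotamerLibrary({"MET": [chis]}))[0]
        for a in p.atoms:
            assert np.linalg.norm(a.coords - by_name[a.name]) < 0.5

    def test_missing_backbone_rejected(self):
        res = ResidueKey("A", 1, "", "ALA")
        model = StructureModel("x", {res: [make_atom("CA", "C", [0, 0, 0])]})
        with pytest.raises(ValueError, match="backbone"):
            mutate_residue(model, res, "F")

    def test_nonstandard_target_rejected(self, toy_met_complex):
        model, res, _ = toy_met_complex
        with pytest.raises(ValueError, match="standard"):
            mutate_residue(model, res, "XYZ")


class TestClashScore:
    def _pair_overlap(self, distance):
        """Overlap of an isolated C–C pair at the given distance."""
        res = ResidueKey("A", 10, "", "ALA")
        probe = ResidueKey("B", 50, "", "ALA")
        model = StructureModel(
            "x",
            {
                res: [
                    make_atom("N", "N", [0, 0, 0]),
                    make_atom("CA", "C", [1.46, 0, 0]),
                    make_atom("C", "C", [2.0, 1.4, 0]),
                ],
                probe: [make_atom("CA", "C", [1.46 + 0, 0, 0])],
            },
        )
        # place the single foreign atom `distance` away from the rebuilt CB
        placements = mutate_residue(model, res, "A")
        cb = placements[0].atoms[0].coords
        model.residues[probe][0] = make_atom("CA", "C", cb + np.array([0, 0, distance]))
        return clash_score(model, placements[0])

    def test_no_overlap_at_4_angstrom(self):
        report = self._pair_overlap(4.0)
        assert report.pairs == [] and not report.clashing

    def test_overlap_arithmetic_at_1_angstrom(self):
        report = self._pair_overlap(1.0)
        assert report.total == pytest.approx(1.7 + 1.7 - 1.0 - 0.4)
        assert report.max_overlap == report.total
        assert report.clashing

    def test_total_is_sum_of_pairs(self, toy_met_complex):
        model, res, _ = toy_met_complex
        placements = mutate_residue(model, res, "F")
        for rep in score_placements(model, placements):
            assert rep.total == pytest.approx(sum(o for _, _, o in rep.pairs))
            assert all(o > 0 for _, _, o in rep.pairs)

    @pytest.mark.parametrize("tol_pair", [(0.0, 0.4), (0.4, 0.8)])
    def test_nonincreasing_in_tolerance(self, toy_met_complex, tol_pair):
        model, res, _ = toy_met_complex
        placements = mutate_residue(model, res, "F")
        lo, hi = tol_pair
        for p in placements:
            t_lo = clash_score(model, p, ClashParameters(tolerance=lo)).total
            t_hi = clash_score(model, p, ClashParameters(tolerance=hi)).total
            assert t_hi <= t_lo + 1e-12

    def test_cramped_vs_roomy_pocket(self, toy_met_complex):
        model, res, lig_key = toy_met_complex
        # cramped: surround the residue with a tight carbon cage
        cage = {
            ResidueKey("C", 100 + i, "", "ALA"): [
                make_atom("CA", "C", xyz, serial=100 + i)
            ]
            for i, xyz in enumerate(
                [[3.5, -1.5, 2.0], [2.5, 0.5, 2.5], [4.0, 0.5, 0.5],
                 [3.0, -2.5, 0.0], [5.0, -0.5, 3.0], [2.0, -2.0, 3.0]]
            )
        }
        cramped = StructureModel("cramped", {**model.residues, **cage})
        placements_c = mutate_residue(cramped, res, "F")
        reports_c = score_placements(cramped, placements_c)
        assert all(r.clashing for r in reports_c)

        placements_r = mutate_residue(model, res, "F")
        reports_r = score_placements(model, placements_r)
        assert any(not r.clashing for r in reports_r)

    def test_unbound_state_ignores_ligand(self, toy_met_complex):
        model, res, lig_key = toy_met_complex
        # move the ring on top of where the side chain goes
        clashing_ring = {
            lig_key: [
                make_atom(f"C{i + 1}", "C", [2.5 + 0.3 * i, -1.0, 1.5], het=True)
                for i in range(6)
            ]
        }
        bound = StructureModel("bound", {**model.residues, **clashing_ring})
        p = mutate_residue(bound, res, "F")[0]
        with_lig = clash_score(bound, p, include_ligand=True)
        without = clash_score(bound, p, include_ligand=False)
        assert with_lig.total > without.total


class TestBestPlacement:
    def test_single_placement_is_itself(self, toy_met_complex):
        model, res, _ = toy_met_complex
        p = mutate_residue(model, res, "G")
        assert best_placement(p, [clash_score(model, p[0])]) is p[0]

    def test_argmin_of_totals(self, toy_met_complex):
        model, res, _ = toy_met_complex
        placements = mutate_residue(model, res, "F")[:3]
        reports = [
            ClashReport(pairs=[], total=t, max_overlap=t)
            for t in (2.1, 0.0, 0.7)
        ]
        assert best_placement(placements, reports) is placements[1]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_argmin(self, seed):
        rng = np.random.default_rng(seed)
        totals = rng.uniform(0, 5, size=8).round(3)
        maxes = totals * rng.uniform(0.1, 1.0, size=8)
        reports = [
            ClashReport(pairs=[], total=float(t), max_overlap=float(m))
            for t, m in zip(totals, maxes)
        ]
        placements = list(range(8))  # stand-ins; best_placement only indexes
        expected = min(
            range(8), key=lambda i: (reports[i].total, reports[i].max_overlap, i)
        )
        assert best_placement(placements, reports) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            best_placement([], [])


class TestAromaticProximity:
    def _ring(self, center, z, het=False, prefix="C"):
        out = []
        for i in range(6):
            a = np.deg2rad(60 * i)
            out.append(
                make_atom(
                    f"{prefix}{i + 1}",
                    "C",
                    [center[0] + 1.39 * np.cos(a), center[1] + 1.39 * np.sin(a), z],
                    het=het,
                )
            )
        return out

    def test_parallel_rings_centroid_distance(self, toy_met_complex):
        model, res, _ = toy_met_complex
        p = mutate_residue(model, res, "F")[0]
        ring_centroid = np.mean(
            [a.coords for a in p.atoms if a.name != "CB"], axis=0
        )
        lig_key = ResidueKey("L", 9, "", "XYZ")
        target = ring_centroid + np.array([0, 0, 3.8])
        lig_model = StructureModel(
            "lig", {**model.residues, lig_key: self._ring(target[:2], target[2], het=True)}
        )
        lig = select_ligand(read_pdb(write_pdb(lig_model)), "XYZ")
        rep = aromatic_proximity(p, lig, [f"C{i + 1}" for i in range(6)])
        assert rep.centroid_distance == pytest.approx(3.8, abs=0.01)

    def test_coincident_rings_give_zero(self, toy_met_complex):
        model, res, _ = toy_met_complex
        p = mutate_residue(model, res, "F")[0]
        names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
        pos = {a.name: a.coords for a in p.atoms}
        lig_key = ResidueKey("L", 9, "", "XYZ")
        copy = [
            make_atom(f"C{i + 1}", "C", pos[n], het=True) for i, n in enumerate(names)
        ]
        model2 = StructureModel("m", {**model.residues, lig_key: copy})
        lig = select_ligand(read_pdb(write_pdb(model2)), "XYZ")
        rep = aromatic_proximity(p, lig, [f"C{i + 1}" for i in range(6)])
        assert rep.centroid_distance == pytest.approx(0.0, abs=0.01)

    def test_auto_takes_nearest_of_two_rings(self, toy_met_complex):
        model, res, _ = toy_met_complex
        p = mutate_residue(model, res, "F")[0]
        centroid = np.mean([a.coords for a in p.atoms if a.name != "CB"], axis=0)
        near = self._ring((centroid[0], centroid[1]), centroid[2] + 4.0, het=True)
        far = self._ring((centroid[0] + 12, centroid[1]), centroid[2] + 4.0, het=True, prefix="D")
        lig_key = ResidueKey("L", 9, "", "BIS")
        model2 = StructureModel("m", {**model.residues, lig_key: near + far})
        lig = select_ligand(read_pdb(write_pdb(model2)), "BIS")
        rep = aromatic_proximity(p, lig, "auto")
        assert rep.centroid_distance == pytest.approx(4.0, abs=0.05)
        assert set(rep.ring_atoms_used[1]) == {f"C{i + 1}" for i in range(6)}

    def test_non_aromatic_placement_rejected(self, toy_met_complex):
        model, res, lig_key = toy_met_complex
        p = mutate_residue(model, res, "L")[0]
        lig = select_ligand(read_pdb(write_pdb(model)), "BPA")
        with pytest.raises(ValueError, match="aromatic"):
            aromatic_proximity(p, lig)

    def test_unresolvable_ring_atoms_rejected(self, toy_met_complex):
        model, res, _ = toy_met_complex
        p = mutate_residue(model, res, "F")[0]
        lig = select_ligand(read_pdb(write_pdb(model)), "BPA")
        with pytest.raises(ValueError, match="not found"):
            aromatic_proximity(p, lig, ["Q1", "Q2", "Q3", "Q4", "Q5", "Q6"])


class TestApplyPlacement:
    def test_mutant_model_swaps_side_chain(self, toy_met_complex):
        model, res, _ = toy_met_complex
        placements = mutate_residue(model, res, "F")
        reports = score_placements(model, placements)
        best = best_placement(placements, reports)
        mutant = apply_placement(model, best)
        new_key = next(k for k in mutant.residues if k.chain == "A")
        assert new_key.name == "PHE"
        names = {a.name for a in mutant.residues[new_key]}
        assert "SD" not in names and "CZ" in names and "N" in names
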