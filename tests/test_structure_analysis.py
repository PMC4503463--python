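import numpy as np
import pytest

from conftest import brute_force_salt_bridges, random_charged_structure
from thermocompare.seqstruct_io import Atom, Chain, Residue, Structure
from thermocompare.structure_analysis import (
    backbone_dihedrals,
    classify_rama,
    detect_salt_bridges,
    dihedral,
    peptide_planarity,
    rama_summary,
    salt_bridge_stats,
)
from thermocompare.synthetic_data import BackboneSpec, build_backbone


class TestDihedral:
    @pytest.mark.parametrize(
        "p4,expected",
        [((2, 1, 0), 180.0), ((0, 1, 0), 0.0), ((1, 1, 1), 90.0)],
    )
    def test_planar_and_perpendicular_arrangements(self, p4, expected):
        assert dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), p4) == pytest.approx(expected)

    def test_agrees_with_biopython_on_random_points(self):
        from Bio.PDB.vectors import Vector, calc_dihedral

        rng = np.random.default_rng(42)
        for _ in range(100):
            pts = rng.uniform(-5, 5, size=(4, 3))
            mine = dihedral(*pts)
            ref = float(np.degrees(calc_dihedral(*(Vector(*p) for p in pts))))
            if ref <= -180.0 + 1e-9:
                ref += 360.0
            assert mine == pytest.approx(ref, abs=1e-9)

    def test_collinear_points_error(self):
        with pytest.raises(ValueError, match="collinear"):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_range_half_open(self):
        ang = dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0))
        assert -180.0 < ang <= 180.0


def circ(a, b):
    """Smallest angular difference in degrees (treats +-180 as identical)."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


class TestBackboneDihedrals:
    def test_build_measure_round_trip(self, ideal_helix):
        for bd in backbone_dihedrals(ideal_helix):
            if bd.phi is not None:
                assert bd.phi == pytest.approx(-57.0, abs=1e-6)
            if bd.psi is not None:
                assert bd.psi == pytest.approx(-47.0, abs=1e-6)
            if bd.omega is not None:
                assert circ(bd.omega, 180.0) < 1e-6

    def test_per_residue_torsion_lists(self):
        phis = [-57.0, -65.0, -120.0, -80.0, -57.0]
        psis = [-47.0, -40.0, 130.0, 150.0, -47.0]
        s = build_backbone(BackboneSpec(n_residues=5, phi=phis, psi=psis, omega=180.0))
        bds = backbone_dihedrals(s)
        for i, bd in enumerate(bds):
            if bd.phi is not None:
                assert bd.phi == pytest.approx(phis[i], abs=1e-6)
            if bd.psi is not None:
                assert bd.psi == pytest.approx(psis[i], abs=1e-6)

    def test_terminal_residues(self):
        s = build_backbone(BackboneSpec(n_residues=3))
        s.chains[0].residues = s.chains[0].residues[:2]  # 2-residue chain
        first, last = backbone_dihedrals(s)
        assert first.phi is None and first.omega is None and first.psi is not None
        assert last.phi is not None and last.omega is not None and last.psi is None

    def test_chain_break_suppresses_spanning_angles(self):
        s = build_backbone(BackboneSpec(n_residues=6))
        for res in s.chains[0].residues[3:]:  # open a >2.5 A C-N gap
            for atom in res.atoms:
                atom.coords = atom.coords + np.array([100.0, 0.0, 0.0])
        bds = backbone_dihedrals(s)
        assert bds[3].phi is None and bds[3].omega is None
        assert bds[2].psi is None

    def test_missing_backbone_atom_skips_residue(self):
        s = build_backbone(BackboneSpec(n_residues=5))
        res = s.chains[0].residues[2]
        res.atoms = [a for a in res.atoms if a.name != "CA"]
        bds = backbone_dihedrals(s)
        assert len(bds) == 4
        assert bds[1].psi is None  # neighbour's dependent angle undefined
        assert bds[2].phi is None

    def test_rigid_motion_invariance(self, ideal_helix):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [31.0, -12.0, 77.0], degrees=True)
        moved = build_backbone(BackboneSpec(n_residues=20, phi=-57.0, psi=-47.0, omega=180.0))
        for res in moved.chains[0].residues:
            for atom in res.atoms:
                atom.coords = rot.apply(atom.coords) + np.array([5.0, -3.0, 11.0])
        before = backbone_dihedrals(ideal_helix)
        after = backbone_dihedrals(moved)
        for b, a in zip(before, after):
            for name in ("phi", "psi", "omega"):
                vb, va = getattr(b, name), getattr(a, name)
                assert (vb is None) == (va is None)
                if vb is not None:
                    assert circ(va, vb) < 1e-8


class TestClassifyRama:
    @pytest.mark.parametrize(
        "phi,psi,res,expected",
        [
            (-57, -47, "ALA", "helix"),
            (-120, 130, "ALA", "sheet"),
            (58, 40, "ALA", "left_helix"),
            (-70, 40, "ALA", "loop_turn"),
            (57, 47, "GLY", "left_helix"),
            (100, 150, "GLY", "sheet"),  # reachable only via the mirrored window
            (100, 150, "ALA", "outlier"),
            (120, -60, "ALA", "disallowed"),
            (120, -60, "GLY", "loop_turn"),  # mirrored bridging band, allowed for Gly
            (-57, -47, "PRO", "helix"),
            (-150, 130, "PRO", "outlier"),  # phi outside proline range
        ],
    )
    def test_window_classification(self, phi, psi, res, expected):
        assert classify_rama(phi, psi, res) == expected


def _two_residue_pair(dist, acid="ASP", base="LYS"):
    from thermocompare.structure_analysis import ACIDIC_ATOMS, BASIC_ATOMS

    r1 = Residue(chain_id="A", seq_number=1, res_name=acid)
    r1.atoms = [Atom("CA", (0, 0, 0), "C"), Atom(ACIDIC_ATOMS[acid][0], (1, 0, 0), "O")]
    r2 = Residue(chain_id="A", seq_number=5, res_name=base)
    r2.atoms = [Atom("CA", (5, 5, 5), "C"), Atom(BASIC_ATOMS[base][0], (1 + dist, 0, 0), "N")]
    return Structure(id="pair", chains=[Chain(id="A", residues=[r1, r2])])


class TestSaltBridges:
    def test_planted_pair_within_cutoff(self):
        records = detect_salt_bridges(_two_residue_pair(3.0), cutoff=3.2)
        assert len(records) == 1
        rec = records[0]
        assert rec.dyad == "ASP-LYS"
        assert rec.min_distance == pytest.approx(3.0)

    def test_pair_beyond_cutoff(self):
        assert detect_salt_bridges(_two_residue_pair(3.5), cutoff=3.2) == []

    def test_pair_level_dedup(self):
        s = _two_residue_pair(3.0)
        s.chains[0].residues[0].atoms.append(Atom("OD2", (1.2, 0, 0), "O"))
        records = detect_salt_bridges(s, cutoff=3.2)
        assert len(records) == 1  # two O contacts, one residue pair

    @pytest.mark.parametrize("acid,base,dyad", [("GLU", "HIS", "GLU-HIS"), ("GLU", "ARG", "GLU-ARG")])
    def test_his_and_arg_dyads_counted(self, acid, base, dyad):
        records = detect_salt_bridges(_two_residue_pair(2.8, acid, base), cutoff=3.2)
        assert [r.dyad for r in records] == [dyad]

    def test_matches_brute_force_oracle_on_random_structures(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            s = random_charged_structure(rng)
            cutoff = float(rng.uniform(2.5, 5.0))
            fast = {
                ((r.acidic_residue[0], r.acidic_residue[1]),
                 (r.basic_residue[0], r.basic_residue[1])): (r.min_distance, r.dyad)
                for r in detect_salt_bridges(s, cutoff)
            }
            slow = brute_force_salt_bridges(s, cutoff)
            assert fast.keys() == slow.keys()
            for key in fast:
                assert fast[key][0] == pytest.approx(slow[key][0])
                assert fast[key][1] == slow[key][1]

    def test_stats_examples(self):
        helix = build_backbone(
            BackboneSpec(n_residues=60, planted_bridges=((5, 9, 3.0), (20, 24, 3.0),
                                                         (35, 39, 3.0)))
        )
        bridges = detect_salt_bridges(helix)
        pct, dyads = salt_bridge_stats(helix, bridges)
        assert pct == pytest.approx(100.0 * 3 / 60)
        assert dyads["ASP-LYS"] == pytest.approx(100.0)
        assert sum(dyads.values()) == pytest.approx(100.0)

    def test_zero_bridges_degenerate(self, ideal_helix):
        pct, dyads = salt_bridge_stats(ideal_helix, [])
        assert pct == 0.0
        assert all(v == 0.0 for v in dyads.values())


class TestPlanarity:
    @pytest.mark.parametrize("omega,expected", [(2.0, "cis"), (179.0, "trans"), (150.0, "nonplanar"),
                                                (-179.5, "trans"), (-25.0, "cis")])
    def test_classification(self, omega, expected):
        s = build_backbone(BackboneSpec(n_residues=3, omega=[180.0, omega, omega]))
        cis, nonplanar, trans = peptide_planarity(backbone_dihedrals(s))
        counts = {"cis": cis, "nonplanar": nonplanar, "trans": trans}
        assert counts[expected] == 2

    def test_partition_over_defined_omegas(self):
        rng = np.random.default_rng(5)
        omegas = [180.0] + list(rng.uniform(-180, 180, size=11))
        s = build_backbone(BackboneSpec(n_residues=12, omega=omegas))
        bds = backbone_dihedrals(s)
        n_defined = sum(1 for b in bds if b.omega is not None)
        assert sum(peptide_planarity(bds)) == n_defined


class TestRamaSummary:
    def test_ideal_helix_is_all_helix(self, ideal_helix):
        summary = rama_summary([ideal_helix])
        assert summary.pct_helix == pytest.approx(100.0)
        assert summary.cis_count == 0
        assert summary.nonplanar_count == 0

    def test_helix_plus_strand_split_evenly(self):
        helix = build_backbone(BackboneSpec(n_residues=20, phi=-57.0, psi=-47.0))
        strand = build_backbone(BackboneSpec(n_residues=20, phi=-120.0, psi=130.0))
        summary = rama_summary([helix, strand])
        assert summary.pct_helix == pytest.approx(50.0)
        assert summary.pct_sheet == pytest.approx(50.0)

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            rama_summary([])
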