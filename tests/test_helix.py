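import numpy as np
import pytest

from conftest import make_chain
from xylopat.geometry import RigidTransform, dihedral, place_atom
from xylopat.helix import (
    FOLD_TARGET_SUM,
    Conformation,
    HelixSpec,
    align_to_z,
    build_ideal_helix,
    classify_linkage,
    compute_dihedrals,
    screw_symmetry_rmsd,
)

FOLDS = ("twofold", "threefold_right", "threefold_left")


class TestGeometryPrimitives:
    def test_place_atom_round_trips_through_dihedral(self, rng):
        for _ in range(20):
            a, b, c = rng.normal(size=(3, 3)) * 3
            bond, angle, torsion = 1.4, 109.5, float(rng.uniform(-179, 179))
            d = place_atom(a, b, c, bond, angle, torsion)
            assert np.linalg.norm(d - c) == pytest.approx(bond, abs=1e-9)
            assert dihedral(a, b, c, d) == pytest.approx(torsion, abs=1e-7)

    def test_dihedral_sign_convention(self):
        # right-handed: rotating d counterclockwise from a about b->c is
        # positive (x -> y about +z gives +90°)
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 0.0])
        c = np.array([0.0, 0.0, 1.0])
        d = np.array([0.0, 1.0, 1.0])
        assert dihedral(a, b, c, d) == pytest.approx(90.0)
        assert dihedral(d, c, b, a) == pytest.approx(90.0)  # reversal symmetry


class TestBuildMeasureRoundTrip:
    @pytest.mark.parametrize("fold", FOLDS)
    @pytest.mark.parametrize("dp", [2, 10, 20])
    def test_target_sum_recovered_from_cartesians(self, fold, dp):
        conf = build_ideal_helix(HelixSpec(fold=fold, dp=dp))
        records = compute_dihedrals(conf)
        assert len(records) == dp - 1
        for rec in records:
            assert rec.sum == pytest.approx(FOLD_TARGET_SUM[fold], abs=0.5)

    def test_dp1_yields_single_ring_no_linkages(self):
        conf = build_ideal_helix(HelixSpec(fold="twofold", dp=1))
        assert conf.dp == 1 and conf.linkages == []

    def test_decoration_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="decoration"):
            HelixSpec(fold="twofold", dp=5, decoration=make_chain(4))

    def test_decorated_helix_carries_substituent_atoms(self):
        conf = build_ideal_helix(
            HelixSpec(fold="twofold", dp=6, decoration=make_chain(6, ac3=[2, 4, 6]))
        )
        names = {a.name for a in conf.atoms if a.residue_index == 2}
        assert {"C3A", "O3A", "C3M"} <= names

    def test_torsions_invariant_under_rigid_motion(self, rng):
        conf = build_ideal_helix(HelixSpec(fold="threefold_left", dp=8))
        # random rotation via QR decomposition
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = conf.transformed(RigidTransform(rotation=q, translation=rng.normal(size=3) * 10))
        before = [(r.phi, r.psi) for r in compute_dihedrals(conf)]
        after = [(r.phi, r.psi) for r in compute_dihedrals(moved)]
        for (p0, s0), (p1, s1) in zip(before, after):
            assert p0 == pytest.approx(p1, abs=1e-6)
            assert s0 == pytest.approx(s1, abs=1e-6)

    def test_missing_atom_error_names_linkage_and_atom(self):
        conf = build_ideal_helix(HelixSpec(fold="twofold", dp=4))
        conf.atoms = [
            a for a in conf.atoms if not (a.residue_index == 2 and a.name == "O4")
        ]
        with pytest.raises(KeyError, match="linkage 2-3.*O4"):
            compute_dihedrals(conf)


class TestClassify:
    @pytest.mark.parametrize(
        "s, expected",
        [
            (120.0, "twofold"),
            (50.0, "threefold_right"),
            (190.0, "threefold_left"),
            (90.0, "twofold"),     # inclusive boundary at tol=30
            (270.0, "other"),
            (480.0, "twofold"),    # wraps mod 360
        ],
    )
    def test_windows(self, s, expected):
        assert classify_linkage(s, tol=30.0) == expected

    def test_every_input_maps_to_exactly_one_class(self):
        for s in np.arange(0.0, 360.0, 0.5):
            assert classify_linkage(s) in (
                "twofold", "threefold_right", "threefold_left", "other"
            )

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            classify_linkage(120.0, tol=35.0)
        with pytest.raises(ValueError, match="positive"):
            classify_linkage(120.0, tol=0.0)


class TestScrewSymmetry:
    @pytest.mark.parametrize("fold", FOLDS)
    def test_ideal_helix_matches_its_own_fold(self, fold):
        conf = build_ideal_helix(HelixSpec(fold=fold, dp=10))
        assert screw_symmetry_rmsd(conf, fold) < 0.1

    def test_threefold_evaluated_as_twofold_mismatch(self):
        conf = build_ideal_helix(HelixSpec(fold="threefold_right", dp=10))
        assert screw_symmetry_rmsd(conf, "twofold") > 0.5

    def test_twofold_evaluated_as_threefold_mismatch(self):
        conf = build_ideal_helix(HelixSpec(fold="twofold", dp=10))
        assert screw_symmetry_rmsd(conf, "threefold_right") > 0.5

    def test_needs_at_least_three_residues(self):
        conf = build_ideal_helix(HelixSpec(fold="twofold", dp=2))
        with pytest.raises(ValueError, match="dp >= 3"):
            screw_symmetry_rmsd(conf, "twofold")


def test_align_to_z_puts_screw_axis_on_z():
    conf = align_to_z(build_ideal_helix(HelixSpec(fold="twofold", dp=10)))
    from xylopat.geometry import fit_screw
    from xylopat.residues3d import RING_NAMES

    src = np.vstack([conf.residue_coords(i, RING_NAMES) for i in range(1, 10)])
    tgt = np.vstack([conf.residue_coords(i, RING_NAMES) for i in range(2, 11)])
    sf = fit_screw(src, tgt)
    assert abs(sf.axis[2]) > 0.9999
    assert np.linalg.norm(sf.point[:2]) < 1e-6
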