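import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sheetfuse import (
    RigidTransform,
    UnclosableGapError,
    apply_transform,
    build_from_torsions,
    kabsch_superpose,
    measure_torsions,
)
from sheetfuse.geometry import (
    BOND_C_N,
    BOND_C_O,
    BOND_CA_C,
    BOND_N_CA,
    close_gap,
)
from sheetfuse.structio import BackboneChain

from .oracles import dihedral_ref, horn_rmsd


def random_cloud(rng, n=10):
    return rng.normal(size=(n, 3)) * 5.0


class TestKabsch:
    def test_identical_sets_give_zero_and_identity(self, rng):
        pts = random_cloud(rng)
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-9)

    def test_exact_recovery_of_applied_transform(self, rng):
        pts = random_cloud(rng)
        theta = np.pi / 2
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1.0]])
        target = pts @ rot.T + np.array([5.0, 0.0, 0.0])
        res = kabsch_superpose(pts, target)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.transform.rotation, rot, atol=1e-9)
        np.testing.assert_allclose(res.transform.translation,
                                   [5.0, 0.0, 0.0], atol=1e-9)

    def test_agrees_with_quaternion_oracle(self, rng):
        for _ in range(200):
            a = random_cloud(rng, n=int(rng.integers(3, 20)))
            b = random_cloud(rng, n=len(a))
            assert kabsch_superpose(a, b).rmsd == pytest.approx(
                horn_rmsd(a, b), abs=1e-8)

    def test_never_reflects(self, rng):
        for _ in range(100):
            a = random_cloud(rng, 6)
            b = a @ np.diag([-1.0, 1.0, 1.0])  # mirrored target
            det = np.linalg.det(kabsch_superpose(a, b).transform.rotation)
            assert det == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_symmetric_and_rigid_invariant(self, rng):
        a, b = random_cloud(rng), random_cloud(rng)
        r_ab = kabsch_superpose(a, b).rmsd
        assert kabsch_superpose(b, a).rmsd == pytest.approx(r_ab, abs=1e-9)
        t = RigidTransform.random(rng)
        assert kabsch_superpose(t.apply(a), b).rmsd == pytest.approx(r_ab, abs=1e-9)
        assert kabsch_superpose(a, t.apply(b)).rmsd == pytest.approx(r_ab, abs=1e-9)

    def test_optimality_under_random_transforms(self, rng):
        a, b = random_cloud(rng), random_cloud(rng)
        best = kabsch_superpose(a, b).rmsd
        for _ in range(1000):
            t = RigidTransform.random(rng)
            moved = t.apply(a)
            rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
            assert rmsd >= best - 1e-9

    def test_collinear_points_flagged(self):
        a = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        res = kabsch_superpose(a, a + 1.0)
        assert res.ill_conditioned
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_shape_errors(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestApplyTransform:
    def test_identity_translation_and_inverse(self, hairpin828):
        chain = hairpin828
        ident = apply_transform(chain, RigidTransform.identity())
        np.testing.assert_allclose(ident.backbone_coords(),
                                   chain.backbone_coords(), atol=1e-12)
        shift = RigidTransform(np.eye(3), np.array([1.0, 0, 0]))
        moved = apply_transform(chain, shift)
        np.testing.assert_allclose(
            moved.backbone_coords() - chain.backbone_coords(),
            np.broadcast_to([1.0, 0, 0], chain.backbone_coords().shape), atol=1e-12)
        t = RigidTransform.random(np.random.default_rng(7))
        back = apply_transform(apply_transform(chain, t), t.inverse())
        np.testing.assert_allclose(back.backbone_coords(),
                                   chain.backbone_coords(), atol=1e-9)


class TestTorsionBuild:
    def test_single_residue_ideal_bonds(self):
        coords = build_from_torsions([(-57.0, -47.0)])
        n, ca, c, o = coords[0]
        assert np.linalg.norm(ca - n) == pytest.approx(BOND_N_CA, abs=1e-6)
        assert np.linalg.norm(c - ca) == pytest.approx(BOND_CA_C, abs=1e-6)
        assert np.linalg.norm(o - c) == pytest.approx(BOND_C_O, abs=1e-6)

    @pytest.mark.parametrize("phi,psi,n", [(-57.0, -47.0, 10), (-120.0, 120.0, 8)])
    def test_round_trip_against_independent_dihedrals(self, phi, psi, n):
        coords = build_from_torsions([(phi, psi)] * n)
        for i in range(1, n):
            got_phi = dihedral_ref(coords[i - 1, 2], coords[i, 0],
                                   coords[i, 1], coords[i, 2])
            assert got_phi == pytest.approx(phi, abs=1e-4)
        for i in range(n - 1):
            got_psi = dihedral_ref(coords[i, 0], coords[i, 1],
                                   coords[i, 2], coords[i + 1, 0])
            assert got_psi == pytest.approx(psi, abs=1e-4)

    def test_helix_rise(self):
        coords = build_from_torsions([(-57.0, -47.0)] * 10)
        ca = coords[:, 1]
        d = np.linalg.norm(ca[1:] - ca[:-1], axis=1)
        assert np.all((d > 3.7) & (d < 3.9))
        rise = np.linalg.norm(ca[-1] - ca[0]) / 9
        assert 1.3 < rise < 1.7  # helical rise per residue ~1.5 Å

    def test_peptide_bond_lengths(self):
        coords = build_from_torsions([(-120.0, 120.0)] * 6)
        for i in range(5):
            assert np.linalg.norm(coords[i + 1, 0] - coords[i, 2]) == pytest.approx(
                BOND_C_N, abs=1e-6)


class TestMeasureTorsions:
    def test_inverse_of_build(self):
        spec = [(-57.0, -47.0, 180.0), (-120.0, 120.0, 180.0),
                (60.0, 30.0, 180.0), (-75.0, 145.0, 180.0), (-135.0, 132.0, 180.0)]
        chain = BackboneChain.from_coords(build_from_torsions(spec))
        got = measure_torsions(chain)
        for i, (phi, psi, omega) in enumerate(spec):
            if i > 0:
                assert got[i][0] == pytest.approx(phi, abs=1e-4)
                assert abs(got[i][2]) == pytest.approx(180.0, abs=1e-4)
            if i < len(spec) - 1:
                assert got[i][1] == pytest.approx(psi, abs=1e-4)

    def test_termini_absent(self):
        chain = BackboneChain.from_coords(build_from_torsions([(-60, -40)] * 3))
        got = measure_torsions(chain)
        assert got[0][0] is None and got[0][2] is None
        assert got[-1][1] is None

    def test_single_residue_all_absent(self):
        chain = BackboneChain.from_coords(build_from_torsions([(-60.0, -40.0)]))
        assert measure_torsions(chain) == [(None, None, None)]

    def test_break_yields_none(self):
        coords = build_from_torsions([(-120, 120)] * 6)
        coords[3:] += 50.0  # tear the chain
        chain = BackboneChain.from_coords(coords)
        got = measure_torsions(chain)
        assert 2 in chain.breaks
        assert got[2][1] is None and got[3][0] is None and got[3][2] is None


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_build_measure_identity_property(seed):
    """build_from_torsions then measuring the torsions returns the input spec."""
    r = np.random.default_rng(seed)
    spec = [(float(r.uniform(-179, 179)), float(r.uniform(-179, 179)), 180.0)
            for _ in range(5)]
    chain = BackboneChain.from_coords(build_from_torsions(spec))
    got = measure_torsions(chain)
    for i in range(1, 5):
        assert got[i][0] == pytest.approx(spec[i][0], abs=1e-4)
    for i in range(4):
        assert got[i][1] == pytest.approx(spec[i][1], abs=1e-4)


class TestCloseGap:
    def test_closes_reachable_gap(self):
        coords = build_from_torsions([(-120.0, 120.0)] * 2)
        target_n = coords[-1, 2] + np.array([2.5, 2.0, 1.0])
        seg = close_gap(coords[-1], target_n, 2)
        assert abs(np.linalg.norm(target_n - seg[-1, 2]) - BOND_C_N) <= 0.05

    def test_unreachable_gap_raises(self):
        coords = build_from_torsions([(-120.0, 120.0)] * 2)
        target_n = coords[-1, 2] + np.array([50.0, 0.0, 0.0])
        with pytest.raises(UnclosableGapError):
            close_gap(coords[-1], target_n, 2)
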