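"""Ensemble superposition, helix-axis fitting and inter-helix angles."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from pephelix.chemshift import HelixSegment
from pephelix.geometry import (
    GeometryError,
    Model,
    ModelEnsemble,
    fit_helix_axis,
    interhelix_angle,
    pairwise_rmsd_matrix,
    ramachandran_summary,
    read_model_ensemble,
    superpose_rmsd,
    write_model_ensemble,
)
from pephelix.sequences import parse_peptide
from pephelix.synthetic import build_hinged_helix_ensemble, build_ideal_helix

SEG_A = HelixSegment(394, 402)
SEG_B = HelixSegment(404, 408)


def rigid_transform(model, rotvec, translation):
    rot = Rotation.from_rotvec(rotvec)
    return Model(
        model.res_numbers,
        model.atom_names,
        model.elements,
        rot.apply(model.coords) + np.asarray(translation),
    )


def oracle_rmsd(P, Q, seed=0, n_grid=4000):
    """Quaternion-grid + simplex-polish minimum RMSD, independent of Kabsch."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n_grid, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    mats = Rotation.from_quat(quats).as_matrix()
    rotated = np.einsum("nij,aj->nai", mats, Qc)
    rmsds = np.sqrt(((rotated - Pc) ** 2).sum(axis=2).mean(axis=1))
    best = Rotation.from_quat(quats[np.argmin(rmsds)]).as_rotvec()

    def cost(rv):
        diff = Rotation.from_rotvec(rv).apply(Qc) - Pc
        return math.sqrt((diff**2).sum() / len(Pc))

    res = minimize(cost, best, method="Nelder-Mead", options={"xatol": 1e-9, "fatol": 1e-12})
    return res.fun


@pytest.fixture(scope="module")
def cb1_helix(cb1):
    return build_ideal_helix(cb1)


class TestSuperposition:
    def test_identical_models_zero(self, cb1_helix):
        rmsd, R, t = superpose_rmsd(cb1_helix, cb1_helix)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_rigid_motion_invariance(self, cb1_helix):
        moved = rigid_transform(cb1_helix, [0.4, -0.2, 0.5], [10.0, -3.0, 7.0])
        rmsd, R, t = superpose_rmsd(cb1_helix, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(moved.coords @ R.T + t, cb1_helix.coords, atol=1e-9)

    def test_symmetry(self, cb1):
        ens = build_hinged_helix_ensemble(cb1, SEG_A, SEG_B, 94.0, n_models=2, jitter=0.5, seed=9)
        a, b = ens.models
        assert superpose_rmsd(a, b)[0] == pytest.approx(superpose_rmsd(b, a)[0], abs=1e-9)

    def test_matches_quaternion_grid_oracle(self):
        rng = np.random.default_rng(123)
        pep = parse_peptide("probe", "AAAA", 1, "free", "free")
        for case in range(50):
            # 10-atom random pair sharing residue/atom labels
            nums = np.repeat([1, 2, 3], [3, 3, 4])
            names = ("N", "CA", "C") * 3 + ("O",)
            elements = ("N", "C", "C") * 3 + ("O",)
            P = rng.normal(scale=3.0, size=(10, 3))
            Q = rng.normal(scale=3.0, size=(10, 3))
            ref = Model(nums, names, elements, P)
            mob = Model(nums, names, elements, Q)
            rmsd, _, _ = superpose_rmsd(ref, mob, selection=set(names))
            assert rmsd == pytest.approx(oracle_rmsd(P, Q, seed=case), abs=1e-3)

    def test_too_few_pairs_rejected(self, cb1_helix):
        with pytest.raises(GeometryError):
            superpose_rmsd(cb1_helix, cb1_helix, selection={"ZZ"})


def synthetic_model(first_num, ca_coords):
    """Backbone model whose CA atoms sit exactly at ``ca_coords``; N and C
    are fixed offsets so the Model backbone invariant holds."""
    ca_coords = np.asarray(ca_coords, dtype=float)
    nums, names, elements, coords = [], [], [], []
    for i, ca in enumerate(ca_coords):
        num = first_num + i
        for name, el, off in (
            ("N", "N", (-0.9, -0.8, -0.6)),
            ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (0.9, 0.7, 0.6)),
        ):
            nums.append(num)
            names.append(name)
            elements.append(el)
            coords.append(ca + np.array(off))
    return Model(np.array(nums), tuple(names), tuple(elements), np.array(coords))


def spiral(n, omega_deg=100.0, rise=1.5, radius=2.3):
    i = np.arange(n)
    th = np.radians(omega_deg * i)
    return np.column_stack([radius * np.cos(th), radius * np.sin(th), rise * i])


class TestHelixAxis:
    def test_collinear_ca_axis_along_z(self):
        model = synthetic_model(1, [(0.0, 0.0, 1.5 * i) for i in range(8)])
        axis = fit_helix_axis(model, HelixSegment(1, 8))
        np.testing.assert_allclose(axis.direction, [0.0, 0.0, 1.0], atol=1e-9)
        assert axis.rms_to_axis == pytest.approx(0.0, abs=1e-9)

    def test_spiral_axis_near_z_with_bounded_bias(self):
        # a discrete helix with non-integer turns tilts the principal axis
        # slightly; the bias shrinks with segment length
        model = synthetic_model(1, spiral(12))
        axis = fit_helix_axis(model, HelixSegment(1, 12))
        tilt = math.degrees(math.acos(float(np.clip(axis.direction[2], -1, 1))))
        assert tilt < 3.0
        assert axis.rms_to_axis == pytest.approx(2.3, abs=0.15)  # helix radius

    def test_orientation_follows_residue_numbering(self):
        up = synthetic_model(1, [(0.0, 0.0, 1.5 * i) for i in range(8)])
        down = synthetic_model(1, [(0.0, 0.0, -1.5 * i) for i in range(8)])
        assert fit_helix_axis(up, HelixSegment(1, 8)).direction[2] == pytest.approx(1.0)
        assert fit_helix_axis(down, HelixSegment(1, 8)).direction[2] == pytest.approx(-1.0)

    def test_storage_order_irrelevant(self, cb1_helix):
        axis = fit_helix_axis(cb1_helix, SEG_A)
        shuffled = Model(
            cb1_helix.res_numbers[::-1].copy(),
            tuple(reversed(cb1_helix.atom_names)),
            tuple(reversed(cb1_helix.elements)),
            cb1_helix.coords[::-1].copy(),
        )
        axis2 = fit_helix_axis(shuffled, SEG_A)
        np.testing.assert_allclose(axis.direction, axis2.direction, atol=1e-9)

    def test_equivariance_under_rotation(self, cb1_helix):
        rotvec = [0.3, 0.7, -0.4]
        rotated = rigid_transform(cb1_helix, rotvec, [0, 0, 0])
        d0 = fit_helix_axis(cb1_helix, SEG_A).direction
        d1 = fit_helix_axis(rotated, SEG_A).direction
        np.testing.assert_allclose(
            Rotation.from_rotvec(rotvec).apply(d0), d1, atol=1e-3
        )

    def test_short_segment_rejected(self, cb1_helix):
        with pytest.raises(GeometryError):
            fit_helix_axis(cb1_helix, HelixSegment(391, 393))


class TestInterhelixAngle:
    def test_prescribed_angle_zero_jitter(self, cb1):
        ens = build_hinged_helix_ensemble(cb1, SEG_A, SEG_B, 94.0, n_models=5, jitter=0.0, seed=0)
        _, mean, sd = interhelix_angle(ens, SEG_A, SEG_B)
        assert mean == pytest.approx(94.0, abs=2.0)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_parallel_and_antiparallel_copies(self):
        # residues 1-10: a spiral helix; residues 15-24: a translated copy
        # (parallel, angle exactly 0) or a copy rotated 180 deg about an
        # axis perpendicular to the fitted axis (antiparallel, exactly 180)
        pep = parse_peptide("two", "A" * 24, 1, "free", "free")
        ca_a = spiral(10)
        seg_a, seg_b = HelixSegment(1, 10), HelixSegment(15, 24)

        def two_segment_model(ca_b):
            a = synthetic_model(1, ca_a)
            b = synthetic_model(15, ca_b)
            return Model(
                np.concatenate([a.res_numbers, b.res_numbers]),
                a.atom_names + b.atom_names,
                a.elements + b.elements,
                np.vstack([a.coords, b.coords]),
            )

        parallel = two_segment_model(ca_a + np.array([12.0, 0.0, 0.0]))
        _, mean0, _ = interhelix_angle(ModelEnsemble((parallel,), pep), seg_a, seg_b)
        assert mean0 == pytest.approx(0.0, abs=1e-6)

        d = fit_helix_axis(parallel, seg_a).direction
        perp = np.cross(d, [1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        flip = Rotation.from_rotvec(math.pi * perp)
        antiparallel = two_segment_model(flip.apply(ca_a) + np.array([12.0, 0.0, 0.0]))
        _, mean180, _ = interhelix_angle(ModelEnsemble((antiparallel,), pep), seg_a, seg_b)
        assert mean180 == pytest.approx(180.0, abs=1e-6)

    def test_invariance_under_global_motion(self, cb1):
        ens = build_hinged_helix_ensemble(cb1, SEG_A, SEG_B, 75.0, n_models=4, jitter=0.1, seed=2)
        moved = ModelEnsemble(
            tuple(rigid_transform(m, [1.0, -0.3, 0.2], [5, 6, 7]) for m in ens.models),
            cb1,
        )
        _, mean_a, sd_a = interhelix_angle(ens, SEG_A, SEG_B)
        _, mean_b, sd_b = interhelix_angle(moved, SEG_A, SEG_B)
        assert mean_b == pytest.approx(mean_a, abs=1e-6)
        assert sd_b == pytest.approx(sd_a, abs=1e-6)


class TestPDBRoundTrip:
    def test_ensemble_round_trip(self, tmp_path, cb1):
        ens = build_hinged_helix_ensemble(cb1, SEG_A, SEG_B, 94.0, n_models=20, jitter=0.2, seed=4)
        path = tmp_path / "ensemble.pdb"
        write_model_ensemble(ens, path)
        back = read_model_ensemble(path, cb1)
        assert len(back) == 20
        for a, b in zip(ens.models, back.models):
            assert a.atom_key() == b.atom_key()
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-3)

    def test_single_model_file(self, tmp_path, cb1, cb1_helix):
        path = tmp_path / "single.pdb"
        write_model_ensemble(ModelEnsemble((cb1_helix,), cb1), path)
        assert len(read_model_ensemble(path, cb1)) == 1

    def test_numbering_mismatch_rejected(self, tmp_path, cb1, cb1_helix):
        shifted = Model(
            cb1_helix.res_numbers + 100,
            cb1_helix.atom_names,
            cb1_helix.elements,
            cb1_helix.coords,
        )
        pep_shifted = parse_peptide("shifted", cb1.sequence, 491, "acetyl", "amide")
        path = tmp_path / "shifted.pdb"
        write_model_ensemble(ModelEnsemble((shifted,), pep_shifted), path)
        with pytest.raises(GeometryError):
            read_model_ensemble(path, cb1)

    def test_heterogeneous_models_rejected(self, cb1, cb1_helix):
        truncated = Model(
            cb1_helix.res_numbers[:-3],
            cb1_helix.atom_names[:-3],
            cb1_helix.elements[:-3],
            cb1_helix.coords[:-3],
        )
        with pytest.raises(GeometryError):
            ModelEnsemble((cb1_helix, truncated), cb1)


class TestRamachandran:
    def test_ideal_helix_fully_favored(self, cb1, cb1_helix):
        ens = ModelEnsemble((cb1_helix,), cb1)
        summary = ramachandran_summary(ens)
        assert summary["favored"] == pytest.approx(1.0)
        assert sum(summary.values()) == pytest.approx(1.0)

    def test_nonhelical_dihedrals_not_favored(self, cb1):
        from pephelix.synthetic import build_ideal_helix as build

        strange = build(cb1, phi=150.0, psi=150.0)
        summary = ramachandran_summary(ModelEnsemble((strange,), cb1))
        assert summary["favored"] == pytest.approx(0.0)


def test_rmsd_matrix_properties(cb1):
    ens = build_hinged_helix_ensemble(cb1, SEG_A, SEG_B, 94.0, n_models=4, jitter=0.3, seed=8)
    mat = pairwise_rmsd_matrix(ens)
    arr = mat.to_numpy()
    assert np.allclose(arr, arr.T)
    assert np.allclose(np.diag(arr), 0.0)
    assert arr[0, 1] > 0.0
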