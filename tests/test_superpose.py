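import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polsite.struct_io import AtomRecord, ConformationEnsemble
from polsite.superpose import (
    atom_pair_distance,
    delta_rmsf,
    domain_rotation_angle,
    kabsch,
    rmsd_series,
    rmsf_profile,
    rotation_angle_deg,
)


def rot_z(deg):
    t = np.radians(deg)
    return np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]])


def random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quaternion_rmsd(mobile, target):
    """Independent oracle: optimal-superposition RMSD via Horn's quaternion method."""
    pm = mobile - mobile.mean(0)
    pt = target - target.mean(0)
    m = pm.T @ pt
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    msd = ((pm**2).sum() + (pt**2).sum() - 2 * lam) / mobile.shape[0]
    return np.sqrt(max(msd, 0.0))


def make_ensemble(frames):
    frames = np.asarray(frames, float)
    atoms = [AtomRecord(i + 1, "CA", "ALA", "A", i + 1, "C") for i in range(frames.shape[1])]
    return ConformationEnsemble(atoms, frames)


class TestKabsch:
    def test_identity(self, rng):
        x = rng.standard_normal((10, 3))
        res = kabsch(x, x)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)
        assert res.rmsd < 1e-12

    def test_recovers_constructed_rotation(self, rng):
        x = rng.standard_normal((10, 3))
        y = x @ rot_z(90).T + np.array([1.0, -2.0, 3.0])
        res = kabsch(x, y)
        assert abs(rotation_angle_deg(res.rotation) - 90.0) < 1e-9
        assert res.rmsd < 1e-9

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(100):
            a = rng.standard_normal((10, 3)) * 5
            b = rng.standard_normal((10, 3)) * 5
            assert abs(kabsch(a, b).rmsd - quaternion_rmsd(a, b)) < 1e-8

    def test_rotation_always_proper(self, rng):
        # near-reflective pairs must still yield det(R) = +1
        a = rng.standard_normal((6, 3))
        b = a.copy()
        b[:, 2] *= -1  # mirrored cloud
        res = kabsch(a, b)
        assert abs(np.linalg.det(res.rotation) - 1.0) < 1e-9

    def test_collinear_flagged_but_proper(self):
        a = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        res = kabsch(a, a @ rot_z(30).T)
        assert res.degenerate
        assert abs(np.linalg.det(res.rotation) - 1.0) < 1e-9

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_weights_validated(self, rng):
        x = rng.standard_normal((5, 3))
        with pytest.raises(ValueError):
            kabsch(x, x, weights=np.zeros(5))

    def test_weighted_fit_prefers_heavy_points(self, rng):
        x = rng.standard_normal((8, 3))
        y = x.copy()
        y[-1] += 10.0  # outlier
        w = np.ones(8)
        w[-1] = 1e-9
        res = kabsch(x, y, weights=w)
        assert res.rmsd < 1e-3


class TestRmsdSeries:
    def test_reference_repeated_is_zero(self, rng):
        ref = rng.standard_normal((6, 3))
        ens = make_ensemble(np.repeat(ref[None], 4, axis=0))
        series = rmsd_series(ens, ref, np.arange(6), {"all": np.arange(6)})
        np.testing.assert_allclose(series["all"], 0.0, atol=1e-12)

    def test_translation_absorbed_by_fit(self, rng):
        ref = rng.standard_normal((6, 3))
        ens = make_ensemble((ref + np.array([1.0, 1.0, 1.0]))[None])
        series = rmsd_series(ens, ref, np.arange(6), {"all": np.arange(6)})
        assert series["all"][0] < 1e-12

    def test_matches_bruteforce_per_frame(self, rng):
        ref = rng.standard_normal((8, 3)) * 3
        frames = ref[None] + rng.standard_normal((5, 8, 3))
        ens = make_ensemble(frames)
        fit = np.arange(4)
        calc = np.arange(4, 8)
        series = rmsd_series(ens, ref, fit, {"sub": calc})
        for f in range(5):
            res = kabsch(frames[f, fit], ref[fit])
            moved = res.transform(frames[f])
            expect = np.sqrt(((moved[calc] - ref[calc]) ** 2).sum() / calc.size)
            assert abs(series["sub"][f] - expect) < 1e-10

    def test_empty_mask_rejected(self, rng):
        ens = make_ensemble(rng.standard_normal((2, 6, 3)))
        with pytest.raises(ValueError):
            rmsd_series(ens, ens.frames[0], np.array([], dtype=int), {"a": np.arange(6)})


class TestRmsf:
    def test_constant_ensemble_is_zero(self, rng):
        ref = rng.standard_normal((5, 3))
        ens = make_ensemble(np.repeat(ref[None], 3, axis=0))
        prof = rmsf_profile(ens, np.arange(5), representative_atoms=None)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in prof.values.values())

    def test_isotropic_jitter_closed_form(self, rng):
        """Independent per-axis Gaussian jitter of sd σ on a rigid body (no net
        motion) gives RMSF = σ√3; enough atoms that the superposition absorbs
        a negligible share of the fluctuation variance."""
        sigma = 0.3
        n = 150
        ref = rng.standard_normal((n, 3)) * 10
        frames = ref[None] + rng.normal(0, sigma, (10000, n, 3))
        prof = rmsf_profile(make_ensemble(frames), np.arange(n), representative_atoms=None)
        for v in prof.values.values():
            assert v == pytest.approx(sigma * np.sqrt(3), rel=0.03)

    def test_matches_bruteforce_two_pass(self, enm_ensemble):
        ens, _ = enm_ensemble
        prof = rmsf_profile(ens, np.arange(ens.n_atoms), representative_atoms=None)
        from polsite.superpose import iterative_mean_structure

        mean, aligned = iterative_mean_structure(ens, np.arange(ens.n_atoms))
        for i, atom in enumerate(ens.atoms):
            expect = np.sqrt(((aligned[:, i, :] - mean[i]) ** 2).sum(1).mean())
            assert prof[atom.residue_key] == pytest.approx(expect, abs=1e-9)

    def test_needs_two_frames(self, rng):
        ens = make_ensemble(rng.standard_normal((1, 5, 3)))
        with pytest.raises(ValueError):
            rmsf_profile(ens, np.arange(5))


class TestDeltaRmsf:
    @staticmethod
    def _profile(vals):
        from polsite.superpose import RmsfProfile

        return RmsfProfile({("A", str(i + 1)): v for i, v in enumerate(vals)})

    def test_self_difference_zero(self):
        a = self._profile([0.5, 1.0, 2.0])
        assert all(v == 0 for v in delta_rmsf(a, a).values())

    def test_zero_baseline_returns_first(self):
        a = self._profile([0.5, 1.0])
        b = self._profile([0.0, 0.0])
        assert list(delta_rmsf(a, b).values()) == [0.5, 1.0]

    def test_antisymmetry(self):
        a = self._profile([0.5, 1.0, 0.2])
        b = self._profile([0.1, 2.0, 0.4])
        d1, d2 = delta_rmsf(a, b), delta_rmsf(b, a)
        assert all(d1[k] == -d2[k] for k in d1)

    def test_disjoint_profiles_rejected(self):
        from polsite.superpose import RmsfProfile

        with pytest.raises(ValueError):
            delta_rmsf(RmsfProfile({("A", "1"): 1.0}), RmsfProfile({("B", "9"): 1.0}))


class TestDomainRotation:
    @staticmethod
    def _hinged(angle_deg, rng):
        """Palm fixed at origin-side, Fingers rotated about the z axis hinge."""
        palm = rng.standard_normal((10, 3)) - [5, 0, 0]
        fingers = rng.standard_normal((10, 3)) + [5, 0, 0]
        a = make_ensemble(np.vstack([palm, fingers])[None])
        rotated = fingers @ rot_z(angle_deg).T
        b = make_ensemble(np.vstack([palm, rotated])[None])
        return a, b, np.arange(10), np.arange(10, 20)

    def test_identical_conformations_zero(self, rng):
        a, _, palm, fingers = self._hinged(0, rng)
        angle, _ = domain_rotation_angle(a, a, palm, fingers)
        assert angle == pytest.approx(0.0, abs=1e-6)

    def test_constructed_30_degrees(self, rng):
        a, b, palm, fingers = self._hinged(30, rng)
        angle, _ = domain_rotation_angle(a, b, palm, fingers)
        assert angle == pytest.approx(30.0, abs=1e-6)

    def test_monotone_in_constructed_angle(self, rng):
        measured = []
        for deg in [10, 60, 110, 170]:
            a, b, palm, fingers = self._hinged(deg, rng)
            angle, _ = domain_rotation_angle(a, b, palm, fingers)
            measured.append(angle)
            assert angle == pytest.approx(deg, abs=1e-6)
        assert measured == sorted(measured)

    def test_small_domain_rejected(self, rng):
        a, b, palm, _ = self._hinged(30, rng)
        with pytest.raises(ValueError):
            domain_rotation_angle(a, b, palm, np.array([10, 11]))

    def test_signed_direction_toward_reference(self, rng):
        a, b, palm, fingers = self._hinged(30, rng)
        target = a.frames[0][palm].mean(0)  # hinge side
        _, toward = domain_rotation_angle(a, b, palm, fingers, direction_reference=target)
        assert toward is not None


class TestAtomPairDistance:
    def _conf(self):
        atoms = [
            AtomRecord(1, "O3'", "DC", "P", 25, "O"),
            AtomRecord(2, "PA", "DCP", "L", 1, "P"),
            AtomRecord(3, "CA", "ALA", "A", 1, "C"),
        ]
        coords = np.array([[[0, 0, 0], [3, 4, 0], [1, 1, 1]]], dtype=float)
        return ConformationEnsemble(atoms, coords)

    def test_three_four_five(self):
        c = self._conf()
        d = atom_pair_distance(c, {"name": "O3'"}, {"name": "PA"})
        assert d == pytest.approx(5.0)

    def test_same_atom_zero(self):
        c = self._conf()
        assert atom_pair_distance(c, {"name": "PA"}, {"name": "PA"}) == 0.0

    def test_missing_atom_lists_spec(self):
        with pytest.raises(KeyError, match="no atom matches"):
            atom_pair_distance(self._conf(), {"name": "MG"}, {"name": "PA"})

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), shift=st.floats(-50, 50))
    def test_invariant_under_rigid_transform(self, seed, shift):
        rng = np.random.default_rng(seed)
        c = self._conf()
        d0 = atom_pair_distance(c, {"name": "O3'"}, {"name": "PA"})
        rot = random_rotation(rng)
        moved = ConformationEnsemble(c.atoms, c.frames @ rot.T + shift)
        d1 = atom_pair_distance(moved, {"name": "O3'"}, {"name": "PA"})
        assert d1 == pytest.approx(d0, abs=1e-9)
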