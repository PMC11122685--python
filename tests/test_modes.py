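import numpy as np
import pytest

from polsite.modes import (
    anm_modes,
    build_anm_hessian,
    dccm,
    dccm_difference,
    mode_overlap,
    pca_modes,
    rmsip,
)
from polsite.struct_io import AtomRecord, ConformationEnsemble
from polsite.synthetic import gen_enm_ensemble, helix_coords, model_dccm


def make_ensemble(frames):
    frames = np.asarray(frames, float)
    atoms = [AtomRecord(i + 1, "CA", "ALA", "A", i + 1, "C") for i in range(frames.shape[1])]
    return ConformationEnsemble(atoms, frames)


def bruteforce_dccm(dev):
    """Double-loop reference: dev is F×M×3 deviations from the mean."""
    f, m, _ = dev.shape
    c = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            num = np.mean([dev[t, i] @ dev[t, j] for t in range(f)])
            di = np.mean([dev[t, i] @ dev[t, i] for t in range(f)])
            dj = np.mean([dev[t, j] @ dev[t, j] for t in range(f)])
            c[i, j] = num / np.sqrt(di * dj)
    return c


class TestDccm:
    @staticmethod
    def _anchored(rng, motion_a, motion_b):
        """Atoms 0 and 1 carry prescribed per-frame displacements; atoms 2-4
        are near-static anchors that pin the superposition so prescribed
        motion is not absorbed by the fit."""
        f = motion_a.shape[0]
        frames = np.zeros((f, 5, 3))
        frames[:, 0] = motion_a + [0, 0, 0]
        frames[:, 1] = motion_b + [5, 0, 0]
        anchors = np.array([[20.0, 0, 0], [20, 20, 0], [0, 20, 20]])
        frames[:, 2:] = anchors + rng.normal(0, 1e-4, (f, 3, 3))
        return make_ensemble(frames), np.array([2, 3, 4])

    def test_common_translation_fully_correlated(self, rng):
        walk = 0.5 * rng.standard_normal((200, 3))
        ens, anchors = self._anchored(rng, walk, walk)
        c = dccm(ens, fit_mask=anchors)
        assert c.matrix[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_antiphase_anticorrelated(self, rng):
        walk = 0.5 * rng.standard_normal((300, 3))
        ens, anchors = self._anchored(rng, walk, -walk)
        c = dccm(ens, fit_mask=anchors)
        assert c.matrix[0, 1] == pytest.approx(-1.0, abs=1e-6)

    def test_matches_bruteforce_double_loop(self, enm_ensemble):
        ens, _ = enm_ensemble
        small = ConformationEnsemble(ens.atoms[:6], ens.frames[:100, :6])
        c = dccm(small)
        from polsite.superpose import iterative_mean_structure

        mean, aligned = iterative_mean_structure(small, np.arange(6))
        ref = bruteforce_dccm(aligned - mean[None])
        np.testing.assert_allclose(c.matrix, ref, atol=1e-10)

    def test_zero_variance_atom_marked_undefined(self, rng):
        # atoms 0-2 are exactly static (and pin the fit); atom 3 moves
        frames = np.zeros((50, 4, 3))
        frames[:, :3] = np.array([[0.0, 0, 0], [4, 0, 0], [0, 4, 4]])
        frames[:, 3] = [8.0, 0, 0] + 0.3 * rng.standard_normal((50, 3))
        c = dccm(make_ensemble(frames), fit_mask=np.array([0, 1, 2]))
        assert {0, 1, 2} <= set(c.undefined.tolist())
        assert np.isnan(c.matrix[0, 3]) and np.isnan(c.matrix[3, 0])
        assert c.matrix[3, 3] == pytest.approx(1.0)

    def test_bounded_and_symmetric(self, enm_ensemble):
        ens, _ = enm_ensemble
        c = dccm(ens)
        np.testing.assert_allclose(c.matrix, c.matrix.T, atol=1e-12)
        assert np.nanmax(np.abs(c.matrix)) <= 1.0 + 1e-9
        np.testing.assert_allclose(np.diag(c.matrix), 1.0, atol=1e-9)


class TestDccmDifference:
    def test_self_difference_zero(self, enm_ensemble):
        ens, _ = enm_ensemble
        c = dccm(ens)
        diff, _ = dccm_difference(c, c)
        np.testing.assert_allclose(diff, 0.0)

    def test_antisymmetric_under_swap(self, enm_ensemble, rng):
        ens, _ = enm_ensemble
        a = dccm(ConformationEnsemble(ens.atoms, ens.frames[:500]))
        b = dccm(ConformationEnsemble(ens.atoms, ens.frames[500:1000]))
        d1, _ = dccm_difference(a, b)
        d2, _ = dccm_difference(b, a)
        np.testing.assert_allclose(d1, -d2)

    def test_key_mismatch_rejected(self, enm_ensemble):
        ens, _ = enm_ensemble
        a = dccm(ens)
        b = dccm(ens.subset(np.arange(10)))
        with pytest.raises(ValueError):
            dccm_difference(a, b)

    def test_designed_anticorrelation_detected_in_blocks(self, rng):
        """A generator with anti-phase Fingers/Palm only in the 'wt' must give a
        positive Fingers–Palm block mean in (mut − wt)."""
        t = rng.standard_normal(400)
        jit = 0.05 * rng.standard_normal((400, 8, 3))
        wt = jit.copy()
        wt[:, :4, 0] += t[:, None]  # Palm
        wt[:, 4:, 0] -= t[:, None]  # Fingers anti-phase
        mu = jit + 0.05 * rng.standard_normal((400, 8, 3))
        offsets = np.arange(8)[:, None] * [3.0, 0, 0]
        ens_wt = make_ensemble(wt + offsets)
        ens_mut = make_ensemble(mu + offsets)
        sub = {}
        for i in range(8):
            a = ens_wt.atoms[i]
            sub[(a.chain_id, a.residue_number, a.name)] = "Palm" if i < 4 else "Fingers"
        fit = np.arange(8)
        cw = dccm(ens_wt, fit_mask=fit)
        cm = dccm(ens_mut, fit_mask=fit)
        _, blocks = dccm_difference(cm, cw, sub)
        assert blocks[("Fingers", "Palm")] > 0.5


class TestAnm:
    def test_exactly_six_rigid_modes(self, helix20):
        h = build_anm_hessian(helix20, cutoff=15.0)
        evals = np.linalg.eigvalsh(h)
        assert np.sum(evals < 1e-8 * evals[-1]) == 6

    def test_two_body_analytic_mode(self):
        """Two beads, one spring of stiffness γ: the single internal mode is the
        symmetric stretch with eigenvalue 2γ."""
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        for gamma in (1.0, 2.5):
            h = build_anm_hessian(coords, cutoff=2.0, gamma=gamma)
            evals, evecs = np.linalg.eigh(h)
            internal = evals[evals > 1e-10]
            assert internal.size == 1
            assert internal[0] == pytest.approx(2.0 * gamma)
            vec = evecs[:, np.argmax(evals)]
            stretch = np.array([1, 0, 0, -1, 0, 0]) / np.sqrt(2)
            assert abs(abs(vec @ stretch) - 1.0) < 1e-10

    def test_hessian_matches_finite_difference(self, rng):
        """ENM potential V = γ/2 Σ (|r_ij| − |r⁰_ij|)²; its numerical Hessian at
        the minimum must equal the analytic network Hessian."""
        coords = rng.standard_normal((5, 3)) * 3
        cutoff, gamma = 100.0, 1.3
        r0 = np.linalg.norm(coords[:, None] - coords[None], axis=-1)

        def potential(flat):
            x = flat.reshape(5, 3)
            r = np.linalg.norm(x[:, None] - x[None], axis=-1)
            mask = np.triu((r0 <= cutoff) & ~np.eye(5, dtype=bool))
            return 0.5 * gamma * ((r - r0)[mask] ** 2).sum()

        h_analytic = build_anm_hessian(coords, cutoff=cutoff, gamma=gamma)
        eps = 1e-5
        flat = coords.ravel()
        n = flat.size
        h_num = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                pp = flat.copy(); pp[i] += eps; pp[j] += eps
                pm = flat.copy(); pm[i] += eps; pm[j] -= eps
                mp = flat.copy(); mp[i] -= eps; mp[j] += eps
                mm = flat.copy(); mm[i] -= eps; mm[j] -= eps
                h_num[i, j] = (
                    potential(pp) - potential(pm) - potential(mp) + potential(mm)
                ) / (4 * eps * eps)
        np.testing.assert_allclose(h_analytic, h_num, atol=1e-6)

    def test_spectrum_invariant_under_rotation(self, helix20, rng):
        from tests.test_superpose import random_rotation

        m1 = anm_modes(helix20, cutoff=15.0)
        m2 = anm_modes(helix20 @ random_rotation(rng).T + 5.0, cutoff=15.0)
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, rtol=1e-8, atol=1e-10)

    def test_disconnected_structure_rejected(self):
        coords = np.vstack([helix_coords(5), helix_coords(5) + [500.0, 0, 0]])
        with pytest.raises(ValueError, match="disconnected"):
            anm_modes(coords, cutoff=15.0)

    def test_fractions_normalized_and_ordered(self, helix20):
        m = anm_modes(helix20, cutoff=15.0)
        assert m.fractions.sum() == pytest.approx(1.0)
        assert np.all(np.diff(m.fractions) <= 1e-12)  # softest mode first

    def test_equal_eigenvalues_give_equal_fractions(self):
        # a regular tetrahedron has degenerate internal modes by symmetry
        coords = np.array(
            [[1.0, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]
        )
        m = anm_modes(coords, cutoff=4.0)
        lam = m.eigenvalues
        close = np.isclose(lam[:-1], lam[1:])
        assert close.any()
        i = int(np.argmax(close))
        assert m.fractions[i] == pytest.approx(m.fractions[i + 1])


class TestPca:
    def test_single_oscillation_single_mode(self):
        t = np.sin(np.linspace(0, 20, 200))
        frames = np.zeros((200, 4, 3))
        offsets = np.arange(4)[:, None] * [3.0, 0, 0]
        frames += offsets
        frames[:, :, 0] += t[:, None] * np.array([1.0, -1.0, 1.0, -1.0])
        m = pca_modes(make_ensemble(frames))
        assert m.n_modes == 1
        assert m.fractions[0] == pytest.approx(1.0)

    def test_covariance_matches_bruteforce(self, enm_ensemble):
        ens, _ = enm_ensemble
        small = ConformationEnsemble(ens.atoms[:5], ens.frames[:200, :5])
        m = pca_modes(small)
        from polsite.superpose import iterative_mean_structure

        mean, aligned = iterative_mean_structure(small, np.arange(5))
        dev = (aligned - mean[None]).reshape(200, -1)
        cov = np.zeros((15, 15))
        for f in range(200):
            cov += np.outer(dev[f], dev[f])
        cov /= 200
        recon = (m.eigenvectors.T * m.eigenvalues) @ m.eigenvectors
        np.testing.assert_allclose(recon, cov, atol=1e-10)

    def test_pca_recovers_anm_subspace(self, helix20):
        ens, _ = gen_enm_ensemble(helix20, cutoff=15.0, n_frames=5000, seed=3)
        pca = pca_modes(ens)
        anm = anm_modes(helix20, cutoff=15.0)
        assert rmsip(pca, anm, 5) >= 0.85

    def test_too_few_frames(self, rng):
        with pytest.raises(ValueError):
            pca_modes(make_ensemble(rng.standard_normal((1, 4, 3))))


class TestModeOverlap:
    def test_identical_vectors(self, rng):
        v = rng.standard_normal(12)
        assert mode_overlap(v, 3 * v) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert mode_overlap([1, 0, 0, 0], [0, 1, 0, 0]) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            mode_overlap([0, 0, 0], [1, 0, 0])

    def test_bessel_inequality_over_orthonormal_modes(self, helix20, rng):
        m = anm_modes(helix20, cutoff=15.0)
        v = rng.standard_normal(m.eigenvectors.shape[1])
        v /= np.linalg.norm(v)
        total = sum(mode_overlap(m.eigenvectors[k], v) ** 2 for k in range(m.n_modes))
        assert total <= 1.0 + 1e-9
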