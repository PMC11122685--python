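"""Dynamic cross-correlation matrices and normal modes (ENM and PCA).

The DCCM is the normalized covariance of atomic displacement vectors,
C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) with Δr the deviation from
the time-mean position after superposition: +1 fully correlated motion,
−1 anti-correlated.  The difference map (mutant − wild-type) localizes
where correlated subdomain motion is gained or lost.

Two mode sets are provided, because collective-motion reports in the
literature come from either source and the choice is rarely stated:

* ``anm_modes`` — anisotropic elastic-network model on a single structure:
  Hessian super-elements −γ d̂ d̂ᵀ for contacts within a cutoff, six
  rigid-body modes removed by eigenvalue rank, variance weight 1/λ.
* ``pca_modes`` — eigendecomposition of the 3M×3M coordinate covariance of
  an aligned ensemble, variance weight λ.

Mode "contribution fractions" are the variance weights normalized over
the retained modes.  Breathing/rocking (or any biological label) is never
hard-coded: ``mode_overlap`` scores a mode against user-supplied reference
displacement vectors and the caller assigns labels by argmax overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .struct_io import ConformationEnsemble, SubdomainMask
from .superpose import iterative_mean_structure, _resolve

__all__ = [
    "Dccm",
    "ModeSet",
    "dccm",
    "dccm_difference",
    "build_anm_hessian",
    "anm_modes",
    "pca_modes",
    "mode_overlap",
    "mode_porcupine",
    "rmsip",
]

RIGID_BODY_MODES = 6


@dataclass
class Dccm:
    matrix: np.ndarray  # M×M, symmetric, unit diagonal, entries in [-1, 1]
    atom_keys: list[tuple]  # (chain, resnum, atom name) per row
    undefined: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ModeSet:
    """Orthonormal mode vectors with variance-based contribution fractions."""

    eigenvectors: np.ndarray  # K × 3M, rows orthonormal
    eigenvalues: np.ndarray  # force constants (ENM) or variances (PCA)
    kind: str  # "ENM" | "PCA"
    fractions: np.ndarray  # in [0,1], sum 1 over retained modes

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[0]

    def top(self, k: int) -> "ModeSet":
        k = min(k, self.n_modes)
        return ModeSet(
            self.eigenvectors[:k], self.eigenvalues[:k], self.kind, self.fractions[:k]
        )


def dccm(
    ensemble: ConformationEnsemble,
    mask: SubdomainMask | np.ndarray | None = None,
    fit_mask: SubdomainMask | np.ndarray | None = None,
) -> Dccm:
    """Dynamic cross-correlation matrix over masked atoms.

    Frames are aligned to the converged mean structure on ``fit_mask``
    (defaults to the analysis mask) before covariances are taken.  An atom
    with zero displacement variance cannot be normalized; its row/column
    are set to NaN and its index reported in ``undefined``.
    """
    if ensemble.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    idx = (
        np.arange(ensemble.n_atoms)
        if mask is None
        else _resolve(mask, ensemble)
    )
    fidx = idx if fit_mask is None else _resolve(fit_mask, ensemble)
    mean, aligned = iterative_mean_structure(ensemble, fidx)
    dev = aligned[:, idx, :] - mean[None, idx, :]  # F × M × 3
    # ⟨Δr_i·Δr_j⟩: contract frame and xyz axes
    cov = np.einsum("fia,fja->ij", dev, dev) / dev.shape[0]
    var = np.diag(cov).copy()
    # zero variance up to alignment round-off: normalization undefined
    zero = np.where(var <= 1e-12 * max(var.max(), 1e-300))[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.outer(var, var))
        mat = cov / denom
    mat[zero, :] = np.nan
    mat[:, zero] = np.nan
    keep = np.setdiff1d(np.arange(len(idx)), zero)
    np.fill_diagonal(mat[np.ix_(keep, keep)], 1.0)
    keys = [
        (ensemble.atoms[i].chain_id, ensemble.atoms[i].residue_number, ensemble.atoms[i].name)
        for i in idx
    ]
    return Dccm(mat, keys, zero)


def dccm_difference(
    mutant: Dccm,
    wild: Dccm,
    subdomain_of: dict[tuple, str] | None = None,
) -> tuple[np.ndarray, dict[tuple[str, str], float]]:
    """Elementwise DCCM difference (mutant − wild) plus per-subdomain-pair means.

    ``subdomain_of`` maps atom keys to subdomain names; the returned summary
    gives the mean difference over each unordered subdomain pair block
    (off-diagonal only within a block), supporting statements like
    "Fingers–Palm anticorrelation lost in the mutant".
    """
    if mutant.atom_keys != wild.atom_keys:
        raise ValueError("DCCMs computed over different atom sets")
    diff = mutant.matrix - wild.matrix
    summary: dict[tuple[str, str], float] = {}
    if subdomain_of:
        names = sorted(set(subdomain_of.values()))
        groups = {
            nm: np.asarray(
                [k for k, key in enumerate(mutant.atom_keys) if subdomain_of.get(key) == nm],
                dtype=int,
            )
            for nm in names
        }
        for a in names:
            for b in names:
                if a > b:
                    continue
                ia, ib = groups[a], groups[b]
                if ia.size == 0 or ib.size == 0:
                    continue
                block = diff[np.ix_(ia, ib)]
                if a == b:
                    off = ~np.eye(ia.size, dtype=bool)
                    vals = block[off]
                else:
                    vals = block.ravel()
                if vals.size:
                    summary[(a, b)] = float(np.nanmean(vals))
    return diff, summary


def build_anm_hessian(coords: np.ndarray, cutoff: float = 15.0, gamma: float = 1.0) -> np.ndarray:
    """3N×3N anisotropic-network Hessian.

    Off-diagonal super-element for a contact pair (i,j) within ``cutoff``:
    −γ (d_ij d_ijᵀ)/|d_ij|²; diagonal super-elements are the negative sum
    of the row's off-diagonal blocks, which enforces translational
    invariance exactly.
    """
    x = np.asarray(coords, dtype=float)
    n = x.shape[0]
    h = np.zeros((3 * n, 3 * n))
    d = x[:, None, :] - x[None, :, :]
    r2 = (d * d).sum(-1)
    within = (r2 <= cutoff * cutoff) & ~np.eye(n, dtype=bool)
    for i in range(n):
        for j in np.where(within[i])[0]:
            if j <= i:
                continue
            dij = d[j, i]  # x_j - x_i ... direction irrelevant for outer product
            block = -gamma * np.outer(dij, dij) / r2[i, j]
            h[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            h[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
            h[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
            h[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return h


def _drop_rigid_modes(
    evals: np.ndarray, evecs: np.ndarray, spectral_gap: float = 1e6
) -> tuple[np.ndarray, np.ndarray]:
    """Remove exactly 6 rigid-body modes by eigenvalue rank.

    Verifies the spectral gap between mode 6 and mode 7 (ratio ≥
    ``spectral_gap`` relative to numerical zero) and that no more than 6
    near-zero modes exist, which would indicate a disconnected network.
    """
    order = np.argsort(evals)
    evals = evals[order]
    evecs = evecs[:, order]
    scale = max(evals[-1], 1e-300)
    near_zero = int(np.sum(evals < 1e-8 * scale))
    if near_zero > RIGID_BODY_MODES:
        raise ValueError(
            f"elastic network is disconnected: {near_zero} near-zero modes "
            "(more than the 6 rigid-body modes); increase the cutoff"
        )
    kept_vals = evals[RIGID_BODY_MODES:]
    kept_vecs = evecs[:, RIGID_BODY_MODES:]
    if kept_vals[0] <= 0 or kept_vals[0] / scale < 1e-12:
        raise ValueError("spectral gap after the 6 rigid-body modes is not resolved")
    return kept_vals, kept_vecs.T


def anm_modes(
    coords: np.ndarray,
    mask: np.ndarray | None = None,
    cutoff: float = 15.0,
    gamma: float = 1.0,
    n_modes: int | None = None,
) -> ModeSet:
    """Elastic-network normal modes of a single structure.

    Contribution fraction of retained mode k is its variance weight
    (1/λ_k) / Σ_m (1/λ_m) — softer modes contribute more fluctuation.
    Defaults (cutoff 15 Å, γ = 1) are standard Cα-network practice; the
    fractions are γ-independent.
    """
    x = np.asarray(coords, float)
    if mask is not None:
        x = x[np.asarray(mask, int)]
    h = build_anm_hessian(x, cutoff=cutoff, gamma=gamma)
    evals, evecs = np.linalg.eigh(h)
    kept_vals, kept_vecs = _drop_rigid_modes(evals, evecs)
    if n_modes is not None:
        kept_vals = kept_vals[:n_modes]
        kept_vecs = kept_vecs[:n_modes]
    weights = 1.0 / kept_vals
    return ModeSet(kept_vecs, kept_vals, "ENM", weights / weights.sum())


def pca_modes(
    ensemble: ConformationEnsemble,
    mask: SubdomainMask | np.ndarray | None = None,
    fit_mask: SubdomainMask | np.ndarray | None = None,
    n_modes: int | None = None,
) -> ModeSet:
    """Principal components of the aligned coordinate covariance.

    Contribution fraction of mode k is λ_k / Σλ.  Modes are ordered by
    decreasing variance; components with (numerically) zero variance are
    dropped.
    """
    if ensemble.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    idx = (
        np.arange(ensemble.n_atoms) if mask is None else _resolve(mask, ensemble)
    )
    fidx = idx if fit_mask is None else _resolve(fit_mask, ensemble)
    mean, aligned = iterative_mean_structure(ensemble, fidx)
    dev = (aligned[:, idx, :] - mean[None, idx, :]).reshape(ensemble.n_frames, -1)
    cov = dev.T @ dev / dev.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T
    nonzero = evals > 1e-12 * max(evals[0], 1e-300)
    evals, evecs = evals[nonzero], evecs[nonzero]
    if n_modes is not None:
        evals, evecs = evals[:n_modes], evecs[:n_modes]
    return ModeSet(evecs, evals, "PCA", evals / evals.sum())


def mode_porcupine(
    reference: np.ndarray,
    mode_vector: np.ndarray,
    scale: float = 5.0,
    n_frames: int = 11,
    atoms=None,
) -> ConformationEnsemble:
    """Multi-model ensemble sweeping reference ± scale·mode for visualization.

    Writing the result with :func:`polsite.struct_io.write_pdb` gives a
    trajectory that molecular viewers animate as the collective motion.
    """
    ref = np.asarray(reference, float)
    vec = np.asarray(mode_vector, float).reshape(ref.shape)
    amps = np.concatenate([np.linspace(-1, 1, n_frames), np.linspace(1, -1, n_frames)[1:-1]])
    frames = ref[None] + scale * amps[:, None, None] * vec[None]
    if atoms is None:
        from .struct_io import AtomRecord

        atoms = [AtomRecord(i + 1, "CA", "ALA", "A", i + 1, "C") for i in range(ref.shape[0])]
    return ConformationEnsemble(atoms, frames)


def mode_overlap(mode_vector: np.ndarray, displacement: np.ndarray) -> float:
    """|cosine| overlap between a mode and a reference displacement, in [0,1]."""
    u = np.asarray(mode_vector, float).ravel()
    v = np.asarray(displacement, float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal dimension")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero vector has no direction")
    return float(abs(np.dot(u, v)) / (nu * nv))


def rmsip(a: ModeSet, b: ModeSet, k: int = 5) -> float:
    """Root mean square inner product between the top-k subspaces of two mode sets."""
    ka = a.eigenvectors[:k]
    kb = b.eigenvectors[:k]
    inner = ka @ kb.T
    return float(np.sqrt((inner * inner).sum() / min(k, ka.shape[0], kb.shape[0])))
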