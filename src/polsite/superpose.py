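"""Rigid-body superposition and per-subdomain deviation/fluctuation metrics.

The workhorse is the weighted Kabsch fit (SVD with reflection correction).
Trajectory metrics follow the usual convention for subdomain analysis:
every frame is least-squares fitted on a *fit mask* (by default the stable
catalytic core), then the metric of interest is evaluated over one or more
*calculation masks* without refitting, so that relative subdomain motion
is not absorbed into the alignment.

RMSF is computed against the converged iterative mean structure rather
than frame 1, which removes the arbitrary-reference bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .struct_io import ConformationEnsemble, SubdomainMask
from .constants import REPRESENTATIVE_ATOMS

__all__ = [
    "SuperpositionResult",
    "RmsdSeries",
    "RmsfProfile",
    "kabsch",
    "apply_transform",
    "align_frames",
    "rmsd_series",
    "rmsf_profile",
    "delta_rmsf",
    "domain_rotation_angle",
    "atom_pair_distance",
    "rotation_angle_deg",
]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3×3, proper (det = +1)
    translation: np.ndarray  # applied after rotation
    rmsd: float
    degenerate: bool = False  # collinear/planar-degenerate input flagged

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RmsdSeries:
    """Per-frame RMSD (Å) for each named subdomain."""

    values: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[name]


@dataclass
class RmsfProfile:
    """Per-residue RMSF (Å) keyed by (chain, residue-number-string)."""

    values: dict[tuple[str, str], float]

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.values[key]

    def keys(self):
        return self.values.keys()


def kabsch(
    mobile: np.ndarray, target: np.ndarray, weights: np.ndarray | None = None
) -> SuperpositionResult:
    """Weighted least-squares rigid fit of ``mobile`` onto ``target``.

    Returns rotation R and translation t minimizing the weighted RMSD of
    ``mobile @ R.T + t`` to ``target``.  Reflections are excluded by sign
    correction on the smallest singular value, so R is always a proper
    rotation.  Collinear point sets are fitted but flagged ``degenerate``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile/target must be equal-shape N×3 arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("at least 3 points are required for a rigid fit")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative, not all zero")
    wsum = w.sum()
    mc = (w[:, None] * mobile).sum(0) / wsum
    tc = (w[:, None] * target).sum(0) / wsum
    pm = mobile - mc
    pt = target - tc
    h = (w[:, None] * pm).T @ pt
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    # rank deficiency of the covariance => collinear (or coincident) points
    degenerate = bool(s[1] <= 1e-10 * max(s[0], 1e-300))
    fitted = pm @ rot.T
    rmsd = float(np.sqrt((w[:, None] * (fitted - pt) ** 2).sum() / wsum))
    translation = tc - mc @ rot.T
    return SuperpositionResult(rot, translation, rmsd, degenerate)


def apply_transform(frames: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    return frames @ result.rotation.T + result.translation


def rotation_angle_deg(rotation: np.ndarray) -> float:
    """Geodesic angle of a rotation matrix, degrees in [0, 180]."""
    c = (np.trace(rotation) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _resolve(mask: SubdomainMask | np.ndarray, ens: ConformationEnsemble) -> np.ndarray:
    if isinstance(mask, SubdomainMask):
        return mask.resolve(ens)
    idx = np.asarray(mask, dtype=int)
    if idx.size == 0:
        raise ValueError("empty mask")
    return idx


def align_frames(
    ensemble: ConformationEnsemble,
    reference: np.ndarray,
    fit_mask: SubdomainMask | np.ndarray,
) -> np.ndarray:
    """All frames rigid-fitted (on fit_mask atoms) onto ``reference``."""
    fit_idx = _resolve(fit_mask, ensemble)
    out = np.empty_like(ensemble.frames)
    for f in range(ensemble.n_frames):
        res = kabsch(ensemble.frames[f, fit_idx], reference[fit_idx])
        out[f] = apply_transform(ensemble.frames[f], res)
    return out


def rmsd_series(
    ensemble: ConformationEnsemble,
    reference: np.ndarray,
    fit_mask: SubdomainMask | np.ndarray,
    calc_masks: dict[str, SubdomainMask | np.ndarray],
) -> RmsdSeries:
    """Per-frame, per-subdomain RMSD to a reference structure.

    Each frame is fitted on ``fit_mask``; RMSD is then computed over each
    calculation mask *without refitting*, so subdomain displacement
    relative to the fitted core is retained.
    """
    reference = np.asarray(reference, dtype=float)
    fit_idx = _resolve(fit_mask, ensemble)
    calc_idx = {name: _resolve(m, ensemble) for name, m in calc_masks.items()}
    out = {name: np.empty(ensemble.n_frames) for name in calc_idx}
    for f in range(ensemble.n_frames):
        res = kabsch(ensemble.frames[f, fit_idx], reference[fit_idx])
        moved = apply_transform(ensemble.frames[f], res)
        for name, idx in calc_idx.items():
            d = moved[idx] - reference[idx]
            out[name][f] = np.sqrt((d * d).sum() / idx.size)
    return RmsdSeries(out)


def iterative_mean_structure(
    ensemble: ConformationEnsemble,
    fit_mask: SubdomainMask | np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Converged mean structure and the frames aligned to it.

    Iterates: align all frames to the current mean (fit on fit_mask),
    recompute the mean, until the mean moves by < ``tol`` Å RMSD.
    """
    fit_idx = _resolve(fit_mask, ensemble)
    mean = ensemble.frames[0].copy()
    aligned = ensemble.frames.copy()
    for _ in range(max_iter):
        for f in range(aligned.shape[0]):
            res = kabsch(aligned[f, fit_idx], mean[fit_idx])
            aligned[f] = apply_transform(aligned[f], res)
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(((new_mean - mean) ** 2).sum() / mean.shape[0]))
        mean = new_mean
        if shift < tol:
            return mean, aligned
    raise RuntimeError(
        f"mean structure failed to converge in {max_iter} iterations "
        f"(last shift {shift:.3e} Å > {tol} Å)"
    )


def rmsf_profile(
    ensemble: ConformationEnsemble,
    fit_mask: SubdomainMask | np.ndarray,
    calc_mask: SubdomainMask | np.ndarray | None = None,
    representative_atoms: frozenset[str] | None = REPRESENTATIVE_ATOMS,
    max_iter: int = 100,
) -> RmsfProfile:
    """Per-residue RMSF about the converged mean structure.

    RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩) over frames, reported per residue using
    a representative atom (Cα for amino acids, C1′ for nucleotides); pass
    ``representative_atoms=None`` to average all selected atoms per residue.
    Non-convergence of the mean within ``max_iter`` iterations is an error.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    mean, aligned = iterative_mean_structure(ensemble, fit_mask, max_iter=max_iter)
    if calc_mask is None:
        calc_idx = np.arange(ensemble.n_atoms)
    else:
        calc_idx = _resolve(calc_mask, ensemble)
    dev = aligned - mean[None, :, :]
    msf = (dev * dev).sum(axis=2).mean(axis=0)  # per-atom mean square fluct.
    per_res: dict[tuple[str, str], list[float]] = {}
    for i in calc_idx:
        a = ensemble.atoms[i]
        if representative_atoms is not None and a.name not in representative_atoms:
            continue
        per_res.setdefault(a.residue_key, []).append(msf[i])
    if not per_res and representative_atoms is not None:
        # no Cα/C1′ in selection (e.g. toy particles) — fall back to all atoms
        for i in calc_idx:
            per_res.setdefault(ensemble.atoms[i].residue_key, []).append(msf[i])
    return RmsfProfile(
        {k: float(np.sqrt(np.mean(v))) for k, v in per_res.items()}
    )


def delta_rmsf(a: RmsfProfile, b: RmsfProfile) -> dict[tuple[str, str], float]:
    """Per-residue RMSF difference a − b on the shared residue keys.

    Residues present in only one profile are dropped (reported via the
    returned mapping's complement); disjoint profiles raise.
    """
    shared = set(a.values) & set(b.values)
    if not shared:
        raise ValueError("profiles share no residues")
    return {k: a.values[k] - b.values[k] for k in sorted(shared)}


def domain_rotation_angle(
    conf_a: ConformationEnsemble,
    conf_b: ConformationEnsemble,
    fit_mask: SubdomainMask | np.ndarray,
    domain_mask: SubdomainMask | np.ndarray,
    direction_reference: np.ndarray | None = None,
) -> tuple[float, float | None]:
    """Rotation (degrees) of a subdomain between two conformations.

    Both structures are first superposed on ``fit_mask`` (e.g. the Palm
    core); a second Kabsch fit maps the domain atoms of *a* onto *b* and
    the unsigned geodesic angle of that rotation is returned.

    If ``direction_reference`` (a point, e.g. the active-site centroid) is
    supplied, the signed projection of the domain-centroid displacement
    onto the direction toward that point is returned second: positive
    means the domain moved toward it.
    """
    fit_a = _resolve(fit_mask, conf_a)
    fit_b = _resolve(fit_mask, conf_b)
    dom_a = _resolve(domain_mask, conf_a)
    dom_b = _resolve(domain_mask, conf_b)
    if dom_a.size < 3 or dom_b.size < 3:
        raise ValueError("domain mask must select at least 3 atoms")
    xa, xb = conf_a.frames[0], conf_b.frames[0]
    core = kabsch(xb[fit_b], xa[fit_a])
    xb_fit = apply_transform(xb, core)
    dom = kabsch(xa[dom_a], xb_fit[dom_b])
    angle = rotation_angle_deg(dom.rotation)
    signed_toward: float | None = None
    if direction_reference is not None:
        ca = xa[dom_a].mean(0)
        cb = xb_fit[dom_b].mean(0)
        toward = np.asarray(direction_reference, float) - ca
        nrm = np.linalg.norm(toward)
        if nrm > 0:
            signed_toward = float(np.dot(cb - ca, toward / nrm))
    return angle, signed_toward


def atom_pair_distance(
    conf: ConformationEnsemble,
    atom_spec_1: dict,
    atom_spec_2: dict,
    frame: int = 0,
) -> float:
    """Euclidean distance (Å) between two uniquely specified atoms.

    Atom specs are keyword mappings for :meth:`ConformationEnsemble.atom_index`,
    e.g. ``{"name": "O3'", "chain_id": "P", "residue_number": 25}``.
    """
    i = conf.atom_index(**atom_spec_1)
    j = conf.atom_index(**atom_spec_2)
    d = conf.frames[frame, i] - conf.frames[frame, j]
    return float(np.linalg.norm(d))
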