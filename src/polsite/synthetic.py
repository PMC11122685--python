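"""Synthetic input generators with known ground truth.

Production molecular-dynamics trajectories for the polymerase systems are
not distributable, so every downstream stage of the pipeline is exercised
on synthetic data whose generating parameters are exactly known:

* ``gen_enm_ensemble`` — Gaussian conformational ensembles drawn from the
  thermal covariance of an elastic-network model, k_B·T H⁺ (pseudo-inverse
  over internal modes), giving subdomain-correlated fluctuations whose
  RMSF, DCCM and principal components have closed-form references.
* ``gen_two_state_distances`` — a two-component bivariate Gaussian mixture
  in (d1, d2) catalytic-distance space with known state occupancies,
  emulating the competent/incompetent active-site populations (wild-type
  d1 centered near 3.5 Å with competent occupancy 0.40; mutant-like d1
  near 4.3 Å with occupancy ≤ 0.15).
* ``gen_toy_topology`` — small charged topologies (an "arginine-like" +1
  residue contacting a "dCTP-like" −4 ligand) for energy-decomposition
  tests with hand-computable pair energies.
* ``gen_itc_isotherm`` — Wiseman single-site titration heats with additive
  Gaussian noise, for fitting-recovery studies.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB_KCAL
from .struct_io import AtomRecord, ConformationEnsemble, ToyTopology
from .modes import build_anm_hessian, RIGID_BODY_MODES

__all__ = [
    "TwoStateDistanceModel",
    "ITCGroundTruth",
    "DistanceSeries",
    "BindingIsotherm",
    "gen_enm_ensemble",
    "gen_two_state_distances",
    "gen_toy_topology",
    "gen_itc_isotherm",
    "helix_coords",
    "WT_TWO_STATE",
    "MUTANT_TWO_STATE",
]


@dataclass
class DistanceSeries:
    """Per-frame values (Å) of named atom-pair distances."""

    values: dict[str, np.ndarray]
    frame_index: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    @property
    def n_frames(self) -> int:
        return self.frame_index.shape[0]


@dataclass
class BindingIsotherm:
    """An ITC titration: geometry, schedule and per-injection heats."""

    injection_volumes_uL: np.ndarray
    cell_volume_uL: float
    cell_concentration_M: float
    syringe_concentration_M: float
    heats_ucal: np.ndarray
    temperature_K: float

    def __post_init__(self):
        self.injection_volumes_uL = np.asarray(self.injection_volumes_uL, float)
        self.heats_ucal = np.asarray(self.heats_ucal, float)
        if np.any(self.injection_volumes_uL <= 0):
            raise ValueError("injection volumes must be positive")
        if min(self.cell_volume_uL, self.cell_concentration_M,
               self.syringe_concentration_M, self.temperature_K) <= 0:
            raise ValueError("volumes, concentrations and temperature must be positive")
        if not np.all(np.isfinite(self.heats_ucal)):
            raise ValueError("heats must be finite")


@dataclass
class TwoStateDistanceModel:
    """Bivariate two-state mixture in (d1, d2) space.

    State A is the catalytically competent well, state B the incompetent
    one.  Defaults are supplied by :data:`WT_TWO_STATE` and
    :data:`MUTANT_TWO_STATE`.
    """

    mean_a: np.ndarray
    mean_b: np.ndarray
    cov_a: np.ndarray
    cov_b: np.ndarray
    p_a: float
    n_frames: int
    seed: int = 853

    def __post_init__(self):
        self.mean_a = np.asarray(self.mean_a, float)
        self.mean_b = np.asarray(self.mean_b, float)
        self.cov_a = np.asarray(self.cov_a, float)
        self.cov_b = np.asarray(self.cov_b, float)
        for c in (self.cov_a, self.cov_b):
            if not np.allclose(c, c.T):
                raise ValueError("covariances must be symmetric")
            if np.any(np.linalg.eigvalsh(c) <= 0):
                raise ValueError("covariances must be positive definite")
        if not 0.0 <= self.p_a <= 1.0:
            raise ValueError("p_a must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


def _two_state(mean_a, mean_b, sd_a, sd_b, p_a, n_frames, seed):
    return TwoStateDistanceModel(
        np.asarray(mean_a, float),
        np.asarray(mean_b, float),
        np.diag([sd_a**2, sd_a**2]),
        np.diag([sd_b**2, sd_b**2]),
        p_a,
        n_frames,
        seed,
    )


def WT_TWO_STATE(n_frames: int = 150_000, seed: int = 853) -> TwoStateDistanceModel:
    """Wild-type-like regime: competent well at d1 ≈ 3.5 Å, occupancy 0.40."""
    return _two_state((3.5, 3.15), (4.3, 3.8), 0.10, 0.25, 0.40, n_frames, seed)


def MUTANT_TWO_STATE(n_frames: int = 150_000, seed: int = 853) -> TwoStateDistanceModel:
    """Mutant-like regime: d1 well shifted to 4.3 Å, competent occupancy 0.12."""
    return _two_state((3.5, 3.15), (4.3, 3.8), 0.10, 0.25, 0.12, n_frames, seed)


@dataclass
class ITCGroundTruth:
    """Known binding parameters plus titration geometry for synthesis.

    Default geometry mirrors a standard low-volume titration: 19 injections
    (one 0.4 μL priming injection then 18 × 2 μL) of 200 μM ligand into a
    200 μL cell holding 5 μM macromolecule at 310.15 K.
    """

    n: float = 1.0
    kd_M: float = 55e-9
    dh_kcal: float = -10.0
    cell_concentration_M: float = 5e-6
    syringe_concentration_M: float = 200e-6
    injection_volumes_uL: np.ndarray = field(
        default_factory=lambda: np.asarray([0.4] + [2.0] * 18)
    )
    cell_volume_uL: float = 200.0
    heat_noise_sd_ucal: float = 0.0
    temperature_K: float = 310.15
    seed: int = 853

    def __post_init__(self):
        self.injection_volumes_uL = np.asarray(self.injection_volumes_uL, float)
        if self.kd_M <= 0:
            raise ValueError("Kd must be positive")
        if min(self.cell_concentration_M, self.syringe_concentration_M,
               self.cell_volume_uL, self.temperature_K) <= 0:
            raise ValueError("concentrations, volumes and temperature must be positive")
        if np.any(self.injection_volumes_uL <= 0):
            raise ValueError("injection volumes must be positive")


# ---------------------------------------------------------------------------


def helix_coords(n: int, rise: float = 1.5, radius: float = 2.3, turn: float = 100.0) -> np.ndarray:
    """A generic helical bead arrangement used as the synthetic reference fold."""
    t = np.arange(n) * np.radians(turn)
    return np.column_stack(
        [radius * np.cos(t), radius * np.sin(t), np.arange(n) * rise]
    )


def gen_enm_ensemble(
    reference: np.ndarray,
    cutoff: float = 15.0,
    gamma: float = 1.0,
    temperature_K: float = 300.0,
    n_frames: int = 1000,
    seed: int = 853,
    atoms: list[AtomRecord] | None = None,
) -> tuple[ConformationEnsemble, np.ndarray]:
    """Sample a Gaussian ensemble from an elastic-network thermal covariance.

    Displacements are drawn from N(0, k_B·T·H⁺) where H is the anisotropic
    network Hessian of the reference structure and the pseudo-inverse runs
    over the 3N−6 internal modes only (rigid modes excluded by rank, after
    checking the spectral gap).  Returns the ensemble and the exact 3N×3N
    covariance used, which is the ground truth for fluctuation, correlation
    and mode-recovery tests downstream.

    temperature_K = 0 returns the reference replicated in every frame.
    """
    x0 = np.asarray(reference, float)
    n = x0.shape[0]
    h = build_anm_hessian(x0, cutoff=cutoff, gamma=gamma)
    evals, evecs = np.linalg.eigh(h)
    scale = max(evals[-1], 1e-300)
    near_zero = int(np.sum(evals < 1e-8 * scale))
    if near_zero > RIGID_BODY_MODES:
        raise ValueError(
            f"structure is disconnected at cutoff {cutoff} Å: "
            f"{near_zero} near-zero modes (> 6 rigid-body modes)"
        )
    internal_vals = evals[RIGID_BODY_MODES:]
    internal_vecs = evecs[:, RIGID_BODY_MODES:]
    var = KB_KCAL * temperature_K / internal_vals  # per-mode variance, Å²
    cov = (internal_vecs * var) @ internal_vecs.T
    rng = np.random.default_rng(seed)
    if temperature_K == 0:
        frames = np.repeat(x0[None], n_frames, axis=0)
    else:
        z = rng.standard_normal((n_frames, internal_vals.shape[0]))
        disp = (z * np.sqrt(var)) @ internal_vecs.T  # F × 3N
        frames = x0[None] + disp.reshape(n_frames, n, 3)
    if atoms is None:
        atoms = [AtomRecord(i + 1, "CA", "ALA", "A", i + 1, "C") for i in range(n)]
    return ConformationEnsemble(atoms, frames), cov


def model_rmsf(covariance: np.ndarray) -> np.ndarray:
    """Per-atom RMSF implied by a 3N×3N displacement covariance."""
    n = covariance.shape[0] // 3
    out = np.empty(n)
    for i in range(n):
        out[i] = np.sqrt(np.trace(covariance[3 * i : 3 * i + 3, 3 * i : 3 * i + 3]))
    return out


def model_dccm(covariance: np.ndarray) -> np.ndarray:
    """DCCM implied by a 3N×3N displacement covariance."""
    n = covariance.shape[0] // 3
    mat = np.empty((n, n))
    tr = np.empty(n)
    for i in range(n):
        tr[i] = np.trace(covariance[3 * i : 3 * i + 3, 3 * i : 3 * i + 3])
    for i in range(n):
        for j in range(n):
            cij = np.trace(covariance[3 * i : 3 * i + 3, 3 * j : 3 * j + 3])
            mat[i, j] = cij / np.sqrt(tr[i] * tr[j])
    return mat


def gen_two_state_distances(model: TwoStateDistanceModel) -> tuple[DistanceSeries, np.ndarray]:
    """Draw per-frame (d1, d2) pairs from the two-state mixture.

    Each frame comes from state A with probability p_a, else state B.
    Negative draws (unphysical distances) are rejected and resampled, which
    for the default regime (means ≥ 2.8 Å, sd ≤ 0.5 Å) essentially never
    triggers and does not materially bias the mode locations.

    Returns the series and the true per-frame state labels (0 = A, 1 = B).
    """
    rng = np.random.default_rng(model.seed)
    labels = (rng.random(model.n_frames) >= model.p_a).astype(int)
    la, lb = np.linalg.cholesky(model.cov_a), np.linalg.cholesky(model.cov_b)
    means = (model.mean_a, model.mean_b)
    chols = (la, lb)
    pts = np.empty((model.n_frames, 2))
    for state in (0, 1):
        idx = np.where(labels == state)[0]
        if idx.size == 0:
            continue
        draws = means[state] + rng.standard_normal((idx.size, 2)) @ chols[state].T
        bad = np.where((draws <= 0).any(axis=1))[0]
        while bad.size:
            draws[bad] = means[state] + rng.standard_normal((bad.size, 2)) @ chols[state].T
            bad = bad[(draws[bad] <= 0).any(axis=1)]
        pts[idx] = draws
    series = DistanceSeries(
        {"d1": pts[:, 0], "d2": pts[:, 1]}, np.arange(model.n_frames)
    )
    return series, labels


def gen_toy_topology(
    residue_charges: dict[str, float],
    atoms_per_residue: int = 1,
    spacing: float = 3.32,
    sigma: float = 3.4,
    epsilon: float = 0.1,
    seed: int = 853,
) -> tuple[ToyTopology, np.ndarray]:
    """Build a toy charged topology from residue net charges.

    Each residue gets ``atoms_per_residue`` beads placed on a line at
    ``spacing`` Å intervals; residue net charge is split equally over its
    beads.  Intra-residue consecutive beads are bonded (so 1-2 exclusions
    exist to exercise the bookkeeping).  Deterministic given its arguments;
    ``seed`` only perturbs nothing by default and exists for interface
    symmetry with the other generators.
    """
    if not residue_charges:
        raise ValueError("at least one residue required")
    if atoms_per_residue < 1:
        raise ValueError("atoms_per_residue must be >= 1")
    charges, sigmas, epsilons, residue_of, coords, bonds = [], [], [], [], [], []
    k = 0
    for r, (label, q) in enumerate(residue_charges.items()):
        for a in range(atoms_per_residue):
            charges.append(q / atoms_per_residue)
            sigmas.append(sigma)
            epsilons.append(epsilon)
            residue_of.append(label)
            coords.append([k * spacing, 0.0, 0.0])
            if a > 0:
                bonds.append((k - 1, k))
            k += 1
    topo = ToyTopology(
        np.asarray(charges), np.asarray(sigmas), np.asarray(epsilons), bonds, residue_of
    )
    return topo, np.asarray(coords)


def gen_itc_isotherm(truth: ITCGroundTruth) -> BindingIsotherm:
    """Synthesize a noisy titration from known (n, Kd, ΔH).

    Heats come from the single-site Wiseman model with perfusion dilution
    (see :mod:`polsite.thermo`), plus i.i.d. Gaussian noise of the given
    standard deviation.  A syringe concentration not well in excess of the
    cell concentration gives a poorly determined fit and triggers a
    warning, not an error.
    """
    import warnings

    from .thermo import wiseman_model

    if truth.syringe_concentration_M <= 5 * truth.cell_concentration_M:
        warnings.warn(
            "syringe concentration ≤ 5× cell concentration: the titration "
            "will not approach saturation and the fit may be poorly determined",
            stacklevel=2,
        )
    heats = wiseman_model(
        truth.injection_volumes_uL,
        truth.cell_volume_uL,
        truth.cell_concentration_M,
        truth.syringe_concentration_M,
        truth.n,
        truth.kd_M,
        truth.dh_kcal,
    )
    rng = np.random.default_rng(truth.seed)
    if truth.heat_noise_sd_ucal > 0:
        heats = heats + rng.normal(0.0, truth.heat_noise_sd_ucal, heats.shape)
    return BindingIsotherm(
        truth.injection_volumes_uL.copy(),
        truth.cell_volume_uL,
        truth.cell_concentration_M,
        truth.syringe_concentration_M,
        heats,
        truth.temperature_K,
    )
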