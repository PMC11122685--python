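"""Catalytic-distance extraction, k-means clustering and competence fractions.

The geometric readiness of a polymerase active site for phosphoryl
transfer is summarized by two distances: d1, primer 3′-oxygen to the
incoming nucleotide's α-phosphate, and d2, catalytic-aspartate carboxylate
oxygen to the primer 3′-oxygen.  Frames with d1 ∈ [3.0, 3.8] Å and
d2 ∈ [2.8, 3.5] Å (closed intervals) lie in the *competence box* — poised
for in-line attack.  Clustering the (d1, d2) scatter with k-means and
measuring box occupancy quantifies how much of an ensemble is
catalytically competent.

Distances are clustered unscaled (both axes in Å, shared units); no
standardization is applied.  Randomness is funnelled through a default
seed of 853 (mnemonic for the mutation site studied).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .struct_io import ConformationEnsemble
from .synthetic import DistanceSeries

__all__ = [
    "DistanceSpec",
    "CompetenceBox",
    "ClusterResult",
    "DEFAULT_BOX",
    "DEFAULT_DISTANCE_SPECS",
    "extract_distances",
    "kmeans_2d",
    "silhouette_best_k",
    "box_occupancy",
    "threshold_fractions",
]

DEFAULT_SEED = 853


@dataclass(frozen=True)
class DistanceSpec:
    """A named atom-pair distance, e.g. primer O3′ to dCTP Pα."""

    name: str
    atom_spec_1: tuple[tuple[str, object], ...]
    atom_spec_2: tuple[tuple[str, object], ...]
    role: str = ""

    @staticmethod
    def make(name: str, spec1: dict, spec2: dict, role: str = "") -> "DistanceSpec":
        return DistanceSpec(name, tuple(sorted(spec1.items())), tuple(sorted(spec2.items())), role)


# The five catalytic coordinates monitored in the active site; atom specs
# are resolved against ensembles built by the synthetic/structural layers.
DEFAULT_DISTANCE_SPECS = [
    DistanceSpec.make("MgA_O3p", {"name": "MG", "residue_name": "MGA"}, {"name": "O3'"}, "purple"),
    DistanceSpec.make("d1_O3p_PA", {"name": "O3'"}, {"name": "PA"}, "tan"),
    DistanceSpec.make("Asp_OD2_MgA", {"name": "OD2"}, {"name": "MG", "residue_name": "MGA"}, "green"),
    DistanceSpec.make("Asp_OD1_MgA", {"name": "OD1"}, {"name": "MG", "residue_name": "MGA"}, "pink"),
    DistanceSpec.make("Asp890_MgB", {"name": "OD1", "residue_number": 890}, {"name": "MG", "residue_name": "MGB"}, "blue"),
]


@dataclass(frozen=True)
class CompetenceBox:
    d1_low: float = 3.0
    d1_high: float = 3.8
    d2_low: float = 2.8
    d2_high: float = 3.5

    def __post_init__(self):
        if not (self.d1_low < self.d1_high and self.d2_low < self.d2_high):
            raise ValueError("box bounds must satisfy low < high on both axes")

    def contains(self, d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
        return (
            (d1 >= self.d1_low)
            & (d1 <= self.d1_high)
            & (d2 >= self.d2_low)
            & (d2 <= self.d2_high)
        )


DEFAULT_BOX = CompetenceBox()


@dataclass
class ClusterResult:
    k: int
    centroids: np.ndarray  # k × 2, (d1, d2) Å
    assignment: np.ndarray  # per-frame cluster index
    occupancies: np.ndarray  # per-cluster frame fractions, sum 1
    inertia: float  # within-cluster sum of squares
    seed: int


def extract_distances(
    ensemble: ConformationEnsemble, specs: list[DistanceSpec]
) -> DistanceSeries:
    """Per-frame Euclidean distances for each named atom-pair spec."""
    out = {}
    for spec in specs:
        try:
            i = ensemble.atom_index(**dict(spec.atom_spec_1))
            j = ensemble.atom_index(**dict(spec.atom_spec_2))
        except KeyError as exc:
            raise KeyError(f"distance {spec.name!r}: {exc}") from exc
        d = ensemble.frames[:, i, :] - ensemble.frames[:, j, :]
        out[spec.name] = np.sqrt((d * d).sum(axis=1))
    return DistanceSeries(out, np.asarray(ensemble.frame_index))


def _kmeans_pp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: first centre uniform, then D²-weighted."""
    n = points.shape[0]
    centers = np.empty((k, points.shape[1]))
    centers[0] = points[rng.integers(n)]
    d2 = ((points - centers[0]) ** 2).sum(1)
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[c:] = points[rng.integers(n, size=k - c)]
            break
        probs = d2 / total
        centers[c] = points[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((points - centers[c]) ** 2).sum(1))
    return centers


def _lloyd(points: np.ndarray, centers: np.ndarray, max_iter: int = 300, tol: float = 1e-10):
    """Lloyd iterations; within-cluster SSE is checked to be non-increasing.

    Assignment ties are broken toward the lowest cluster index (argmin on
    the distance matrix returns the first minimum).
    """
    prev_inertia = np.inf
    for _ in range(max_iter):
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        assignment = d2.argmin(1)
        inertia = float(d2[np.arange(points.shape[0]), assignment].sum())
        assert inertia <= prev_inertia + 1e-9 * max(1.0, prev_inertia), (
            "Lloyd iteration increased the within-cluster sum of squares"
        )
        new_centers = centers.copy()
        for c in range(centers.shape[0]):
            members = points[assignment == c]
            if members.shape[0]:
                new_centers[c] = members.mean(0)
        if abs(prev_inertia - inertia) <= tol * max(1.0, inertia):
            centers = new_centers
            break
        centers, prev_inertia = new_centers, inertia
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    assignment = d2.argmin(1)
    inertia = float(d2[np.arange(points.shape[0]), assignment].sum())
    return centers, assignment, inertia


def kmeans_2d(
    points: np.ndarray, k: int, seed: int = DEFAULT_SEED, n_init: int = 10
) -> ClusterResult:
    """Seeded k-means (k-means++ + Lloyd, best of ``n_init`` restarts)."""
    points = np.asarray(points, float)
    if points.ndim != 2:
        raise ValueError("points must be F×D")
    f = points.shape[0]
    if not 1 <= k <= f:
        raise ValueError("need F >= k >= 1")
    n_distinct = np.unique(points, axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(f"only {n_distinct} distinct points for k={k} clusters")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centers = _kmeans_pp_init(points, k, rng)
        centers, assignment, inertia = _lloyd(points, centers)
        if best is None or inertia < best[2]:
            best = (centers, assignment, inertia)
    centers, assignment, inertia = best
    # deterministic presentation: order clusters by centroid (d1, then d2)
    order = np.lexsort((centers[:, 1], centers[:, 0]))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    centers = centers[order]
    assignment = remap[assignment]
    occ = np.bincount(assignment, minlength=k) / f
    return ClusterResult(k, centers, assignment, occ, inertia, seed)


def silhouette_best_k(
    points: np.ndarray,
    k_range: range = range(2, 7),
    seed: int = DEFAULT_SEED,
    max_sample: int = 5000,
) -> int:
    """Default-k heuristic: best mean silhouette score over k ∈ {2..6}.

    Scored on a seeded subsample for tractability on long trajectories.
    """
    from sklearn.metrics import silhouette_score

    points = np.asarray(points, float)
    rng = np.random.default_rng(seed)
    if points.shape[0] > max_sample:
        idx = rng.choice(points.shape[0], max_sample, replace=False)
        sample = points[idx]
    else:
        sample = points
    best_k, best_s = None, -np.inf
    for k in k_range:
        if np.unique(sample, axis=0).shape[0] <= k:
            continue
        res = kmeans_2d(sample, k, seed=seed, n_init=4)
        if np.unique(res.assignment).shape[0] < 2:
            continue
        s = silhouette_score(sample, res.assignment)
        if s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no k in range produced a valid clustering")
    return best_k


def box_occupancy(
    series: DistanceSeries,
    box: CompetenceBox = DEFAULT_BOX,
    clusters: ClusterResult | None = None,
    d1_key: str = "d1",
    d2_key: str = "d2",
) -> dict:
    """Fraction of frames inside the closed competence box.

    Returns a mapping with the frame-count fraction plus, when a cluster
    result is supplied, which centroids fall inside the box and the total
    occupancy of those clusters (the two readings of "snapshots in the
    box": per-frame membership vs. membership of box-centred clusters).
    """
    if d1_key not in series or d2_key not in series:
        raise KeyError(f"series must contain {d1_key!r} and {d2_key!r}")
    d1 = series[d1_key]
    d2 = series[d2_key]
    inside = box.contains(d1, d2)
    out = {
        "fraction": float(inside.mean()),
        "count": int(inside.sum()),
        "n_frames": int(d1.shape[0]),
    }
    if clusters is not None:
        cin = box.contains(clusters.centroids[:, 0], clusters.centroids[:, 1])
        out["clusters_in_box"] = np.where(cin)[0].tolist()
        out["cluster_fraction"] = float(clusters.occupancies[cin].sum())
    return out


def threshold_fractions(
    series: DistanceSeries,
    competent_max: float = 3.8,
    incompetent_min: float = 4.0,
    d1_key: str = "d1",
) -> tuple[float, float, float]:
    """(competent, incompetent, intermediate) fractions from d1 thresholds.

    Competent: d1 < competent_max (strict); incompetent: d1 > incompetent_min
    (strict); intermediate: the remainder.  The three fractions sum to 1.
    """
    if competent_max > incompetent_min:
        raise ValueError("competent_max must be <= incompetent_min")
    d1 = series[d1_key]
    f_comp = float((d1 < competent_max).mean())
    f_incomp = float((d1 > incompetent_min).mean())
    return f_comp, f_incomp, 1.0 - f_comp - f_incomp
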