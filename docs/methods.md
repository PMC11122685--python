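# Methods

This note documents the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices a maintainer would want to know.

## Coordinate conventions and I/O

Coordinates are in ångström throughout; residue numbering is 1-based and
range selections are inclusive of both endpoints. Multi-model PDB is the
canonical trajectory interchange format; a whitespace XYZ dialect
(count / comment / element x y z) is accepted for synthetic ensembles.
When parsing real PDB files, the first alternate location of an atom is
kept and insertion codes are treated as distinct residues — deterministic
behaviour without modelling crystallographic detail. Writing refuses any
coordinate that does not fit the fixed 8.3 column (no silent truncation).
Subdomain masks are residue-level selections; overlapping masks are
allowed by design, since subdomain boundaries are conventions rather than
partitions.

Backbone-level metrics (RMSD, RMSF, DCCM, modes) use one representative
atom per residue — Cα for amino acids, C1′ for nucleotides — which is
standard practice for subdomain dynamics; toy systems without those atom
names fall back to all atoms.

## Superposition and fluctuation metrics

Rigid fits use the weighted Kabsch algorithm (SVD with a sign correction
on the smallest singular value, so the returned rotation is always
proper; collinear inputs are fitted but flagged degenerate). Trajectory
metrics follow the fit-mask/calc-mask convention: each frame is
least-squares fitted on a stable core (the Palm-like subdomain by
default, chosen as the least mobile catalytic core; configurable) and the
metric is evaluated over each analysis mask *without refitting*, so that
relative subdomain displacement is retained rather than absorbed.

RMSF is computed about the converged iterative mean structure (align all
frames to the current mean, recompute, iterate until the mean moves by
less than 1e-6 Å RMSD), which removes the arbitrary-reference bias of
aligning to frame 1. The RMSF entry point errors after 100 iterations;
the shared alignment helper allows up to 500 because small, very noisy
toy ensembles converge geometrically but slowly. On small systems the
superposition itself absorbs up to 6/(3N) of the fluctuation variance;
consistency tests therefore use enough atoms (or compare against the
generating covariance directly) so this bias is below their tolerance.

Domain rotation between two conformations is measured by superposing both
on the fit mask and Kabsch-fitting the domain atoms of one onto the
other; the unsigned geodesic angle θ = acos((tr R − 1)/2) ∈ [0°, 180°] is
reported. "Toward/away" directionality is deliberately separate: the
signed projection of the domain-centroid displacement onto the direction
of a user-supplied reference point (e.g. the active-site centroid).

## Correlated motion and modes

The DCCM is the normalized covariance of representative-atom displacement
vectors after alignment. Atoms whose displacement variance is zero (up to
alignment round-off, threshold 1e-12 of the largest variance) cannot be
normalized; their rows/columns are set to NaN and reported rather than
silently dropped. Difference maps are computed mutant − wild-type, with
per-subdomain-pair block means (off-diagonal within a block) as the
summary statistic for gained/lost correlation.

Two mode sets are provided because collective-motion reports in the
literature come from either source and the choice is rarely stated:

* **ENM/ANM** on a single structure: Hessian super-elements
  −γ d̂ d̂ᵀ for contacts within a cutoff; defaults cutoff 15 Å, γ = 1
  (standard Cα-network practice; contribution fractions are γ-free).
  Exactly six rigid-body modes are removed by eigenvalue rank — not by
  threshold — after verifying that no more than six near-zero eigenvalues
  exist (more indicates a disconnected network, which is an error naming
  the cause). Mode k's contribution fraction is its variance weight
  (1/λ_k)/Σ(1/λ_m) over retained modes.
* **PCA** of the aligned ensemble covariance: fraction λ_k/Σλ.

Reports list the top 10 modes (all, when fewer exist) and label which
variant produced them. Biological labels such as "breathing" vs
"rocking" are never hard-coded: `mode_overlap` scores |cos| against
user-supplied reference displacement vectors (e.g. open-minus-closed
coordinates) and the caller assigns labels by argmax — a quantitative,
explicit surrogate for what is otherwise a visual-inspection call.
`mode_porcupine` writes reference ± scaled-mode sweeps as multi-model PDB
for animation in a molecular viewer.

## Catalytic competence

d1 (primer O3′ → dNTP Pα) and d2 (catalytic-aspartate carboxylate O →
primer O3′) are clustered unscaled — both axes share units of Å, so no
standardization is applied. k-means is the in-package seeded Lloyd
algorithm (k-means++ initialization, best of n_init = 10 restarts; the
within-cluster sum of squares is asserted non-increasing at every
iteration; assignment ties break toward the lowest cluster index;
clusters are presented sorted by centroid for determinism). scikit-learn
serves as an independent cross-check in the tests, never as the
implementation. The default k is chosen by silhouette score over
k ∈ {2..6} on a seeded subsample — an explicit, reproducible surrogate
for an unstated cluster count.

The competence box is the closed region d1 ∈ [3.0, 3.8] Å,
d2 ∈ [2.8, 3.5] Å. Because "fraction of snapshots in the box" admits two
readings, both are reported: the per-frame membership fraction, and the
total occupancy of clusters whose centroids lie inside the box.
Threshold fractions use strict inequalities (competent d1 < 3.8 Å,
incompetent d1 > 4.0 Å, intermediate the remainder) and sum to one.
The default seed everywhere randomness exists is 853, a mnemonic for the
mutation site studied.

## Energy decomposition

Pairwise non-bonded energies between disjoint atom groups:
Coulomb 332.0636·q_a·q_b/r (kcal·Å·mol⁻¹·e⁻²) and Lennard-Jones
4ε[(σ/r)¹² − (σ/r)⁶] with Lorentz–Berthelot combining. Bonded neighbours
follow the Amber convention: 1-2/1-3 excluded, 1-4 scaled by 1/1.2
(electrostatics) and 1/2.0 (LJ). The vacuum, no-cutoff, no-lattice-sum
convention is adopted deliberately: it makes pairwise energies exact and
strictly additive over groups, which is what makes a per-residue
decomposition well defined. Atom pairs closer than 0.1 Å indicate broken
geometry and error out. Group arguments are canonicalized before
summation so E(A,B) = E(B,A) bit-exactly.

Profiles report mean ± SEM (sample sd/√F) of Coulomb and LJ terms per
residue against the reference group, intra-reference energies excluded.
Internally all values are signed (negative = attractive); the ranking
layer reports the magnitude of attractive totals as "stabilization",
flagged as such, since that is how stabilizer rankings are phrased.
Ties rank by ascending residue number.

## Binding thermodynamics

The single-site Wiseman model: site occupancy Θ is the smaller root of
Θ² − Θ(1 + X_t/(nM_t) + K_d/(nM_t)) + X_t/(nM_t) = 0, cell heat content
Q = nΘM_tΔH·V₀. Dilution uses the perfusion model (constant cell volume;
each injection of volume v expels fraction v/V₀ of the well-mixed cell
contents). The per-injection heat is the change in Q corrected for heat
carried out by the displaced volume,
ΔQ_i = Q_i − Q_{i−1} + (v_i/V₀)(Q_i + Q_{i−1})/2; without this term the
tight-binding limit loses the heat of expelled bound complex and the
total under-counts the stoichiometric nΔH·M_t·V₀ by over 10%. Analysis
programs differ slightly in these conventions, which is why they are
spelled out here.

Fitting is nonlinear least squares (lmfit) over (n, ln K_d, ΔH); the
first injection — the small priming injection of the usual schedule — is
down-weighted to zero; standard errors come from the Jacobian (delta
method for K_d). A c-value nM_t/K_d outside [1, 1000] attaches a warning
(titration shape weakly constrains K_d), not an error. All-zero heats
return ΔH ≈ 0 with K_d flagged unidentifiable. ΔG° = RT ln(K_d/1 M) with
R = 1.98720425×10⁻³ kcal·mol⁻¹·K⁻¹; conversions of measured affinities
use 310.15 K, the titration temperature. Recovery tests use n = 1, the
value appropriate for a single nucleotide-binding site.

## Synthetic data: what it emulates and what it does not

* `gen_enm_ensemble` draws i.i.d. Gaussian displacements from the exact
  thermal covariance k_B·T·H⁺ (pseudo-inverse over the 3N−6 internal
  modes). It reproduces the *spatial* statistics of a harmonically
  fluctuating protein — subdomain-correlated motion, RMSF profiles, mode
  structure — but has no time correlation, no anharmonicity and no
  conformational transitions. Passing tests therefore validate the
  analysis algebra, not conformational-sampling behaviour of real MD.
* `gen_two_state_distances` is a bivariate two-Gaussian mixture in
  (d1, d2): competent state centred at (3.5, 3.15) Å, incompetent at
  (4.3, 3.8) Å, matching the reported wells; occupancies 0.40
  (wild-type-like) and 0.12 (mutant-like, consistent with the reported
  <15% bound). State standard deviations are 0.10 Å (competent) and
  0.25 Å (incompetent) per axis — realistic heavy-atom distance
  fluctuation scales chosen once; the tighter competent well reflects a
  hydrogen-bond-constrained geometry. Negative draws are rejected and
  resampled (not truncated), which is bias-free at these parameters.
  Frames are i.i.d.: no switching kinetics.
* `gen_toy_topology` builds bead-per-residue charged systems (e.g. a +1
  arginine-like residue at a 3.32 Å contact with a −4 nucleotide-like
  ligand) whose pair energies are hand-computable; it exercises the EDA
  bookkeeping, not force-field realism.
* `gen_itc_isotherm` adds i.i.d. Gaussian noise to exact model heats for
  the standard 19-injection schedule (0.4 μL priming + 18 × 2 μL, 200 μL
  cell, 5 μM macromolecule); real baseline drift and integration error
  are not modelled.

Every generator is a pure function of (parameters, seed).

## Problem sizes

Default study sizes: 150,000 two-state frames (the combined-trajectory
scale of the emulated study); 20,000-frame, 20-atom elastic-network
ensembles for fluctuation/mode consistency checks (Frobenius covariance
error < 5%, RMSF error < 3%, top-5 RMSIP > 0.9 at this size); 45-atom,
300-frame ensembles in the pipeline drivers, where the point is the
analysis graph rather than statistical convergence.

## Known limitations

* The elastic-network generator cannot produce the specific mode-fraction
  inversions (e.g. a >95% breathing mode) reported for the real systems —
  those depend on the actual trajectories; the package validates mode
  machinery by parameter recovery instead.
* EDA magnitudes on toy topologies are not comparable to full force-field
  values; only orderings and the statistical machinery are validated.
* k on real (d1, d2) scatters is a modelling choice; the silhouette
  default is a heuristic, and published cluster counts should be set
  explicitly when reproducing a specific figure.
* The ITC model assumes a single class of independent sites and perfect
  injection mixing.
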