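# polsite

Analysis toolkit for polymerase active-site dynamics: how a single
active-site substitution (arginine → alanine at the dNTP-ribose contact of
the mitochondrial DNA polymerase Pol γ) destabilizes the catalytic centre.
The package implements the complete computational chain used to
characterize such a mutant against wild type:

* **per-subdomain trajectory metrics** — Kabsch superposition, RMSD per
  Palm/Fingers/Thumb subdomain, per-residue RMSF and the mutant−wild-type
  ΔRMSF profile, and subdomain rotation angles (e.g. the ~30° open↔closed
  Fingers transition);
* **correlated motion** — dynamic cross-correlation matrices
  C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), their wild-type-referenced
  difference maps, and collective modes from both an anisotropic
  elastic-network model (ENM) and ensemble PCA, with per-mode contribution
  fractions and mode–displacement overlaps;
* **catalytic competence** — the two active-site coordinates d1 (primer
  O3′ → dNTP Pα) and d2 (catalytic-aspartate O → primer O3′), k-means
  clustering of the (d1, d2) scatter, and occupancy of the competence box
  d1 ∈ [3.0, 3.8] Å, d2 ∈ [2.8, 3.5] Å within which the site is poised for
  phosphoryl transfer;
* **energy decomposition (EDA)** — residue-pairwise Coulomb +
  Lennard-Jones interaction energies with a reference residue or ligand,
  averaged over frames with SEM error bars, and stabilizer ranking;
* **binding thermodynamics** — the Wiseman single-site ITC model
  (exact one-site quadratic with perfusion dilution), nonlinear
  least-squares fitting of (n, K_d, ΔH), and ΔG = RT ln K_d conversions.

Production MD trajectories for such systems are rarely distributable, so
the package ships a first-class synthetic-data layer
(`polsite.synthetic`): Gaussian ensembles drawn from an exact
elastic-network thermal covariance, two-state (d1, d2) mixtures with known
occupancies, charged toy topologies, and noisy titrations with known
binding parameters. Every downstream stage is validated by recovering
that ground truth.

Intended users: structural bioinformaticians and molecular modellers who
need a tested, deterministic reference implementation of these analyses.

## Worked example

The `analysis/` directory holds the numbered end-to-end study; each script
is a thin driver over the library. Running them in order:

```bash
python analysis/01_generate_inputs.py
python analysis/04_competence_clustering.py
python analysis/06_nucleotide_binding.py
```

prints, among other lines:

```
wt: k=2, 39.9% of frames in the competence box (1 centroid(s) inside); d1-threshold split: 41.2% competent / 53.2% incompetent
mut: k=2, 12.2% of frames in the competence box (1 centroid(s) inside); d1-threshold split: 14.1% competent / 77.9% incompetent
...
from the measured Kd values (55 nM vs 37 μM): 672.7-fold, ΔΔG = 4.01 kcal/mol; ΔG = -10.303 / -6.289 kcal/mol
```

Reading: the wild-type-like ensemble keeps ~40% of frames inside the
competence box while the mutant-like ensemble keeps ~12% (both recover
their generating occupancies, 0.40 and 0.12), and the measured
dissociation constants convert to binding free energies of −10.3 vs
−6.3 kcal/mol — a ~673-fold affinity loss worth ~4 kcal/mol.

The same graph runs as one configured pipeline:

```bash
polsite run           # defaults; writes summary.json + CSVs + run.log
polsite run my.yaml --out results/run1
```

Two runs of the same config produce byte-identical `summary.json`.

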