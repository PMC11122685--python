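"""Residue-pairwise energy decomposition against a reference residue.

Loads the toy charged topology, jitters its coordinates over frames, and
decomposes each residue's Coulomb and van der Waals interaction with the
arginine-like reference, with SEM error bars over frames.  The −4-charged
ligand-like residue sitting at contact distance dominates the ranking, the
analogue of a charged active-site residue being the largest nucleotide
stabilizer.  Writes results/eda/{profile.csv, ranking.csv}.
"""

from pathlib import Path

import numpy as np

from polsite import eda
from polsite.struct_io import load_topology

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 853


def main() -> None:
    out = ROOT / "eda"
    out.mkdir(parents=True, exist_ok=True)
    topo, coords = load_topology(ROOT / "inputs" / "toy_topology.yaml")
    rng = np.random.default_rng(SEED + 20)
    frames = coords[None] + rng.normal(0.0, 0.05, (50, *coords.shape))
    prof = eda.eda_profile(frames, topo, "ARG853")
    prof.table.to_csv(out / "profile.csv", index=False)
    ranked = eda.rank_contributors(prof, top_n=len(prof.table))
    ranked.to_csv(out / "ranking.csv", index=False)
    top = ranked.iloc[0]
    print(f"reference ARG853, {prof.n_frames} frames")
    print(f"largest contributor: {top['residue']} "
          f"({top['stabilization']:.1f} kcal/mol {top['role']}; "
          f"Coulomb {top['coulomb_mean']:.1f} ± {top['coulomb_sem']:.2f}, "
          f"vdW {top['vdw_mean']:.2f} ± {top['vdw_sem']:.3f})")


if __name__ == "__main__":
    main()
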