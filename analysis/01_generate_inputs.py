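"""Generate every synthetic input the downstream analyses consume.

Writes, under results/inputs/:
  * wt_ensemble.pdb / mut_ensemble.pdb — elastic-network Gaussian ensembles
    of the helical reference fold (mutant sampled at a higher effective
    temperature, emulating loosened active-site packing);
  * distances_wt.csv / distances_mut.csv — two-state (d1, d2) catalytic
    distance series (competent occupancy 0.40 wild-type-like, 0.12
    mutant-like);
  * toy_topology.yaml — charged toy system for energy decomposition;
  * itc_wt.csv / itc_mut.csv — noisy single-site titrations
    (Kd 55 nM / 37 μM, the measured wild-type and mutant affinities).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from polsite import synthetic
from polsite.struct_io import write_pdb, write_topology

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
SEED = 853


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ref = synthetic.helix_coords(45)
    for name, temp, seed in (("wt", 300.0, SEED + 1), ("mut", 450.0, SEED + 2)):
        ens, _ = synthetic.gen_enm_ensemble(
            ref, cutoff=12.0, temperature_K=temp, n_frames=300, seed=seed
        )
        write_pdb(ens, OUT / f"{name}_ensemble.pdb")
        print(f"{name}: {ens.n_frames} frames × {ens.n_atoms} atoms")

    for name, p in (("wt", 0.40), ("mut", 0.12)):
        model = synthetic._two_state(
            (3.5, 3.15), (4.3, 3.8), 0.10, 0.25, p, 150_000, SEED + 10
        )
        series, labels = synthetic.gen_two_state_distances(model)
        pd.DataFrame(
            {"frame": series.frame_index, "d1": series["d1"],
             "d2": series["d2"], "state": labels}
        ).to_csv(OUT / f"distances_{name}.csv", index=False)
        print(f"{name}: two-state series, true competent occupancy {p}")

    topo, coords = synthetic.gen_toy_topology(
        {"LIG": -4.0, "ARG853": 1.0, "ASP890": -1.0,
         "GLU895": -1.0, "LYS947": 1.0, "LYS1191": 1.0}
    )
    write_topology(topo, OUT / "toy_topology.yaml", coords)
    print(f"toy topology: {topo.n_atoms} atoms, net charge {topo.charges.sum():+.1f} e")

    for name, kd, dh, syr in (("wt", 55e-9, -10.0, 200e-6), ("mut", 37e-6, -8.0, 2e-3)):
        iso = synthetic.gen_itc_isotherm(
            synthetic.ITCGroundTruth(
                kd_M=kd, dh_kcal=dh, syringe_concentration_M=syr,
                heat_noise_sd_ucal=0.05, seed=SEED + 30,
            )
        )
        pd.DataFrame(
            {"injection": np.arange(1, 20), "volume_uL": iso.injection_volumes_uL,
             "heat_ucal": iso.heats_ucal}
        ).to_csv(OUT / f"itc_{name}.csv", index=False)
        print(f"{name}: isotherm with true Kd {kd:.2e} M")


if __name__ == "__main__":
    main()
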