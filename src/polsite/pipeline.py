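"""Configuration-driven end-to-end analysis runner.

Reproduces the full wild-type vs. mutant analysis graph on a pair of
conformational ensembles (synthetic by default, file-backed if paths are
given): per-subdomain RMSD → RMSF → ΔRMSF → DCCM difference → normal
modes → catalytic-distance clustering and competence occupancy → energy
decomposition → nucleotide-binding thermodynamics → difference report.

Runs are deterministic: all randomness is funnelled through per-stage
generators derived from one run seed, every default is printed into the
run log, and the machine-readable summary is byte-identical across
reruns of the same config.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from . import clustering, eda, modes, superpose, synthetic, thermo
from .struct_io import read_pdb, read_xyz

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "compare_report"]

DEFAULT_CONFIG: dict = {
    "seed": 853,
    "plots": False,
    "ensemble": {
        # synthetic elastic-network ensembles; set wt_path/mut_path to load
        # multi-model PDB or XYZ trajectories instead
        "n_atoms": 45,
        "n_frames": 300,
        "cutoff": 12.0,
        "gamma": 1.0,
        "temperature_K": 300.0,
        # mutant ensemble sampled softer (warmer) to emulate loosened packing
        "mutant_temperature_K": 450.0,
        "wt_path": None,
        "mut_path": None,
    },
    # synthetic subdomain partition of the helical reference (atom ranges,
    # inclusive, 1-based) standing in for Palm / Fingers / Thumb
    "subdomains": {"Palm": [1, 15], "Fingers": [16, 30], "Thumb": [31, 45]},
    "fit_subdomain": "Palm",
    "modes": {"n_report": 10},
    "two_state": {
        "wt_p_competent": 0.40,
        "mut_p_competent": 0.12,
        "n_frames": 150000,
    },
    "clustering": {"k": "auto", "n_init": 10},
    "box": {"d1": [3.0, 3.8], "d2": [2.8, 3.5]},
    "thresholds": {"competent_max": 3.8, "incompetent_min": 4.0},
    "eda": {
        "reference": "ARG853",
        "residues": {
            "LIG": -4.0,
            "ARG853": 1.0,
            "ASP890": -1.0,
            "GLU895": -1.0,
            "LYS947": 1.0,
            "LYS1191": 1.0,
        },
        "jitter_sd": 0.05,
        "n_frames": 50,
    },
    "itc": {
        "wt": {"kd_M": 55e-9, "dh_kcal": -10.0, "syringe_M": 200e-6},
        "mut": {"kd_M": 37e-6, "dh_kcal": -8.0, "syringe_M": 2e-3},
        "cell_M": 5e-6,
        "cell_volume_uL": 200.0,
        "temperature_K": 310.15,
        "noise_sd_ucal": 0.05,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return _merge(DEFAULT_CONFIG, raw)


def _subdomain_masks(cfg: dict, n_atoms: int) -> dict[str, np.ndarray]:
    masks = {}
    for name, (lo, hi) in cfg["subdomains"].items():
        if hi > n_atoms or lo < 1:
            raise ValueError(f"subdomain {name!r} range {lo}-{hi} outside 1-{n_atoms}")
        masks[name] = np.arange(lo - 1, hi)
    return masks


def _load_or_generate_ensembles(cfg: dict, seed: int, log: list[str]):
    ens_cfg = cfg["ensemble"]
    truth = {}
    if ens_cfg.get("wt_path") and ens_cfg.get("mut_path"):
        loaders = {".pdb": read_pdb, ".xyz": read_xyz}
        out = []
        for p in (ens_cfg["wt_path"], ens_cfg["mut_path"]):
            p = Path(p)
            if not p.exists():
                raise FileNotFoundError(f"ensemble file {p} does not exist")
            out.append(loaders.get(p.suffix, read_pdb)(p))
            log.append(f"loaded ensemble {p}")
        return out[0], out[1], truth
    ref = synthetic.helix_coords(int(ens_cfg["n_atoms"]))
    wt, cov_wt = synthetic.gen_enm_ensemble(
        ref,
        cutoff=ens_cfg["cutoff"],
        gamma=ens_cfg["gamma"],
        temperature_K=ens_cfg["temperature_K"],
        n_frames=int(ens_cfg["n_frames"]),
        seed=seed + 1,
    )
    mut, cov_mut = synthetic.gen_enm_ensemble(
        ref,
        cutoff=ens_cfg["cutoff"],
        gamma=ens_cfg["gamma"],
        temperature_K=ens_cfg["mutant_temperature_K"],
        n_frames=int(ens_cfg["n_frames"]),
        seed=seed + 2,
    )
    truth = {"cov_wt": cov_wt, "cov_mut": cov_mut, "reference": ref}
    log.append(
        f"generated elastic-network ensembles: N={ens_cfg['n_atoms']}, "
        f"F={ens_cfg['n_frames']}, cutoff={ens_cfg['cutoff']} Å, "
        f"T(wt)={ens_cfg['temperature_K']} K, T(mut)={ens_cfg['mutant_temperature_K']} K"
    )
    return wt, mut, truth


def _system_bundle(name, ensemble, reference, masks, fit_name, cfg, seed, log):
    fit_idx = masks[fit_name]
    rmsd = superpose.rmsd_series(ensemble, reference, fit_idx, masks)
    rmsf = superpose.rmsf_profile(ensemble, fit_idx)
    d = modes.dccm(ensemble, fit_mask=fit_idx)
    pca = modes.pca_modes(ensemble, fit_mask=fit_idx)
    n_rep = int(cfg["modes"]["n_report"])
    log.append(f"[{name}] metrics + DCCM + PCA modes done")
    return {
        "name": name,
        "rmsd_mean": {k: float(v.mean()) for k, v in rmsd.values.items()},
        "rmsd_series": rmsd,
        "rmsf": rmsf,
        "dccm": d,
        "pca": pca,
        "pca_fractions_top": [float(x) for x in pca.fractions[:n_rep]],
    }


def run_pipeline(config: dict | str | Path | None, out_dir: str | Path) -> dict:
    """Run the full analysis graph; returns the machine-readable summary.

    Writes per-stage CSVs, ``summary.json`` and ``run.log`` under
    ``out_dir``.  Deterministic for a fixed config.
    """
    cfg = load_config(config) if not isinstance(config, dict) else _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    log: list[str] = [f"run seed: {seed}", "resolved config:", yaml.safe_dump(cfg)]
    summary: dict = {"seed": seed}

    # --- ensembles, metrics, correlations, modes ---------------------------
    wt, mut, truth = _load_or_generate_ensembles(cfg, seed, log)
    if wt.n_atoms != mut.n_atoms:
        raise ValueError("wild-type and mutant ensembles differ in atom count")
    masks = _subdomain_masks(cfg, wt.n_atoms)
    fit_name = cfg["fit_subdomain"]
    reference = truth.get("reference", wt.frames[0])

    bundles = {}
    for name, ens in (("wt", wt), ("mut", mut)):
        bundles[name] = _system_bundle(
            name, ens, reference, masks, fit_name, cfg, seed, log
        )
    summary["rmsd_mean"] = {n: b["rmsd_mean"] for n, b in bundles.items()}

    # ΔRMSF (mut − wt)
    drmsf = superpose.delta_rmsf(bundles["mut"]["rmsf"], bundles["wt"]["rmsf"])
    summary["delta_rmsf_mean"] = float(np.mean(list(drmsf.values())))
    summary["delta_rmsf_max"] = float(np.max(list(drmsf.values())))

    # DCCM difference with subdomain block summary
    key_to_sub = {}
    for sub, idx in masks.items():
        for i in idx:
            a = wt.atoms[i]
            key_to_sub[(a.chain_id, a.residue_number, a.name)] = sub
    diff, block_means = modes.dccm_difference(
        bundles["mut"]["dccm"], bundles["wt"]["dccm"], key_to_sub
    )
    summary["dccm_block_mean_diff"] = {
        f"{a}-{b}": round(v, 12) for (a, b), v in sorted(block_means.items())
    }

    # ENM modes of the shared reference + PCA fractions per system
    anm = modes.anm_modes(reference, cutoff=cfg["ensemble"]["cutoff"])
    n_rep = int(cfg["modes"]["n_report"])
    summary["modes"] = {
        "anm_fractions_top": [float(x) for x in anm.fractions[:n_rep]],
        "pca_fractions_top": {
            n: b["pca_fractions_top"] for n, b in bundles.items()
        },
        "rmsip_wt_anm_top5": float(modes.rmsip(bundles["wt"]["pca"], anm, 5)),
    }

    # --- catalytic-distance clustering -------------------------------------
    ts = cfg["two_state"]
    box = clustering.CompetenceBox(
        cfg["box"]["d1"][0], cfg["box"]["d1"][1], cfg["box"]["d2"][0], cfg["box"]["d2"][1]
    )
    summary["competence"] = {}
    for name, p in (("wt", ts["wt_p_competent"]), ("mut", ts["mut_p_competent"])):
        model = synthetic._two_state(
            (3.5, 3.15), (4.3, 3.8), 0.10, 0.25, p, int(ts["n_frames"]), seed + 10
        )
        series, _ = synthetic.gen_two_state_distances(model)
        pts = np.column_stack([series["d1"], series["d2"]])
        k_cfg = cfg["clustering"]["k"]
        k = clustering.silhouette_best_k(pts, seed=seed) if k_cfg == "auto" else int(k_cfg)
        clusters = clustering.kmeans_2d(pts, k, seed=seed, n_init=int(cfg["clustering"]["n_init"]))
        occ = clustering.box_occupancy(series, box, clusters)
        th = cfg["thresholds"]
        f_comp, f_incomp, f_mid = clustering.threshold_fractions(
            series, th["competent_max"], th["incompetent_min"]
        )
        summary["competence"][name] = {
            "k": k,
            "box_fraction": occ["fraction"],
            "box_cluster_fraction": occ["cluster_fraction"],
            "clusters_in_box": occ["clusters_in_box"],
            "threshold_fractions": {
                "competent": f_comp,
                "incompetent": f_incomp,
                "intermediate": f_mid,
            },
        }
        pd_df(series, clusters).to_csv(out / f"distances_{name}.csv", index=False)
        log.append(f"[{name}] clustering k={k}, box occupancy {occ['fraction']:.4f}")

    # --- energy decomposition ----------------------------------------------
    ecfg = cfg["eda"]
    topo, coords = synthetic.gen_toy_topology(
        {k: float(v) for k, v in ecfg["residues"].items()}
    )
    rng = np.random.default_rng(seed + 20)
    frames = coords[None] + rng.normal(0, ecfg["jitter_sd"], (int(ecfg["n_frames"]),) + coords.shape)
    prof = eda.eda_profile(frames, topo, ecfg["reference"])
    ranked = eda.rank_contributors(prof, top_n=len(prof.table))
    ranked.to_csv(out / "eda_ranking.csv", index=False)
    summary["eda"] = {
        "reference": ecfg["reference"],
        "top_residue": str(ranked.iloc[0]["residue"]),
        "top_total_kcal": float(ranked.iloc[0]["total_mean"]),
        "top_role": str(ranked.iloc[0]["role"]),
    }
    log.append(f"EDA reference {ecfg['reference']}: top contributor {summary['eda']['top_residue']}")

    # --- nucleotide-binding thermodynamics ----------------------------------
    icfg = cfg["itc"]
    summary["itc"] = {}
    fits = {}
    for name in ("wt", "mut"):
        sc = icfg[name]
        truth_itc = synthetic.ITCGroundTruth(
            n=1.0,
            kd_M=sc["kd_M"],
            dh_kcal=sc["dh_kcal"],
            cell_concentration_M=icfg["cell_M"],
            syringe_concentration_M=sc["syringe_M"],
            cell_volume_uL=icfg["cell_volume_uL"],
            heat_noise_sd_ucal=icfg["noise_sd_ucal"],
            temperature_K=icfg["temperature_K"],
            seed=seed + 30,
        )
        iso = synthetic.gen_itc_isotherm(truth_itc)
        fit = thermo.fit_isotherm(iso)
        fits[name] = fit
        summary["itc"][name] = {
            "kd_M": fit.kd_M,
            "dh_kcal": fit.dh_kcal,
            "dg_kcal": fit.dg_kcal,
            "n": fit.n,
            "true_kd_M": sc["kd_M"],
        }
        log.append(f"[{name}] ITC fit Kd={fit.kd_M:.3e} M, ΔG={fit.dg_kcal:.3f} kcal/mol")
    fold, ddg = thermo.affinity_fold_change(
        fits["mut"].kd_M, fits["wt"].kd_M, icfg["temperature_K"]
    )
    summary["itc"]["fold_change"] = fold
    summary["itc"]["ddg_kcal"] = ddg

    summary["comparison"] = compare_report(bundles["wt"], bundles["mut"], summary)

    if cfg.get("plots"):
        _write_plots(out, cfg, bundles, drmsf, diff, box, seed, log)

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n"
    )
    (out / "run.log").write_text("\n".join(log) + "\n")
    return summary


def _write_plots(out, cfg, bundles, drmsf, dccm_diff, box, seed, log):
    """RMSD traces, ΔRMSF bars, DCCM difference heatmap and cluster scatter
    with the competence box overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    fig, axes = plt.subplots(2, 2, figsize=(11, 9))
    ax = axes[0, 0]
    for name, b in bundles.items():
        for sub, series in b["rmsd_series"].values.items():
            ax.plot(series, lw=0.8, label=f"{name} {sub}")
    ax.set_xlabel("frame"), ax.set_ylabel("RMSD (Å)"), ax.legend(fontsize=6)
    ax.set_title("per-subdomain RMSD")

    ax = axes[0, 1]
    keys = sorted(drmsf)
    ax.bar(range(len(keys)), [drmsf[k] for k in keys], color="firebrick")
    ax.set_xlabel("residue"), ax.set_ylabel("ΔRMSF mut−wt (Å)")
    ax.set_title("ΔRMSF")

    ax = axes[1, 0]
    im = ax.imshow(dccm_diff, cmap="RdBu_r", vmin=-1, vmax=1)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title("DCCM difference (mut − wt)")

    ax = axes[1, 1]
    for name, color in (("wt", "tab:blue"), ("mut", "tab:orange")):
        df = pd.read_csv(out / f"distances_{name}.csv")
        sub = df.sample(min(len(df), 4000), random_state=seed)
        ax.scatter(sub["d1"], sub["d2"], s=2, alpha=0.3, color=color, label=name)
    ax.add_patch(
        plt.Rectangle(
            (box.d1_low, box.d2_low), box.d1_high - box.d1_low,
            box.d2_high - box.d2_low, fill=False, ec="k", lw=1.5,
        )
    )
    ax.set_xlabel("d1 (Å)"), ax.set_ylabel("d2 (Å)"), ax.legend()
    ax.set_title("catalytic distances + competence box")

    fig.tight_layout()
    fig.savefig(out / "overview.png", dpi=150)
    plt.close(fig)
    log.append("wrote overview.png")


def pd_df(series, clusters):
    import pandas as pd

    return pd.DataFrame(
        {
            "frame": series.frame_index,
            "d1": series["d1"],
            "d2": series["d2"],
            "cluster": clusters.assignment,
        }
    )


def compare_report(wt_bundle: dict, mut_bundle: dict, summary: dict | None = None) -> dict:
    """Wild-type vs. mutant difference report from two system bundles.

    Requires bundles computed over the same subdomain masks; signed
    quantities negate under argument swap.
    """
    if set(wt_bundle["rmsd_mean"]) != set(mut_bundle["rmsd_mean"]):
        raise ValueError("bundles use different subdomain masks")
    drmsf = superpose.delta_rmsf(mut_bundle["rmsf"], wt_bundle["rmsf"])
    diff, _ = modes.dccm_difference(mut_bundle["dccm"], wt_bundle["dccm"])
    report = {
        "rmsd_mean_diff": {
            k: mut_bundle["rmsd_mean"][k] - wt_bundle["rmsd_mean"][k]
            for k in sorted(wt_bundle["rmsd_mean"])
        },
        "delta_rmsf_mean": float(np.mean(list(drmsf.values()))),
        "dccm_diff_max_abs": float(np.nanmax(np.abs(diff))),
    }
    if summary is not None and "competence" in summary:
        report["box_occupancy_contrast"] = (
            summary["competence"]["wt"]["box_fraction"]
            - summary["competence"]["mut"]["box_fraction"]
        )
    return report
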