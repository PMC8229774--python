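"""End-to-end pipeline: simulate -> QC -> paint -> ancestry -> diversity
-> uniparental -> social model, from a single config with derived seeds.

Per-stage seeds are derived as (master_seed + crc32(stage_name)) mod 2^31,
so adding or removing a stage does not reshuffle the others. Every output
file is recorded in a manifest with its SHA-256 checksum; reruns with the
same config are bit-identical for the deterministic stages.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry as anc
from . import diversity as div
from . import painting as pnt
from . import qc
from . import simdata as sim
from . import social
from . import structure as struct
from . import uniparental as uni
from .genotypes import write_population_map, write_vcf

logger = logging.getLogger("popmosaic")

STAGE_ORDER = [
    "simulate",
    "qc",
    "structure",
    "paint",
    "ancestry",
    "diversity",
    "uniparental",
    "social",
]

DEFAULT_CONFIG: dict = {
    "out_dir": "popmosaic_run",
    "master_seed": 1,
    "stages": STAGE_ORDER,
    "simulate": {
        "n_sites": 4000,
        "fst": [0.15, 0.05, 0.05],
        "source_labels": ["EUR", "GOG", "ANG"],
        "n_per_source": 6,
        "admixed": {"CREOLE": {"n": 6, "proportions": [0.10, 0.55, 0.35]}},
        "mean_spacing": 5000.0,
        "ystr": {
            "n_lineages": 24,
            "generations": 17,
            "mu": 0.0025,
            "n_loci": 10,
            "founder_repeat": 12,
        },
        "sequences": {"length": 300, "n": 10, "subs_rate": 0.01},
    },
    "qc": {"max_missing": 0.15, "kinship_threshold": 0.177},
    "paint": {
        "n_haps_per_source": 8,
        "switch_rate": 2e-3,
        "n_recipients_per_pop": 4,
        "mosaics": {
            "CRE_A": [0.0, 0.58, 0.42],
            "CRE_B": [0.0, 0.76, 0.24],
            "YRI_REF": [0.0, 1.0, 0.0],
            "GAN_REF": [0.0, 0.0, 1.0],
            "NYK_REF": [0.0, 0.0, 1.0],
        },
    },
    "ancestry": {
        "n_bootstrap": 100,
        "target": "CRE_A",
        "ref_gog": "YRI_REF",
        "ref_ang_pair": ["GAN_REF", "NYK_REF"],
    },
    "diversity": {"downsample_to": 5, "reps": 5},
    "uniparental": {"mu": 0.0025, "n_loci": 10, "gen_time": 30.0},
    "social": {"d": 0.05, "b": 3.0, "tau": 1.0, "q0": 1.0, "T": 17, "target_p": 0.6},
}


class DependencyError(RuntimeError):
    """A stage requires outputs of a disabled stage."""


def stage_seed(master_seed: int, stage: str) -> int:
    return int((master_seed + zlib.crc32(stage.encode())) % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _record(manifest: dict, stage: str, path: Path) -> None:
    manifest["files"].append(
        {"stage": stage, "path": str(path), "sha256": _sha256(path)}
    )


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = copy.deepcopy(path_or_dict)
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_pipeline(config=None, out_dir: str | Path | None = None) -> dict:
    """Run the enabled stages in dependency order; return the manifest."""
    cfg = load_config(config or {})
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGE_ORDER if s in set(cfg["stages"])]
    master = int(cfg["master_seed"])
    manifest: dict = {
        "master_seed": master,
        "stages": stages,
        "seeds": {s: stage_seed(master, s) for s in stages},
        "files": [],
        "results": {},
        "failed_stage": None,
    }
    state: dict = {}
    try:
        for stage in stages:
            logger.info("running stage %s", stage)
            _RUNNERS[stage](cfg, stage_seed(master, stage), out, state, manifest)
    except Exception as exc:  # partial manifest with the failure recorded
        manifest["failed_stage"] = {"stage": stage, "error": repr(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_simulate(cfg, seed, out, state, manifest):
    c = cfg["simulate"]
    freqs = sim.sample_source_frequencies(
        c["n_sites"], c["fst"], seed, labels=c["source_labels"]
    )
    specs = [
        sim.AdmixtureSpec(lab, np.eye(len(c["fst"]))[k], c["n_per_source"])
        for k, lab in enumerate(c["source_labels"])
    ]
    for lab, spec in c["admixed"].items():
        specs.append(sim.AdmixtureSpec(lab, np.asarray(spec["proportions"]), spec["n"]))
    g = sim.simulate_admixed_genotypes(
        freqs, specs, seed, mean_spacing=c["mean_spacing"], with_depth=True
    )
    state["freqs"] = freqs
    state["genotypes"] = g
    vcf = out / "simulated.vcf"
    write_vcf(g, vcf)
    popmap = out / "populations.tsv"
    write_population_map(g.samples, g.populations, popmap)
    ystr_cfg = c["ystr"]
    state["ystr"] = sim.simulate_ystr(
        "star",
        [ystr_cfg["founder_repeat"]] * ystr_cfg["n_loci"],
        ystr_cfg["generations"],
        ystr_cfg["mu"],
        ystr_cfg["n_lineages"],
        seed=seed + 1,
    )
    ystr_path = out / "ystr.tsv"
    sim.write_ystr_table(state["ystr"], ystr_path)
    seq_cfg = c["sequences"]
    root = "".join(
        np.random.default_rng(seed + 2).choice(list("ACGT"), size=seq_cfg["length"])
    )
    state["sequences"], _ = sim.simulate_sequences(
        root, seq_cfg["n"], seq_cfg["subs_rate"], seed + 3
    )
    fasta = out / "sequences.fasta"
    sim.write_fasta(state["sequences"], fasta)
    for p in (vcf, popmap, ystr_path, fasta):
        _record(manifest, "simulate", p)


def _run_qc(cfg, seed, out, state, manifest):
    if "genotypes" not in state:
        raise DependencyError("qc requires the simulate stage")
    c = cfg["qc"]
    g, report = qc.filter_sites(state["genotypes"], max_missing=c["max_missing"])
    g, hwe_report = qc.hwe_filter(g)
    g, removed = qc.prune_relatives(g, threshold=c["kinship_threshold"])
    state["genotypes_qc"] = g
    report_path = out / "qc_report.json"
    report.removed["hwe"] = hwe_report.removed.get("hwe", 0)
    report.surviving_sites = g.n_sites
    report.to_json(report_path)
    vcf = out / "filtered.vcf"
    write_vcf(g, vcf)
    manifest["results"]["qc"] = {
        "surviving_sites": g.n_sites,
        "ti_tv": report.ti_tv,
        "removed_samples": removed,
    }
    _record(manifest, "qc", report_path)
    _record(manifest, "qc", vcf)


def _run_structure(cfg, seed, out, state, manifest):
    g = state.get("genotypes_qc", state.get("genotypes"))
    if g is None:
        raise DependencyError("structure requires genotypes")
    res = struct.pca(g, n_components=5)
    coords_path = out / "pca_coordinates.tsv"
    res.coordinates.to_csv(coords_path, sep="\t")
    state["pca"] = res
    fst = struct.fst_matrix(g)
    fst_path = out / "fst_matrix.tsv"
    fst.to_csv(fst_path, sep="\t")
    manifest["results"]["structure"] = {"fst": fst.to_dict()}
    _record(manifest, "structure", coords_path)
    _record(manifest, "structure", fst_path)


def _run_paint(cfg, seed, out, state, manifest):
    if "freqs" not in state:
        raise DependencyError("paint requires the simulate stage")
    c = cfg["paint"]
    source_haps = sim.simulate_source_haplotypes(
        state["freqs"], c["n_haps_per_source"], seed
    )
    haps, inds, pops = [], [], []
    for lab, arr in source_haps.items():
        for h in range(0, arr.shape[0], 2):
            haps.extend([arr[h], arr[h + 1]])
            inds.extend([f"{lab}_{h // 2}"] * 2)
            pops.extend([lab] * 2)
    for lab, props in c["mosaics"].items():
        mosaic = sim.simulate_haplotype_mosaic(
            source_haps,
            props,
            c["switch_rate"],
            2 * c["n_recipients_per_pop"],
            seed + zlib.crc32(lab.encode()) % 1000,
        )
        for h in range(mosaic.haps.shape[0]):
            haps.append(mosaic.haps[h])
            inds.append(f"{lab}_{h // 2}")
            pops.append(lab)
    panel = pnt.HaplotypePanel(
        haps=np.stack(haps),
        individuals=np.asarray(inds, dtype=object),
        populations=np.asarray(pops, dtype=object),
    )
    cm = pnt.coancestry(
        panel,
        mode="donor_recipient",
        donor_set=list(source_haps),
        recipient_set=list(c["mosaics"]),
    )
    state["coancestry"] = cm
    path = out / "coancestry.tsv"
    cm.chunk_counts.to_csv(path, sep="\t")
    _record(manifest, "paint", path)


def _run_ancestry(cfg, seed, out, state, manifest):
    if "coancestry" not in state:
        raise DependencyError("ancestry requires the paint stage (copy profiles)")
    c = cfg["ancestry"]
    cm = state["coancestry"]
    profiles = cm.individual_profiles()
    labels = [cm.recipient_populations[r] for r in profiles.index]
    tree = anc.bootstrap_support(profiles, labels, n_reps=c["n_bootstrap"], seed=seed)
    newick_path = out / "tvd_nj_tree.nwk"
    newick_path.write_text(tree.to_newick() + "\n")
    est = anc.nj_geometry_ancestry(
        tree, c["target"], c["ref_gog"], tuple(c["ref_ang_pair"])
    )
    tvd_path = out / "tvd_matrix.tsv"
    anc.tvd_matrix(cm.population_profiles()).to_csv(tvd_path, sep="\t")
    manifest["results"]["ancestry"] = {
        "nj_geometry": {k: v for k, v in est.items() if k != "method"}
    }
    _record(manifest, "ancestry", newick_path)
    _record(manifest, "ancestry", tvd_path)


def _run_diversity(cfg, seed, out, state, manifest):
    g = state.get("genotypes_qc", state.get("genotypes"))
    if g is None:
        raise DependencyError("diversity requires genotypes")
    c = cfg["diversity"]
    segments = div.call_roh(g)
    summary = div.roh_summary(segments, g.samples)
    roh_path = out / "roh_summary.tsv"
    summary.to_csv(roh_path, sep="\t")
    het = div.het_stats(g)
    het_path = out / "het_stats.tsv"
    het.to_csv(het_path, sep="\t")
    sfs = {}
    for pop in dict.fromkeys(g.populations):
        idx = g.samples_in(pop)
        if len(idx) >= c["downsample_to"]:
            sfs[pop] = div.folded_sfs(
                g, pop, c["downsample_to"], c["reps"], seed
            ).tolist()
    sfs_path = out / "folded_sfs.tsv"
    pd.DataFrame(sfs).to_csv(sfs_path, sep="\t", index=False)
    manifest["results"]["diversity"] = {"n_roh_segments": len(segments)}
    for p in (roh_path, het_path, sfs_path):
        _record(manifest, "diversity", p)


def _run_uniparental(cfg, seed, out, state, manifest):
    if "ystr" not in state:
        raise DependencyError("uniparental requires the simulate stage")
    c = cfg["uniparental"]
    data = state["ystr"]
    modal, freq = uni.modal_haplotype(data)
    cluster = uni.delimit_descent_cluster(data, modal)
    est = uni.rho_tmrca(
        cluster, mu=c["mu"], n_loci=c["n_loci"], gen_time=c["gen_time"]
    )
    res = {
        "modal_frequency": freq,
        "cluster_size": cluster.n,
        "rho": est.rho,
        "tmrca_years": est.years,
        "ci_years": [est.ci_low_years, est.ci_high_years],
    }
    if "sequences" in state:
        res["mtdna_like"] = uni.seq_diversity(state["sequences"])
    path = out / "uniparental.json"
    path.write_text(json.dumps(res, indent=2, default=str))
    manifest["results"]["uniparental"] = res
    _record(manifest, "uniparental", path)


def _run_social(cfg, seed, out, state, manifest):
    c = cfg["social"]
    model = social.DominanceModel(d=c["d"], b=c["b"], tau=c["tau"], q0=c["q0"])
    traj = social.trajectory(model, c["T"])
    traj_path = out / "social_trajectory.tsv"
    pd.DataFrame({"generation": np.arange(traj.p.size), "p": traj.p, "q": traj.q}).to_csv(
        traj_path, sep="\t", index=False
    )
    b_star, attainable = social.required_advantage(
        c["target_p"], c["T"], social.DominanceModel(d=c["d"], b=1.0, tau=c["tau"], q0=c["q0"])
    )
    manifest["results"]["social"] = {
        "final_p": float(traj.p[-1]),
        "required_advantage": b_star,
        "attainable": attainable,
    }
    _record(manifest, "social", traj_path)


_RUNNERS = {
    "simulate": _run_simulate,
    "qc": _run_qc,
    "structure": _run_structure,
    "paint": _run_paint,
    "ancestry": _run_ancestry,
    "diversity": _run_diversity,
    "uniparental": _run_uniparental,
    "social": _run_social,
}
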