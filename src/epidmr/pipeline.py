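"""End-to-end synthetic-study pipeline with a reproducibility manifest.

``run_pipeline`` generates a synthetic study from a config (genome, gene
models, MeDIP-style counts with planted DMRs, correlated module blocks,
pathology observations), then runs every analysis stage: window testing,
DMR calling, gene annotation, DMR-set comparison, module detection with
trait correlation, and disease classification. All stage outputs land in
the run directory together with ``manifest.json`` (config hash, seed,
output hashes), which suffices to reproduce the run byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, compare, comod, dmr, meth_test, pathology, synthdata, windows
from .genome import InvalidParameterError, write_gff3

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "window_size": 1000,
    "genome": {"n_chroms": 2, "chrom_length": 300_000, "cpg_rate": 0.01},
    "n_genes": 60,
    "design": {
        "n_per_group": 6,
        "exposures": ["exposureA", "exposureB"],
        "dispersion": 0.1,
        "depth_per_window": 10.0,
        "library_cv": 0.2,
        "n_planted_per_exposure": 5,
        "planted_width_windows": 3,
        "planted_log2fc": 2.0,
        "n_module_blocks": 2,
        "module_block_size": 40,
        "module_loading": 0.7,
    },
    "thresholds": {"seed_p": 1e-6, "extend_p": 0.1, "max_gap_bp": 1000,
                   "relaxed_p": 0.05, "gene_distance": 10_000, "min_row_sum": 10},
    "seed_p_overrides": {},     # comparison -> looser seed p (sparse-DMR case)
    "wgcna": {"n_top": 400, "power": 4, "min_module_size": 30,
              "merge_cut_height": 0.25, "cut_height_frac": 0.99},
    "pathology": {"n_control": 10, "n_case": 10, "control_rate": 2.0,
                  "case_shift": 3.0, "n_observers": 3},
    "write_reads": False,
}


def merge_config(overrides: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def build_design(cfg: dict, grid: windows.WindowGrid) -> synthdata.StudyDesign:
    """Deterministically lay out samples, comparisons, planted DMRs and
    module blocks on the grid."""
    d = cfg["design"]
    rng = np.random.default_rng(np.random.SeedSequence(cfg["seed"]).spawn(2)[1])
    groups_of = {"control": [f"control_{i + 1}" for i in range(d["n_per_group"])]}
    for exp in d["exposures"]:
        groups_of[exp] = [f"{exp}_{i + 1}" for i in range(d["n_per_group"])]
    sample_rows = []
    for grp, ids in groups_of.items():
        for s in ids:
            row = {"sample_id": s, "exposure": grp}
            for exp in d["exposures"]:
                row[f"is_{exp}"] = int(grp == exp)
            sample_rows.append(row)
    samples = pd.DataFrame(sample_rows)
    comparisons = {f"{exp}_vs_control": (groups_of[exp], groups_of["control"])
                   for exp in d["exposures"]}

    # planted DMRs: evenly spread non-overlapping runs, distinct per exposure
    n_w = grid.n_windows
    width = d["planted_width_windows"]
    n_total = d["n_planted_per_exposure"] * len(d["exposures"])
    stride = max(n_w // max(n_total + 1, 1), width + 2)
    planted = []
    pos = stride // 2
    for k in range(n_total):
        exp = d["exposures"][k % len(d["exposures"])]
        if pos + width > n_w:
            break
        planted.append(synthdata.PlantedDMR(pos, pos + width, d["planted_log2fc"],
                                            f"{exp}_vs_control"))
        pos += stride
    taken = set()
    for p in planted:
        taken.update(range(p.window_start, p.window_end))

    # module blocks on windows free of planted effects
    free = [w for w in range(n_w) if w not in taken]
    blocks = []
    for b in range(d["n_module_blocks"]):
        chunk = free[b * d["module_block_size"]:(b + 1) * d["module_block_size"]]
        if len(chunk) < d["module_block_size"]:
            break
        trait = f"is_{d['exposures'][0]}" if b == 0 else None
        blocks.append(synthdata.ModuleBlock(tuple(chunk), d["module_loading"], trait))

    depth_total = d["depth_per_window"] * n_w
    lib_factor = np.exp(rng.normal(0.0, d["library_cv"], len(samples)))
    lib_targets = {s: float(depth_total * f)
                   for s, f in zip(samples["sample_id"], lib_factor)}
    baseline = synthdata.baseline_from_cpg(grid, d["depth_per_window"])
    return synthdata.StudyDesign(samples=samples, groups=comparisons,
                                 library_size_targets=lib_targets,
                                 planted_dmrs=planted, dispersion=d["dispersion"],
                                 baseline_mu=baseline, module_blocks=blocks,
                                 seed=cfg["seed"])


def run_pipeline(config: dict | None = None, outdir: str | Path = "run",
                 force: bool = False, log=sys.stderr) -> dict:
    """Run every stage; returns the manifest dict.

    If the run directory already holds a manifest for the same config, the
    run is skipped; a manifest for a different config is refused unless
    ``force``.
    """
    cfg = merge_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == chash and not force and \
                all((out / f).exists() for f in old.get("outputs", {})):
            print(f"[epidmr] run up to date (config {chash}); skipping", file=log)
            return old
        if old.get("config_hash") != chash and not force:
            raise InvalidParameterError(
                f"run directory holds results for config {old.get('config_hash')}, "
                f"current config is {chash}; pass force to overwrite")

    t0 = time.time()

    def stage(name: str) -> None:
        print(f"[epidmr] {name} ({time.time() - t0:.1f}s)", file=log)

    stage("simulate: genome + design")
    g = cfg["genome"]
    genome = synthdata.generate_genome(g["n_chroms"], g["chrom_length"],
                                       g["cpg_rate"], cfg["seed"],
                                       window_size=cfg["window_size"])
    grid = windows.make_windows(genome, cfg["window_size"])
    genes = synthdata.generate_genes(genome, cfg["n_genes"], cfg["seed"] + 1)
    design = build_design(cfg, grid)
    genome.write_chrom_sizes(out / "genome.chrom.sizes")
    genome.write_cpg_bed(out / "cpg.bed")
    write_gff3(genes, out / "genes.gff3")
    design.samples.to_csv(out / "samples.csv", index=False)
    synthdata.write_design(design, out / "design.yaml")

    stage("simulate: counts")
    cm = synthdata.simulate_counts(design, grid)
    windows.write_counts_tsv(cm, grid, out / "counts.tsv")
    if cfg["write_reads"]:
        rs = synthdata.counts_to_reads(cm, grid)
        rs.write_bed(out / "reads")

    stage("window filter")
    thr = cfg["thresholds"]
    cm_f, kept = windows.filter_low_coverage(cm, thr["min_row_sum"])
    win_table = grid.to_frame().iloc[kept].reset_index(drop=True)

    stage("differential methylation tests + DMR calls")
    dmr_sets: list[compare.DMRSet] = []
    stats_by_comp: dict[str, pd.DataFrame] = {}
    for comp, (ga, gb) in design.groups.items():
        stats = meth_test.test_all_windows(cm_f, ga, gb, dispersion="grid_cml")
        stats = pd.concat([win_table, stats.drop(columns="window")], axis=1)
        stats.insert(0, "window", kept)
        stats_out = stats.copy()
        stats_out.insert(0, "window_id", [f"w{o}" for o in kept])
        stats_out.drop(columns="window").to_csv(out / f"stats_{comp}.tsv",
                                                sep="\t", index=False)
        stats_by_comp[comp] = stats
        seed_p = cfg["seed_p_overrides"].get(comp, thr["seed_p"])
        calls = dmr.call_dmrs(stats, seed_p=seed_p, extend_p=thr["extend_p"],
                              max_gap_bp=thr["max_gap_bp"], genome=genome)
        dmr.write_dmr_tsv(calls, out / f"dmrs_{comp}.tsv", comparison=comp)
        dmr.write_dmr_bed(calls, out / f"dmrs_{comp}.bed")
        dmr_sets.append(compare.DMRSet(comp, calls, seed_p=seed_p, comparison=comp))

    stage("gene annotation")
    for ds in dmr_sets:
        table = dmr.dmr_table(ds.dmrs, ds.comparison)
        assoc = annotate.associate_genes(table, genes, thr["gene_distance"])
        assoc.to_csv(out / f"genes_{ds.comparison}.tsv", sep="\t", index=False)

    stage("DMR set comparison")
    comparison_out: dict = {"venn": {}, "extended_overlap": None, "clusters": {}}
    if len(dmr_sets) >= 2:
        venn = compare.venn_overlap(dmr_sets)
        comparison_out["venn"] = {"+".join(sorted(k)): v for k, v in venn.items()}
    ext = compare.overlap_matrix(dmr_sets,
                                 {c: s for c, s in stats_by_comp.items()},
                                 relaxed_p=thr["relaxed_p"])
    ext.to_csv(out / "extended_overlap.csv", index=False)
    comparison_out["extended_overlap"] = ext.to_dict(orient="records")
    for ds in dmr_sets:
        cl = compare.cluster_scan(ds, genome,
                                  scan_window_bp=min(2_000_000, genome.chrom_lengths[0]),
                                  step_bp=min(500_000, max(genome.chrom_lengths[0] // 4, 1)))
        comparison_out["clusters"][ds.label] = [vars(c) for c in cl]
    (out / "comparison.json").write_text(json.dumps(comparison_out, indent=2, default=str))

    stage("coexpression modules")
    wg = cfg["wgcna"]
    rpkm_all = cm_f.counts / ((grid.lengths[kept] / 1e3)[:, None]
                              * (cm_f.library_sizes / 1e6)[None, :])
    n_top = min(wg["n_top"], rpkm_all.shape[0])
    top = comod.select_top_windows(rpkm_all, n_top)
    profiles = rpkm_all[top]
    adj = comod.adjacency(profiles, power=wg["power"])
    tom = comod.tom_similarity(adj)
    assign = comod.detect_modules(1.0 - tom, wg["min_module_size"],
                                  wg["cut_height_frac"])
    assign = comod.merge_close_modules(profiles, assign, wg["merge_cut_height"])
    pd.DataFrame({"window_id": [f"w{kept[t]}" for t in top],
                  "module": assign.labels}).to_csv(out / "modules.tsv",
                                                   sep="\t", index=False)
    traits = design.samples.set_index("sample_id")[
        [c for c in design.samples.columns if c.startswith("is_")]]
    eg = comod.eigengene_matrix(profiles, assign)
    if len(eg.columns):
        eg.insert(0, "sample_id", cm_f.sample_ids)
        eg.to_csv(out / "eigengenes.csv", index=False)
        mt = comod.module_trait_correlation(eg.drop(columns="sample_id"),
                                            traits.loc[cm_f.sample_ids].reset_index(drop=True))
        mt.to_csv(out / "module_trait.csv", index=False)

    stage("pathology")
    pa = cfg["pathology"]
    records = synthdata.simulate_pathology(pa["n_control"], pa["n_case"],
                                           pa["control_rate"], pa["case_shift"],
                                           pa["n_observers"], cfg["seed"] + 2)
    records.to_csv(out / "pathology_records.csv", index=False)
    thresholds = pathology.compute_thresholds(records)
    calls = pathology.classify_animals(records, thresholds,
                                       pathology.ObserverRule(2, pa["n_observers"]))
    calls.to_csv(out / "disease_calls.csv", index=False)
    report = pathology.disease_frequency_report(calls)
    report.rename(columns={"lineage": "lineage"}).to_csv(out / "disease_frequency.csv",
                                                         index=False)

    stage("manifest")
    outputs = sorted(p.name for p in out.iterdir()
                     if p.is_file() and p.name != "manifest.json")
    manifest = {"config": cfg, "config_hash": chash, "seed": cfg["seed"],
                "outputs": {f: _file_hash(out / f) for f in outputs},
                "elapsed_s": round(time.time() - t0, 2)}
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
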