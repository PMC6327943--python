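"""End-to-end orchestration: simulate/ingest -> DE -> correlation -> TAD
statistics, with deterministic per-stage seeding and a run manifest.

Per-stage seeds are derived by hashing (master seed, stage name, detail), so
adding or re-running one stage never perturbs another's random stream.
Default stage parameters equal the study's published choices: DE thresholds
|FC| >= 1.5 with q < 0.05 for the hypothalamus and |FC| >= 2 with q < 0.01
for frontal cortex and striatum; the 10% group-change gate for correlating
genes; the >= 5-gene TAD filter; B = 1000 permutations; alpha = 0.05 for
the regulated-TAD tail.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coregulation as coreg
from . import diffexpr, io_formats, pheno_correlation, regulated_tads, synthetic_data
from . import tad_conformance, tad_map, setops

DE_THRESHOLDS = {"HT": (1.5, 0.05), "FC": (2.0, 0.01), "ST": (2.0, 0.01)}

_KNOWN_KEYS = {
    "seed", "out_dir", "expr", "meta", "pheno", "tads", "genes",
    "simulate", "de_thresholds", "min_change", "corr_q_max", "min_genes",
    "anchor", "schemes", "B", "alpha", "tail_family", "regions",
    "include_rho_conformance",
}


@dataclass
class PipelineConfig:
    """Flat configuration of a full run; unknown keys are rejected."""

    seed: int
    out_dir: str
    expr: str = None
    meta: str = None
    pheno: str = None
    tads: str = None
    genes: str = None
    simulate: dict = None            # SimulationConfig overrides, or None
    de_thresholds: dict = field(default_factory=lambda: dict(DE_THRESHOLDS))
    min_change: float = 1.10
    corr_q_max: float = 0.05
    min_genes: int = 5
    anchor: str = "tss"
    schemes: tuple = ("gene_reassign", "border_shuffle")
    B: int = 1000
    alpha: float = 0.05
    tail_family: str = "lognormal"
    regions: tuple = ("FC", "ST", "HT")
    include_rho_conformance: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("master seed is mandatory")
        if "out_dir" not in raw:
            raise ValueError("out_dir is mandatory")
        cfg = cls(**raw)
        if cfg.simulate is None:
            for key in ("expr", "meta", "pheno", "tads", "genes"):
                p = getattr(cfg, key)
                if p is None:
                    raise ValueError(f"input path {key!r} missing and no "
                                     "simulate section given")
                if not Path(p).exists():
                    raise ValueError(f"input file not found: {p}")
        return cfg


def stage_seed(master: int, stage: str, *details) -> int:
    """Deterministic sub-seed below 2^31 from the master seed and stage tag."""
    tag = ":".join([str(int(master)), stage, *map(str, details)])
    digest = hashlib.sha256(tag.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31 - 1)


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``out_dir/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"master_seed": int(config.seed), "stages": []}

    def record(stage, outputs, t0, seed=None):
        manifest["stages"].append({
            "stage": stage, "seed": seed,
            "outputs": [str(o) for o in outputs],
            "wall_time_s": round(time.time() - t0, 3),
        })

    # ---- inputs ----------------------------------------------------------
    t0 = time.time()
    truth = None
    if config.simulate is not None:
        sim_seed = stage_seed(config.seed, "simulate")
        overrides = dict(config.simulate or {})
        overrides.pop("seed", None)       # the master seed governs
        sim_cfg = synthetic_data.SimulationConfig(seed=sim_seed, **overrides)
        genome = synthetic_data.make_genome(sim_cfg)
        study, pheno, truth = synthetic_data.make_study(genome, config=sim_cfg)
        tads, genes = genome
        io_formats.write_expression(study, out / "expr.tsv", out / "meta.csv")
        io_formats.write_phenotypes(pheno, out / "pheno.csv")
        io_formats.write_tads(tads, out / "tads.bed")
        io_formats.write_genes(genes, out / "genes.bed")
        truth.to_json(out / "ground_truth.json")
        record("simulate", [out / "expr.tsv", out / "ground_truth.json"],
               t0, sim_seed)
    else:
        study = io_formats.read_expression(config.expr, config.meta)
        pheno = io_formats.read_phenotypes(config.pheno)
        tads = io_formats.read_tads(config.tads)
        genes = io_formats.read_genes(config.genes)
        record("ingest", [config.expr, config.pheno, config.tads, config.genes], t0)

    regions = [r for r in config.regions
               if r in set(study.sample_meta["region"])]

    # ---- differential expression ----------------------------------------
    de_results, de_sets = {}, {}
    for region in regions:
        t0 = time.time()
        de = diffexpr.fit_de(study, region)
        fc_min, q_max = config.de_thresholds.get(region, (1.5, 0.05))
        de_sets[region] = diffexpr.select_de(de, fc_min=fc_min, q_max=q_max)
        de_results[region] = de
        path = out / f"de_{region}.csv"
        io_formats.write_table(de.table, path, seed=None,
                               params={"region": region, "fc_min": fc_min,
                                       "q_max": q_max})
        record(f"diffexpr:{region}", [path], t0)

    # ---- phenotype correlation ------------------------------------------
    scores = pheno_correlation.phenotype_scores(pheno)
    corr_sets = {r: {} for r in regions}
    corr_results = {r: {} for r in regions}
    for region in regions:
        sub = study.subset_region(region)
        for variable in scores.columns:
            t0 = time.time()
            res = pheno_correlation.spearman_fisher(sub, scores[variable],
                                                    variable=variable)
            corr_sets[region][variable] = pheno_correlation.select_correlating(
                res, min_change=config.min_change, q_max=config.corr_q_max)
            corr_results[region][variable] = res
            path = out / f"corr_{region}_{variable}.csv"
            io_formats.write_table(res.table, path,
                                   params={"region": region, "variable": variable})
            record(f"correlate:{region}:{variable}", [path], t0)

    # ---- TAD mapping -----------------------------------------------------
    t0 = time.time()
    gmap = tad_map.assign_genes(genes, tads, anchor=config.anchor)
    eligible = tad_map.filter_eligible(gmap, k=config.min_genes)
    map_table = pd.DataFrame({
        "tad_id": [eligible.gene_to_tad.get(g) for g in study.genes],
    }, index=pd.Index(study.genes, name="gene_id"))
    io_formats.write_table(map_table, out / "gene_tad_map.csv",
                           params={"k": config.min_genes, "anchor": config.anchor})
    record("map-tads", [out / "gene_tad_map.csv"], t0)

    # ---- conformance -----------------------------------------------------
    conformance = {}
    for region in regions:
        fc_scores = de_results[region].table["log2fc"]
        score_sets = {"log2fc": fc_scores}
        if config.include_rho_conformance:
            for variable in scores.columns:
                score_sets[f"rho_{variable}"] = \
                    corr_results[region][variable].table["rho"]
        for score_name, s in score_sets.items():
            for scheme in config.schemes:
                t0 = time.time()
                seed = stage_seed(config.seed, "conformance", region,
                                  score_name, scheme)
                res = tad_conformance.conformance_test(
                    s, eligible, tads=tads, genes=genes, scheme=scheme,
                    B=config.B, seed=seed, score_name=f"{region}:{score_name}")
                conformance[(region, score_name, scheme)] = res
                path = out / f"conformance_{region}_{score_name}_{scheme}.json"
                _write_json(path, {
                    "score": res.score_name, "scheme": res.scheme,
                    "observed_H": res.observed_h, "chi2_p": res.chi2_pvalue,
                    "df": res.df, "empirical_p": res.empirical_p,
                    "rank": res.rank, "B": res.n_permutations,
                    "mean_permuted_H": float(res.permuted_h.mean()),
                    "seed": res.seed,
                })
                record(f"conformance:{region}:{score_name}:{scheme}",
                       [path], t0, seed)

    # ---- responsive sets and regulated TADs ------------------------------
    t0 = time.time()
    responsive_by_region = {}
    for region in regions:
        signed = dict(de_sets[region])
        for variable in scores.columns:
            for g, s in corr_sets[region][variable].items():
                signed.setdefault(g, s)
        responsive_by_region[region] = signed
    union = [set(s) for s in responsive_by_region.values()]
    counts = regulated_tads.count_responsive(eligible, union)
    fits, best = regulated_tads.fit_tail(counts.values)
    chosen = next(f for f in fits if f.family == config.tail_family)
    reg = regulated_tads.select_regulated(counts, chosen, alpha=config.alpha)
    _write_json(out / "regulated_tads.json", {
        "family_ranking": [{"family": f.family, "aic": f.aic} for f in fits],
        "best_family_by_aic": best,
        "selection_family": chosen.family,
        "alpha": config.alpha,
        "n_selected": len(reg.tad_ids),
        "tad_ids": list(reg.tad_ids),
        "count_threshold": reg.count_threshold,
    })
    record("regulated-tads", [out / "regulated_tads.json"], t0)

    # ---- coregulation ----------------------------------------------------
    coreg_results = {}
    if reg.tad_ids:
        for region in regions:
            t0 = time.time()
            seed = stage_seed(config.seed, "coregulation", region)
            try:
                res = coreg.coregulation_test(
                    eligible, responsive_by_region[region], reg.tad_ids,
                    B=config.B, seed=seed, region=region)
            except ValueError:
                continue
            coreg_results[region] = res
            path = out / f"coregulation_{region}.json"
            _write_json(path, {
                "region": region, "observed_mean_deviation": res.observed_mean,
                "pvalue": res.pvalue, "B": int(res.permuted_means.size),
                "seed": res.seed,
            })
            record(f"coregulation:{region}", [path], t0, seed)

    # ---- overlaps --------------------------------------------------------
    t0 = time.time()
    de_only = {r: set(de_sets[r]) for r in regions}
    overlaps = {}
    if len(regions) >= 2 and all(de_only.values()):
        venn = setops.venn_counts(*[de_only[r] for r in regions])
        overlaps["venn_de"] = {"".join(map(str, k)): v for k, v in venn.items()}
        overlaps["venn_regions"] = list(regions)
    resp_sets = {r: set(responsive_by_region[r]) for r in regions
                 if responsive_by_region[r]}
    if len(resp_sets) >= 2:
        mat = setops.pairwise_overlap_matrix(resp_sets)
        mat.to_csv(out / "responsive_overlap.csv")
        overlaps["responsive_overlap_file"] = "responsive_overlap.csv"
    _write_json(out / "overlaps.json", overlaps)
    record("overlaps", [out / "overlaps.json"], t0)

    _write_json(out / "manifest.json", manifest)
    result = {
        "manifest": manifest, "de_sets": de_sets, "corr_sets": corr_sets,
        "responsive": responsive_by_region, "counts": counts,
        "regulated": reg, "conformance": conformance,
        "coregulation": coreg_results, "truth": truth,
    }
    return result


def _write_json(path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
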