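"""Synthetic genomes, paired expression studies and phenotypes with known truth.

The generator emulates the statistical structure of a free-choice diet study:
the same mice assayed in three brain regions (frontal cortex FC, striatum ST,
hypothalamus HT), four mice per diet group (standard chow SC vs chocolate
mixture CM), switch-like differential-expression effects (|log2FC| up to 2),
subtle phenotype-correlated effects (|log2FC| in the 0.2-0.4 band), and
responsive genes planted sign-coherently inside a handful of regulated TADs.

Everything is deterministic given ``SimulationConfig.seed``; the genome and
the study use independent sub-streams so regenerating one never perturbs the
other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionStudy, GeneAnnotation, PhenotypeTable, TadSegmentation,
)

#: the five analysis variables correlated with expression
ANALYSIS_VARIABLES = (
    "body_weight", "compulsivity", "inflexibility", "energy_intake", "eating_rate",
)

#: raw phenotype columns driven by the body-weight latent factor
BODY_WEIGHT_FAMILY = ("final_weight", "pct_gain")
#: raw phenotype columns driven by the compulsivity latent factor
COMPULSIVITY_FAMILY = (
    "grooming", "nesting", "intake_d1", "intake_d2", "intake_d3", "quinine",
)


@dataclass
class SimulationConfig:
    """All knobs of the generator; ``seed`` is mandatory.

    Lengths are in bp, expression effects in log2 units.  Defaults give a
    desk-scale genome (3 chromosomes x 50 TADs, ~5000 genes) with the paired
    4-mice-per-diet, 3-region design.
    """

    seed: int
    n_chromosomes: int = 3
    n_tads_per_chromosome: int = 50
    tad_length_median: float = 800_000.0
    tad_length_sigma: float = 0.45
    gap_median: float = 100_000.0
    gap_sigma: float = 0.6
    genes_per_tad_mean: float = 33.0
    gene_density_sigma: float = 0.3   # per-TAD log-normal density multiplier
    gap_gene_fraction: float = 0.05
    chromosome_length: int | None = None   # None: derived from content
    n_mice_per_diet: int = 4
    regions: tuple = ("FC", "ST", "HT")
    noise_sd: float = 0.1
    mouse_sd: float | None = None          # None: noise_sd / 2
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    region_sd: float = 0.3
    de_effect_range: tuple = (0.6, 2.0)
    correlating_effect_range: tuple = (0.2, 0.4)
    n_regulated_tads: int = 10
    responsive_per_tad: int = 10
    de_fraction: float = 0.5
    n_scattered_responsive: int = 300
    within_tad_sign_coherence: float = 1.0
    cross_region_sign_flip: bool = True
    pheno_diet_shift: float = 2.0          # latent-factor shift (z units)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_chromosomes", "n_tads_per_chromosome", "n_mice_per_diet"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.within_tad_sign_coherence <= 1.0:
            raise ValueError("within_tad_sign_coherence must lie in [0, 1]")
        if self.mouse_sd is None:
            self.mouse_sd = self.noise_sd / 2.0


@dataclass
class GroundTruth:
    """Planted structure of a synthetic study; the acceptance oracle.

    ``de_genes[region]`` and ``correlating_genes[region][variable]`` map gene
    id -> sign (+1 up in CM, -1 down).  ``slopes`` holds the per-gene
    regression coefficient of correlating genes on their (z-scored) phenotype
    variable.  ``phenotype_scores`` are the per-mouse scores actually used
    when planting, so composite-recovery can be asserted directly.
    """

    de_genes: dict
    correlating_genes: dict
    slopes: dict
    regulated_tads: list
    tad_sign: dict                 # tad -> region -> planted base sign
    phenotype_scores: pd.DataFrame = None
    latent_factors: pd.DataFrame = None

    def responsive(self, region: str) -> dict:
        """Union of DE and correlating genes for a region, gene -> sign."""
        out = dict(self.de_genes.get(region, {}))
        for per_gene in self.correlating_genes.get(region, {}).values():
            for g, s in per_gene.items():
                out.setdefault(g, s)
        return out

    def to_json(self, path) -> None:
        payload = {
            "de_genes": self.de_genes,
            "correlating_genes": self.correlating_genes,
            "slopes": self.slopes,
            "regulated_tads": list(self.regulated_tads),
            "tad_sign": self.tad_sign,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def make_genome(config: SimulationConfig):
    """Lay down TADs with positive inter-TAD gaps and place genes inside them.

    Returns ``(TadSegmentation, GeneAnnotation)``.  TAD ids are ``T<chrom>.<i>``
    and gene ids ``g<serial>``; genes are anchored (TSS) strictly inside their
    TAD, with a configurable fraction anchored inside gaps instead.

    Gene placement is an inhomogeneous Poisson process: each TAD carries a
    log-normal density multiplier (``gene_density_sigma``) around a base
    density chosen so the mean count per TAD is ``genes_per_tad_mean``.
    Counts therefore scale with TAD length and are heavy-tailed across TADs
    (a Poisson-log-normal mixture), as in real genomes where larger domains
    hold more genes.
    """
    rng = np.random.default_rng([int(config.seed), 101])
    tad_rows, gene_rows = [], []
    chrom_length = {}
    serial = 0

    def lognormal_lengths(median, sigma, n):
        return np.maximum(1000, rng.lognormal(np.log(median), sigma, n)).astype(int)

    for c in range(1, config.n_chromosomes + 1):
        chrom = f"chr{c}"
        n = config.n_tads_per_chromosome
        lengths = lognormal_lengths(config.tad_length_median, config.tad_length_sigma, n)
        gaps = lognormal_lengths(config.gap_median, config.gap_sigma, n + 1)
        pos = int(gaps[0])
        gap_intervals = [(0, pos)]
        for i in range(n):
            start, end = pos, pos + int(lengths[i])
            tad_rows.append({
                "tad_id": f"T{c}.{i + 1}", "chrom": chrom, "start": start, "end": end,
            })
            gap_intervals.append((end, end + int(gaps[i + 1])))
            pos = end + int(gaps[i + 1])
        if config.chromosome_length is not None:
            if pos > config.chromosome_length:
                raise ValueError(
                    f"infeasible packing on {chrom}: TADs+gaps span {pos} bp, "
                    f"chromosome is {config.chromosome_length} bp"
                )
            chrom_length[chrom] = config.chromosome_length
        else:
            chrom_length[chrom] = pos

        # genes anchored inside TADs: Poisson counts at a length-proportional
        # rate with per-TAD log-normal density heterogeneity
        s = config.gene_density_sigma
        mean_len = config.tad_length_median * np.exp(config.tad_length_sigma ** 2 / 2)
        base_density = config.genes_per_tad_mean / mean_len
        density = rng.lognormal(-s ** 2 / 2.0, s, n) if s > 0 else np.ones(n)
        counts = rng.poisson(base_density * lengths * density)
        chrom_tads = tad_rows[-n:]
        anchors, strands = [], []
        for tad, k in zip(chrom_tads, counts):
            a = rng.integers(tad["start"], tad["end"], size=k)
            anchors.extend(int(x) for x in a)
        # genes anchored inside gaps
        n_tad_genes = int(counts.sum())
        frac = config.gap_gene_fraction
        n_gap_genes = int(round(frac / (1.0 - frac) * n_tad_genes)) if frac > 0 else 0
        if n_gap_genes:
            widths = np.array([b - a for a, b in gap_intervals], dtype=float)
            pick = rng.choice(len(gap_intervals), size=n_gap_genes, p=widths / widths.sum())
            for j in pick:
                a, b = gap_intervals[j]
                anchors.append(int(rng.integers(a, b)))
        strands = rng.choice(["+", "-"], size=len(anchors))
        glens = rng.integers(2_000, 20_000, size=len(anchors))
        order = np.argsort(anchors, kind="stable")
        for idx in order:
            serial += 1
            tss, strand, L = anchors[idx], strands[idx], int(glens[idx])
            if strand == "+":
                start, end = tss, tss + L
            else:
                start, end = tss + 1 - L, tss + 1
            start = max(0, start)
            gene_rows.append({
                "gene_id": f"g{serial:05d}", "chrom": chrom,
                "start": int(start), "end": int(end), "strand": str(strand),
            })

    tads = TadSegmentation(pd.DataFrame(tad_rows), chrom_length=chrom_length)
    genes = GeneAnnotation(pd.DataFrame(gene_rows))
    return tads, genes


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _make_phenotypes(config: SimulationConfig, rng):
    """Two latent factors per mouse drive the raw variables.

    Returns (PhenotypeTable, scores, latents): ``scores`` holds the z-scale
    per-mouse values of the five analysis variables actually used when
    planting correlating effects.
    """
    mice = [f"SC{i + 1}" for i in range(config.n_mice_per_diet)] + \
           [f"CM{i + 1}" for i in range(config.n_mice_per_diet)]
    diet = ["SC"] * config.n_mice_per_diet + ["CM"] * config.n_mice_per_diet
    is_cm = np.array([d == "CM" for d in diet], dtype=float)
    n = len(mice)
    shift = config.pheno_diet_shift

    lat_bw = shift * is_cm + rng.normal(0, 1, n)
    lat_comp = shift * is_cm + rng.normal(0, 1, n)
    load = 0.9
    resid = np.sqrt(1 - load ** 2)

    def from_latent(lat, scale, offset):
        return offset + scale * (load * lat + resid * rng.normal(0, 1, n))

    raw = pd.DataFrame(index=pd.Index(mice, name="mouse"))
    raw["diet"] = diet
    raw["final_weight"] = from_latent(lat_bw, 1.5, 24.0)      # g
    raw["pct_gain"] = from_latent(lat_bw, 6.0, 18.0)          # %
    raw["grooming"] = from_latent(lat_comp, 25.0, 80.0)       # s
    raw["nesting"] = from_latent(lat_comp, 0.6, 2.0).clip(0.05)  # g cotton
    raw["intake_d1"] = from_latent(lat_comp, 8.0, 40.0)       # kJ
    raw["intake_d2"] = from_latent(lat_comp, 8.0, 45.0)
    raw["intake_d3"] = from_latent(lat_comp, 8.0, 48.0)
    raw["quinine"] = from_latent(lat_comp, 9.0, 35.0)         # kJ
    raw["total_intake"] = 250.0 + 40.0 * (shift * is_cm + rng.normal(0, 1, n))
    raw["eating_rate"] = 2.0 + 0.5 * (shift * is_cm + rng.normal(0, 1, n))

    def z(x):
        x = np.asarray(x, dtype=float)
        return (x - x.mean()) / x.std(ddof=0)

    scores = pd.DataFrame({
        "body_weight": z(lat_bw),
        "compulsivity": z(lat_comp),
        "inflexibility": z(raw["quinine"]),
        "energy_intake": z(raw["total_intake"]),
        "eating_rate": z(raw["eating_rate"]),
    }, index=raw.index)
    latents = pd.DataFrame({"body_weight": lat_bw, "compulsivity": lat_comp},
                           index=raw.index)
    return PhenotypeTable(raw), scores, latents


# ---------------------------------------------------------------------------
# study
# ---------------------------------------------------------------------------

def make_study(genome, truth_spec=None, config: SimulationConfig = None):
    """Generate the paired expression study plus phenotypes and ground truth.

    ``genome`` is the ``(tads, genes)`` pair from :func:`make_genome`.
    ``truth_spec`` optionally overrides the planting parameters of ``config``
    (keys: ``n_regulated_tads``, ``responsive_per_tad``, ``de_fraction``,
    ``n_scattered_responsive``).

    The expression model for gene *g*, mouse *m*, region *r* is::

        y = baseline_g + region_offset_{g,r} + mouse_offset_{g,m}
            + de_effect_{g,r} * 1[diet(m) = CM]
            + slope_g * sign_{g,r} * pheno_score_{v(g), m}
            + N(0, noise_sd)

    DE effects are switch-like (|log2FC| drawn from ``de_effect_range``);
    correlating effects are sized so the CM-SC contrast lands in
    ``correlating_effect_range``.  The mouse offset is shared across regions,
    reproducing the within-mouse correlation the paired design blocks on.
    """
    if config is None:
        raise ValueError("config is required")
    tads, genes = genome
    rng = np.random.default_rng([int(config.seed), 202])
    spec = {
        "n_regulated_tads": config.n_regulated_tads,
        "responsive_per_tad": config.responsive_per_tad,
        "de_fraction": config.de_fraction,
        "n_scattered_responsive": config.n_scattered_responsive,
    }
    if truth_spec:
        unknown = set(truth_spec) - set(spec)
        if unknown:
            raise ValueError(f"unknown truth_spec keys: {sorted(unknown)}")
        spec.update(truth_spec)

    pheno, scores, latents = _make_phenotypes(config, rng)
    mice = list(pheno.table.index)
    diets = pheno.table["diet"]
    regions = list(config.regions)

    gene_ids = genes.table["gene_id"].tolist()
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    n_genes = len(gene_ids)

    # --- map genes to TADs by anchor (local, to pick planting locations) ---
    from .tad_map import assign_genes
    gmap = assign_genes(genes, tads)
    tad_members = {}
    for g, t in gmap.gene_to_tad.items():
        if t is not None:
            tad_members.setdefault(t, []).append(g)

    # --- choose regulated TADs and plant responsive genes ----------------
    k_resp = spec["responsive_per_tad"]
    candidates = sorted(t for t, m in tad_members.items() if len(m) >= k_resp)
    if len(candidates) < spec["n_regulated_tads"]:
        raise ValueError(
            f"only {len(candidates)} TADs hold >= {k_resp} genes; "
            f"cannot plant {spec['n_regulated_tads']} regulated TADs"
        )
    reg_tads = sorted(rng.choice(candidates, size=spec["n_regulated_tads"],
                                 replace=False).tolist())

    de_genes = {r: {} for r in regions}
    corr_genes = {r: {v: {} for v in ANALYSIS_VARIABLES} for r in regions}
    slopes = {}
    tad_sign = {}
    de_lo, de_hi = config.de_effect_range
    c_lo, c_hi = config.correlating_effect_range

    # diet contrast of each planted score (for sizing correlating slopes)
    is_cm = (diets == "CM").values
    score_contrast = {
        v: float(scores[v][is_cm].mean() - scores[v][~is_cm].mean())
        for v in ANALYSIS_VARIABLES
    }

    de_effect = np.zeros((n_genes, len(regions)))      # log2 CM-SC shift
    corr_coef = np.zeros((n_genes, len(regions)))      # coefficient on score
    corr_var = np.empty(n_genes, dtype=object)         # which score drives g

    def region_sign(base, region):
        if config.cross_region_sign_flip and region == "HT":
            return -base
        return base

    def plant(gene, base_sign, coherent, kind, variable, tad=None):
        """Record one planted responsive gene across all regions."""
        mag_de = rng.uniform(de_lo, de_hi)
        # unimodal within the subtle band: fine-tuned effects pile up inside
        # the range rather than at its edges
        mag_corr = rng.triangular(c_lo, (c_lo + c_hi) / 2.0, c_hi)
        for j, r in enumerate(regions):
            s = region_sign(base_sign, r) * (1 if coherent else -1)
            if kind == "de":
                de_effect[gene_pos[gene], j] = s * mag_de
                de_genes[r][gene] = int(s)
            else:
                contrast = score_contrast[variable]
                beta = s * mag_corr / contrast
                corr_coef[gene_pos[gene], j] = beta
                corr_var[gene_pos[gene]] = variable
                corr_genes[r][variable][gene] = int(s)
        if kind == "corr":
            slopes[gene] = float(mag_corr / score_contrast[variable])

    planted = set()
    for t in reg_tads:
        base = int(rng.choice([-1, 1]))
        tad_sign[t] = {r: int(region_sign(base, r)) for r in regions}
        members = rng.permutation(tad_members[t])[:k_resp]
        n_de = int(round(spec["de_fraction"] * len(members)))
        for i, g in enumerate(members):
            coherent = bool(rng.random() < config.within_tad_sign_coherence)
            kind = "de" if i < n_de else "corr"
            variable = ANALYSIS_VARIABLES[i % len(ANALYSIS_VARIABLES)]
            plant(g, base, coherent, kind, variable, tad=t)
            planted.add(g)

    # scattered responsive genes form the background of the per-TAD counts
    pool = [g for g in gene_ids if g not in planted]
    n_scatter = min(spec["n_scattered_responsive"], len(pool))
    if n_scatter:
        for g in rng.choice(pool, size=n_scatter, replace=False):
            base = int(rng.choice([-1, 1]))
            kind = "de" if rng.random() < spec["de_fraction"] else "corr"
            variable = ANALYSIS_VARIABLES[int(rng.integers(len(ANALYSIS_VARIABLES)))]
            plant(str(g), base, True, kind, variable)

    # --- assemble the matrix ---------------------------------------------
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_genes)
    region_offset = rng.normal(0.0, config.region_sd, (n_genes, len(regions)))
    mouse_offset = rng.normal(0.0, config.mouse_sd, (n_genes, len(mice)))

    # per-gene, per-mouse driving score (zero for genes without one)
    score_mat = np.zeros((n_genes, len(mice)))
    for i in range(n_genes):
        if corr_var[i] is not None:
            score_mat[i, :] = scores[corr_var[i]].values

    samples, meta_rows = [], []
    cols = []
    for j, r in enumerate(regions):
        for m_idx, m in enumerate(mice):
            sid = f"{m}_{r}"
            samples.append(sid)
            meta_rows.append({"sample_id": sid, "region": r,
                              "diet": diets[m], "mouse": m})
            col = baseline + region_offset[:, j] + mouse_offset[:, m_idx]
            if diets[m] == "CM":
                col = col + de_effect[:, j]
            col = col + corr_coef[:, j] * score_mat[:, m_idx]
            if config.noise_sd > 0:
                col = col + rng.normal(0.0, config.noise_sd, n_genes)
            cols.append(col)
    values = np.column_stack(cols)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    study = ExpressionStudy(gene_ids, samples, values, meta)

    truth = GroundTruth(
        de_genes=de_genes,
        correlating_genes=corr_genes,
        slopes=slopes,
        regulated_tads=reg_tads,
        tad_sign=tad_sign,
        phenotype_scores=scores,
        latent_factors=latents,
    )
    return study, pheno, truth


# ---------------------------------------------------------------------------
# count-level simulators (for tail-fit and regulated-TAD tests)
# ---------------------------------------------------------------------------

def make_tad_counts(n_tads=150, n_enriched=10, background_median=2.0,
                    background_sigma=0.5, enrichment_sigmas=3.0, seed=0):
    """Per-TAD responsive-gene counts: log-normal background plus planted
    enriched TADs whose log-count sits ``enrichment_sigmas`` SDs above the
    background mean (with small positive jitter).

    Returns ``(counts, enriched_ids)`` with counts a Series indexed by TAD id.
    """
    rng = np.random.default_rng([int(seed), 303])
    mu = np.log(background_median)
    logc = rng.normal(mu, background_sigma, n_tads)
    ids = [f"T{i + 1}" for i in range(n_tads)]
    enriched = sorted(rng.choice(n_tads, size=n_enriched, replace=False).tolist())
    for i in enriched:
        logc[i] = mu + background_sigma * (enrichment_sigmas + abs(rng.normal(0, 0.25)))
    counts = pd.Series(np.maximum(1, np.rint(np.exp(logc))).astype(int), index=ids)
    return counts, [ids[i] for i in enriched]


def draw_counts(family, n, rng, **params):
    """Draw positive integer counts from a named family (for model-recovery
    checks): ``poisson`` (lam), ``lognormal`` (mean, sigma), ``exponential``
    (scale) or ``powerlaw`` (alpha)."""
    if family == "poisson":
        x = rng.poisson(params.get("lam", 3.0), size=n)
    elif family == "lognormal":
        x = np.rint(rng.lognormal(
            np.log(params.get("mean", 3.0)) - params.get("sigma", 0.7) ** 2 / 2,
            params.get("sigma", 0.7), size=n)).astype(int)
    elif family == "exponential":
        x = np.rint(rng.exponential(params.get("scale", 3.0), size=n)).astype(int)
    elif family == "powerlaw":
        alpha = params.get("alpha", 2.5)
        u = rng.random(n)
        x = np.floor(u ** (-1.0 / (alpha - 1.0))).astype(int)  # Pareto tail, xmin=1
    else:
        raise ValueError(f"unknown family {family!r}")
    return x[x >= 1]
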