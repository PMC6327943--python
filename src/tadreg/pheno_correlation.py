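"""PCA composite phenotype scores and gene-phenotype Spearman correlation.

Two composites condense the raw phenotype variables: a body-weight score
(PC1 of final weight and % gain) and a compulsivity score (PC1 of grooming,
nesting, limited-access intake days 1-3 and quinine-test intake).  Together
with inflexibility (quinine intake), total energy intake and eating rate
these form the five variables correlated with expression.  Each gene is
correlated by Spearman's rho; significance comes from the Fisher z transform
(z = atanh(rho), SD 1/sqrt(n-3)) with BH adjustment across genes within one
(region, variable) family.  The selection applies a dual filter: adjusted
p < 0.05 and a >= 10% change between diet groups on the linear scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io_formats import ExpressionStudy, PhenotypeTable

log = logging.getLogger("tadreg")

COMPOSITES = {
    "body_weight": ["final_weight", "pct_gain"],
    "compulsivity": ["grooming", "nesting", "intake_d1", "intake_d2",
                     "intake_d3", "quinine"],
}
SINGLE_VARIABLES = {
    "inflexibility": "quinine",
    "energy_intake": "total_intake",
    "eating_rate": "eating_rate",
}


@dataclass
class CompositeScore:
    """PC1 of a standardized variable block, one score per mouse."""

    name: str
    scores: pd.Series          # per mouse, centered
    loadings: pd.Series        # unit norm; first variable's loading >= 0
    explained_fraction: float


@dataclass
class CorrelationResult:
    region: str
    variable: str
    table: pd.DataFrame   # index gene; rho, pvalue, adj_pvalue, change, passed


def pca_composite(phenotypes: PhenotypeTable, variable_names) -> CompositeScore:
    """PC1 scores of z-scored variables; mice with missing data are dropped.

    Sign convention: the loading of the first listed variable is non-negative.
    """
    variable_names = list(variable_names)
    if len(variable_names) < 2:
        raise ValueError("PCA composite needs >= 2 variables")
    block = phenotypes.table[variable_names].astype(float)
    complete = block.dropna()
    dropped = sorted(set(block.index) - set(complete.index))
    if dropped:
        log.info("pca_composite: dropped mice with missing data: %s", dropped)
    if len(complete) < 3:
        raise ValueError("PCA composite needs >= 3 mice with complete data")
    sd = complete.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant variable(s): {bad}")
    z = (complete - complete.mean()) / sd
    u, s, vt = np.linalg.svd(z.values, full_matrices=False)
    load = vt[0]
    if load[0] < 0:
        load, u0 = -load, -u[:, 0]
    else:
        u0 = u[:, 0]
    scores = pd.Series(u0 * s[0], index=complete.index,
                       name="+".join(variable_names))
    explained = float(s[0] ** 2 / (s ** 2).sum())
    return CompositeScore(
        name="+".join(variable_names),
        scores=scores - scores.mean(),
        loadings=pd.Series(load, index=variable_names),
        explained_fraction=explained,
    )


def phenotype_scores(phenotypes: PhenotypeTable) -> pd.DataFrame:
    """The five per-mouse analysis scores (two composites + three raw)."""
    cols = {}
    for name, members in COMPOSITES.items():
        cols[name] = pca_composite(phenotypes, members).scores
    for name, raw in SINGLE_VARIABLES.items():
        cols[name] = phenotypes.values_for(raw)
    return pd.DataFrame(cols)


def spearman_fisher(expr_region: ExpressionStudy, score: pd.Series,
                    variable: str = "score") -> CorrelationResult:
    """Spearman rho of every gene with a per-mouse score, p by Fisher z.

    Samples are matched to scores through the mouse id in the metadata.
    rho is the Pearson correlation of average-tie midranks; the two-sided
    p-value is 2(1 - Phi(|atanh(rho)| sqrt(n-3))), BH-adjusted across genes.
    Mice without a score are dropped.  Zero-variance genes get rho = 0, p = 1.
    """
    mice = expr_region.sample_meta["mouse"]
    keep = [s for s in expr_region.samples
            if mice[s] in score.index and np.isfinite(score[mice[s]])]
    if len(keep) < len(expr_region.samples):
        log.info("spearman_fisher: dropped %d samples without scores",
                 len(expr_region.samples) - len(keep))
    sub = expr_region.subset_samples(keep)
    y = np.array([score[mice[s]] for s in keep], dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("Fisher-z correlation needs >= 4 observations")

    ry = stats.rankdata(y)
    rx = np.apply_along_axis(stats.rankdata, 1, sub.values)
    rxc = rx - rx.mean(axis=1, keepdims=True)
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum(axis=1) * (ryc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, rxc @ ryc / denom, 0.0)
    rho = np.clip(rho, -1.0, 1.0)
    flat = denom == 0
    if flat.any():
        log.info("spearman_fisher: %d zero-variance genes get rho=0, p=1",
                 int(flat.sum()))
    zstat = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    p = 2.0 * stats.norm.sf(np.abs(zstat) * np.sqrt(n - 3))
    p = np.where(flat, 1.0, p)
    adj = bh_adjust(p)

    diet = sub.sample_meta["diet"]
    cm = np.array([diet[s] == "CM" for s in keep])
    change = _group_change(sub.values, cm)

    table = pd.DataFrame({
        "rho": rho, "pvalue": p, "adj_pvalue": adj, "change": change,
    }, index=pd.Index(sub.genes, name="gene_id"))
    return CorrelationResult(region=str(sub.sample_meta["region"].iloc[0]),
                             variable=variable, table=table)


def _group_change(values, cm_mask):
    """|mean_linear(CM) / mean_linear(SC) - 1| on antilogged intensities."""
    lin = 2.0 ** values
    mean_cm = lin[:, cm_mask].mean(axis=1)
    mean_sc = lin[:, ~cm_mask].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean_sc > 0, mean_cm / mean_sc, np.inf)
    return np.abs(ratio - 1.0)


def select_correlating(result: CorrelationResult, min_change: float = 1.10,
                       q_max: float = 0.05) -> dict:
    """Signed correlating set: adjusted p < q_max AND linear-scale group
    change of at least ``min_change - 1`` (default 10%).

    Returns gene id -> sign of rho.
    """
    t = result.table
    mask = (t["adj_pvalue"] < q_max) & (t["change"] >= (min_change - 1.0)) & \
           (t["rho"] != 0)
    return {g: int(np.sign(r)) for g, r in t.loc[mask, "rho"].items()}


def high_rho_fc_profile(corr: CorrelationResult, de_table: pd.DataFrame,
                        rho_min: float = 0.9, fc_bins=None) -> pd.DataFrame:
    """Histogram of |log2FC| for genes with |rho| > ``rho_min``.

    Counts are split by the sign of rho.  ``de_table`` must carry a
    ``log2fc`` column; only genes present in both universes are binned.
    """
    if fc_bins is None:
        fc_bins = np.arange(0.0, 2.1, 0.1)
    fc_bins = np.asarray(fc_bins, dtype=float)
    shared = corr.table.index.intersection(de_table.index)
    labels = [f"[{a:.1f},{b:.1f})" for a, b in zip(fc_bins[:-1], fc_bins[1:])]
    out = pd.DataFrame(0, index=labels, columns=["positive", "negative"])
    if len(shared) == 0:
        return out
    rho = corr.table.loc[shared, "rho"]
    fc = de_table.loc[shared, "log2fc"].abs()
    for sign, col in ((1, "positive"), (-1, "negative")):
        sel = fc[(rho.abs() > rho_min) & (np.sign(rho) == sign)]
        counts, _ = np.histogram(sel.values, bins=fc_bins)
        out[col] = counts
    return out
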