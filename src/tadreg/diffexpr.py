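"""Probe filtering, replicate collapsing, moderated-t differential expression.

The differential-expression contrast is CM - SC within one brain region, on
log2 intensities.  Per-gene variances are shrunk toward a common prior by
empirical Bayes: a scaled inverse-chi-square prior whose hyperparameters
(prior df d0, prior variance s0^2) are estimated by the method of moments on
the log sample variances, giving the moderated t with d0 + d_g degrees of
freedom.  Benjamini-Hochberg adjustment is applied per region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import ExpressionStudy

log = logging.getLogger("tadreg")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def filter_probes(expr: ExpressionStudy, negctrl_p95_per_array,
                  factor: float = 1.10, min_arrays: int = 4) -> ExpressionStudy:
    """Keep probes whose intensity exceeds ``factor`` times the array's
    negative-control background (95th percentile of negative-control probes)
    on at least ``min_arrays`` arrays.

    ``negctrl_p95_per_array`` maps sample id -> background level, on the same
    intensity scale as the matrix.
    """
    neg = pd.Series(negctrl_p95_per_array, dtype=float)
    missing = [s for s in expr.samples if s not in neg.index]
    if missing:
        raise ValueError(f"no negative-control value for arrays: {missing}")
    thresholds = neg.loc[expr.samples].values * factor
    above = expr.values > thresholds[np.newaxis, :]
    keep = above.sum(axis=1) >= min_arrays
    kept = [g for g, k in zip(expr.genes, keep) if k]
    return ExpressionStudy(kept, expr.samples, expr.values[keep],
                           expr.sample_meta)


def collapse_replicates(expr: ExpressionStudy, probe_to_gene) -> ExpressionStudy:
    """Replace within-array replicate probes by their per-sample average,
    yielding the one-value-one-gene matrix.

    Probes mapping to no gene are dropped (counted in the log, not an error).
    Gene order follows first appearance among the probes.
    """
    gene_rows = {}
    order = []
    n_dropped = 0
    for i, probe in enumerate(expr.genes):
        gene = probe_to_gene.get(probe)
        if gene is None:
            n_dropped += 1
            continue
        if gene not in gene_rows:
            gene_rows[gene] = []
            order.append(gene)
        gene_rows[gene].append(i)
    if n_dropped:
        log.info("collapse_replicates: dropped %d unmapped probes", n_dropped)
    if not order:
        raise ValueError("no probe maps to any gene")
    values = np.vstack([expr.values[gene_rows[g]].mean(axis=0) for g in order])
    return ExpressionStudy(order, expr.samples, values, expr.sample_meta)


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

@dataclass
class ModeratedTParams:
    """Empirical-Bayes hyperparameters and the per-gene inputs they shrink."""

    d0: float          # prior degrees of freedom (may be inf)
    s0_squared: float  # prior variance
    s2: pd.Series      # per-gene pooled sample variance
    df: pd.Series      # per-gene residual df

    def __post_init__(self):
        if self.d0 < 0:
            raise ValueError("prior df must be >= 0")
        if self.s0_squared <= 0 and self.d0 > 0:
            raise ValueError("prior variance must be positive")


@dataclass
class DEResult:
    """Per-gene differential-expression statistics for one region."""

    region: str
    table: pd.DataFrame   # index gene; log2fc, t, pvalue, adj_pvalue,
                          # df_residual, posterior_var
    params: ModeratedTParams = None


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float):
    """Method-of-moments fit of (d0, s0^2) on the log sample variances.

    Under the scaled inverse-chi-square prior, log s_g^2 is a shifted
    log-F; matching its mean and variance via digamma/trigamma gives the
    hyperparameters.  Genes with zero variance are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 genes with positive variance")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    resid = evar - special.polygamma(1, df / 2.0)
    if resid <= 0:
        # less spread than pure chi-square noise: complete shrinkage toward
        # the pooled variance
        d0 = np.inf
        s0_sq = float(s2[ok].mean())
    else:
        d0 = 2.0 * _trigamma_inverse(resid)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def fit_de(expr: ExpressionStudy, region: str, d0: float = None,
           s0_squared: float = None) -> DEResult:
    """Moderated-t differential expression (CM vs SC) within one region.

    log2FC = mean(CM) - mean(SC); the t denominator uses the posterior
    variance s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g); p-values come from
    the t distribution with d0 + d_g df.  ``d0``/``s0_squared`` may be forced
    (0 recovers the ordinary two-sample t; inf uses s0^2 for every gene).
    """
    sub = expr.subset_region(region)
    diet = sub.sample_meta["diet"]
    cm = np.array([d == "CM" for d in diet])
    n1, n2 = int(cm.sum()), int((~cm).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 samples per diet in region {region!r}")
    df_resid = n1 + n2 - 2
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")

    x_cm, x_sc = sub.values[:, cm], sub.values[:, ~cm]
    log2fc = x_cm.mean(axis=1) - x_sc.mean(axis=1)
    ss = ((x_cm - x_cm.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((x_sc - x_sc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if d0 is None:
        d0_hat, s0_hat = estimate_prior(s2, df_resid)
    else:
        d0_hat = float(d0)
        s0_hat = float(s0_squared) if s0_squared is not None else \
            (float(np.median(s2[s2 > 0])) if d0 > 0 else 1.0)

    if np.isinf(d0_hat):
        post_var = np.full_like(s2, s0_hat)
        df_total = np.inf
    elif d0_hat == 0:
        post_var = s2.copy()
        df_total = float(df_resid)
    else:
        post_var = (d0_hat * s0_hat + df_resid * s2) / (d0_hat + df_resid)
        df_total = d0_hat + df_resid
    # the prior is no more informative than the genes that estimated it
    df_total = min(df_total, float(df_resid) * len(sub.genes))

    se = np.sqrt(post_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    constant = se == 0
    if constant.any():
        log.info("fit_de(%s): %d all-constant genes get t=0, p=1",
                 region, int(constant.sum()))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(constant, 1.0, p)
    adj = bh_adjust(p)

    table = pd.DataFrame({
        "log2fc": log2fc, "t": t, "pvalue": p, "adj_pvalue": adj,
        "df_residual": float(df_resid), "posterior_var": post_var,
    }, index=pd.Index(sub.genes, name="gene_id"))
    params = ModeratedTParams(
        d0=d0_hat, s0_squared=s0_hat,
        s2=pd.Series(s2, index=table.index),
        df=pd.Series(float(df_resid), index=table.index),
    )
    return DEResult(region=region, table=table, params=params)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def select_de(de: DEResult, fc_min: float, q_max: float) -> dict:
    """Signed DE set: |log2FC| >= log2(fc_min) and adjusted p < q_max.

    ``fc_min`` is a linear-scale fold change (1.5 means 2^0.585 in log2
    units).  Returns gene id -> +1/-1 by the sign of log2FC.
    """
    if fc_min <= 0 or q_max <= 0:
        raise ValueError("thresholds must be positive")
    t = de.table
    cut = np.log2(fc_min)
    mask = (t["log2fc"].abs() >= cut) & (t["adj_pvalue"] < q_max) & \
           (t["log2fc"] != 0)
    return {g: int(np.sign(fc)) for g, fc in t.loc[mask, "log2fc"].items()}


# ---------------------------------------------------------------------------
# MDS on leading log2FC
# ---------------------------------------------------------------------------

def leading_logfc_distance(expr: ExpressionStudy, top: int = 500) -> pd.DataFrame:
    """Pairwise sample distance: RMS of the ``top`` largest absolute per-gene
    log2 differences, selected independently for each pair."""
    n = expr.n_samples
    if expr.n_genes < top:
        log.warning("leading_logfc_distance: only %d genes, using all",
                    expr.n_genes)
        top = expr.n_genes
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(expr.values[:, i] - expr.values[:, j])
            sel = np.sort(diff)[::-1][:top]
            d[i, j] = d[j, i] = np.sqrt(np.mean(sel ** 2))
    return pd.DataFrame(d, index=expr.samples, columns=expr.samples)


def mds_leading_logfc(expr: ExpressionStudy, top: int = 500,
                      dims: int = 2) -> pd.DataFrame:
    """Classical metric MDS (double centering + eigendecomposition) of the
    leading-log2FC distance matrix; axes ordered by eigenvalue."""
    if expr.n_samples < 3:
        raise ValueError("MDS needs >= 3 samples")
    D = leading_logfc_distance(expr, top=top).values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    coords = np.zeros((n, dims))
    for k in range(min(dims, n)):
        if w[k] > 0:
            coords[:, k] = v[:, k] * np.sqrt(w[k])
    return pd.DataFrame(coords, index=expr.samples,
                        columns=[f"dim{k + 1}" for k in range(dims)])
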