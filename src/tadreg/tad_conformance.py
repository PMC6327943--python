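"""Do per-gene scores distribute non-randomly across TADs?

The conformance statistic is the Kruskal-Wallis H of per-gene scores
(log2 fold changes or phenotype correlations) grouped by TAD, over TADs
holding at least five genes.  Its null distribution is obtained by
permutation under two complementary schemes:

``gene_reassign``
    re-deal the in-TAD genes into the same TADs, preserving every TAD's
    gene count (destroys the gene-to-domain topology, keeps the count
    profile);

``border_shuffle``
    per chromosome, re-order the (TAD length, downstream gap) pairs and lay
    the borders down again from the first original TAD start, keeping every
    gene at its genomic position (perturbs the borders, keeps the gene
    positions; the minimum-gene filter is re-applied each round).

The empirical p-value uses the (k+1)/(B+1) convention; the raw descending
rank of the observed H among the permuted values is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneAnnotation, TadSegmentation
from .tad_map import GeneTadMap, assign_genes, filter_eligible

SCHEMES = ("gene_reassign", "border_shuffle")


@dataclass
class ConformanceResult:
    score_name: str
    observed_h: float
    chi2_pvalue: float
    df: int
    permuted_h: np.ndarray
    empirical_p: float
    rank: int              # 1 = observed larger than every permuted value
    scheme: str
    seed: int
    n_permutations: int = field(init=False)

    def __post_init__(self):
        self.permuted_h = np.asarray(self.permuted_h, dtype=float)
        self.n_permutations = self.permuted_h.size
        assert 0.0 < self.empirical_p <= 1.0


def kruskal_wallis(scores: pd.Series, gmap: GeneTadMap):
    """Kruskal-Wallis H with average-tie midranks and tie correction.

    ``scores`` must cover every gene of the map's eligible TADs; genes
    outside eligible TADs are ignored.  Returns ``(H, chi2_p)`` with the
    chi-square p on #groups - 1 df.  All-identical scores give H = 0, p = 1.
    """
    groups = gmap.groups()
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 eligible TADs")
    gene_lists = list(groups.values())
    all_genes = [g for lst in gene_lists for g in lst]
    x = scores.loc[all_genes].values.astype(float)
    n = x.size
    ranks = stats.rankdata(x)          # average ties
    if np.ptp(x) == 0:
        return 0.0, 1.0
    grand = (n + 1) / 2.0
    h = 0.0
    pos = 0
    for lst in gene_lists:
        k = len(lst)
        rbar = ranks[pos:pos + k].mean()
        h += k * (rbar - grand) ** 2
        pos += k
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(x, return_counts=True)
    tie_corr = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    h /= tie_corr
    df = len(groups) - 1
    return float(h), float(stats.chi2.sf(h, df))


def permute_gene_assignment(gmap: GeneTadMap, seed) -> GeneTadMap:
    """Uniformly re-partition the eligible genes into the same TADs,
    preserving each TAD's gene count exactly."""
    rng = _rng(seed)
    groups = gmap.groups()
    tad_order = list(groups)
    genes = [g for t in tad_order for g in groups[t]]
    shuffled = list(np.array(genes, dtype=object)[rng.permutation(len(genes))])
    mapping = {}
    pos = 0
    for t in tad_order:
        k = len(groups[t])
        for g in shuffled[pos:pos + k]:
            mapping[g] = t
        pos += k
    return GeneTadMap(mapping, min_genes=gmap.min_genes)


def permute_tad_borders(tads: TadSegmentation, genes: GeneAnnotation, seed,
                        anchor: str = "tss", min_genes: int = 1) -> GeneTadMap:
    """Shuffle TAD borders per chromosome and re-assign the (fixed) genes.

    The multiset of (length, downstream gap) pairs is conserved per
    chromosome, the leading gap before the first TAD stays fixed, so the
    re-built segmentation spans exactly the original interval.
    """
    shuffled = shuffle_borders(tads, seed)
    gmap = assign_genes(genes, shuffled, anchor=anchor)
    if min_genes > 1:
        gmap = filter_eligible(gmap, k=min_genes)
    return gmap


def shuffle_borders(tads: TadSegmentation, seed) -> TadSegmentation:
    """The raw border permutation, returned as a new segmentation."""
    rng = _rng(seed)
    rows = []
    for chrom, grp in tads.by_chrom():
        starts = grp["start"].values
        ends = grp["end"].values
        ids = grp["tad_id"].values
        n = len(ids)
        lengths = ends - starts
        gaps = np.empty(n, dtype=np.int64)
        gaps[:-1] = starts[1:] - ends[:-1]
        gaps[-1] = 0                       # trailing sequence ends at the last end
        order = rng.permutation(n)
        pos = int(starts[0])               # leading gap kept fixed
        for i in order:
            rows.append({"tad_id": ids[i], "chrom": chrom,
                         "start": pos, "end": pos + int(lengths[i])})
            pos += int(lengths[i]) + int(gaps[i])
        # pairs conserve the total span, so the rebuilt sequence cannot
        # overrun the original chromosome extent
        assert pos == int(starts[0]) + int((lengths + gaps).sum()), \
            "span not conserved"
    return TadSegmentation(pd.DataFrame(rows), chrom_length=tads.chrom_length)


def conformance_test(scores: pd.Series, gmap: GeneTadMap,
                     tads: TadSegmentation = None, genes: GeneAnnotation = None,
                     scheme: str = "gene_reassign", B: int = 1000, seed: int = 0,
                     score_name: str = "score",
                     refilter: bool = True) -> ConformanceResult:
    """Observed H versus B permutation replicates under the chosen scheme.

    For ``border_shuffle`` the minimum-gene eligibility filter is re-applied
    inside every round (disable with ``refilter=False``).  The empirical
    p-value is (#{H_perm >= H_obs} + 1) / (B + 1).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if B < 1:
        raise ValueError("B must be >= 1")
    if scheme == "border_shuffle":
        if tads is None or genes is None:
            raise ValueError("border_shuffle needs the segmentation and annotation")
        # only scored genes can enter a permuted grouping
        keep = genes.table["gene_id"].isin(scores.index)
        genes = GeneAnnotation(genes.table.loc[keep])

    h_obs, chi2_p = kruskal_wallis(scores, gmap)
    df = len(gmap.eligible) - 1
    rng = _rng(seed)
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=B)
    h_perm = np.empty(B)
    for b in range(B):
        if scheme == "gene_reassign":
            pm = permute_gene_assignment(gmap, int(child_seeds[b]))
            h_perm[b], _ = kruskal_wallis(scores, pm)
        else:
            k = gmap.min_genes if refilter else 1
            pm = permute_tad_borders(tads, genes, int(child_seeds[b]),
                                     min_genes=k)
            pm_scores = scores.reindex(pm.eligible_genes())
            h_perm[b], _ = kruskal_wallis(pm_scores, pm)
    n_ge = int((h_perm >= h_obs).sum())
    return ConformanceResult(
        score_name=score_name, observed_h=h_obs, chi2_pvalue=chi2_p, df=df,
        permuted_h=h_perm, empirical_p=(n_ge + 1) / (B + 1), rank=n_ge + 1,
        scheme=scheme, seed=int(seed),
    )


def _rng(seed):
    return np.random.default_rng(seed if isinstance(seed, (list, tuple))
                                 else int(seed))
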