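"""Assign genes to TADs and apply the minimum-gene eligibility filter.

A gene belongs to the TAD whose half-open interval [start, end) contains its
anchor point; the default anchor is the TSS (start on '+', end-1 on '-'),
with the gene-body midpoint as an alternative.  Genes in inter-TAD gaps, or
on chromosomes absent from the segmentation, stay unassigned.  All TAD-level
statistics downstream use only TADs holding at least ``k`` genes (default 5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation, TadSegmentation

log = logging.getLogger("tadreg")


@dataclass
class GeneTadMap:
    """gene id -> TAD id (or None), per-TAD counts, and eligibility flags."""

    gene_to_tad: dict
    min_genes: int = 1
    tad_counts: pd.Series = field(default=None)
    eligible: set = field(default=None)

    def __post_init__(self):
        assigned = pd.Series(
            {g: t for g, t in self.gene_to_tad.items() if t is not None},
            dtype=object,
        )
        self.tad_counts = assigned.value_counts() if len(assigned) else \
            pd.Series(dtype=int)
        self.eligible = set(self.tad_counts.index[self.tad_counts >= self.min_genes])

    @property
    def n_unassigned(self) -> int:
        return sum(1 for t in self.gene_to_tad.values() if t is None)

    def eligible_genes(self) -> list:
        """Genes sitting in eligible TADs, in input order."""
        return [g for g, t in self.gene_to_tad.items()
                if t is not None and t in self.eligible]

    def groups(self) -> dict:
        """eligible TAD id -> list of member genes (input order)."""
        out = {t: [] for t in self.eligible}
        for g, t in self.gene_to_tad.items():
            if t in out:
                out[t].append(g)
        return out


def assign_genes(genes: GeneAnnotation, tads: TadSegmentation,
                 anchor: str = "tss") -> GeneTadMap:
    """Map each gene to the TAD containing its anchor point.

    Half-open convention: an anchor equal to a TAD's ``end`` is outside it.
    """
    if anchor == "tss":
        anchors = genes.tss()
    elif anchor == "midpoint":
        anchors = genes.midpoint()
    else:
        raise ValueError(f"unknown anchor {anchor!r}")

    by_chrom = {
        c: (grp["start"].values, grp["end"].values, grp["tad_id"].values)
        for c, grp in tads.table.groupby("chrom", sort=False)
    }
    gt = genes.table
    gene_ids = gt["gene_id"].values
    assigned = np.full(len(gt), None, dtype=object)
    n_unknown_chrom = 0
    pos_all = anchors.values
    chrom_all = gt["chrom"].values
    for chrom in pd.unique(chrom_all):
        idx = np.nonzero(chrom_all == chrom)[0]
        entry = by_chrom.get(chrom)
        if entry is None:
            n_unknown_chrom += idx.size
            continue
        starts, ends, ids = entry
        pos = pos_all[idx]
        i = np.searchsorted(starts, pos, side="right") - 1
        inside = (i >= 0) & (pos < ends[np.clip(i, 0, None)])
        assigned[idx[inside]] = ids[i[inside]]
    mapping = dict(zip(gene_ids, assigned))
    if n_unknown_chrom:
        log.info("assign_genes: %d genes on chromosomes absent from the "
                 "segmentation left unassigned", n_unknown_chrom)
    return GeneTadMap(mapping, min_genes=1)


def filter_eligible(gmap: GeneTadMap, k: int = 5) -> GeneTadMap:
    """Flag TADs with fewer than ``k`` genes ineligible.

    Their genes are excluded from all TAD-level statistics.  Raises if no
    TAD survives (the statistics are then undefined).
    """
    out = GeneTadMap(dict(gmap.gene_to_tad), min_genes=k)
    if not out.eligible:
        raise ValueError(f"no TAD holds >= {k} genes; TAD statistics undefined")
    return out
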