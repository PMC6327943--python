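"""Readers, writers and validated domain types for every external format.

All coordinates are 0-based half-open (BED convention): a feature whose
anchor equals an interval's ``end`` lies *outside* that interval.  Every
downstream module consumes only the types defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("tadreg")

REGIONS = ("FC", "ST", "HT")
DIETS = ("SC", "CM")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionStudy:
    """A log2 expression matrix (rows = genes or probes) with sample metadata.

    Parameters
    ----------
    genes : list of str
        Ordered row identifiers (probe ids before collapsing, gene ids after).
    samples : list of str
        Ordered column identifiers.
    values : ndarray of shape (n_genes, n_samples)
        log2 intensities; must be finite.
    sample_meta : DataFrame indexed by sample id
        Columns ``region``, ``diet`` (SC or CM) and ``mouse``.
    """

    genes: list
    samples: list
    values: np.ndarray
    sample_meta: pd.DataFrame

    def __post_init__(self):
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = pd.Index(self.genes)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate row ids: {dupes[:5]}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        missing = [s for s in self.samples if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        for col in ("region", "diet", "mouse"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample metadata lacks required column {col!r}")
        bad_diet = set(self.sample_meta.loc[self.samples, "diet"]) - set(DIETS)
        if bad_diet:
            raise ValueError(f"unknown diet labels: {sorted(bad_diet)}")
        # keep metadata aligned and restricted to the matrix samples
        self.sample_meta = self.sample_meta.loc[self.samples].copy()

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self) -> pd.Index:
        return pd.Index(self.genes)

    def subset_samples(self, sample_ids) -> "ExpressionStudy":
        idx = [self.samples.index(s) for s in sample_ids]
        return ExpressionStudy(
            self.genes, list(sample_ids), self.values[:, idx],
            self.sample_meta.loc[list(sample_ids)],
        )

    def subset_region(self, region: str) -> "ExpressionStudy":
        keep = [s for s in self.samples if self.sample_meta.at[s, "region"] == region]
        if not keep:
            raise ValueError(f"no samples for region {region!r}")
        return self.subset_samples(keep)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class GeneAnnotation:
    """Gene coordinates: id, chromosome, start, end (half-open), strand."""

    table: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    def __post_init__(self):
        t = self.table
        required = ["gene_id", "chrom", "start", "end", "strand"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"annotation lacks columns {missing}")
        if t["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in annotation")
        if (t["start"] >= t["end"]).any():
            bad = t.loc[t["start"] >= t["end"], "gene_id"].tolist()[:5]
            raise ValueError(f"start >= end for genes {bad}")
        if not t["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def tss(self) -> pd.Series:
        """Anchor point of each gene: start on '+', end - 1 on '-'."""
        t = self.table
        pos = np.where(t["strand"] == "+", t["start"], t["end"] - 1)
        return pd.Series(pos, index=t["gene_id"].values, name="tss")

    def midpoint(self) -> pd.Series:
        t = self.table
        return pd.Series(
            (t["start"].values + t["end"].values) // 2,
            index=t["gene_id"].values, name="midpoint",
        )


@dataclass
class TadSegmentation:
    """Per-chromosome ordered, non-overlapping intervals with unique ids."""

    table: pd.DataFrame  # columns: tad_id, chrom, start, end
    chrom_length: dict = field(default_factory=dict)

    def __post_init__(self):
        t = self.table
        required = ["tad_id", "chrom", "start", "end"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"segmentation lacks columns {missing}")
        if t["tad_id"].duplicated().any():
            raise ValueError("duplicate TAD ids")
        if (t["start"] >= t["end"]).any():
            raise ValueError("TAD with start >= end")
        t = t.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        for chrom, grp in t.groupby("chrom", sort=False):
            ends = grp["end"].values[:-1]
            starts = grp["start"].values[1:]
            bad = np.nonzero(starts < ends)[0]
            if bad.size:
                i = bad[0]
                a, b = grp["tad_id"].values[i], grp["tad_id"].values[i + 1]
                raise ValueError(f"overlapping TADs {a!r} and {b!r} on {chrom}")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def tad_ids(self) -> list:
        return self.table["tad_id"].tolist()

    def by_chrom(self):
        return self.table.groupby("chrom", sort=False)


@dataclass
class PhenotypeTable:
    """Per-mouse diet label plus named numeric variables; NaN marks missing."""

    table: pd.DataFrame  # indexed by mouse id; 'diet' column + numeric columns

    def __post_init__(self):
        t = self.table
        if t.index.duplicated().any():
            raise ValueError("duplicate mouse ids")
        if "diet" not in t.columns:
            raise ValueError("phenotype table lacks 'diet' column")
        bad = set(t["diet"]) - set(DIETS)
        if bad:
            raise ValueError(f"unknown diet labels: {sorted(bad)}")

    @property
    def variables(self) -> list:
        return [c for c in self.table.columns if c != "diet"]

    def values_for(self, variable: str) -> pd.Series:
        if variable not in self.table.columns:
            raise KeyError(f"unknown phenotype variable {variable!r}")
        return self.table[variable]


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional descriptions."""

    sets: dict            # name -> frozenset of gene ids
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name):
        return self.sets[name]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression(path, meta_path) -> ExpressionStudy:
    """Read a genes x samples TSV plus a sample-metadata CSV.

    The TSV has a header row of sample ids and row ids in the first column;
    the CSV is keyed by ``sample_id`` with columns region, diet, mouse.
    Row and column order are preserved from the file.
    """
    mat = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if mat.index.duplicated().any():
        raise FormatError("duplicate row ids in expression matrix")
    if mat.columns.duplicated().any():
        raise FormatError("duplicate sample ids in expression matrix")
    for col in mat.columns:
        if not pd.api.types.is_numeric_dtype(mat[col]):
            bad_rows = mat.index[pd.to_numeric(mat[col], errors="coerce").isna()]
            raise FormatError(
                f"non-numeric value in column {col!r}, row(s) {list(bad_rows[:3])}"
            )
    meta = pd.read_csv(meta_path)
    if "sample_id" not in meta.columns:
        raise FormatError("metadata CSV lacks 'sample_id' column")
    if meta["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in metadata")
    meta = meta.set_index("sample_id")
    absent = [s for s in mat.columns if s not in meta.index]
    if absent:
        raise FormatError(f"samples missing from metadata: {absent}")
    return ExpressionStudy(
        list(mat.index), list(mat.columns), mat.values, meta
    )


def _read_bed(path, n_required):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < n_required:
                raise FormatError(f"{path}:{lineno}: expected >= {n_required} columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            rows.append((lineno, parts, start, end))
    return rows


def read_tads(path) -> TadSegmentation:
    """Read a BED3(+name) TAD segmentation; ids auto-generated if absent."""
    rows = _read_bed(path, 3)
    recs = []
    for i, (lineno, parts, start, end) in enumerate(rows):
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start >= end")
        tad_id = parts[3] if len(parts) > 3 and parts[3] not in ("", ".") else f"TAD{i + 1}"
        recs.append({"tad_id": tad_id, "chrom": parts[0], "start": start, "end": end})
    return TadSegmentation(pd.DataFrame(recs, columns=["tad_id", "chrom", "start", "end"]))


def read_genes(path) -> GeneAnnotation:
    """Read gene coordinates from BED6 (chrom start end name score strand)."""
    rows = _read_bed(path, 6)
    recs = []
    for lineno, parts, start, end in rows:
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start >= end")
        recs.append({
            "gene_id": parts[3], "chrom": parts[0],
            "start": start, "end": end, "strand": parts[5],
        })
    return GeneAnnotation(pd.DataFrame(
        recs, columns=["gene_id", "chrom", "start", "end", "strand"]
    ))


def read_phenotypes(path) -> PhenotypeTable:
    """Read the per-mouse phenotype CSV; empty cells become NaN, never zero."""
    t = pd.read_csv(path)
    if "mouse" not in t.columns or "diet" not in t.columns:
        raise FormatError("phenotype CSV needs 'mouse' and 'diet' columns")
    t = t.set_index("mouse")
    for col in t.columns:
        if col == "diet":
            continue
        t[col] = pd.to_numeric(t[col], errors="raise")
    return PhenotypeTable(t)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets, descs = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line with no genes")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: empty gene set {name!r}")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(genes)
            descs[name] = desc
    return GeneSetCollection(sets, descs)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(result: pd.DataFrame, path, seed=None, params=None) -> None:
    """Write a result table as CSV with a provenance comment line.

    The comment records the RNG seed and a hash of the parameters so that
    permutation-based results can be reproduced exactly.
    """
    import hashlib
    import json

    blob = json.dumps(params, sort_keys=True, default=str) if params else ""
    phash = hashlib.sha256(blob.encode()).hexdigest()[:12] if blob else "none"
    with open(path, "w") as fh:
        fh.write(f"# tadreg v0.1.0 seed={seed} params_hash={phash}\n")
        result.to_csv(fh, index=True)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=0)


def write_expression(study: ExpressionStudy, expr_path, meta_path) -> None:
    study.to_frame().to_csv(expr_path, sep="\t", index_label="gene_id")
    meta = study.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path)


def write_tads(tads: TadSegmentation, path) -> None:
    with open(path, "w") as fh:
        for row in tads.table.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.tad_id}\n")


def write_genes(genes: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        for row in genes.table.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\n"
            )


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    t = pheno.table.copy()
    t.index.name = "mouse"
    t.to_csv(path)
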