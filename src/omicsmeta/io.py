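"""Data model and readers/writers for the pipeline's external formats.

Tabular inputs (summary statistics, traits, covariates, kinship,
annotations) are tab-separated with a header row; genotypes come from VCF;
gene sets (PPI modules, GO terms) use the GMT format. All genomic
coordinates are 1-based and intervals are inclusive, following GFF/VCF
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "GeneModel",
    "ModuleCollection",
    "GENE_SCORE_COLUMNS",
    "RVA_CATEGORIES",
    "compute_maf",
    "read_gmt",
    "write_gmt",
    "read_vcf",
    "read_gene_models",
    "read_table",
    "read_kinship",
    "write_gene_scores",
    "read_gene_scores",
    "clip_pvalues",
    "align_samples",
    "AlignmentError",
]

#: Functional categories used by the rare-variant stage; "none" marks rows
#: from sources that do not stratify by category.
RVA_CATEGORIES = (
    "synonymous",
    "missense",
    "plof",
    "promoter_CAGE",
    "promoter_DHS",
    "enhancer_CAGE",
    "enhancer_DHS",
    "upstream",
    "downstream",
    "UTR",
)

GENE_SCORE_COLUMNS = ["gene_id", "trait", "source", "category", "p", "beta", "n_units"]

#: Floor applied to p-values on ingestion so z-transforms stay finite.
P_FLOOR = 1e-300


class AlignmentError(ValueError):
    """Raised when sample tables share no samples."""


@dataclass
class VariantRecord:
    """A biallelic variant with per-sample alt-allele dosages.

    ``dosages`` holds values in {0, 1, 2} with ``nan`` for missing calls.
    ``maf`` is the folded allele frequency computed from non-missing calls.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    dosages: np.ndarray
    maf: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.maf is None:
            self.maf = compute_maf(self.dosages)


@dataclass
class GeneModel:
    """A gene body interval (1-based, inclusive). Strand is carried but
    ignored by every computation: variant-to-gene windows are symmetric."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )


class ModuleCollection(dict):
    """Ordered mapping of set name -> list of gene ids, with a provenance
    tag (e.g. physical vs functional PPI network)."""

    def __init__(self, sets=None, provenance: str = ""):
        super().__init__(sets or {})
        self.provenance = provenance


def compute_maf(dosages) -> float:
    """Folded minor-allele frequency from dosages in {0, 1, 2, nan}.

    Missing dosages are excluded (never imputed) so the MAF reflects
    observed alleles only.
    """
    d = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(d)
    if not ok.any():
        raise ValueError("MAF undefined: all dosages missing")
    f = float(np.mean(d[ok])) / 2.0
    return min(f, 1.0 - f)


def read_gmt(path, provenance: str = "") -> ModuleCollection:
    """Parse a GMT file: one gene set per line, tab-separated
    ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line are dropped (first occurrence kept) with a
    warning; malformed lines raise with their line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line == "":
                raise ValueError(f"{path}: empty line at line {lineno}")
            fields = line.split("\t")
            if len(fields) < 3 or fields[0] == "":
                raise ValueError(
                    f"{path}: malformed GMT line {lineno} "
                    f"(need name, description, >=1 gene)"
                )
            name, _desc, *genes = fields
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    warnings.warn(
                        f"{path}:{lineno}: duplicate gene {g!r} in set {name!r}"
                    )
                else:
                    seen[g] = None
            sets[name] = list(seen)
    return ModuleCollection(sets, provenance=provenance)


def write_gmt(modules: ModuleCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in modules.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_vcf(path, samples: list[str] | None = None):
    """Read biallelic SNVs from a VCF into (variants, sample_ids).

    Returns a list of :class:`VariantRecord` (dosages ordered like
    ``sample_ids``) and the sample id list. Multi-allelic records are
    skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    if samples is not None:
        vcf.set_samples(samples)
    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(f"skipping multi-allelic record at {rec.CHROM}:{rec.POS}")
            continue
        gt = np.asarray(rec.gt_types, dtype=float)  # 0/1/2, 3 = missing
        gt[gt == 3] = np.nan
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(
            VariantRecord(vid, str(rec.CHROM), rec.POS, rec.REF, rec.ALT[0], gt)
        )
    return variants, sample_ids


def read_gene_models(path) -> list[GeneModel]:
    """Read gene intervals from a BED-like TSV with header
    ``gene_id chrom start end [strand]`` (1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    has_strand = "strand" in df.columns
    return [
        GeneModel(
            str(r.gene_id),
            str(r.chrom),
            int(r.start),
            int(r.end),
            str(r.strand) if has_strand else "unknown",
        )
        for r in df.itertuples()
    ]


def read_table(path, index_col: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if index_col is not None:
        df = df.set_index(index_col)
        df.index = df.index.astype(str)
    return df


def read_kinship(path) -> pd.DataFrame:
    """Square kinship matrix TSV with sample ids as first row and column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError("kinship matrix row and column ids differ")
    return df


def clip_pvalues(p):
    """Clip p-values into [1e-300, 1] so downstream z-transforms are finite."""
    return np.clip(np.asarray(p, dtype=float), P_FLOOR, 1.0)


def write_gene_scores(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in GENE_SCORE_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan if col in ("beta",) else ""
    out[GENE_SCORE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["p"] = clip_pvalues(df["p"].to_numpy())
    if "category" in df.columns:
        df["category"] = df["category"].fillna("none")
    return df


def align_samples(*tables, sample_ids: list[list[str]] | None = None):
    """Intersect sample ids across tables and reindex all of them to a
    common order (the first table's order restricted to the intersection).

    Each table is a pandas object indexed by sample id, or (for matrices
    whose *columns* are samples) pass ``axis='columns'`` by pre-transposing.
    Returns (aligned_tables, common_ids, n_dropped_per_table).
    """
    id_lists = (
        sample_ids
        if sample_ids is not None
        else [list(map(str, t.index)) for t in tables]
    )
    common = set(id_lists[0])
    for ids in id_lists[1:]:
        common &= set(ids)
    if not common:
        raise AlignmentError("no samples shared across tables")
    order = [s for s in id_lists[0] if s in common]
    dropped = [len(ids) - len(order) for ids in id_lists]
    aligned = []
    for t, ids in zip(tables, id_lists):
        if isinstance(t, (pd.DataFrame, pd.Series)):
            t2 = t.copy()
            t2.index = list(map(str, t2.index))
            aligned.append(t2.loc[order])
        else:  # ndarray rows ordered like ids
            pos = {s: i for i, s in enumerate(ids)}
            aligned.append(np.asarray(t)[[pos[s] for s in order]])
    return aligned, order, dropped
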