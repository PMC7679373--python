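"""Gene annotation, count matrices and RPKM normalization.

Expression is quantified as reads per kilobase of exon model per million
mapped reads (RPKM).  A gene is considered *present* in a sample when its
RPKM is at or above a floor (3 RPKM by default); genes absent from both
sides of a contrast are excluded from differential testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PRESENCE_FLOOR",
    "GeneModel",
    "GeneAnnotation",
    "CountMatrix",
    "ExpressionMatrix",
    "read_annotation",
    "write_annotation",
    "read_counts",
    "write_counts",
    "rpkm",
    "pool_replicates",
]

#: Minimum RPKM at which a transcript is called significantly present.
PRESENCE_FLOOR = 3.0

_VALID_STRANDS = frozenset({"+", "-"})


@dataclass(frozen=True)
class GeneModel:
    """One gene: the unit to which counts, peaks and memory calls attach.

    ``tss`` is a 0-based genomic coordinate; ``exon_length`` is the summed
    exon-model length in bp used by the RPKM denominator.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int
    exon_length: int

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0, got {self.tss}")
        if self.exon_length < 1:
            raise ValueError(f"gene {self.gene_id}: exon_length must be >= 1, got {self.exon_length}")


class GeneAnnotation:
    """Ordered, unique-id collection of :class:`GeneModel`."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValueError(f"duplicate gene_id in annotation: {g.gene_id}")
            self._genes[g.gene_id] = g

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self):
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def exon_lengths(self) -> pd.Series:
        return pd.Series({g.gene_id: g.exon_length for g in self}, name="exon_length")


_ANNOTATION_COLUMNS = ["gene_id", "chrom", "strand", "tss", "exon_length", "symbol"]


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read a 6-column annotation TSV (gene_id, chrom, strand, tss, exon_length, symbol)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation is missing columns {missing}")
    genes = [
        GeneModel(
            gene_id=row.gene_id,
            symbol=row.symbol,
            chrom=row.chrom,
            strand=row.strand,
            tss=int(row.tss),
            exon_length=int(row.exon_length),
        )
        for row in df.itertuples(index=False)
    ]
    return GeneAnnotation(genes)


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss, g.exon_length, g.symbol) for g in annotation],
        columns=_ANNOTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass
class CountMatrix:
    """Raw read counts, genes x samples, with per-sample library sizes.

    ``library_sizes`` are total *mapped* reads per sample.  They may exceed
    the column sums (mapped reads include intergenic and multi-gene reads
    that never land in a gene-level count), so no sum constraint is imposed.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.library_sizes.index]
        if missing:
            raise ValueError(f"library size missing for samples: {missing}")
        self.library_sizes = self.library_sizes.loc[list(self.counts.columns)].astype(float)
        if (self.library_sizes <= 0).any():
            bad = self.library_sizes[self.library_sizes <= 0].index.tolist()
            raise ValueError(f"library sizes must be positive; offending samples: {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def read_counts(
    path: str | Path,
    annotation: GeneAnnotation,
    library_sizes: Mapping[str, float] | None = None,
) -> CountMatrix:
    """Read a counts TSV (gene_id + one column per sample) against an annotation.

    Genes are reordered to annotation order.  Unknown gene ids, duplicates
    and negative counts are rejected with the offending identifiers named.
    When ``library_sizes`` is not given, the per-sample column sum is used
    as the total-mapped-reads stand-in.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    dup = df["gene_id"][df["gene_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate gene_ids: {sorted(set(dup))}")
    unknown = [g for g in df["gene_id"] if g not in annotation]
    if unknown:
        raise ValueError(f"{path}: gene_ids absent from annotation: {unknown[:10]}")
    df = df.set_index("gene_id")
    try:
        counts = df.astype("int64")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-integer count value ({exc})") from exc
    if (counts.values < 0).any():
        bad = counts.index[(counts.values < 0).any(axis=1)].tolist()
        raise ValueError(f"{path}: negative counts for genes: {bad[:10]}")
    missing = [g for g in annotation.gene_ids if g not in counts.index]
    if missing:
        raise ValueError(f"{path}: annotation genes missing from counts: {missing[:10]}")
    counts = counts.loc[annotation.gene_ids]
    if library_sizes is None:
        libs = counts.sum(axis=0).astype(float)
    else:
        libs = pd.Series(dict(library_sizes), dtype=float)
    return CountMatrix(counts=counts, library_sizes=libs)


def write_counts(matrix: CountMatrix, path: str | Path, library_sizes_path: str | Path | None = None) -> None:
    """Write counts as TSV; optionally write library sizes as an adjacent JSON."""
    matrix.counts.rename_axis("gene_id").to_csv(path, sep="\t")
    if library_sizes_path is not None:
        with open(library_sizes_path, "w") as fh:
            json.dump({k: float(v) for k, v in matrix.library_sizes.items()}, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class ExpressionMatrix:
    """RPKM values plus per-(gene, sample) presence flags."""

    rpkm: pd.DataFrame
    present: pd.DataFrame
    floor: float = PRESENCE_FLOOR

    def present_in_any(self, samples: Sequence[str]) -> pd.Series:
        """Genes present (RPKM >= floor) in at least one of ``samples``."""
        return self.present[list(samples)].any(axis=1)


def rpkm(
    counts: CountMatrix,
    annotation: GeneAnnotation,
    floor: float = PRESENCE_FLOOR,
) -> ExpressionMatrix:
    """RPKM[g, s] = counts[g, s] * 1e9 / (library_size[s] * exon_length[g]).

    The presence flag is inclusive at the floor (a gene at exactly the floor
    counts as present).
    """
    lengths = annotation.exon_lengths().loc[counts.gene_ids]
    vals = counts.counts.values * 1e9 / (
        counts.library_sizes.values[None, :] * lengths.values[:, None]
    )
    rp = pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns)
    return ExpressionMatrix(rpkm=rp, present=rp >= floor, floor=floor)


def pool_replicates(matrix: CountMatrix, groups: Mapping[str, Sequence[str]]) -> CountMatrix:
    """Sum replicate columns (and their library sizes) into one column per condition.

    The replicate-free two-library test operates on pooled libraries, so
    replicates of a condition are combined by summation before testing.
    """
    pooled = {}
    libs = {}
    for condition, samples in groups.items():
        samples = list(samples)
        unknown = [s for s in samples if s not in matrix.counts.columns]
        if unknown:
            raise KeyError(f"unknown samples for condition {condition!r}: {unknown}")
        pooled[condition] = matrix.counts[samples].sum(axis=1)
        libs[condition] = float(matrix.library_sizes[samples].sum())
    return CountMatrix(counts=pd.DataFrame(pooled), library_sizes=pd.Series(libs))
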