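"""Accessibility peak files and their assignment to genes by TSS proximity.

Peaks come from ATAC-seq or DNase-seq peak callers as BED3+/narrowPeak.
A peak annotates a gene when it overlaps, by at least 1 bp, the window
[TSS - W, TSS + W) around the gene's transcription start site (W = 5 kb by
default).  Coordinates are 0-based half-open throughout, per BED.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .expression import GeneAnnotation, GeneModel

__all__ = [
    "TSS_WINDOW",
    "PeakInterval",
    "TssAssignment",
    "read_bed",
    "write_bed",
    "assign_peaks_to_tss",
    "assign_peaks_brute_force",
    "tss_profile",
]

#: Default padding distance from the TSS, in bp.
TSS_WINDOW = 5000


@dataclass(frozen=True)
class PeakInterval:
    """One called peak, 0-based half-open [start, end).

    ``summit`` is the absolute summit coordinate when the source was a
    narrowPeak file with a valid summit offset, else None.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"peak start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted peak interval [{self.start}, {self.end})")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def reference_point(self) -> int:
        """Summit when known, else the interval midpoint."""
        return self.summit if self.summit is not None else self.midpoint


def read_bed(path: str | Path) -> list[PeakInterval]:
    """Read BED3+/narrowPeak into peak intervals.

    Track/browser/comment lines are skipped.  narrowPeak summit offsets
    (10th column, -1 meaning unknown) are resolved to absolute coordinates.
    Malformed coordinates raise with the line number.
    """
    peaks: list[PeakInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            summit = None
            if len(fields) >= 10:  # narrowPeak: col 10 is summit offset from start
                try:
                    offset = int(fields[9])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric summit offset") from exc
                if offset >= 0:
                    summit = start + offset
            try:
                peaks.append(
                    PeakInterval(chrom=chrom, start=start, end=end, name=name, score=score, summit=summit)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_bed(peaks: Iterable[PeakInterval], path: str | Path) -> None:
    """Write peaks as BED3 (plus name/score columns when any peak carries them)."""
    peaks = list(peaks)
    with_name = any(p.name is not None for p in peaks)
    with_score = any(p.score is not None for p in peaks)
    with open(path, "w") as fh:
        for p in peaks:
            fields = [p.chrom, str(p.start), str(p.end)]
            if with_name or with_score:
                fields.append(p.name if p.name is not None else ".")
            if with_score:
                fields.append(f"{p.score:g}" if p.score is not None else ".")
            fh.write("\t".join(fields) + "\n")


@dataclass
class TssAssignment:
    """Peak-to-gene assignment within the TSS window.

    ``pairs`` holds one row per (peak, gene) pair with the strand-aware
    signed distance from the TSS to the peak reference point (positive =
    downstream in transcript orientation).
    """

    window: int
    pairs: list[tuple[int, str, int]]  # (peak index, gene_id, signed distance)
    peaks: list[PeakInterval]

    @property
    def gene_to_peaks(self) -> dict[str, set[int]]:
        out: dict[str, set[int]] = defaultdict(set)
        for pi, gid, _ in self.pairs:
            out[gid].add(pi)
        return dict(out)

    @property
    def peak_to_genes(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = defaultdict(set)
        for pi, gid, _ in self.pairs:
            out[pi].add(gid)
        return dict(out)

    @property
    def annotated_genes(self) -> set[str]:
        """Genes with at least one assigned peak."""
        return {gid for _, gid, _ in self.pairs}


def _signed_distance(peak: PeakInterval, gene: GeneModel) -> int:
    d = peak.reference_point - gene.tss
    return d if gene.strand == "+" else -d


def assign_peaks_to_tss(
    peaks: Sequence[PeakInterval],
    genes: GeneAnnotation | Iterable[GeneModel],
    window: int = TSS_WINDOW,
) -> TssAssignment:
    """Assign each peak to every gene whose half-open window [TSS-W, TSS+W) it overlaps by >= 1 bp.

    Windows are clipped at coordinate 0.  Implemented with a per-chromosome
    interval index; contractually identical to the all-pairs scan.
    """
    if window < 0:
        raise ValueError(f"window must be >= 0, got {window}")
    peaks = list(peaks)
    genes = list(genes)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        lo = max(0, g.tss - window)
        hi = g.tss + window
        if lo < hi:
            trees[g.chrom].addi(lo, hi, g)
    pairs: list[tuple[int, str, int]] = []
    for i, p in enumerate(peaks):
        if p.chrom not in trees:
            continue
        for iv in trees[p.chrom].overlap(p.start, p.end):
            g = iv.data
            pairs.append((i, g.gene_id, _signed_distance(p, g)))
    pairs.sort(key=lambda t: (t[0], t[1]))
    return TssAssignment(window=window, pairs=pairs, peaks=peaks)


def assign_peaks_brute_force(
    peaks: Sequence[PeakInterval],
    genes: GeneAnnotation | Iterable[GeneModel],
    window: int = TSS_WINDOW,
) -> TssAssignment:
    """Reference all-pairs scan with the identical overlap rule (for cross-checks)."""
    if window < 0:
        raise ValueError(f"window must be >= 0, got {window}")
    peaks = list(peaks)
    genes = list(genes)
    pairs: list[tuple[int, str, int]] = []
    for i, p in enumerate(peaks):
        for g in genes:
            if p.chrom != g.chrom:
                continue
            lo = max(0, g.tss - window)
            hi = g.tss + window
            if min(p.end, hi) - max(p.start, lo) >= 1:
                pairs.append((i, g.gene_id, _signed_distance(p, g)))
    pairs.sort(key=lambda t: (t[0], t[1]))
    return TssAssignment(window=window, pairs=pairs, peaks=peaks)


def tss_profile(assignment: TssAssignment, unique: bool = False) -> pd.DataFrame:
    """Signed TSS-distance table for plotting the peak distribution around TSSs.

    One row per (peak, gene) pair: gene_id, signed distance of the peak
    summit/midpoint from the TSS (strand-aware), peak score.  With
    ``unique=True`` only the nearest gene per peak is kept (one dot = one
    peak assigned to a unique gene), ties broken by gene_id.
    """
    rows = [
        {
            "peak_index": pi,
            "chrom": assignment.peaks[pi].chrom,
            "start": assignment.peaks[pi].start,
            "end": assignment.peaks[pi].end,
            "gene_id": gid,
            "distance": dist,
            "score": assignment.peaks[pi].score,
        }
        for pi, gid, dist in assignment.pairs
    ]
    df = pd.DataFrame(
        rows, columns=["peak_index", "chrom", "start", "end", "gene_id", "distance", "score"]
    )
    if unique and not df.empty:
        df = (
            df.assign(absd=df["distance"].abs())
            .sort_values(["peak_index", "absd", "gene_id"], kind="mergesort")
            .drop_duplicates("peak_index", keep="first")
            .drop(columns="absd")
            .reset_index(drop=True)
        )
    return df
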