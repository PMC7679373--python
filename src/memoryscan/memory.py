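"""The inflammatory-memory intersection cascade.

Genes differentially expressed under chronic TNF exposure are intersected
with the union of the short-term TNF contrasts to yield sustained activated
genes (mSAGs) and sustained repressed genes (mSRGs); those are filtered for
accessible chromatin near the TSS in both short-term and chronic peak sets;
finally the surviving genes are mapped to human orthologs and kept only if
the human contrast shows the same direction at both time points (hSAGs /
hSRGs).  Every step records numerator, denominator and percentage so the
Venn-diagram numbers are auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DegSetCollection",
    "MemoryCallSet",
    "OverlapStep",
    "OverlapSummary",
    "call_sustained",
    "epigenomic_filter",
    "human_conservation_filter",
    "classify_memory",
    "overlap_summary",
    "percentage",
    "read_ortholog_map",
    "write_ortholog_map",
]


@dataclass
class DegSetCollection:
    """Up/down gene sets per contrast: each short-term mouse timepoint, mouse chronic, human 8 h/24 h."""

    short_term_up: dict[str, set[str]]
    short_term_down: dict[str, set[str]]
    chronic_up: set[str]
    chronic_down: set[str]
    human_up: dict[str, set[str]]
    human_down: dict[str, set[str]]

    def __post_init__(self) -> None:
        for label, (up, down) in self._contrasts().items():
            clash = up & down
            if clash:
                raise ValueError(f"contrast {label!r}: genes in both up and down: {sorted(clash)[:5]}")

    def _contrasts(self) -> dict[str, tuple[set, set]]:
        out = {f"short_term:{k}": (self.short_term_up[k], self.short_term_down[k]) for k in self.short_term_up}
        out["chronic"] = (self.chronic_up, self.chronic_down)
        out.update({f"human:{k}": (self.human_up[k], self.human_down[k]) for k in self.human_up})
        return out


@dataclass
class MemoryCallSet:
    """Nested gene sets of the cascade, mouse ids for m*/epi_* and human symbols for h*."""

    msag: set[str]
    msrg: set[str]
    epi_msag: set[str]
    epi_msrg: set[str]
    hsag: set[str]
    hsrg: set[str]
    ortholog_map: dict[str, str] = field(default_factory=dict)


def call_sustained(
    chronic_up: set[str],
    chronic_down: set[str],
    short_term_up: Sequence[set[str]],
    short_term_down: Sequence[set[str]],
    mode: str = "union",
) -> tuple[set[str], set[str]]:
    """Sustained genes: chronic DE genes that recur in the short-term contrasts.

    ``mode='union'`` requires the same direction in at least one short-term
    exposure (the default cascade rule); ``mode='all'`` requires it in every
    short-term exposure (sensitivity analysis).
    """
    if not list(short_term_up) or not list(short_term_down):
        raise ValueError("at least one short-term contrast is required")
    if mode == "union":
        st_up = set().union(*short_term_up)
        st_down = set().union(*short_term_down)
    elif mode == "all":
        st_up = set.intersection(*map(set, short_term_up))
        st_down = set.intersection(*map(set, short_term_down))
    else:
        raise ValueError(f"mode must be 'union' or 'all', got {mode!r}")
    return chronic_up & st_up, chronic_down & st_down


def epigenomic_filter(
    genes: set[str],
    annotated_short_term: set[str],
    annotated_chronic: set[str],
) -> set[str]:
    """Keep genes with accessible chromatin near the TSS in BOTH peak sets."""
    return genes & annotated_short_term & annotated_chronic


def human_conservation_filter(
    mouse_genes: set[str],
    ortholog_map: Mapping[str, str],
    human_t1: set[str],
    human_t2: set[str],
) -> set[str]:
    """Human orthologs of mouse genes that are differential (same direction) at both human time points.

    Mouse genes without an ortholog are dropped (and logged); the map must
    be functional (at most one human symbol per mouse gene, guaranteed by
    the Mapping type).
    """
    unmapped = sorted(g for g in mouse_genes if g not in ortholog_map)
    if unmapped:
        logger.info("human_conservation_filter: %d gene(s) without ortholog: %s",
                    len(unmapped), unmapped[:10])
    mapped = {ortholog_map[g] for g in mouse_genes if g in ortholog_map}
    return mapped & human_t1 & human_t2


def classify_memory(
    deg: DegSetCollection,
    annotated_short_term: set[str],
    annotated_chronic: set[str],
    ortholog_map: Mapping[str, str],
    short_term_mode: str = "union",
) -> MemoryCallSet:
    """Run the full cascade on one study's DE sets, peak annotations and ortholog map."""
    msag, msrg = call_sustained(
        deg.chronic_up,
        deg.chronic_down,
        [deg.short_term_up[k] for k in deg.short_term_up],
        [deg.short_term_down[k] for k in deg.short_term_down],
        mode=short_term_mode,
    )
    epi_msag = epigenomic_filter(msag, annotated_short_term, annotated_chronic)
    epi_msrg = epigenomic_filter(msrg, annotated_short_term, annotated_chronic)
    human_tp = sorted(deg.human_up)
    hsag = human_conservation_filter(
        epi_msag, ortholog_map, deg.human_up[human_tp[0]], deg.human_up[human_tp[1]]
    )
    hsrg = human_conservation_filter(
        epi_msrg, ortholog_map, deg.human_down[human_tp[0]], deg.human_down[human_tp[1]]
    )
    return MemoryCallSet(
        msag=msag, msrg=msrg, epi_msag=epi_msag, epi_msrg=epi_msrg,
        hsag=hsag, hsrg=hsrg, ortholog_map=dict(ortholog_map),
    )


def percentage(numerator: int, denominator: int, precision: int = 0) -> float | None:
    """numerator/denominator x 100, rounded half-up to ``precision`` decimals; None when undefined."""
    if numerator < 0 or denominator < 0 or numerator > denominator:
        raise ValueError(f"need 0 <= numerator <= denominator, got {numerator}/{denominator}")
    if denominator == 0:
        return None
    quant = Decimal(1).scaleb(-precision)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(quant, rounding=ROUND_HALF_UP)
    return float(value)


@dataclass(frozen=True)
class OverlapStep:
    name: str
    numerator: int
    denominator: int
    percentage: float | None


@dataclass
class OverlapSummary:
    """Counts and percentages for every cascade step, in cascade order."""

    steps: list[OverlapStep]

    def to_dict(self) -> dict:
        return {
            s.name: {"numerator": s.numerator, "denominator": s.denominator, "percentage": s.percentage}
            for s in self.steps
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.numerator, s.denominator, s.percentage) for s in self.steps],
            columns=["step", "numerator", "denominator", "percentage"],
        )

    def __getitem__(self, name: str) -> OverlapStep:
        for s in self.steps:
            if s.name == name:
                return s
        raise KeyError(name)


def overlap_summary(cascade: MemoryCallSet, deg: DegSetCollection, precision: int = 1) -> OverlapSummary:
    """Per-step overlap accounting: sustained over chronic, epi-filtered over
    sustained, human-conserved over epi-filtered, and human cross-timepoint
    agreement over the union of the two human DE sets."""
    human_tp = sorted(deg.human_up)
    h_up_common = deg.human_up[human_tp[0]] & deg.human_up[human_tp[1]]
    h_up_union = deg.human_up[human_tp[0]] | deg.human_up[human_tp[1]]
    h_down_common = deg.human_down[human_tp[0]] & deg.human_down[human_tp[1]]
    h_down_union = deg.human_down[human_tp[0]] | deg.human_down[human_tp[1]]
    raw = [
        ("sustained_up", len(cascade.msag), len(deg.chronic_up)),
        ("sustained_down", len(cascade.msrg), len(deg.chronic_down)),
        ("epi_up", len(cascade.epi_msag), len(cascade.msag)),
        ("epi_down", len(cascade.epi_msrg), len(cascade.msrg)),
        ("human_up", len(cascade.hsag), len(cascade.epi_msag)),
        ("human_down", len(cascade.hsrg), len(cascade.epi_msrg)),
        ("human_timepoint_overlap_up", len(h_up_common), len(h_up_union)),
        ("human_timepoint_overlap_down", len(h_down_common), len(h_down_union)),
    ]
    steps = [OverlapStep(n, num, den, percentage(num, den, precision)) for n, num, den in raw]
    return OverlapSummary(steps=steps)


def read_ortholog_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (mouse id/symbol -> human symbol); header optional."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            if lineno == 1 and fields[0].lower() in ("mouse", "mouse_gene", "gene_id"):
                continue
            if fields[0] in out:
                raise ValueError(f"{path}:{lineno}: duplicate mouse gene {fields[0]!r}")
            out[fields[0]] = fields[1]
    return out


def write_ortholog_map(ortholog_map: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mouse_gene\thuman_gene\n")
        for m, h in ortholog_map.items():
            fh.write(f"{m}\t{h}\n")
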