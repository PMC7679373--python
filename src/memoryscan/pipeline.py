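"""End-to-end pipeline: normalize -> differential expression -> peak
annotation -> memory classification -> report.

Every stage writes its intermediates as TSV/JSON under the output
directory, and a run log records thresholds and in/out counts per filter so
the Venn numbers are auditable from the log alone.  A failing stage raises
:class:`PipelineError` carrying the stage name and leaves a
``FAILED_<stage>`` marker next to any partial outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .diffexpr import call_differential, deg_sets, write_results
from .expression import (
    CountMatrix,
    GeneAnnotation,
    pool_replicates,
    read_annotation,
    read_counts,
    rpkm,
)
from .memory import (
    DegSetCollection,
    MemoryCallSet,
    OverlapSummary,
    classify_memory,
    overlap_summary,
    read_ortholog_map,
)
from .peaks import assign_peaks_to_tss, read_bed, tss_profile

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline", "config_for_dataset"]


class PipelineError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Input paths, thresholds and flags for one pipeline run.

    Thresholds default to the analysis' fixed cut-offs: twofold change,
    alpha 0.05, 3-RPKM presence floor, 5-kb TSS window.  ``contrasts``
    names each treated/control condition pair; ``*_groups`` map a condition
    to its replicate sample columns (identity when omitted).
    """

    annotation: str = ""
    human_annotation: str = ""
    counts_mouse: str = ""
    counts_human: str = ""
    library_sizes: str | None = None
    peaks_short_term: str = ""
    peaks_chronic: str = ""
    ortholog_map: str = ""
    short_term_contrasts: dict[str, list[str]] = field(default_factory=dict)  # label -> [treated, control]
    chronic_contrast: list[str] = field(default_factory=list)
    human_contrasts: dict[str, list[str]] = field(default_factory=dict)
    mouse_groups: dict[str, list[str]] = field(default_factory=dict)
    human_groups: dict[str, list[str]] = field(default_factory=dict)
    fold_threshold: float = 2.0
    alpha: float = 0.05
    presence_floor: float = 3.0
    window: int = 5000
    pseudocount: float = 0.1
    use_adjusted: bool = True
    short_term_mode: str = "union"
    unique_profile: bool = True

    def __post_init__(self) -> None:
        for name, v in (("fold_threshold", self.fold_threshold), ("alpha", self.alpha),
                        ("presence_floor", self.presence_floor)):
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.window < 0:
            raise ValueError(f"window must be >= 0, got {self.window}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class PipelineResult:
    outdir: Path
    deg: DegSetCollection
    callset: MemoryCallSet
    summary: OverlapSummary


def _load_library_sizes(path: str | None) -> dict[str, float] | None:
    if not path:
        return None
    with open(path) as fh:
        return {k: float(v) for k, v in json.load(fh).items()}


def _pool(counts: CountMatrix, groups: Mapping[str, list[str]]) -> CountMatrix:
    if not groups:
        return counts
    return pool_replicates(counts, groups)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Run every stage on the configured inputs; write artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"memoryscan version: {__version__}",
        f"fold_threshold: {config.fold_threshold}",
        f"alpha: {config.alpha}",
        f"presence_floor: {config.presence_floor}",
        f"window: {config.window}",
        f"use_adjusted: {config.use_adjusted}",
        f"short_term_mode: {config.short_term_mode}",
    ]
    stage = "load"
    try:
        annotation = read_annotation(config.annotation)
        human_annotation = read_annotation(config.human_annotation)
        libs = _load_library_sizes(config.library_sizes)
        mouse_counts = read_counts(config.counts_mouse, annotation, library_sizes=libs)
        human_counts = read_counts(config.counts_human, human_annotation, library_sizes=libs)
        ortholog_map = read_ortholog_map(config.ortholog_map)
        mouse_counts = _pool(mouse_counts, config.mouse_groups)
        human_counts = _pool(human_counts, config.human_groups)
        log_lines += [
            f"load: {len(annotation)} mouse genes, {len(human_annotation)} human genes",
            f"load: mouse samples {mouse_counts.sample_ids}",
            f"load: human samples {human_counts.sample_ids}",
        ]

        stage = "normalize"
        mouse_expr = rpkm(mouse_counts, annotation, floor=config.presence_floor)
        human_expr = rpkm(human_counts, human_annotation, floor=config.presence_floor)
        mouse_expr.rpkm.rename_axis("gene_id").to_csv(outdir / "rpkm_mouse.tsv", sep="\t")
        human_expr.rpkm.rename_axis("gene_id").to_csv(outdir / "rpkm_human.tsv", sep="\t")
        log_lines.append(
            f"normalize: presence floor {config.presence_floor} RPKM; "
            f"mouse genes present in >=1 sample: {int(mouse_expr.present.any(axis=1).sum())}"
        )

        stage = "de"
        de_kwargs = dict(
            fold_threshold=config.fold_threshold,
            alpha=config.alpha,
            use_adjusted=config.use_adjusted,
            pseudocount=config.pseudocount,
        )
        st_up: dict[str, set] = {}
        st_down: dict[str, set] = {}
        for label, (treated, control) in sorted(config.short_term_contrasts.items()):
            res = call_differential(mouse_expr, mouse_counts, treated, control, **de_kwargs)
            write_results(res, outdir / f"de_short_term_{label}.tsv")
            st_up[label], st_down[label] = deg_sets(res)
            log_lines.append(
                f"de: short_term {label}: {len(res)} tested, {len(st_up[label])} up, {len(st_down[label])} down"
            )
        treated, control = config.chronic_contrast
        res = call_differential(mouse_expr, mouse_counts, treated, control, **de_kwargs)
        write_results(res, outdir / "de_chronic.tsv")
        chronic_up, chronic_down = deg_sets(res)
        log_lines.append(f"de: chronic: {len(res)} tested, {len(chronic_up)} up, {len(chronic_down)} down")
        h_up: dict[str, set] = {}
        h_down: dict[str, set] = {}
        for label, (treated, control) in sorted(config.human_contrasts.items()):
            res = call_differential(human_expr, human_counts, treated, control, **de_kwargs)
            write_results(res, outdir / f"de_human_{label}.tsv")
            h_up[label], h_down[label] = deg_sets(res)
            log_lines.append(
                f"de: human {label}: {len(res)} tested, {len(h_up[label])} up, {len(h_down[label])} down"
            )
        deg = DegSetCollection(
            short_term_up=st_up, short_term_down=st_down,
            chronic_up=chronic_up, chronic_down=chronic_down,
            human_up=h_up, human_down=h_down,
        )

        stage = "annotate_peaks"
        annotated: dict[str, set] = {}
        for label, path in (("short_term", config.peaks_short_term), ("chronic", config.peaks_chronic)):
            peak_list = read_bed(path)
            assignment = assign_peaks_to_tss(peak_list, annotation, window=config.window)
            profile = tss_profile(assignment, unique=config.unique_profile)
            profile.to_csv(outdir / f"tss_profile_{label}.tsv", sep="\t", index=False)
            annotated[label] = assignment.annotated_genes
            _write_gene_list(annotated[label], outdir / f"annotated_genes_{label}.txt")
            log_lines.append(
                f"annotate_peaks: {label}: {len(peak_list)} peaks, "
                f"{len(assignment.pairs)} peak-gene pairs, {len(annotated[label])} genes annotated"
            )

        stage = "classify"
        callset = classify_memory(
            deg, annotated["short_term"], annotated["chronic"], ortholog_map,
            short_term_mode=config.short_term_mode,
        )
        for name, genes in (("mSAG", callset.msag), ("mSRG", callset.msrg),
                            ("epi_mSAG", callset.epi_msag), ("epi_mSRG", callset.epi_msrg),
                            ("hSAG", callset.hsag), ("hSRG", callset.hsrg)):
            _write_gene_list(genes, outdir / f"genes_{name}.txt")
            log_lines.append(f"classify: {name}: {len(genes)} genes")

        stage = "report"
        summary = overlap_summary(callset, deg)
        summary.to_json(outdir / "overlap_summary.json")
        summary.to_frame().to_csv(outdir / "overlap_summary.tsv", sep="\t", index=False)
        for s in summary.steps:
            log_lines.append(f"report: {s.name}: {s.numerator} of {s.denominator} ({s.percentage}%)")
        (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    except PipelineError:
        raise
    except Exception as exc:
        (outdir / f"FAILED_{stage}").write_text(f"{type(exc).__name__}: {exc}\n")
        (outdir / "run_log.txt").write_text("\n".join(log_lines) + f"\nFAILED at stage {stage}: {exc}\n")
        raise PipelineError(stage, str(exc)) from exc
    return PipelineResult(outdir=outdir, deg=deg, callset=callset, summary=summary)


def _write_gene_list(genes: set[str], path: Path) -> None:
    path.write_text("".join(f"{g}\n" for g in sorted(genes)))


def config_for_dataset(paths: Mapping[str, Path], dataset) -> PipelineConfig:
    """Pipeline config wired to the file layout of :meth:`SyntheticDataset.write`."""
    scenario = dataset.scenario
    return PipelineConfig(
        annotation=str(paths["annotation"]),
        human_annotation=str(paths["human_annotation"]),
        counts_mouse=str(paths["counts_mouse"]),
        counts_human=str(paths["counts_human"]),
        library_sizes=str(paths["library_sizes"]),
        peaks_short_term=str(paths["peaks_short_term"]),
        peaks_chronic=str(paths["peaks_chronic"]),
        ortholog_map=str(paths["ortholog_map"]),
        short_term_contrasts={tp: [f"tnf_{tp}", "mouse_ctrl"] for tp in scenario.short_term_timepoints},
        chronic_contrast=["chronic", "chronic_ctrl"],
        human_contrasts={tp: [f"human_tnf_{tp}", "human_ctrl"] for tp in scenario.human_timepoints},
        mouse_groups=dataset.mouse_groups if scenario.replicates > 1 else {},
        human_groups=dataset.human_groups if scenario.replicates > 1 else {},
    )
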