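"""Synthetic study generator with planted inflammatory-memory classes.

Emulates the study design the pipeline analyzes: mouse fibroblast-like
synoviocytes under short-term TNF (16/24/48 h) and chronic TNF exposure,
human RA-FLS under TNF at 8/24 h, chromatin-accessibility peak sets for the
short-term and chronic conditions, and a 1:1 mouse-to-human ortholog map.
Each gene is planted in one class:

  sustained_activated   up in every short-term timepoint AND chronic
  transient_activated   up in short-term only
  sustained_repressed   down in short-term AND chronic
  transient_repressed   down in short-term only
  chronic_only          up in chronic only
  null                  unchanged everywhere

Counts are Poisson (or negative-binomial when ``dispersion > 0``) around
expected values set by a per-gene baseline expression level (drawn on the
RPKM scale), the gene's exon length and the library size.  Accessibility
peaks land near a gene's TSS in both, one, or neither condition according
to class-dependent concordance probabilities; human orthologs recapitulate
the mouse direction at both human time points with class-dependent
conservation probabilities.  Everything is reproducible byte-for-byte from
the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .expression import CountMatrix, GeneAnnotation, GeneModel, write_annotation, write_counts
from .memory import write_ortholog_map
from .peaks import PeakInterval, write_bed

__all__ = [
    "GENE_CLASSES",
    "MemoryScenario",
    "GroundTruth",
    "SyntheticDataset",
    "generate_annotation",
    "generate_truth",
    "generate_counts",
    "generate_peaks",
    "simulate",
]

GENE_CLASSES = (
    "sustained_activated",
    "transient_activated",
    "sustained_repressed",
    "transient_repressed",
    "chronic_only",
    "null",
)

_UP_CLASSES = {"sustained_activated", "transient_activated", "chronic_only"}
_DOWN_CLASSES = {"sustained_repressed", "transient_repressed"}

# Epigenomic-concordance fractions observed in the study this design
# emulates: 72.3% of sustained activated and 52.3% of sustained repressed
# genes carried accessible chromatin near the TSS in both conditions.
_DEFAULT_EPI = {
    "sustained_activated": 0.723,
    "transient_activated": 0.4,
    "sustained_repressed": 0.523,
    "transient_repressed": 0.4,
    "chronic_only": 0.4,
    "null": 0.2,
}

# Human-conservation fractions: 52 of 141 epi-concordant sustained
# activated genes and 7 of 34 sustained repressed genes were confirmed in
# human RA-FLS.
_DEFAULT_CONSERVATION = {
    "sustained_activated": 52 / 141,
    "transient_activated": 0.3,
    "sustained_repressed": 7 / 34,
    "transient_repressed": 0.3,
    "chronic_only": 0.3,
    "null": 0.0,
}

_DEFAULT_FRACTIONS = {
    "sustained_activated": 0.05,
    "transient_activated": 0.08,
    "sustained_repressed": 0.03,
    "transient_repressed": 0.05,
    "chronic_only": 0.02,
    "null": 0.77,
}


@dataclass
class MemoryScenario:
    """Parameters of one synthetic study.

    Defaults describe a desk-scale version of the emulated design: 2000
    genes, fourfold effects, 1e7 mapped reads per library, Poisson counts,
    single libraries per condition (the differential test is replicate-free)
    and the concordance/conservation rates given above.
    """

    n_genes: int = 2000
    class_fractions: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_FRACTIONS))
    fold_change_active: float = 4.0
    library_size_per_sample: float = 1e7
    gene_length_range: tuple[int, int] = (500, 5000)
    dispersion: float = 0.0
    epi_concordance: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_EPI))
    human_conservation: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_CONSERVATION))
    short_term_timepoints: tuple[str, ...] = ("16h", "24h", "48h")
    human_timepoints: tuple[str, ...] = ("8h", "24h")
    replicates: int = 1
    baseline_rpkm_range: tuple[float, float] = (3.0, 500.0)
    background_peak_rate: float = 0.2
    tss_spacing: int = 20000
    n_chromosomes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        missing = set(GENE_CLASSES) - set(self.class_fractions)
        if missing:
            raise ValueError(f"class_fractions missing classes: {sorted(missing)}")
        if any(v < 0 for v in self.class_fractions.values()):
            raise ValueError("class fractions must be non-negative")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        if self.fold_change_active < 1:
            raise ValueError(f"fold_change_active must be >= 1, got {self.fold_change_active}")
        if self.dispersion < 0:
            raise ValueError(f"dispersion must be >= 0, got {self.dispersion}")
        lo, hi = self.gene_length_range
        if lo > hi or lo < 1:
            raise ValueError(f"invalid gene_length_range ({lo}, {hi}): need 1 <= min <= max")
        for name, probs in (("epi_concordance", self.epi_concordance),
                            ("human_conservation", self.human_conservation)):
            for cls in GENE_CLASSES:
                p = probs.get(cls)
                if p is None or not (0.0 <= p <= 1.0):
                    raise ValueError(f"{name}[{cls!r}] must be a probability in [0, 1], got {p}")
        if not self.short_term_timepoints:
            raise ValueError("at least one short-term timepoint is required")
        if len(self.human_timepoints) != 2:
            raise ValueError("exactly two human timepoints are required")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.library_size_per_sample <= 0:
            raise ValueError("library_size_per_sample must be positive")

    def _rng(self, stream: int) -> np.random.Generator:
        # independent deterministic streams per generation stage
        children = np.random.SeedSequence(self.seed).spawn(4)
        return np.random.default_rng(children[stream])

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["gene_length_range"] = list(self.gene_length_range)
        data["baseline_rpkm_range"] = list(self.baseline_rpkm_range)
        data["short_term_timepoints"] = list(self.short_term_timepoints)
        data["human_timepoints"] = list(self.human_timepoints)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MemoryScenario":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("gene_length_range", "baseline_rpkm_range", "short_term_timepoints", "human_timepoints"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GroundTruth:
    """Planted per-gene labels: class, accessibility flags, conservation flag."""

    table: pd.DataFrame  # index gene_id; columns: gene_class, epi_short, epi_chronic, epi_concordant, conserved

    def gene_ids(self, gene_class: str | None = None) -> list[str]:
        if gene_class is None:
            return list(self.table.index)
        return list(self.table.index[self.table["gene_class"] == gene_class])

    def write(self, path: str | Path) -> None:
        self.table.rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruth":
        # keep_default_na: the class label "null" must not parse as missing
        df = pd.read_csv(path, sep="\t", index_col="gene_id", keep_default_na=False)
        for col in ("epi_short", "epi_chronic", "epi_concordant", "conserved"):
            df[col] = df[col].astype(bool)
        return cls(table=df)


def _gene_names(n: int) -> tuple[list[str], list[str]]:
    width = max(4, len(str(n)))
    mouse = [f"Gene{i:0{width}d}" for i in range(1, n + 1)]
    human = [m.upper() for m in mouse]
    return mouse, human


def generate_annotation(scenario: MemoryScenario) -> GeneAnnotation:
    """Synthetic gene models on a few chromosomes with well-spaced TSSs.

    Consecutive TSSs on a chromosome are at least ``tss_spacing`` apart
    (20 kb by default) so the 5-kb peak windows of neighbouring genes do
    not overlap unless a scenario deliberately crowds them.
    """
    rng = scenario._rng(0)
    mouse_ids, _ = _gene_names(scenario.n_genes)
    lo, hi = scenario.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=scenario.n_genes)
    strands = rng.choice(["+", "-"], size=scenario.n_genes)
    chroms = [f"chr{(i % scenario.n_chromosomes) + 1}" for i in range(scenario.n_genes)]
    # cumulative per-chromosome TSS layout with jitter on top of the minimum spacing
    next_tss = {f"chr{c + 1}": 100_000 for c in range(scenario.n_chromosomes)}
    genes = []
    for i, gid in enumerate(mouse_ids):
        chrom = chroms[i]
        tss = int(next_tss[chrom])
        next_tss[chrom] = tss + scenario.tss_spacing + int(rng.integers(0, scenario.tss_spacing // 2 + 1))
        genes.append(
            GeneModel(gene_id=gid, symbol=gid, chrom=chrom, strand=str(strands[i]),
                      tss=tss, exon_length=int(lengths[i]))
        )
    return GeneAnnotation(genes)


def _class_counts(scenario: MemoryScenario) -> dict[str, int]:
    """Largest-remainder apportionment so realized class counts match the
    requested fractions to within one gene."""
    n = scenario.n_genes
    exact = {c: scenario.class_fractions[c] * n for c in GENE_CLASSES}
    counts = {c: int(np.floor(v)) for c, v in exact.items()}
    remainder = n - sum(counts.values())
    by_frac = sorted(GENE_CLASSES, key=lambda c: (-(exact[c] - counts[c]), c))
    for c in by_frac[:remainder]:
        counts[c] += 1
    return counts


def generate_truth(scenario: MemoryScenario, annotation: GeneAnnotation) -> GroundTruth:
    """Assign every gene a class and its planted accessibility/conservation flags.

    Epigenomic flags: with probability ``epi_concordance[class]`` a gene is
    accessible near its TSS in both conditions; otherwise the short-only,
    chronic-only and neither outcomes are equally likely.
    """
    rng = scenario._rng(1)
    gene_ids = annotation.gene_ids
    counts = _class_counts(scenario)
    labels = np.repeat([c for c in GENE_CLASSES], [counts[c] for c in GENE_CLASSES])
    rng.shuffle(labels)
    probs_epi = np.array([scenario.epi_concordance[c] for c in labels])
    concordant = rng.random(len(labels)) < probs_epi
    # non-concordant genes: short-only / chronic-only / neither, equally likely
    split = rng.integers(0, 3, size=len(labels))
    epi_short = concordant | (~concordant & (split == 0))
    epi_chronic = concordant | (~concordant & (split == 1))
    probs_cons = np.array([scenario.human_conservation[c] for c in labels])
    conserved = rng.random(len(labels)) < probs_cons
    table = pd.DataFrame(
        {
            "gene_class": labels,
            "epi_short": epi_short,
            "epi_chronic": epi_chronic,
            "epi_concordant": concordant,
            "conserved": conserved,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return GroundTruth(table=table)


def _sample_names(condition: str, replicates: int) -> list[str]:
    if replicates == 1:
        return [condition]
    return [f"{condition}_r{i}" for i in range(1, replicates + 1)]


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def generate_counts(
    scenario: MemoryScenario,
    annotation: GeneAnnotation,
    truth: GroundTruth,
) -> tuple[CountMatrix, CountMatrix]:
    """Draw mouse and human count matrices around class-determined expected values.

    The expected control count of gene g is rpkm_g * length_g * N / 1e9 with
    a baseline rpkm_g drawn log-uniformly; affected condition/class pairs
    multiply (activated) or divide (repressed) that expectation by
    ``fold_change_active``.  All samples share the configured library size.
    Returns ``(mouse_counts, human_counts)``.
    """
    missing = [g for g in annotation.gene_ids if g not in truth.table.index]
    if missing:
        raise ValueError(f"ground truth missing labels for genes: {missing[:10]}")
    rng = scenario._rng(2)
    gene_ids = annotation.gene_ids
    labels = truth.table.loc[gene_ids, "gene_class"].to_numpy()
    conserved = truth.table.loc[gene_ids, "conserved"].to_numpy()
    lengths = annotation.exon_lengths().loc[gene_ids].to_numpy(dtype=float)
    lib = float(scenario.library_size_per_sample)
    fold = scenario.fold_change_active

    lo, hi = scenario.baseline_rpkm_range
    base_rpkm = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(gene_ids)))
    base_mu = base_rpkm * lengths * lib / 1e9

    up = np.isin(labels, list(_UP_CLASSES))
    down = np.isin(labels, list(_DOWN_CLASSES))
    short_affected = np.isin(labels, ["sustained_activated", "transient_activated",
                                      "sustained_repressed", "transient_repressed"])
    chronic_affected = np.isin(labels, ["sustained_activated", "sustained_repressed", "chronic_only"])

    def effect(mask_affected: np.ndarray) -> np.ndarray:
        f = np.ones(len(gene_ids))
        f[mask_affected & up] = fold
        f[mask_affected & down] = 1.0 / fold
        return f

    mouse_conditions: dict[str, np.ndarray] = {"mouse_ctrl": np.ones(len(gene_ids))}
    for tp in scenario.short_term_timepoints:
        mouse_conditions[f"tnf_{tp}"] = effect(short_affected)
    mouse_conditions["chronic_ctrl"] = np.ones(len(gene_ids))
    mouse_conditions["chronic"] = effect(chronic_affected)

    mouse_cols = {}
    for condition, f in mouse_conditions.items():
        for name in _sample_names(condition, scenario.replicates):
            mouse_cols[name] = _draw_counts(rng, base_mu * f, scenario.dispersion)
    mouse = CountMatrix(
        counts=pd.DataFrame(mouse_cols, index=pd.Index(gene_ids, name="gene_id")),
        library_sizes=pd.Series({s: lib for s in mouse_cols}),
    )

    # human: conserved orthologs carry the mouse direction at both timepoints
    human_effect = np.ones(len(gene_ids))
    human_effect[conserved & up] = fold
    human_effect[conserved & down] = 1.0 / fold
    human_conditions: dict[str, np.ndarray] = {"human_ctrl": np.ones(len(gene_ids))}
    for tp in scenario.human_timepoints:
        human_conditions[f"human_tnf_{tp}"] = human_effect
    _, human_ids = _gene_names(scenario.n_genes)
    human_cols = {}
    for condition, f in human_conditions.items():
        for name in _sample_names(condition, scenario.replicates):
            human_cols[name] = _draw_counts(rng, base_mu * f, scenario.dispersion)
    human = CountMatrix(
        counts=pd.DataFrame(human_cols, index=pd.Index(human_ids, name="gene_id")),
        library_sizes=pd.Series({s: lib for s in human_cols}),
    )
    return mouse, human


def generate_peaks(
    scenario: MemoryScenario,
    annotation: GeneAnnotation,
    truth: GroundTruth,
) -> tuple[list[PeakInterval], list[PeakInterval]]:
    """Place accessibility peaks according to the planted flags.

    A flagged gene receives one peak of width 200-1000 bp fully inside its
    [TSS-5kb, TSS+5kb) window in the corresponding set(s).  Background
    peaks (``background_peak_rate`` x n_genes per set) are placed at least
    50 kb beyond the last TSS of each chromosome.
    """
    rng = scenario._rng(3)
    window = 5000
    short: list[PeakInterval] = []
    chronic: list[PeakInterval] = []
    genes = list(annotation)
    for g in genes:
        flags = truth.table.loc[g.gene_id]
        for flag, dest, tag in ((flags["epi_short"], short, "st"), (flags["epi_chronic"], chronic, "ch")):
            if not flag:
                continue
            width = int(rng.integers(200, 1001))
            lo = max(0, g.tss - window)
            hi = max(lo + 1, g.tss + window - width)
            start = int(rng.integers(lo, hi))
            dest.append(PeakInterval(chrom=g.chrom, start=start, end=start + width,
                                     name=f"{tag}_{g.gene_id}"))
    # background peaks well clear of every TSS window
    chrom_max_tss: dict[str, int] = {}
    for g in genes:
        chrom_max_tss[g.chrom] = max(chrom_max_tss.get(g.chrom, 0), g.tss)
    chroms = sorted(chrom_max_tss)
    n_bg = int(round(scenario.background_peak_rate * scenario.n_genes))
    for dest, tag in ((short, "st"), (chronic, "ch")):
        for j in range(n_bg):
            chrom = chroms[j % len(chroms)]
            width = int(rng.integers(200, 1001))
            offset = 60_000 + (j // len(chroms)) * 3000 + int(rng.integers(0, 1000))
            start = chrom_max_tss[chrom] + offset
            dest.append(PeakInterval(chrom=chrom, start=start, end=start + width,
                                     name=f"{tag}_bg{j:05d}"))
    return short, chronic


@dataclass
class SyntheticDataset:
    """One complete generated study plus its ground truth."""

    scenario: MemoryScenario
    annotation: GeneAnnotation
    human_annotation: GeneAnnotation
    truth: GroundTruth
    counts_mouse: CountMatrix
    counts_human: CountMatrix
    peaks_short_term: list[PeakInterval]
    peaks_chronic: list[PeakInterval]
    ortholog_map: dict[str, str]

    @property
    def mouse_groups(self) -> dict[str, list[str]]:
        """condition -> replicate sample columns, mouse matrix."""
        conditions = (["mouse_ctrl"] + [f"tnf_{tp}" for tp in self.scenario.short_term_timepoints]
                      + ["chronic_ctrl", "chronic"])
        return {c: _sample_names(c, self.scenario.replicates) for c in conditions}

    @property
    def human_groups(self) -> dict[str, list[str]]:
        conditions = ["human_ctrl"] + [f"human_tnf_{tp}" for tp in self.scenario.human_timepoints]
        return {c: _sample_names(c, self.scenario.replicates) for c in conditions}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every artifact as plain text; returns the path of each."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotation": outdir / "annotation.tsv",
            "human_annotation": outdir / "human_annotation.tsv",
            "counts_mouse": outdir / "counts_mouse.tsv",
            "counts_human": outdir / "counts_human.tsv",
            "library_sizes": outdir / "library_sizes.json",
            "peaks_short_term": outdir / "peaks_short_term.bed",
            "peaks_chronic": outdir / "peaks_chronic.bed",
            "ortholog_map": outdir / "ortholog_map.tsv",
            "truth": outdir / "truth.tsv",
            "scenario": outdir / "scenario.yaml",
        }
        write_annotation(self.annotation, paths["annotation"])
        write_annotation(self.human_annotation, paths["human_annotation"])
        write_counts(self.counts_mouse, paths["counts_mouse"])
        write_counts(self.counts_human, paths["counts_human"])
        libs = {**{k: float(v) for k, v in self.counts_mouse.library_sizes.items()},
                **{k: float(v) for k, v in self.counts_human.library_sizes.items()}}
        import json
        paths["library_sizes"].write_text(json.dumps(libs, indent=2, sort_keys=True) + "\n")
        write_bed(self.peaks_short_term, paths["peaks_short_term"])
        write_bed(self.peaks_chronic, paths["peaks_chronic"])
        write_ortholog_map(self.ortholog_map, paths["ortholog_map"])
        self.truth.write(paths["truth"])
        self.scenario.to_yaml(paths["scenario"])
        return paths


def simulate(scenario: MemoryScenario) -> SyntheticDataset:
    """Generate a full study from one scenario (annotation, truth, counts, peaks, ortholog map)."""
    annotation = generate_annotation(scenario)
    truth = generate_truth(scenario, annotation)
    counts_mouse, counts_human = generate_counts(scenario, annotation, truth)
    peaks_short, peaks_chronic = generate_peaks(scenario, annotation, truth)
    mouse_ids, human_ids = _gene_names(scenario.n_genes)
    ortholog_map = dict(zip(mouse_ids, human_ids))
    human_annotation = GeneAnnotation(
        GeneModel(gene_id=h, symbol=h, chrom=g.chrom, strand=g.strand, tss=g.tss,
                  exon_length=g.exon_length)
        for h, g in zip(human_ids, annotation)
    )
    return SyntheticDataset(
        scenario=scenario,
        annotation=annotation,
        human_annotation=human_annotation,
        truth=truth,
        counts_mouse=counts_mouse,
        counts_human=counts_human,
        peaks_short_term=peaks_short,
        peaks_chronic=peaks_chronic,
        ortholog_map=ortholog_map,
    )
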