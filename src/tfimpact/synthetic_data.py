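"""Synthetic regulatory-genomics data with planted structure.

Generates a gene annotation, per-TF peak sets (one TF with peaks planted
near its target genes' TSS), a two-group log-scale expression matrix with
planted up/down genes, and GMT categories with one planted category —
everything a full pipeline run needs, fully determined by a seed.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass

import numpy as np

from tfimpact.io_formats import (
    ExpressionMatrix,
    FunctionalCategory,
    GeneModel,
    GenomeAnnotation,
    Peak,
    PeakSet,
    write_annotation_tsv,
    write_expression_matrix,
    write_gmt,
    write_narrowpeak,
)

_PEAK_HALF_WIDTH = 100  # simulated peaks are 200 bp wide

# independent, seed-derived RNG streams per generator
_STREAM_ANNOTATION = 0
_STREAM_TARGETS = 1
_STREAM_PEAKS = 2
_STREAM_EXPRESSION = 3
_STREAM_CATEGORIES = 4


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 1000
    chrom_length: int = 50_000_000
    min_spacing: int = 25_000
    n_tfs: int = 8
    planted_tf: str = "TF01"
    n_target_genes: int = 200
    proximity_sd: float = 300.0
    background_peaks_per_tf: int = 2000
    q_value_range: tuple[float, float] = (1e-12, 0.5)
    planted_q: float | None = None
    n_control: int = 6
    n_treatment: int = 9
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    effect_size: float = 1.5
    frac_targets_down: float = 0.7
    noise_sd: float = 0.5
    n_categories: int = 20
    planted_category_overlap: float = 0.8
    category_size_range: tuple[int, int] = (10, 200)

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "chrom_length", "min_spacing", "n_tfs", "n_target_genes",
            "n_control", "n_treatment", "n_categories",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.background_peaks_per_tf < 0:
            raise ValueError("background_peaks_per_tf must be >= 0")
        if not (0.0 <= self.frac_targets_down <= 1.0):
            raise ValueError(f"frac_targets_down must be in [0,1], got {self.frac_targets_down}")
        if not (0.0 <= self.planted_category_overlap <= 1.0):
            raise ValueError("planted_category_overlap must be in [0,1]")
        if self.n_target_genes > self.n_genes:
            raise ValueError("n_target_genes exceeds n_genes")
        lo, hi = self.q_value_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"q_value_range must satisfy 0 < lo <= hi <= 1, got {self.q_value_range}")

    @property
    def tf_names(self) -> list[str]:
        names = [f"TF{i + 1:02d}" for i in range(self.n_tfs)]
        if self.planted_tf not in names:
            names[0] = self.planted_tf
        return names


@dataclass
class PlantedTruth:
    """Ground-truth planted assignments, written to truth.json."""

    planted_tf: str
    target_genes: list[str]
    down_targets: list[str]
    up_genes: list[str]
    planted_category_id: str


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def simulate_annotation(cfg: SimulationConfig) -> GenomeAnnotation:
    """Place n_genes TSS uniformly with >= min_spacing bp between neighbours."""
    span = cfg.chrom_length - (cfg.n_genes - 1) * cfg.min_spacing
    if span <= cfg.n_genes:
        raise ValueError(
            f"infeasible spacing: {cfg.n_genes} genes x {cfg.min_spacing} bp "
            f"do not fit in {cfg.chrom_length} bp"
        )
    rng = _rng(cfg, _STREAM_ANNOTATION)
    base = np.sort(rng.integers(0, span, size=cfg.n_genes))
    tss = base + np.arange(cfg.n_genes) * cfg.min_spacing
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    genes = [
        GeneModel(gene_id=f"g{i:04d}", chrom="chrS", strand=str(strands[i]), tss=int(tss[i]))
        for i in range(cfg.n_genes)
    ]
    return GenomeAnnotation(genes=genes, chrom_sizes={"chrS": cfg.chrom_length})


def planted_assignment(cfg: SimulationConfig, ann: GenomeAnnotation) -> PlantedTruth:
    """Choose planted target genes and the planted up/down DE gene sets.

    Down genes are a fraction of the planted TF's targets; the planted up
    set is an equally sized draw from the non-target genes, so recovery of
    the planted TF shows up in the down direction.
    """
    rng = _rng(cfg, _STREAM_TARGETS)
    ids = np.array(ann.gene_ids())
    targets = rng.choice(ids, size=cfg.n_target_genes, replace=False)
    n_down = int(round(cfg.frac_targets_down * cfg.n_target_genes))
    down = targets[:n_down]
    non_targets = np.array(sorted(set(ids) - set(targets)))
    n_up = min(n_down, len(non_targets)) if n_down > 0 else 0
    up = rng.choice(non_targets, size=n_up, replace=False) if n_up else np.array([], dtype=ids.dtype)
    return PlantedTruth(
        planted_tf=cfg.planted_tf,
        target_genes=[str(g) for g in targets],
        down_targets=[str(g) for g in down],
        up_genes=[str(g) for g in up],
        planted_category_id="cat_planted",
    )


def _draw_q(rng: np.random.Generator, size: int, cfg: SimulationConfig) -> np.ndarray:
    lo, hi = cfg.q_value_range
    return 10.0 ** rng.uniform(math.log10(lo), math.log10(hi), size=size)


def _make_peak(cfg: SimulationConfig, anchor: int, q: float, with_summit: bool) -> Peak:
    anchor = int(np.clip(anchor, _PEAK_HALF_WIDTH, cfg.chrom_length - _PEAK_HALF_WIDTH - 1))
    return Peak(
        chrom="chrS",
        start=anchor - _PEAK_HALF_WIDTH,
        end=anchor + _PEAK_HALF_WIDTH,
        summit=anchor if with_summit else None,
        score=1000.0,
        q_value=float(q),
    )


def simulate_peaks(cfg: SimulationConfig, ann: GenomeAnnotation) -> list[PeakSet]:
    """Two replicates per TF.

    The planted TF gets one peak per target gene with anchor ~
    Normal(tss, proximity_sd) (redrawn independently per replicate) plus
    uniform background peaks; all other TFs get background peaks only.
    Peak q-values are log-uniform in q_value_range unless ``planted_q``
    pins the planted peaks' q.
    """
    rng = _rng(cfg, _STREAM_PEAKS)
    truth = planted_assignment(cfg, ann)
    tss_by_id = {g.gene_id: g.tss for g in ann.genes}
    out: list[PeakSet] = []
    for tf in cfg.tf_names:
        for rep in ("rep1", "rep2"):
            peaks: list[Peak] = []
            if tf == cfg.planted_tf:
                for gid in truth.target_genes:
                    anchor = int(round(rng.normal(tss_by_id[gid], cfg.proximity_sd)))
                    q = cfg.planted_q if cfg.planted_q is not None else float(_draw_q(rng, 1, cfg)[0])
                    peaks.append(_make_peak(cfg, anchor, q, with_summit=True))
            n_bg = cfg.background_peaks_per_tf
            if n_bg:
                anchors = rng.integers(
                    _PEAK_HALF_WIDTH, cfg.chrom_length - _PEAK_HALF_WIDTH, size=n_bg
                )
                qs = _draw_q(rng, n_bg, cfg)
                peaks.extend(
                    _make_peak(cfg, int(a), float(q), with_summit=True)
                    for a, q in zip(anchors, qs)
                )
            out.append(PeakSet(tf_name=tf, replicate=rep, peaks=peaks))
    return out


def simulate_expression(cfg: SimulationConfig, ann: GenomeAnnotation) -> ExpressionMatrix:
    """Two-group log-scale matrix with planted treatment effects."""
    rng = _rng(cfg, _STREAM_EXPRESSION)
    truth = planted_assignment(cfg, ann)
    ids = ann.gene_ids()
    n_samples = cfg.n_control + cfg.n_treatment
    sample_ids = [f"ctrl{i + 1}" for i in range(cfg.n_control)] + [
        f"trt{i + 1}" for i in range(cfg.n_treatment)
    ]
    labels = {s: ("control" if s.startswith("ctrl") else "treatment") for s in sample_ids}

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(ids))
    effect = np.zeros(len(ids))
    idx = {g: i for i, g in enumerate(ids)}
    for g in truth.down_targets:
        effect[idx[g]] = -cfg.effect_size
    for g in truth.up_genes:
        effect[idx[g]] = +cfg.effect_size

    values = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(len(ids), n_samples))
    treat_cols = np.arange(cfg.n_control, n_samples)
    values[:, treat_cols] += effect[:, None]
    return ExpressionMatrix(gene_ids=list(ids), sample_ids=sample_ids, values=values, group_labels=labels)


def simulate_categories(cfg: SimulationConfig, ann: GenomeAnnotation) -> list[FunctionalCategory]:
    """GMT categories: one planted category seeded with planted-down targets.

    The planted category takes ``planted_category_overlap`` of the
    planted-down targets plus random filler genes; the remaining
    n_categories - 1 categories are random draws with sizes in
    category_size_range.
    """
    rng = _rng(cfg, _STREAM_CATEGORIES)
    truth = planted_assignment(cfg, ann)
    ids = np.array(ann.gene_ids())
    lo, hi = cfg.category_size_range

    cats: list[FunctionalCategory] = []
    n_core = int(round(cfg.planted_category_overlap * len(truth.down_targets)))
    core = list(rng.choice(truth.down_targets, size=n_core, replace=False)) if n_core else []
    pool = np.array(sorted(set(ids) - set(truth.target_genes)))
    n_fill = max(lo - n_core, max(5, n_core // 4))
    fill = list(rng.choice(pool, size=min(n_fill, len(pool)), replace=False))
    cats.append(
        FunctionalCategory(
            category_id=truth.planted_category_id,
            name="planted category",
            genes=frozenset(str(g) for g in core + fill),
        )
    )
    for i in range(cfg.n_categories - 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(ids, size=min(size, len(ids)), replace=False)
        cats.append(
            FunctionalCategory(
                category_id=f"cat{i + 1:03d}",
                name=f"random category {i + 1}",
                genes=frozenset(str(g) for g in members),
            )
        )
    return cats


@dataclass
class SimulatedData:
    config: SimulationConfig
    annotation: GenomeAnnotation
    peaksets: list[PeakSet]
    expression: ExpressionMatrix
    categories: list[FunctionalCategory]
    truth: PlantedTruth


def simulate_all(cfg: SimulationConfig) -> SimulatedData:
    ann = simulate_annotation(cfg)
    return SimulatedData(
        config=cfg,
        annotation=ann,
        peaksets=simulate_peaks(cfg, ann),
        expression=simulate_expression(cfg, ann),
        categories=simulate_categories(cfg, ann),
        truth=planted_assignment(cfg, ann),
    )


def write_simulation(data: SimulatedData, outdir: str) -> dict[str, str]:
    """Write all simulated inputs to ``outdir``; returns a path manifest."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "annotation": os.path.join(outdir, "genes.tsv"),
        "expression": os.path.join(outdir, "expr.tsv"),
        "groups": os.path.join(outdir, "groups.tsv"),
        "gmt": os.path.join(outdir, "categories.gmt"),
        "truth": os.path.join(outdir, "truth.json"),
        "peaks_manifest": os.path.join(outdir, "manifest.tsv"),
    }
    write_annotation_tsv(data.annotation, paths["annotation"])
    write_expression_matrix(data.expression, paths["expression"])
    with open(paths["groups"], "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s in data.expression.sample_ids:
            fh.write(f"{s}\t{data.expression.group_labels[s]}\n")
    write_gmt(data.categories, paths["gmt"])
    with open(paths["truth"], "w") as fh:
        json.dump(asdict(data.truth), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(paths["peaks_manifest"], "w") as fh:
        fh.write("tf_name\treplicate\tpath\tdialect\n")
        for ps in data.peaksets:
            fname = f"{ps.tf_name}.{ps.replicate}.narrowPeak"
            write_narrowpeak(ps, os.path.join(outdir, fname))
            fh.write(f"{ps.tf_name}\t{ps.replicate}\t{fname}\tnarrowPeak\n")
    return paths
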