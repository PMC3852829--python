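"""Distance-decay regulatory potential per gene and top-N regulated gene sets.

Each gene's score is the sum, over binding sites whose anchor lies within a
cutoff distance D of the TSS, of exp(-(0.5 + 4*delta)) where delta is the
anchor-TSS distance normalised by D (so the weight runs from exp(-0.5) at
the TSS down to exp(-4.5) at the cutoff).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from tfimpact.io_formats import GenomeAnnotation, PeakSet


def _delta_denominator(delta_norm: str, D: int) -> float:
    """Parse the distance-normalisation mode: 'cutoff' -> D, 'fixed:<bp>' -> bp."""
    if delta_norm == "cutoff":
        return float(D)
    if delta_norm.startswith("fixed:"):
        denom = float(delta_norm.split(":", 1)[1])
        if denom <= 0:
            raise ValueError(f"fixed delta normaliser must be positive, got {denom}")
        return denom
    raise ValueError(f"unknown delta_norm {delta_norm!r}")


def site_weight(delta_bp: int, D: int, delta_norm: str = "cutoff") -> float:
    """Weight of one binding site at distance ``delta_bp`` under cutoff ``D``."""
    if D < 1:
        raise ValueError(f"D must be >= 1, got {D}")
    if not (0 <= delta_bp <= D):
        raise ValueError(f"delta_bp must be in [0, {D}], got {delta_bp}")
    denom = _delta_denominator(delta_norm, D)
    return math.exp(-(0.5 + 4.0 * delta_bp / denom))


@dataclass
class RPTable:
    """Per-gene regulatory potential for one (TF, replicate, cutoff)."""

    tf_name: str
    replicate: str
    cutoff_D: int
    scores: dict[str, float] = field(default_factory=dict)
    site_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class RegulatedGeneSet:
    """The top-N genes by regulatory potential, ties broken lexicographically."""

    tf_name: str
    replicate: str
    cutoff_D: int
    N: int
    genes: list[str]
    min_score: float


def regulatory_potential(
    peaks: PeakSet,
    ann: GenomeAnnotation,
    D: int,
    delta_norm: str = "cutoff",
) -> RPTable:
    """Score every annotated gene against one peak set.

    A peak contributes to a gene when its anchor point (summit if present,
    else the floored interval midpoint) lies within ``D`` bp of the TSS,
    boundary inclusive. Genes with no peak in range get score 0, count 0.
    """
    if D < 1:
        raise ValueError(f"D must be >= 1, got {D}")
    denom = _delta_denominator(delta_norm, D)

    anchors_by_chrom: dict[str, np.ndarray] = {}
    for p in peaks.peaks:
        anchors_by_chrom.setdefault(p.chrom, []).append(p.anchor)  # type: ignore[attr-defined]
    anchors_by_chrom = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in anchors_by_chrom.items()}

    scores: dict[str, float] = {}
    counts: dict[str, int] = {}
    for g in ann.genes:
        anchors = anchors_by_chrom.get(g.chrom)
        if anchors is None or anchors.size == 0:
            scores[g.gene_id] = 0.0
            counts[g.gene_id] = 0
            continue
        lo = int(np.searchsorted(anchors, g.tss - D, side="left"))
        hi = int(np.searchsorted(anchors, g.tss + D, side="right"))
        if hi <= lo:
            scores[g.gene_id] = 0.0
            counts[g.gene_id] = 0
            continue
        dist = np.abs(anchors[lo:hi] - g.tss)
        weights = np.exp(-(0.5 + 4.0 * dist / denom))
        scores[g.gene_id] = float(weights.sum())
        counts[g.gene_id] = int(hi - lo)
    return RPTable(
        tf_name=peaks.tf_name,
        replicate=peaks.replicate,
        cutoff_D=D,
        scores=scores,
        site_counts=counts,
    )


def top_genes(rp: RPTable, N: int, min_score: float = 0.0) -> RegulatedGeneSet:
    """Top-``N`` genes with score strictly above ``min_score``.

    Ordered by descending score, gene_id ascending on ties; may return
    fewer than N genes.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    eligible = [(gid, s) for gid, s in rp.scores.items() if s > min_score]
    eligible.sort(key=lambda t: (-t[1], t[0]))
    chosen = [gid for gid, _ in eligible[:N]]
    return RegulatedGeneSet(
        tf_name=rp.tf_name,
        replicate=rp.replicate,
        cutoff_D=rp.cutoff_D,
        N=N,
        genes=chosen,
        min_score=min_score,
    )
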