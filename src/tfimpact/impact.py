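"""TF impact scores with hypergeometric significance over a (D, N) grid.

For each TF/replicate, the top-N genes by regulatory potential at cutoff D
are intersected with the up- and down-regulated gene sets; the impact score
R is the overlapping fraction and its significance is the upper
hypergeometric tail against the gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from tfimpact.io_formats import GenomeAnnotation, PeakSet, ValidationError
from tfimpact.regpotential import regulatory_potential, top_genes

logger = logging.getLogger(__name__)

DEFAULT_NS: tuple[int, ...] = (100, 200, 500, 800)
DEFAULT_DS: tuple[int, ...] = (1000, 3000, 5000, 10000)


@dataclass
class Universe:
    """Background gene set defining N in every hypergeometric test."""

    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        self.gene_ids = frozenset(self.gene_ids)
        if not self.gene_ids:
            raise ValidationError("universe is empty")

    def require(self, genes: Iterable[str], label: str) -> None:
        missing = sorted(set(genes) - self.gene_ids)
        if missing:
            shown = ", ".join(missing[:10])
            raise ValidationError(
                f"{len(missing)} {label} gene(s) not in universe: {shown}"
                + ("..." if len(missing) > 10 else "")
            )

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class ImpactResult:
    """One grid cell: a TF/replicate scored at one (D, N)."""

    tf_name: str
    replicate: str
    cutoff_D: int
    set_size_N: int
    n_t: int
    n_e_up: int
    n_e_down: int
    R_up: float
    R_down: float
    p_up: float
    p_down: float
    significant_up: bool
    significant_down: bool


def hypergeom_tail(N: int, M: int, n: int, x: int) -> float:
    """Upper tail P(X >= x) for X ~ Hypergeometric(N, M, n).

    Computed by summing log-pmf terms with logsumexp; exact support bounds
    are respected so impossible tails return exactly 0 and x <= 0 returns
    exactly 1.
    """
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, M={M}, n={n}")
    upper = min(M, n)
    if not (0 <= x <= upper + 1):
        raise ValueError(f"x={x} outside [0, min(M,n)+1={upper + 1}]")
    if x <= max(0, n - (N - M)):
        return 1.0
    if x > upper:
        return 0.0
    i = np.arange(x, upper + 1, dtype=np.int64)
    log_pmf = (
        gammaln(M + 1)
        - gammaln(i + 1)
        - gammaln(M - i + 1)
        + gammaln(N - M + 1)
        - gammaln(n - i + 1)
        - gammaln(N - M - n + i + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def impact_score(
    regulated: set[str], de_set: set[str], universe: Universe
) -> tuple[float, float, int]:
    """Impact score R = |regulated & de_set| / |regulated| with its tail p."""
    universe.require(regulated, "regulated")
    universe.require(de_set, "differential-expression")
    if not regulated:
        logger.warning("empty regulated set: R = 0, p = 1")
        return 0.0, 1.0, 0
    n_e = len(regulated & de_set)
    R = n_e / len(regulated)
    p = hypergeom_tail(len(universe), len(regulated), len(de_set), n_e)
    return R, p, n_e


def scan_impact(
    tf_peaksets: Iterable[PeakSet],
    ann: GenomeAnnotation,
    up: set[str],
    down: set[str],
    Ns: Sequence[int] = DEFAULT_NS,
    Ds: Sequence[int] = DEFAULT_DS,
    p_threshold: float = 0.001,
    tested_genes: set[str] | None = None,
    delta_norm: str = "cutoff",
    min_score: float = 0.0,
) -> list[ImpactResult]:
    """Score every (TF, replicate, D, N) grid cell against up and down sets.

    The universe is the annotation restricted to ``tested_genes`` (the genes
    that survived the expression pre-filter) when given, else the whole
    annotation; regulated sets are clipped to the universe before scoring.
    """
    if up & down:
        raise ValidationError(f"up and down sets overlap: {sorted(up & down)[:5]}")
    ann_ids = set(ann.gene_ids())
    uni_ids = ann_ids & tested_genes if tested_genes is not None else ann_ids
    universe = Universe(frozenset(uni_ids))
    universe.require(up, "upregulated")
    universe.require(down, "downregulated")

    results: list[ImpactResult] = []
    for ps in tf_peaksets:
        for D in Ds:
            rp = regulatory_potential(ps, ann, D, delta_norm=delta_norm)
            for N in Ns:
                reg = set(top_genes(rp, N, min_score=min_score).genes) & universe.gene_ids
                R_up, p_up, n_e_up = impact_score(reg, up, universe)
                R_down, p_down, n_e_down = impact_score(reg, down, universe)
                results.append(
                    ImpactResult(
                        tf_name=ps.tf_name,
                        replicate=ps.replicate,
                        cutoff_D=D,
                        set_size_N=N,
                        n_t=len(reg),
                        n_e_up=n_e_up,
                        n_e_down=n_e_down,
                        R_up=R_up,
                        R_down=R_down,
                        p_up=p_up,
                        p_down=p_down,
                        significant_up=p_up < p_threshold,
                        significant_down=p_down < p_threshold,
                    )
                )
    return results


def impact_table(results: list[ImpactResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def rank_tfs(results: list[ImpactResult], D: int, N: int) -> list[ImpactResult]:
    """TFs at one grid cell, best first: R_down desc, p_down asc, name asc."""
    cell = [r for r in results if r.cutoff_D == D and r.set_size_N == N]
    return sorted(cell, key=lambda r: (-r.R_down, r.p_down, r.tf_name, r.replicate))


def merge_replicates_union(peaksets: Iterable[PeakSet]) -> list[PeakSet]:
    """Pool each TF's replicates into a single 'union' peak set."""
    by_tf: dict[str, list[PeakSet]] = {}
    for ps in peaksets:
        by_tf.setdefault(ps.tf_name, []).append(ps)
    merged = []
    for tf, sets in by_tf.items():
        pooled = [p for ps in sets for p in ps.peaks]
        merged.append(PeakSet(tf_name=tf, replicate="union", peaks=pooled))
    return merged
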