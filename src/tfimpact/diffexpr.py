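"""Two-group differential expression: Welch t-test + Benjamini-Hochberg.

A deliberately simple stand-in for moderated linear-model engines; the
pipeline also accepts precomputed up/down gene lists, so any external DE
engine can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tfimpact.io_formats import ExpressionMatrix, ValidationError

_P_FLOOR = 1e-300  # p-values live in (0,1]


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2_fc: float  # treatment mean - control mean
    p_value: float
    adj_p: float
    direction: str  # up / down / ns


def filter_low_variability(m: ExpressionMatrix, min_sd: float) -> ExpressionMatrix:
    """Keep genes whose across-sample sd (ddof=1) is >= ``min_sd``."""
    if min_sd < 0:
        raise ValueError(f"min_sd must be >= 0, got {min_sd}")
    sds = np.std(m.values, axis=1, ddof=1)
    keep = sds >= min_sd
    if not keep.any():
        raise ValidationError("low-variability filter removed every gene")
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(m.gene_ids, keep) if k],
        sample_ids=list(m.sample_ids),
        values=m.values[keep, :],
        group_labels=dict(m.group_labels),
    )


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    # factor computed first so the j=m term is exactly p (keeps adj >= raw)
    ranked = p[order] * (m / np.arange(1, m + 1))
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def differential_expression(m: ExpressionMatrix, alpha: float = 0.01) -> list[DEResult]:
    """Per-gene two-sided Welch t-test (treatment vs control) with BH correction.

    Degenerate genes (zero variance in both groups) get p = 1 when the group
    means agree and a floor p otherwise.
    """
    ctrl = m.group_columns("control")
    trt = m.group_columns("treatment")
    if ctrl.shape[1] < 2 or trt.shape[1] < 2:
        raise ValidationError("both groups need >= 2 samples for a t-test")

    log2_fc = trt.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(trt, ctrl, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    p[degenerate & (log2_fc == 0)] = 1.0
    p[degenerate & (log2_fc != 0)] = _P_FLOOR
    p = np.clip(p, _P_FLOOR, 1.0)

    adj = bh_adjust(p)
    results = []
    for gid, fc, pv, ap in zip(m.gene_ids, log2_fc, p, adj):
        if ap < alpha and fc > 0:
            direction = "up"
        elif ap < alpha and fc < 0:
            direction = "down"
        else:
            direction = "ns"
        results.append(
            DEResult(gene_id=gid, log2_fc=float(fc), p_value=float(pv), adj_p=float(ap), direction=direction)
        )
    return results


def de_gene_sets(results: list[DEResult], alpha: float = 0.01) -> tuple[set[str], set[str]]:
    """Split results into (up, down) gene sets at adjusted p strictly < alpha."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    up = {r.gene_id for r in results if r.adj_p < alpha and r.log2_fc > 0}
    down = {r.gene_id for r in results if r.adj_p < alpha and r.log2_fc < 0}
    return up, down


def de_table(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "log2_fc": [r.log2_fc for r in results],
            "p_value": [r.p_value for r in results],
            "adj_p": [r.adj_p for r in results],
            "direction": [r.direction for r in results],
        }
    )


def de_results_from_table(df: pd.DataFrame) -> list[DEResult]:
    return [
        DEResult(
            gene_id=str(row.gene_id),
            log2_fc=float(row.log2_fc),
            p_value=float(row.p_value),
            adj_p=float(row.adj_p),
            direction=str(row.direction),
        )
        for row in df.itertuples()
    ]
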