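"""Two-stage functional analysis.

Stage 1 tests each category for enrichment among the TF-regulated genes;
stage 2 takes the stage-1 survivors and asks whether the regulated genes
falling in the category are themselves enriched for up- or down-regulated
genes. Categories passing both stages in a direction are flagged as
process-related for that direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from tfimpact.diffexpr import bh_adjust
from tfimpact.impact import Universe, hypergeom_tail
from tfimpact.io_formats import FunctionalCategory

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    category_id: str
    name: str
    M_cat: int  # regulated genes mapped to the category
    x_up: int
    x_down: int
    p_reg: float
    p_up: float
    p_down: float
    adj_p_reg: float
    adj_p_up: float
    adj_p_down: float
    emt_related_up: bool
    emt_related_down: bool


def enrich_regulated(
    regulated: set[str],
    categories: Sequence[FunctionalCategory],
    universe: Universe,
) -> pd.DataFrame:
    """Stage 1: hypergeometric enrichment of each category in the regulated set.

    Categories with no genes in the universe are skipped with a warning.
    Returns a frame with columns category_id, name, M_cat, p_reg, adj_p_reg.
    """
    universe.require(regulated, "regulated")
    rows = []
    for cat in categories:
        cat_in_uni = cat.genes & universe.gene_ids
        if not cat_in_uni:
            logger.warning("category %s has no genes in universe; skipped", cat.category_id)
            continue
        overlap = len(cat_in_uni & regulated)
        p = hypergeom_tail(len(universe), len(cat_in_uni), len(regulated), overlap)
        rows.append((cat.category_id, cat.name, overlap, p))
    df = pd.DataFrame(rows, columns=["category_id", "name", "M_cat", "p_reg"])
    df["adj_p_reg"] = bh_adjust(df["p_reg"].to_numpy()) if len(df) else []
    return df


def cross_enrichment(
    regulated: set[str],
    up: set[str],
    down: set[str],
    categories: Sequence[FunctionalCategory],
    universe: Universe,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Stage 1 + stage 2 over all categories.

    Stage 2 runs only on stage-1 survivors (adjusted p_reg < alpha): with
    M = the regulated genes mapped to the category, the direction tail is
    P(X >= x | N=|universe|, M, n=|direction set|) where x counts direction
    genes within that regulated slice. BH is applied per direction across
    the survivors; non-survivors carry p_dir = 1 and are never flagged.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    universe.require(up, "upregulated")
    universe.require(down, "downregulated")
    stage1 = enrich_regulated(regulated, categories, universe)
    by_id = {c.category_id: c for c in categories}

    survivors = stage1[stage1["adj_p_reg"] < alpha]
    logger.info(
        "stage-2 BH m = %d survivor categories (of %d tested)", len(survivors), len(stage1)
    )
    N = len(universe)
    p_up_list, p_down_list, counts = [], [], []
    for row in survivors.itertuples():
        cat = by_id[row.category_id]
        reg_slice = cat.genes & universe.gene_ids & regulated
        M_cat = len(reg_slice)
        x_up = len(reg_slice & up)
        x_down = len(reg_slice & down)
        p_up_list.append(hypergeom_tail(N, M_cat, len(up), x_up))
        p_down_list.append(hypergeom_tail(N, M_cat, len(down), x_down))
        counts.append((x_up, x_down))
    adj_up = bh_adjust(p_up_list) if p_up_list else []
    adj_down = bh_adjust(p_down_list) if p_down_list else []

    stage2 = {
        row.category_id: (p_up_list[i], p_down_list[i], adj_up[i], adj_down[i], counts[i])
        for i, row in enumerate(survivors.itertuples())
    }
    results = []
    for row in stage1.itertuples():
        if row.category_id in stage2:
            p_u, p_d, a_u, a_d, (x_u, x_d) = stage2[row.category_id]
            flag_up = row.adj_p_reg < alpha and a_u < alpha
            flag_down = row.adj_p_reg < alpha and a_d < alpha
        else:
            p_u = p_d = a_u = a_d = 1.0
            x_u = x_d = 0
            flag_up = flag_down = False
        results.append(
            EnrichmentResult(
                category_id=row.category_id,
                name=row.name,
                M_cat=int(row.M_cat),
                x_up=int(x_u),
                x_down=int(x_d),
                p_reg=float(row.p_reg),
                p_up=float(p_u),
                p_down=float(p_d),
                adj_p_reg=float(row.adj_p_reg),
                adj_p_up=float(a_u),
                adj_p_down=float(a_d),
                emt_related_up=bool(flag_up),
                emt_related_down=bool(flag_down),
            )
        )
    return results


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
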