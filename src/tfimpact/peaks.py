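"""Peak-set filtering and cross-cell-line consensus intersection."""

from __future__ import annotations

from dataclasses import replace

from tfimpact.io_formats import Peak, PeakSet


def filter_by_q(peaks: PeakSet, q_max: float) -> PeakSet:
    """Keep peaks with ``q_value < q_max`` (strict). Order preserved."""
    if not (0.0 < q_max <= 1.0):
        raise ValueError(f"q_max must be in (0,1], got {q_max}")
    kept = [p for p in peaks.peaks if p.q_value < q_max]
    return PeakSet(tf_name=peaks.tf_name, replicate=peaks.replicate, peaks=kept)


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Collapse overlapping or book-ended intervals."""
    if not ivals:
        return []
    ivals = sorted(ivals)
    merged = [ivals[0]]
    for s, e in ivals[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def _intersect_unions(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two merged interval lists (two-pointer sweep)."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def overlap_consensus(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> PeakSet:
    """Consensus sites shared between two peak sets.

    Peaks from both sets are clustered per chromosome by single-linkage
    chaining (two peaks link when they share >= ``min_overlap`` bases). Each
    cluster containing peaks from both sides emits one consensus peak
    spanning the intersection of the cluster's a-side and b-side merged
    spans, with q_value = max of the member q-values; summits are dropped.
    Output is sorted by (chrom, start) and is symmetric in a and b.
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    tagged: list[tuple[str, int, int, str, Peak]] = []
    for src, ps in (("a", a), ("b", b)):
        for p in ps.peaks:
            tagged.append((p.chrom, p.start, p.end, src, p))
    tagged.sort(key=lambda t: (t[0], t[1], t[2]))

    consensus: list[Peak] = []
    cluster: list[tuple[str, Peak]] = []
    cur_chrom: str | None = None
    cur_end = -1

    def flush() -> None:
        a_ivals = _merge_intervals([(p.start, p.end) for s, p in cluster if s == "a"])
        b_ivals = _merge_intervals([(p.start, p.end) for s, p in cluster if s == "b"])
        if not a_ivals or not b_ivals:
            return
        inter = _intersect_unions(a_ivals, b_ivals)
        if not inter:
            return
        chrom = cluster[0][1].chrom
        consensus.append(
            Peak(
                chrom=chrom,
                start=inter[0][0],
                end=inter[-1][1],
                summit=None,
                score=max(p.score for _, p in cluster),
                q_value=max(p.q_value for _, p in cluster),
            )
        )

    for chrom, start, end, src, p in tagged:
        # link when overlap with the cluster's covered span >= min_overlap
        if cluster and chrom == cur_chrom and start <= cur_end - min_overlap:
            cluster.append((src, p))
            cur_end = max(cur_end, end)
        else:
            if cluster:
                flush()
            cluster = [(src, p)]
            cur_chrom = chrom
            cur_end = end
    if cluster:
        flush()

    consensus.sort(key=lambda p: (p.chrom, p.start))
    return PeakSet(
        tf_name=f"{a.tf_name}x{b.tf_name}",
        replicate="consensus",
        peaks=consensus,
    )


def merge_count(ps: PeakSet) -> int:
    """Number of intervals after collapsing overlapping/book-ended peaks."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in ps.peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    return sum(len(_merge_intervals(v)) for v in by_chrom.values())
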