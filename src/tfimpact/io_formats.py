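"""Domain types and readers/writers for every external format the pipeline touches.

All coordinates are 0-based, half-open (BED convention). Downstream modules
consume only the types defined here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """One gene collapsed to a single TSS.

    ``tss`` is a 0-based genomic coordinate; on the minus strand it is the
    last base of the interval the gene was derived from.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_id}: tss must be >= 0, got {self.tss}")


@dataclass
class GenomeAnnotation:
    """Ordered collection of genes; the anchor for all distance computation."""

    genes: list[GeneModel]
    chrom_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r} in annotation")
            seen.add(g.gene_id)
        if self.chrom_sizes is not None:
            for g in self.genes:
                size = self.chrom_sizes.get(g.chrom)
                if size is not None and g.tss >= size:
                    raise ValidationError(
                        f"gene {g.gene_id}: tss {g.tss} beyond {g.chrom} length {size}"
                    )

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass(frozen=True)
class Peak:
    """One binding site. ``q_value`` is a raw FDR probability in (0, 1]."""

    chrom: str
    start: int
    end: int
    summit: int | None = None
    score: float = 0.0
    q_value: float = 1.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"peak {self.chrom}:{self.start}-{self.end}: start >= end")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"peak {self.chrom}:{self.start}-{self.end}: summit {self.summit} outside interval"
            )
        if not (0.0 < self.q_value <= 1.0):
            raise ValidationError(
                f"peak {self.chrom}:{self.start}-{self.end}: q_value {self.q_value} outside (0,1]"
            )

    @property
    def anchor(self) -> int:
        """Best point estimate of the binding event: summit, else midpoint."""
        if self.summit is not None:
            return self.summit
        return (self.start + self.end) // 2


@dataclass
class PeakSet:
    """All peaks for one TF in one replicate."""

    tf_name: str
    replicate: str
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass
class ExpressionMatrix:
    """Gene x sample log-scale intensities with a two-group design."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group_labels: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        missing = [s for s in self.sample_ids if s not in self.group_labels]
        if missing:
            raise ValidationError(f"samples without group label: {missing}")
        bad = {s: g for s, g in self.group_labels.items() if g not in ("control", "treatment")}
        if bad:
            raise ValidationError(f"group labels must be control/treatment, got {bad}")
        for grp in ("control", "treatment"):
            if not any(self.group_labels[s] == grp for s in self.sample_ids):
                raise ValidationError(f"group {grp!r} has no samples")

    def group_columns(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids) if self.group_labels[s] == group]
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class FunctionalCategory:
    """One gene set from a GMT file."""

    category_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"category {self.category_id}: empty gene set")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_gene_annotation(path: str, dialect: str = "tsv") -> GenomeAnnotation:
    """Read a gene annotation as ``tsv`` (gene_id, chrom, strand, tss columns)
    or ``bed6`` (TSS = start on '+', end-1 on '-')."""
    if dialect not in ("tsv", "bed6"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    genes: list[GeneModel] = []
    with open(path) as fh:
        if dialect == "tsv":
            header = fh.readline().rstrip("\n").split("\t")
            try:
                cols = {c: header.index(c) for c in ("gene_id", "chrom", "strand", "tss")}
            except ValueError as exc:
                raise ParseError(f"{path}: missing required column ({exc})") from exc
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                try:
                    genes.append(
                        GeneModel(
                            gene_id=parts[cols["gene_id"]],
                            chrom=parts[cols["chrom"]],
                            strand=parts[cols["strand"]],
                            tss=int(parts[cols["tss"]]),
                        )
                    )
                except (IndexError, ValueError) as exc:
                    if isinstance(exc, ValidationError):
                        raise
                    raise ParseError(f"{path}:{lineno}: malformed annotation row") from exc
        else:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 6:
                    raise ParseError(f"{path}:{lineno}: bed6 needs 6 columns, got {len(parts)}")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
                if start >= end:
                    raise ParseError(f"{path}:{lineno}: start >= end")
                strand = parts[5]
                tss = start if strand == "+" else end - 1
                genes.append(GeneModel(gene_id=parts[3], chrom=parts[0], strand=strand, tss=tss))
    return GenomeAnnotation(genes=genes)


def read_peaks(path: str, dialect: str, tf_name: str, replicate: str) -> PeakSet:
    """Read peaks from ``narrowPeak`` (col 9 = -log10 q, col 10 = summit
    offset or -1) or ``bed5q`` (chrom, start, end, score, raw q)."""
    if dialect not in ("narrowPeak", "bed5q"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                if dialect == "narrowPeak":
                    if len(parts) < 10:
                        raise ParseError(
                            f"{path}:{lineno}: narrowPeak needs 10 columns, got {len(parts)}"
                        )
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    score = float(parts[4])
                    neg_log10_q = float(parts[8])
                    q = 10.0 ** (-neg_log10_q)
                    offset = int(parts[9])
                    summit = start + offset if offset >= 0 else None
                else:
                    if len(parts) < 5:
                        raise ParseError(
                            f"{path}:{lineno}: bed5q needs 5 columns, got {len(parts)}"
                        )
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    score = float(parts[3])
                    q = float(parts[4])
                    summit = None
                if start >= end:
                    raise ParseError(f"{path}:{lineno}: start >= end")
                if not (0.0 < q <= 1.0):
                    raise ValidationError(
                        f"{path}:{lineno}: q-value {q} outside (0,1] after transform"
                    )
                peaks.append(
                    Peak(chrom=chrom, start=start, end=end, summit=summit, score=score, q_value=q)
                )
            except (ParseError, ValidationError):
                raise
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed peak row") from exc
    return PeakSet(tf_name=tf_name, replicate=replicate, peaks=peaks)


def read_expression_matrix(path: str, group_map: Mapping[str, str]) -> ExpressionMatrix:
    """Read a TSV matrix (first column = gene ids, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    unknown = [s for s in group_map if s not in df.columns]
    if unknown:
        raise ValidationError(f"group_map samples not in matrix: {unknown}")
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        group_labels=dict(group_map),
    )


def read_group_map(path: str) -> dict[str, str]:
    """Read a two-column TSV (sample_id, group) with optional header."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns")
            if lineno == 1 and parts[:2] == ["sample_id", "group"]:
                continue
            groups[parts[0]] = parts[1]
    return groups


def read_gene_list(path: str) -> set[str]:
    """Read a plain-text gene list, one gene per line; duplicates collapse."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            gene = line.strip()
            if gene:
                out.add(gene)
    return out


def read_gmt(path: str) -> list[FunctionalCategory]:
    """Read GMT: tab-separated category_id, name, member genes."""
    categories: list[FunctionalCategory] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            genes = frozenset(g for g in parts[2:] if g)
            if len(parts) < 3 or not genes:
                logger.warning("%s:%d: GMT line with no genes, skipped", path, lineno)
                continue
            categories.append(
                FunctionalCategory(category_id=parts[0], name=parts[1], genes=genes)
            )
    return categories


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str, sort_by: str | Sequence[str] | None = None) -> None:
    """Write a result table as TSV with a deterministic row and column order.

    Floats are emitted with ``repr`` so a write/read round trip is lossless.
    """
    out = df.copy()
    if sort_by is not None:
        out = out.sort_values(
            by=list(sort_by) if not isinstance(sort_by, str) else [sort_by],
            kind="mergesort",
        )
    out.to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))


def write_expression_matrix(m: ExpressionMatrix, path: str) -> None:
    df = m.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=lambda x: repr(float(x)))


def write_peaks_bed(peaks: PeakSet, path: str) -> None:
    """Write peaks as bed5q (chrom, start, end, score, q)."""
    rows = sorted(peaks.peaks, key=lambda p: (p.chrom, p.start, p.end))
    with open(path, "w") as fh:
        for p in rows:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{repr(p.score)}\t{repr(p.q_value)}\n")


def write_narrowpeak(peaks: PeakSet, path: str) -> None:
    rows = sorted(peaks.peaks, key=lambda p: (p.chrom, p.start, p.end))
    with open(path, "w") as fh:
        for i, p in enumerate(rows):
            neg_log10_q = -math.log10(p.q_value)
            offset = p.summit - p.start if p.summit is not None else -1
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{peaks.tf_name}_{peaks.replicate}_{i}\t"
                f"{p.score:g}\t.\t0\t-1\t{neg_log10_q!r}\t{offset}\n"
            )


def write_gene_list(genes: Iterable[str], path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(f"{g}\n")


def write_gmt(categories: Iterable[FunctionalCategory], path: str) -> None:
    with open(path, "w") as fh:
        for cat in categories:
            members = "\t".join(sorted(cat.genes))
            fh.write(f"{cat.category_id}\t{cat.name}\t{members}\n")


def write_annotation_tsv(ann: GenomeAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for g in ann.genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")
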