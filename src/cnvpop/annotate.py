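"""Genic context, gene overlap, term enrichment, and interval intersections.

CNVRs are classified against gene models with exon > intron > intergenic
precedence, assigned to genes they cover by at least half of the shorter
feature, tested for term over-representation with a hypergeometric upper
tail + Benjamini-Hochberg FDR, and intersected with QTL intervals and
published CNVR sets (>= 1 bp overlap).

Gene models come from GFF3 (1-based inclusive, converted to half-open on
read); QTLs and external region sets from BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputDataError, ParameterError

__all__ = [
    "GeneModel",
    "GenicContext",
    "GeneIndex",
    "TermMap",
    "EnrichmentResult",
    "QTLRecord",
    "read_gff3_genes",
    "read_term_map",
    "read_bed_intervals",
    "classify_genic_context",
    "overlapping_genes",
    "enrichment_test",
    "qtl_overlap",
    "cross_study_overlap",
    "overlap_percentage",
]


class GenicContext(str, Enum):
    EXONIC = "EXONIC"
    INTRONIC = "INTRONIC"
    INTERGENIC = "INTERGENIC"


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    ivs = sorted(ivs)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return tuple((s, e) for s, e in out)


@dataclass(frozen=True)
class GeneModel:
    """One gene: span plus merged exon intervals, half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputDataError(f"gene {self.gene_id}: end <= start")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise InputDataError(f"gene {self.gene_id}: exon outside gene span")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Parse gene features (with their exons, via any parent chain) from GFF3."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        exons = [
            (e.start - 1, e.end)
            for e in db.children(g, featuretype="exon")
        ]
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand or ".",
                exons=_merge_intervals(exons),
            )
        )
    if not genes:
        raise InputDataError(f"{path}: no gene features found")
    return genes


class GeneIndex:
    """Interval trees over gene spans and exons, per chromosome."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._span: dict[str, IntervalTree] = {}
        self._exon: dict[str, IntervalTree] = {}
        for g in genes:
            self._span.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
            for s, e in g.exons:
                self._exon.setdefault(g.chrom, IntervalTree()).addi(s, e, g)

    def spans_overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._span.get(chrom)
        return [iv.data for iv in tree.overlap(start, end)] if tree else []

    def exons_overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._exon.get(chrom)
        return [iv.data for iv in tree.overlap(start, end)] if tree else []


def classify_genic_context(
    region: tuple[str, int, int], index: GeneIndex
) -> GenicContext:
    """Exon > intron > intergenic precedence for a (chrom, start, end) region."""
    chrom, start, end = region
    if index.exons_overlapping(chrom, start, end):
        return GenicContext.EXONIC
    if index.spans_overlapping(chrom, start, end):
        return GenicContext.INTRONIC
    return GenicContext.INTERGENIC


def overlapping_genes(
    region: tuple[str, int, int],
    index: GeneIndex,
    min_fraction: float = 0.5,
) -> list[GeneModel]:
    """Genes overlapping the region by >= min_fraction of the shorter feature.

    Complete containment of either feature always qualifies (the overlap
    then equals the shorter length).
    """
    if not (0 < min_fraction <= 1):
        raise ParameterError("min_fraction must be in (0, 1]")
    chrom, start, end = region
    region_len = end - start
    kept = []
    for g in index.spans_overlapping(chrom, start, end):
        overlap = min(end, g.end) - max(start, g.start)
        if overlap >= min_fraction * min(g.length, region_len):
            kept.append(g)
    kept.sort(key=lambda g: (g.start, g.gene_id))
    return kept


@dataclass(frozen=True)
class TermMap:
    """gene id -> set of term ids, with optional term descriptions."""

    gene_to_terms: Mapping[str, frozenset[str]]
    term_names: Mapping[str, str] = field(default_factory=dict)

    def genes_for(self, term: str, universe: Iterable[str] | None = None) -> set[str]:
        genes = {g for g, ts in self.gene_to_terms.items() if term in ts}
        if universe is not None:
            genes &= set(universe)
        return genes

    @property
    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_to_terms.values():
            out |= ts
        return out


def read_term_map(path: str | Path) -> TermMap:
    """Two- or three-column TSV: gene_id, term_id[, term_name]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise InputDataError(f"{path}: expected gene_id and term_id columns")
    mapping: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for row in df.itertuples(index=False):
        mapping.setdefault(row[0], set()).add(row[1])
        if len(row) > 2 and isinstance(row[2], str):
            names[row[1]] = row[2]
    return TermMap({g: frozenset(ts) for g, ts in mapping.items()}, names)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    name: str
    k: int  # term genes in the query set
    K: int  # term genes in the background
    n: int  # query set size
    N: int  # background size
    p_value: float
    q_value: float


def enrichment_test(
    genes: Iterable[str],
    term_map: TermMap,
    background: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail over-representation with BH correction.

    Per term, p = P(X >= k) drawing n genes from a background of N of
    which K carry the term. Every term with K >= 1 in the background is
    tested; results are sorted by p.
    """
    gene_set = set(genes)
    if background is None:
        bg = set(term_map.gene_to_terms)
    else:
        bg = set(background)
    if not gene_set <= bg:
        raise InputDataError("query gene set is not a subset of the background")
    if not gene_set:
        return []
    N, n = len(bg), len(gene_set)
    rows: list[tuple[str, int, int]] = []
    for term in sorted(term_map.terms):
        term_genes = term_map.genes_for(term, bg)
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & gene_set)
        rows.append((term, k, K))
    pvals = np.array(
        [stats.hypergeom.sf(k - 1, N, K, n) for _, k, K in rows], dtype=float
    )
    if len(pvals) == 0:
        return []
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            term=t,
            name=term_map.term_names.get(t, ""),
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=float(p),
            q_value=float(q),
        )
        for (t, k, K), p, q in zip(rows, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


@dataclass(frozen=True)
class QTLRecord:
    qtl_id: str
    trait: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputDataError(f"QTL {self.qtl_id}: end <= start")


def read_bed_intervals(path: str | Path) -> list[QTLRecord]:
    """BED: chrom start end [name [trait]]; half-open as BED already is."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        name = row[3] if len(row) > 3 else f"iv_{i}"
        trait = row[4] if len(row) > 4 else ""
        records.append(
            QTLRecord(str(name), str(trait), str(row[0]), int(row[1]), int(row[2]))
        )
    return records


def _interval_tree(regions: Sequence) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
    return trees


def qtl_overlap(
    cnvrs: Sequence, qtls: Sequence[QTLRecord]
) -> tuple[pd.DataFrame, int, int]:
    """All (CNVR, QTL) pairs overlapping >= 1 bp, plus distinct counts."""
    trees = _interval_tree(qtls)
    rows = []
    hit_cnvrs: set[int] = set()
    hit_qtls: set[str] = set()
    for i, r in enumerate(cnvrs):
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(r.start, r.end)):
            q = iv.data
            rows.append(
                {
                    "chrom": r.chrom,
                    "cnvr_start": r.start,
                    "cnvr_end": r.end,
                    "qtl_id": q.qtl_id,
                    "trait": q.trait,
                    "qtl_start": q.start,
                    "qtl_end": q.end,
                }
            )
            hit_cnvrs.add(i)
            hit_qtls.add(q.qtl_id)
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "cnvr_start",
            "cnvr_end",
            "qtl_id",
            "trait",
            "qtl_start",
            "qtl_end",
        ],
    )
    return df, len(hit_cnvrs), len(hit_qtls)


def overlap_percentage(count: int, total: int) -> float:
    """count / total as a percentage, rounded to 2 decimals."""
    if total <= 0:
        raise InputDataError("total must be positive")
    return round(count / total * 100.0, 2)


def cross_study_overlap(ours: Sequence, theirs: Sequence) -> tuple[int, float]:
    """How many of ``theirs`` overlap (>= 1 bp) anything in ``ours``.

    Returns (count, percentage of theirs), the convention used when
    benchmarking a CNVR set against a previously published one.
    """
    if len(theirs) == 0:
        raise InputDataError("empty external region set")
    trees = _interval_tree(ours)
    count = 0
    for r in theirs:
        tree = trees.get(r.chrom)
        if tree is not None and tree.overlap(r.start, r.end):
            count += 1
    return count, overlap_percentage(count, len(theirs))
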