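"""CNV regions: merging calls, cross-population accounting, summary statistics.

Population-level calls are merged into CNV regions (CNVRs) when two
neighboring calls are close (gap smaller than 20% of their combined
length) *and* their per-individual mean-depth vectors are significantly
correlated (Pearson t-test at p < 0.01). Merging iterates to a fixpoint,
so the result does not depend on the scan order.

Across populations, CNVRs overlapping by at least 1 bp are treated as the
same region; Venn-style shared/unique counts are taken over the connected
components of that overlap graph.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import GAIN, LOSS, CNVSegment, correlation_significant
from .errors import InputDataError, ParameterError
from .windows import GenomeLayout, NormalizedDepthMatrix

__all__ = [
    "CNVR",
    "merge_calls_to_cnvrs",
    "population_cnvr_sets",
    "PopulationSetResult",
    "summarize_sizes",
    "CNV_SIZE_BINS_KB",
    "CNVR_SIZE_BINS_KB",
    "chromosome_count_regression",
    "mean_length_kb",
    "cnvr_table",
]

_TYPE_FROM_DIRECTIONS = {
    frozenset({GAIN}): "GAIN",
    frozenset({LOSS}): "LOSS",
    frozenset({GAIN, LOSS}): "BOTH",
}

# default size-bin edges (kb): events use 0-2 / 2-4 / >4; regions a finer grid
CNV_SIZE_BINS_KB = (0.0, 2.0, 4.0, float("inf"))
CNVR_SIZE_BINS_KB = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, float("inf"))


@dataclass(frozen=True)
class CNVR:
    """A copy-number-variable region: the union of correlated nearby calls."""

    chrom: str
    start: int
    end: int
    cnvr_type: str  # GAIN, LOSS or BOTH
    mean_rd: np.ndarray = field(repr=False)  # per-individual, over the region span
    populations: tuple[str, ...] = ()
    call_ids: tuple[int, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "CNVR") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def _region_mean_rd(norm: NormalizedDepthMatrix, chrom: str, start: int, end: int) -> np.ndarray:
    idx = norm.grid.windows_overlapping(chrom, start, end)
    if len(idx) == 0:
        raise InputDataError(f"region {chrom}:{start}-{end} covers no grid windows")
    return norm.values[idx].mean(axis=0)


def merge_calls_to_cnvrs(
    calls: Sequence[CNVSegment],
    norm: NormalizedDepthMatrix,
    gap_fraction: float = 0.2,
    alpha: float = 0.01,
    population: str | None = None,
    individuals: Sequence[str] | None = None,
) -> list[CNVR]:
    """Merge neighboring calls into CNVRs; iterate until no pair merges.

    Two neighbors merge iff gap < gap_fraction * (lenA + lenB) and the
    Pearson correlation of their per-individual mean-RD vectors (over the
    analysis group) is significant two-sided at p < alpha. A merged region
    spans min(start)..max(end); its type is GAIN/LOSS when all constituent
    calls agree, else BOTH.
    """
    if not (0 < gap_fraction):
        raise ParameterError("gap_fraction must be positive")
    if individuals is None:
        cols = np.arange(len(norm.individuals))
    else:
        cols = np.array([norm.individuals.index(i) for i in individuals])

    # working clusters: [chrom, start, end, directions(set), call_ids(list)]
    clusters = [
        {
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "dirs": {c.direction},
            "ids": [i],
            "vec": c.mean_rd[cols],
        }
        for i, c in enumerate(calls)
    ]
    clusters.sort(key=lambda cl: (cl["chrom"], cl["start"], cl["end"]))

    changed = True
    while changed:
        changed = False
        merged: list[dict] = []
        for cl in clusters:
            prev = merged[-1] if merged else None
            if prev is not None and prev["chrom"] == cl["chrom"]:
                gap = cl["start"] - prev["end"]  # may be <= 0 when overlapping
                combined = (prev["end"] - prev["start"]) + (cl["end"] - cl["start"])
                if gap < gap_fraction * combined and correlation_significant(
                    prev["vec"], cl["vec"], alpha
                ):
                    prev["end"] = max(prev["end"], cl["end"])
                    prev["start"] = min(prev["start"], cl["start"])
                    prev["dirs"] |= cl["dirs"]
                    prev["ids"] += cl["ids"]
                    prev["vec"] = _region_mean_rd(
                        norm, prev["chrom"], prev["start"], prev["end"]
                    )[cols]
                    changed = True
                    continue
            merged.append(cl)
        clusters = merged

    out: list[CNVR] = []
    for cl in clusters:
        mean_rd = _region_mean_rd(norm, cl["chrom"], cl["start"], cl["end"])
        out.append(
            CNVR(
                chrom=cl["chrom"],
                start=int(cl["start"]),
                end=int(cl["end"]),
                cnvr_type=_TYPE_FROM_DIRECTIONS[frozenset(cl["dirs"])],
                mean_rd=mean_rd,
                populations=(population,) if population else (),
                call_ids=tuple(sorted(cl["ids"])),
            )
        )
    return out


@dataclass
class PopulationSetResult:
    """Cross-population CNVR accounting."""

    venn: dict[tuple[str, ...], int]  # population combination -> component count
    n_union: int
    components: list[list[tuple[str, CNVR]]]

    def shared_by_all(self, populations: Sequence[str]) -> int:
        return self.venn.get(tuple(sorted(populations)), 0)

    def unique_to(self, population: str) -> int:
        return self.venn.get((population,), 0)


def population_cnvr_sets(
    per_population: Mapping[str, Sequence[CNVR]],
) -> PopulationSetResult:
    """Connected components of the >=1 bp overlap graph across populations.

    Each component is one region of the union set, labeled with the
    populations contributing to it; Venn counts are component counts per
    label combination and sum to the union count.
    """
    if len(per_population) < 2:
        raise InputDataError("need at least two populations")
    items: list[tuple[str, int, int, str, CNVR]] = []
    for pop, regions in per_population.items():
        for r in regions:
            items.append((r.chrom, r.start, r.end, pop, r))
    items.sort(key=lambda t: (t[0], t[1], t[2]))

    components: list[list[tuple[str, CNVR]]] = []
    cur: list[tuple[str, CNVR]] = []
    cur_chrom: str | None = None
    cur_end = -1
    for chrom, start, end, pop, r in items:
        if cur and chrom == cur_chrom and start < cur_end:
            cur.append((pop, r))
            cur_end = max(cur_end, end)
        else:
            if cur:
                components.append(cur)
            cur = [(pop, r)]
            cur_chrom = chrom
            cur_end = end
    if cur:
        components.append(cur)

    venn: Counter[tuple[str, ...]] = Counter()
    for comp in components:
        venn[tuple(sorted({pop for pop, _ in comp}))] += 1
    return PopulationSetResult(dict(venn), len(components), components)


def summarize_sizes(
    lengths_bp: Sequence[int] | np.ndarray,
    bin_edges_kb: Sequence[float] = CNVR_SIZE_BINS_KB,
) -> pd.Series:
    """Fraction of regions per size bin; exhaustive bins summing to 1."""
    lengths_bp = np.asarray(lengths_bp, dtype=float)
    if lengths_bp.size == 0:
        raise InputDataError("empty region list")
    edges = np.asarray(bin_edges_kb, dtype=float) * 1e3
    counts, _ = np.histogram(lengths_bp, bins=edges)
    labels = []
    for lo, hi in zip(bin_edges_kb[:-1], bin_edges_kb[1:]):
        labels.append(f">{lo:g}kb" if np.isinf(hi) else f"{lo:g}-{hi:g}kb")
    return pd.Series(counts / lengths_bp.size, index=labels, name="fraction")


def chromosome_count_regression(
    counts: Mapping[str, int], lengths: Mapping[str, int]
) -> tuple[float, float, float]:
    """OLS of per-chromosome CNVR count on chromosome length.

    Returns (slope, intercept, R^2). Chromosomes absent from ``counts``
    enter with count 0.
    """
    chroms = list(lengths)
    if len(chroms) < 3:
        raise InputDataError("regression requires >= 3 chromosomes")
    x = np.array([lengths[c] for c in chroms], dtype=float)
    y = np.array([counts.get(c, 0) for c in chroms], dtype=float)
    if np.ptp(x) == 0:
        raise InputDataError("zero variance in chromosome lengths")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def mean_length_kb(total_length_mb: float, count: int) -> float:
    """Mean feature length in kb implied by a total length (Mb) and a count,
    rounded to the 2 decimals summary tables report."""
    if count <= 0:
        raise InputDataError("count must be positive")
    return round(total_length_mb * 1e3 / count, 2)


def cnvr_table(cnvrs: Sequence[CNVR], individuals: Sequence[str] | None = None) -> pd.DataFrame:
    """BED-like TSV payload: chrom start end id type n_carriers mean_RD populations."""
    rows = []
    for i, r in enumerate(cnvrs):
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "id": f"cnvr_{i}",
                "type": r.cnvr_type,
                "n_calls": len(r.call_ids),
                "mean_RD": float(np.mean(r.mean_rd)),
                "populations": ",".join(r.populations) or ".",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "id",
            "type",
            "n_calls",
            "mean_RD",
            "populations",
        ],
    )
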