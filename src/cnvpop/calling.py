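"""Per-individual window classification and CNV call construction.

A window is called in an individual only when both halves of a conjunctive
criterion agree: the normalized depth must deviate from the diploid
baseline by more than ``stdev_multiplier`` standard deviations of that
individual's normalized depth (statistical half), *and* clear an empirical
cutoff placed between the diploid and heterozygous expectations
(loss < 0.65, gain > 1.35).

Population-level filtering then keeps a window as a CNV candidate only if
it is carried by at least 5% of individuals or by at least three
homozygous carriers; adjacent candidate windows whose across-individual
depth vectors are significantly correlated (Pearson t-test) are merged
into calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputDataError, ParameterError
from .windows import NormalizedDepthMatrix, RawDepthMatrix, WindowGrid

__all__ = [
    "LOSS",
    "NORMAL",
    "GAIN",
    "CallingParams",
    "WindowStateMatrix",
    "CNVSegment",
    "IndividualCNVEvent",
    "classify_windows",
    "low_coverage_mask",
    "candidate_windows",
    "correlation_significant",
    "merge_adjacent_windows",
    "call_individual_events",
    "summarize_events",
]

log = logging.getLogger(__name__)

LOSS, NORMAL, GAIN = -1, 0, 1
_DIRECTION_NAME = {LOSS: "LOSS", GAIN: "GAIN"}


@dataclass(frozen=True)
class CallingParams:
    """Thresholds of the two-criterion caller and its population filters."""

    del_cutoff: float = 0.65
    dup_cutoff: float = 1.35
    stdev_multiplier: float = 2.0
    min_carrier_freq: float = 0.05
    min_homozygous: int = 3
    hom_del_ceiling: float = 0.25
    hom_dup_floor: float = 1.75
    merge_alpha: float = 0.05
    low_coverage_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.del_cutoff < 1 < self.dup_cutoff):
            raise ParameterError(
                f"require 0 < del_cutoff < 1 < dup_cutoff, got "
                f"{self.del_cutoff}, {self.dup_cutoff}"
            )
        if not (0 < self.merge_alpha < 1):
            raise ParameterError(f"merge_alpha must be in (0,1), got {self.merge_alpha}")
        if not (0 < self.min_carrier_freq <= 1):
            raise ParameterError(
                f"min_carrier_freq must be in (0,1], got {self.min_carrier_freq}"
            )
        if self.min_homozygous < 1:
            raise ParameterError("min_homozygous must be >= 1")


@dataclass(frozen=True)
class WindowStateMatrix:
    """Per-(window, individual) state: LOSS (-1), NORMAL (0) or GAIN (+1)."""

    grid: WindowGrid
    individuals: tuple[str, ...]
    states: np.ndarray  # int8, shape (n_windows, n_individuals)

    def __post_init__(self) -> None:
        if self.states.shape != (self.grid.n_windows, len(self.individuals)):
            raise InputDataError("state matrix shape mismatch")


@dataclass(frozen=True)
class CNVSegment:
    """A merged run of candidate windows, one direction, population-level."""

    chrom: str
    start: int
    end: int
    direction: int  # GAIN or LOSS
    window_indices: tuple[int, ...]
    mean_rd: np.ndarray  # per-individual mean normalized RD over the segment

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def direction_name(self) -> str:
        return _DIRECTION_NAME[self.direction]


@dataclass(frozen=True)
class IndividualCNVEvent:
    """One individual's CNV over one segment."""

    individual: str
    chrom: str
    start: int
    end: int
    direction: int
    mean_rd: float

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def direction_name(self) -> str:
        return _DIRECTION_NAME[self.direction]


def classify_windows(
    norm: NormalizedDepthMatrix, params: CallingParams = CallingParams()
) -> WindowStateMatrix:
    """Apply the conjunctive statistical + empirical criterion per cell."""
    rd = norm.values
    lo_stat = 1.0 - params.stdev_multiplier * norm.stdev  # per individual
    hi_stat = 1.0 + params.stdev_multiplier * norm.stdev
    states = np.zeros(rd.shape, dtype=np.int8)
    states[(rd < lo_stat) & (rd < params.del_cutoff)] = LOSS
    states[(rd > hi_stat) & (rd > params.dup_cutoff)] = GAIN
    return WindowStateMatrix(norm.grid, norm.individuals, states)


def low_coverage_mask(raw: RawDepthMatrix, fraction: float = 0.10) -> np.ndarray:
    """Boolean mask of windows to *exclude*: across-individual mean raw depth
    below ``fraction`` of the grand mean (unmappable / gap-like windows)."""
    window_mean = raw.values.mean(axis=1)
    return window_mean < fraction * window_mean.mean()


def candidate_windows(
    states: WindowStateMatrix,
    norm: NormalizedDepthMatrix,
    params: CallingParams = CallingParams(),
    individuals: Sequence[str] | None = None,
    exclude: np.ndarray | None = None,
) -> pd.DataFrame:
    """Population-level candidate filter, evaluated per direction.

    A window is a candidate for a direction iff carriers/total >= the
    minimum carrier frequency OR at least ``min_homozygous`` carriers look
    homozygous (RD < 0.25 for loss, > 1.75 for gain). ``individuals``
    restricts the analysis group (one population, or all pooled).

    Returns a DataFrame with columns window, direction, n_carriers,
    n_homozygous sorted by (window, direction).
    """
    if individuals is None:
        cols = np.arange(len(states.individuals))
    else:
        cols = np.array([states.individuals.index(i) for i in individuals])
    n = len(cols)
    if n == 0:
        raise InputDataError("empty analysis group")
    st = states.states[:, cols]
    rd = norm.values[:, cols]
    rows: list[tuple[int, str, int, int]] = []
    for direction in (GAIN, LOSS):
        carriers = (st == direction).sum(axis=1)
        if direction == GAIN:
            hom = ((st == direction) & (rd > params.hom_dup_floor)).sum(axis=1)
        else:
            hom = ((st == direction) & (rd < params.hom_del_ceiling)).sum(axis=1)
        keep = (carriers / n >= params.min_carrier_freq) | (hom >= params.min_homozygous)
        keep &= carriers > 0
        if exclude is not None:
            keep &= ~exclude
        for w in np.flatnonzero(keep):
            rows.append((int(w), _DIRECTION_NAME[direction], int(carriers[w]), int(hom[w])))
    df = pd.DataFrame(rows, columns=["window", "direction", "n_carriers", "n_homozygous"])
    return df.sort_values(["window", "direction"]).reset_index(drop=True)


def correlation_significant(
    x: np.ndarray, y: np.ndarray, alpha: float
) -> bool:
    """Two-sided Pearson t-test: t = r*sqrt((n-2)/(1-r^2)), df = n-2.

    Constant vectors leave the correlation undefined: not significant
    (logged). Ties at p == alpha are not significant (strict inequality).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise InputDataError("Pearson merge test requires >= 4 individuals")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.info("constant RD vector: correlation undefined, not merging")
        return False
    r, p = stats.pearsonr(x, y)
    if np.isnan(p):
        return False
    return p < alpha


def merge_adjacent_windows(
    candidates: pd.DataFrame,
    norm: NormalizedDepthMatrix,
    alpha: float = 0.05,
    individuals: Sequence[str] | None = None,
) -> list[CNVSegment]:
    """Merge grid-adjacent candidate windows of one direction into calls.

    Walking left to right, a candidate window joins the current segment iff
    it is the next grid window on the same chromosome, has the same
    direction, and its across-individual RD vector is significantly
    correlated (p < alpha, two-sided) with the previous window's. Merging
    never spans a non-candidate window. Singleton candidates become
    single-window segments.

    The correlation is evaluated over ``individuals`` (the analysis group);
    segment ``mean_rd`` is stored for *all* individuals in ``norm``.
    """
    if individuals is None:
        cols = np.arange(len(norm.individuals))
    else:
        cols = np.array([norm.individuals.index(i) for i in individuals])
    chroms = norm.grid.windows["chrom"].to_numpy()
    starts = norm.grid.windows["start"].to_numpy()
    ends = norm.grid.windows["end"].to_numpy()

    segments: list[CNVSegment] = []

    def _emit(direction: int, run: list[int]) -> None:
        w = np.asarray(run)
        mean_rd = norm.values[w].mean(axis=0)
        segments.append(
            CNVSegment(
                chrom=str(chroms[run[0]]),
                start=int(starts[run[0]]),
                end=int(ends[run[-1]]),
                direction=direction,
                window_indices=tuple(run),
                mean_rd=mean_rd,
            )
        )

    for dname, sub in candidates.groupby("direction", sort=True):
        direction = GAIN if dname == "GAIN" else LOSS
        idx = np.sort(sub["window"].to_numpy())
        run: list[int] = []
        for w in idx:
            w = int(w)
            if run and w == run[-1] + 1 and chroms[w] == chroms[run[-1]]:
                prev_vec = norm.values[run[-1], cols]
                cur_vec = norm.values[w, cols]
                if correlation_significant(prev_vec, cur_vec, alpha):
                    run.append(w)
                    continue
            if run:
                _emit(direction, run)
            run = [w]
        if run:
            _emit(direction, run)
    segments.sort(key=lambda s: (s.chrom, s.start, s.direction))
    return segments


def _passes(rd: float, direction: int, stdev: float, params: CallingParams) -> bool:
    if direction == LOSS:
        return rd < 1 - params.stdev_multiplier * stdev and rd < params.del_cutoff
    return rd > 1 + params.stdev_multiplier * stdev and rd > params.dup_cutoff


def call_individual_events(
    segments: Sequence[CNVSegment],
    norm: NormalizedDepthMatrix,
    params: CallingParams = CallingParams(),
    individuals: Sequence[str] | None = None,
) -> list[IndividualCNVEvent]:
    """Emit one event per (individual, segment) whose segment-mean RD passes
    the classification thresholds in the segment's direction."""
    group = tuple(individuals) if individuals is not None else norm.individuals
    events: list[IndividualCNVEvent] = []
    for seg in segments:
        for ind in group:
            j = norm.individuals.index(ind)
            rd = float(seg.mean_rd[j])
            if _passes(rd, seg.direction, float(norm.stdev[j]), params):
                events.append(
                    IndividualCNVEvent(
                        individual=ind,
                        chrom=seg.chrom,
                        start=seg.start,
                        end=seg.end,
                        direction=seg.direction,
                        mean_rd=rd,
                    )
                )
    return events


def summarize_events(
    events: Sequence[IndividualCNVEvent],
    popmap: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-population event tally: count, gains, losses, total Mb, mean kb."""
    rows = []
    if popmap is None:
        groups: dict[str, list[IndividualCNVEvent]] = {"ALL": list(events)}
    else:
        groups = {}
        for ev in events:
            groups.setdefault(popmap[ev.individual], []).append(ev)
    for pop in sorted(groups):
        evs = groups[pop]
        total_bp = sum(e.length for e in evs)
        rows.append(
            {
                "population": pop,
                "count": len(evs),
                "duplication": sum(1 for e in evs if e.direction == GAIN),
                "deletion": sum(1 for e in evs if e.direction == LOSS),
                "total_length_mb": total_bp / 1e6,
                "mean_length_kb": (total_bp / len(evs) / 1e3) if evs else 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "population",
            "count",
            "duplication",
            "deletion",
            "total_length_mb",
            "mean_length_kb",
        ],
    )
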