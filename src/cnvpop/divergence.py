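"""Vst: between-population divergence of copy number over CNVRs.

Vst is the Fst analogue for quantitative copy-number signals:

    Vst = (Vtotal - (Vpop1*Npop1 + Vpop2*Npop2) / Ntotal) / Vtotal

where Vtotal is the variance of the pooled per-individual values over a
region and Vpop the within-population variances. A fixed copy-number
difference between populations gives Vst = 1; identical distributions
give Vst near 0. Values can be slightly negative by sampling noise and
are reported as computed.

All variances here are unbiased sample variances (divisor n-1); the
per-individual value for a region is its mean normalized read depth
(optionally log2-transformed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputDataError, ParameterError
from .regions import CNVR
from .windows import NormalizedDepthMatrix

__all__ = ["VstRecord", "vst", "vst_scan", "VstScanResult", "read_population_map"]


@dataclass(frozen=True)
class VstRecord:
    """Variance decomposition for one region and one population pair."""

    pop1: str
    pop2: str
    n_pop1: int
    n_pop2: int
    v_pop1: float
    v_pop2: float
    v_total: float
    vst: float  # nan when undefined
    defined: bool
    chrom: str = ""
    start: int = -1
    end: int = -1

    @property
    def n_total(self) -> int:
        return self.n_pop1 + self.n_pop2


def vst(
    values_pop1: Sequence[float] | np.ndarray,
    values_pop2: Sequence[float] | np.ndarray,
    pop1: str = "pop1",
    pop2: str = "pop2",
) -> VstRecord:
    """Compute Vst for two per-individual value vectors.

    If the pooled variance is zero the statistic is undefined and the
    record is flagged (vst = nan); such records are excluded from
    rankings and means downstream.
    """
    a = np.asarray(values_pop1, dtype=float)
    b = np.asarray(values_pop2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputDataError("each population needs at least 2 values")
    v1 = float(np.var(a, ddof=1))
    v2 = float(np.var(b, ddof=1))
    pooled = np.concatenate([a, b])
    v_total = float(np.var(pooled, ddof=1))
    n1, n2 = a.size, b.size
    if v_total == 0.0:
        return VstRecord(pop1, pop2, n1, n2, v1, v2, v_total, float("nan"), False)
    within = (v1 * n1 + v2 * n2) / (n1 + n2)
    return VstRecord(pop1, pop2, n1, n2, v1, v2, v_total, (v_total - within) / v_total, True)


def read_population_map(path) -> dict[str, str]:
    """Two-column TSV ``individual  population``."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise InputDataError(f"{path}: expected individual and population columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


@dataclass
class VstScanResult:
    records: list[VstRecord]  # ranked descending by Vst (defined first)
    mean_vst: float  # over defined records
    top_k: list[VstRecord]
    top_fraction: list[VstRecord]

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "pop1": r.pop1,
                    "pop2": r.pop2,
                    "n_pop1": r.n_pop1,
                    "n_pop2": r.n_pop2,
                    "v_pop1": r.v_pop1,
                    "v_pop2": r.v_pop2,
                    "v_total": r.v_total,
                    "vst": r.vst,
                    "defined": r.defined,
                }
                for r in self.records
            ]
        )


def vst_scan(
    cnvrs: Sequence[CNVR],
    norm: NormalizedDepthMatrix,
    popmap: Mapping[str, str],
    pair: tuple[str, str],
    value_mode: Literal["rd", "log2"] = "rd",
    top_k: int = 5,
    top_fraction: float = 0.01,
) -> VstScanResult:
    """Vst per CNVR for one population pair, ranked descending.

    The per-individual value is the mean normalized depth over the grid
    windows the region spans (log2-transformed in ``log2`` mode, with
    zeros floored at 1/64 of a copy). Undefined records (zero pooled
    variance) are kept in the output but rank last and do not enter the
    mean. Both a top-k and a top-fraction selection are emitted.
    """
    p1, p2 = pair
    members1 = [i for i in norm.individuals if popmap.get(i) == p1]
    members2 = [i for i in norm.individuals if popmap.get(i) == p2]
    if len(members1) < 2 or len(members2) < 2:
        raise InputDataError(f"population pair {pair} needs >= 2 members each")
    if value_mode not in ("rd", "log2"):
        raise ParameterError(f"unknown value_mode {value_mode!r}")
    cols1 = [norm.individuals.index(i) for i in members1]
    cols2 = [norm.individuals.index(i) for i in members2]

    records: list[VstRecord] = []
    for r in cnvrs:
        idx = norm.grid.windows_overlapping(r.chrom, r.start, r.end)
        if len(idx) == 0:
            raise InputDataError(f"CNVR {r.chrom}:{r.start}-{r.end} off the grid")
        values = norm.values[idx].mean(axis=0)
        if value_mode == "log2":
            values = np.log2(np.maximum(values, 1.0 / 64.0))
        rec = vst(values[cols1], values[cols2], p1, p2)
        records.append(
            VstRecord(
                rec.pop1,
                rec.pop2,
                rec.n_pop1,
                rec.n_pop2,
                rec.v_pop1,
                rec.v_pop2,
                rec.v_total,
                rec.vst,
                rec.defined,
                chrom=r.chrom,
                start=r.start,
                end=r.end,
            )
        )
    records.sort(key=lambda r: (not r.defined, -(r.vst if r.defined else 0.0)))
    defined = [r for r in records if r.defined]
    mean_vst = float(np.mean([r.vst for r in defined])) if defined else float("nan")
    n_top = max(1, int(np.ceil(top_fraction * len(defined)))) if defined else 0
    return VstScanResult(
        records=records,
        mean_vst=mean_vst,
        top_k=defined[:top_k],
        top_fraction=defined[:n_top],
    )
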