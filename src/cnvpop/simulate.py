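"""Synthetic genomes, multi-population CNV truth sets, and noisy depth matrices.

The generator emulates the study design the pipeline is built for: three
populations of eight individuals sequenced at ~7x, an 800 bp window grid,
an L-shaped CNV length distribution over 0.8-8 kb, duplications about
three times as frequent as deletions, CNVRs shared by all populations or
private to one, and a few strongly divergent regions (carrier frequency
1.0 in one population, 0.0 elsewhere).

Depth noise models the per-window total base coverage as a Poisson count
(expectation mean_depth * window * copy_number/2), i.e. a clean Poisson
coverage process; a negative-binomial (gamma-Poisson) mode adds the
overdispersion real short-read data shows. A zero-noise mode supports
exact tests. Planted region boundaries snap to the window grid so truth
comparisons are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel, QTLRecord
from .errors import InputDataError, ParameterError
from .windows import GenomeLayout, RawDepthMatrix, WindowGrid, make_window_grid

__all__ = [
    "PlantedCNVR",
    "TruthSet",
    "simulate_genome",
    "simulate_populations",
    "simulate_depth",
    "evaluate_recovery",
    "write_gff3",
    "write_bed",
    "write_population_map",
    "write_truth_bed",
]


@dataclass(frozen=True)
class PlantedCNVR:
    """One simulated CNVR with integer copy numbers for its carriers."""

    chrom: str
    start: int
    end: int
    cnvr_type: str  # GAIN or LOSS
    copy_numbers: Mapping[str, int]  # carriers only; everyone else diploid
    frequencies: Mapping[str, float]  # per-population carrier frequency
    divergent: bool = False

    def copy_number(self, individual: str) -> int:
        return int(self.copy_numbers.get(individual, 2))

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TruthSet:
    """Planted CNVRs plus the population design they were planted into."""

    genome: GenomeLayout
    individuals: tuple[str, ...]
    populations: Mapping[str, tuple[str, ...]]
    regions: tuple[PlantedCNVR, ...]
    seed: int

    def popmap(self) -> dict[str, str]:
        return {ind: pop for pop, inds in self.populations.items() for ind in inds}


def simulate_genome(
    n_chromosomes: int = 3,
    chrom_length: int = 2_000_000,
    n_genes: int = 60,
    n_qtls: int = 12,
    window_size: int = 800,
    seed: int = 0,
    lengths: Sequence[int] | None = None,
) -> tuple[GenomeLayout, list[GeneModel], list[QTLRecord]]:
    """Random genome layout with non-overlapping genes and QTL intervals.

    Gene spans (2-20 kb, 1-10 exons) are placed uniformly without overlap;
    QTLs (10-100 kb) are placed independently and may overlap each other.
    """
    rng = np.random.default_rng(seed)
    if lengths is None:
        lengths = [chrom_length] * n_chromosomes
    for L in lengths:
        if L < 10 * window_size:
            raise ParameterError("chromosome shorter than 10 windows")
    genome = GenomeLayout.from_pairs(
        (f"chr{i + 1}", int(L)) for i, L in enumerate(lengths)
    )

    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}
    attempts = 0
    while len(genes) < n_genes:
        attempts += 1
        if attempts > 200 * max(n_genes, 1):
            raise ParameterError(
                f"could not place {n_genes} non-overlapping genes; density infeasible"
            )
        chrom = genome.names[rng.integers(len(genome.names))]
        span = int(rng.integers(2_000, 20_001))
        limit = genome.lengths[chrom] - span
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        end = start + span
        if any(start < e and s < end for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        n_exons = int(rng.integers(1, 11))
        cuts = np.sort(rng.choice(np.arange(1, span), size=2 * n_exons, replace=False))
        exons = tuple(
            (start + int(cuts[2 * i]), start + int(cuts[2 * i + 1]))
            for i in range(n_exons)
        )
        genes.append(
            GeneModel(
                gene_id=f"gene{len(genes) + 1}",
                chrom=chrom,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                exons=exons,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))

    qtls: list[QTLRecord] = []
    for i in range(n_qtls):
        chrom = genome.names[rng.integers(len(genome.names))]
        span = int(rng.integers(10_000, 100_001))
        span = min(span, genome.lengths[chrom] - 1)
        start = int(rng.integers(0, genome.lengths[chrom] - span))
        qtls.append(
            QTLRecord(f"qtl{i + 1}", f"trait{i % 5 + 1}", chrom, start, start + span)
        )
    qtls.sort(key=lambda q: (q.chrom, q.start))
    return genome, genes, qtls


def _draw_copy_number(rng: np.random.Generator, cnvr_type: str) -> int:
    if cnvr_type == "LOSS":
        return 1 if rng.random() < 0.8 else 0
    return 3 if rng.random() < 0.8 else 4


def simulate_populations(
    genome: GenomeLayout,
    grid: WindowGrid,
    n_per_pop: int = 8,
    pop_names: Sequence[str] = ("HTS", "VTS", "OTS"),
    n_shared: int = 30,
    n_unique: int = 10,
    n_divergent: int = 3,
    gain_fraction: float = 0.75,
    carrier_freq: float = 0.5,
    divergent_freqs: tuple[float, float] = (1.0, 0.0),
    divergent_copy_number: int | None = None,
    min_windows: int = 1,
    max_windows: int = 10,
    seed: int = 0,
    retry_cap: int = 1000,
) -> TruthSet:
    """Plant shared, population-private and divergent CNVRs on the grid.

    Region lengths in windows follow a truncated geometric distribution
    (p = 0.5), giving the L-shape observed for real CNV sizes. Types are
    GAIN with probability ``gain_fraction`` (duplications ~3x deletions at
    the 0.75 default). Carrier counts per population are round(freq * n);
    carrier copy numbers are drawn per carrier (LOSS: 1 or rarely 0; GAIN:
    3 or rarely 4) unless ``divergent_copy_number`` pins divergent ones.
    """
    rng = np.random.default_rng(seed)
    if not (1 <= min_windows <= max_windows):
        raise ParameterError("need 1 <= min_windows <= max_windows")
    individuals = tuple(
        f"{pop}_{i + 1}" for pop in pop_names for i in range(n_per_pop)
    )
    populations = {
        pop: tuple(f"{pop}_{i + 1}" for i in range(n_per_pop)) for pop in pop_names
    }

    slices = grid.chromosome_slices()
    chrom_names = list(slices)
    chrom_sizes = np.array([slices[c].stop - slices[c].start for c in chrom_names])
    # occupied window index ranges, padded by one window so planted regions
    # stay separated on the grid
    taken: list[tuple[int, int]] = []

    def _place(k: int) -> tuple[str, int, int] | None:
        for _ in range(retry_cap):
            ci = rng.choice(len(chrom_names), p=chrom_sizes / chrom_sizes.sum())
            sl = slices[chrom_names[ci]]
            n_avail = sl.stop - sl.start - k
            if n_avail <= 0:
                continue
            w0 = sl.start + int(rng.integers(0, n_avail + 1))
            if any(w0 - 1 < e and s < w0 + k + 1 for s, e in taken):
                continue
            taken.append((w0, w0 + k))
            return chrom_names[ci], w0, w0 + k
        return None

    def _length_windows() -> int:
        # truncated geometric, p=0.5: heavy at the minimum length
        while True:
            k = min_windows + int(rng.geometric(0.5)) - 1
            if k <= max_windows:
                return k

    plan: list[tuple[str, str | None]] = [("shared", None)] * n_shared
    for pop in pop_names:
        plan += [("unique", pop)] * n_unique
    for i in range(n_divergent):
        plan.append(("divergent", pop_names[i % len(pop_names)]))

    regions: list[PlantedCNVR] = []
    for kind, focal in plan:
        k = _length_windows()
        placed = _place(k)
        if placed is None:
            raise ParameterError(
                "could not place planted CNVRs without overlap; reduce counts or lengths"
            )
        chrom, w0, w1 = placed
        start = int(grid.windows["start"].iloc[w0])
        end = int(grid.windows["end"].iloc[w1 - 1])
        cnvr_type = "GAIN" if rng.random() < gain_fraction else "LOSS"
        freqs: dict[str, float] = {}
        for pop in pop_names:
            if kind == "shared":
                freqs[pop] = carrier_freq
            elif kind == "unique":
                freqs[pop] = carrier_freq if pop == focal else 0.0
            else:
                freqs[pop] = divergent_freqs[0] if pop == focal else divergent_freqs[1]
        copy_numbers: dict[str, int] = {}
        for pop in pop_names:
            n_car = int(round(freqs[pop] * n_per_pop))
            if n_car == 0:
                continue
            carriers = rng.choice(n_per_pop, size=n_car, replace=False)
            for ci in carriers:
                ind = populations[pop][int(ci)]
                if kind == "divergent":
                    # a fixed allele makes carriers homozygous: cn 4 / 0
                    if divergent_copy_number is not None:
                        copy_numbers[ind] = divergent_copy_number
                    else:
                        copy_numbers[ind] = 4 if cnvr_type == "GAIN" else 0
                else:
                    copy_numbers[ind] = _draw_copy_number(rng, cnvr_type)
        regions.append(
            PlantedCNVR(
                chrom=chrom,
                start=start,
                end=end,
                cnvr_type=cnvr_type,
                copy_numbers=copy_numbers,
                frequencies=freqs,
                divergent=(kind == "divergent"),
            )
        )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return TruthSet(genome, individuals, populations, tuple(regions), seed)


def simulate_depth(
    truth: TruthSet,
    grid: WindowGrid,
    mean_depth: float = 7.0,
    noise: str = "poisson",
    dispersion: float = 0.1,
    seed: int = 0,
) -> RawDepthMatrix:
    """Draw the raw depth matrix implied by a truth set.

    Expected depth per (window, individual) is mean_depth * copy_number/2.
    ``poisson`` draws the window's total base coverage as Poisson;
    ``negative-binomial`` mixes the Poisson rate with a gamma of the given
    dispersion (variance/mean^2 excess); ``none`` returns expectations
    exactly.
    """
    if mean_depth <= 0:
        raise ParameterError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    n_w, n_i = grid.n_windows, len(truth.individuals)
    cn = np.full((n_w, n_i), 2, dtype=np.int16)
    ind_index = {ind: j for j, ind in enumerate(truth.individuals)}
    for r in truth.regions:
        win = grid.windows_overlapping(r.chrom, r.start, r.end)
        for ind, c in r.copy_numbers.items():
            cn[win, ind_index[ind]] = c
    expected = mean_depth * cn / 2.0
    W = grid.window_size
    if noise == "none":
        values = expected
    elif noise == "poisson":
        values = rng.poisson(expected * W).astype(float) / W
    elif noise in ("negative-binomial", "negbin", "nb"):
        if dispersion <= 0:
            raise ParameterError("dispersion must be positive")
        rate = rng.gamma(1.0 / dispersion, dispersion * expected * W)
        values = rng.poisson(rate).astype(float) / W
    else:
        raise ParameterError(f"unknown noise mode {noise!r}")
    return RawDepthMatrix(grid, truth.individuals, values)


def evaluate_recovery(
    called: Sequence, truth: TruthSet
) -> tuple[float, float, pd.DataFrame]:
    """Region-level sensitivity/precision against the truth (>= 1 bp overlap).

    Sensitivity: fraction of planted regions hit by any call; precision:
    fraction of called regions hitting any planted region.
    """
    def _hits(a, b_set) -> bool:
        return any(
            a.chrom == b.chrom and a.start < b.end and b.start < a.end for b in b_set
        )

    n_truth = len(truth.regions)
    n_called = len(called)
    tp_truth = sum(1 for t in truth.regions if _hits(t, called))
    tp_called = sum(1 for c in called if _hits(c, truth.regions))
    sens = tp_truth / n_truth if n_truth else float("nan")
    prec = tp_called / n_called if n_called else float("nan")
    detail = pd.DataFrame(
        {
            "chrom": [t.chrom for t in truth.regions],
            "start": [t.start for t in truth.regions],
            "end": [t.end for t in truth.regions],
            "type": [t.cnvr_type for t in truth.regions],
            "recovered": [_hits(t, called) for t in truth.regions],
        }
    )
    return sens, prec, detail


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Emit gene + exon features (1-based inclusive, exons Parent=gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tcnvpop\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons):
                fh.write(
                    f"{g.chrom}\tcnvpop\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i + 1};Parent={g.gene_id}\n"
                )


def write_bed(records: Sequence[QTLRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.qtl_id}\t{r.trait}\n")


def write_population_map(truth: TruthSet, path) -> None:
    with open(path, "w") as fh:
        for pop, inds in truth.populations.items():
            for ind in inds:
                fh.write(f"{ind}\t{pop}\n")


def write_truth_bed(truth: TruthSet, path) -> None:
    """Planted regions as BED with type, frequencies and carrier copy numbers."""
    with open(path, "w") as fh:
        for r in truth.regions:
            freqs = ",".join(f"{p}:{f:g}" for p, f in r.frequencies.items())
            cns = ",".join(f"{i}:{c}" for i, c in sorted(r.copy_numbers.items()))
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.cnvr_type}\t{freqs}\t{cns or '.'}\n"
            )
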