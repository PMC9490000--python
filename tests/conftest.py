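import numpy as np
import pandas as pd
import pytest

from cnvpop.windows import (
    GenomeLayout,
    NormalizedDepthMatrix,
    WindowGrid,
    make_window_grid,
)


def build_norm(values, window_size=800, chrom="chr1", individuals=None):
    """NormalizedDepthMatrix from a raw (n_windows, n_individuals) array,
    one chromosome, stdev taken from the data (ddof=0)."""
    values = np.asarray(values, dtype=float)
    n_w, n_i = values.shape
    genome = GenomeLayout.from_pairs([(chrom, n_w * window_size)])
    grid = make_window_grid(genome, window_size)
    if individuals is None:
        individuals = tuple(f"s{j}" for j in range(n_i))
    return NormalizedDepthMatrix(
        grid, tuple(individuals), values, np.ones(n_i), values.std(axis=0, ddof=0)
    )


def vectors_with_exact_correlation(r, n, seed=0):
    """Two vectors whose sample Pearson correlation is exactly r."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = x - x.mean()
    x /= np.linalg.norm(x)
    z = z - z.mean()
    z -= (z @ x) * x
    z /= np.linalg.norm(z)
    y = r * x + np.sqrt(1.0 - r * r) * z
    return x, y


@pytest.fixture
def norm_factory():
    return build_norm


@pytest.fixture(scope="session")
def default_study():
    """A full synthetic study at the default design: 3 populations x 8
    individuals, ~7x depth, 800 bp windows, shared/unique/divergent CNVRs."""
    from cnvpop.simulate import simulate_depth, simulate_genome, simulate_populations
    from cnvpop.windows import normalize_depth

    genome, genes, qtls = simulate_genome(seed=11)
    grid = make_window_grid(genome, 800)
    truth = simulate_populations(genome, grid, seed=12)
    raw = simulate_depth(truth, grid, seed=13)
    norm = normalize_depth(raw)
    return {
        "genome": genome,
        "genes": genes,
        "qtls": qtls,
        "grid": grid,
        "truth": truth,
        "raw": raw,
        "norm": norm,
    }
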