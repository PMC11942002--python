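import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dermsig.expression import ExpressionMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_matrix(counts, lengths=None, groups=None, library_sizes=None):
    """Build an ExpressionMatrix from a plain 2-D array."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    genes = [f"G{i:03d}" for i in range(1, n_genes + 1)]
    samples = [f"S{j}" for j in range(1, n_samples + 1)]
    if groups is None:
        half = n_samples // 2
        groups = ["A"] * half + ["B"] * (n_samples - half)
    lengths = pd.Series(1000.0 if lengths is None else lengths, index=genes)
    lib = None if library_sizes is None else pd.Series(library_sizes, index=samples, dtype=float)
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_lengths=lengths,
        design=pd.Series(groups, index=samples),
        library_sizes=lib,
    )


@pytest.fixture
def toy_matrix():
    """6-sample matrix exercising the detectability rule: an all-zero gene,
    a gene with a single read in exactly 2 samples, and one in only 1."""
    counts = np.array(
        [
            [0, 0, 0, 0, 0, 0],  # never detected
            [1, 0, 0, 1, 0, 0],  # detected in 2 of 6
            [0, 0, 3, 0, 0, 0],  # detected in 1 of 6
            [50, 60, 55, 45, 52, 58],  # robustly expressed
            [5, 6, 4, 5, 7, 6],
        ]
    )
    return make_matrix(counts, groups=["A", "A", "A", "B", "B", "B"])


@pytest.fixture
def simple_de_table():
    """Hand-built DE table for ranking/classification unit tests."""
    return pd.DataFrame(
        {
            "fc": [2.0, 0.5, 1.0, 1.6, 1.2],
            "log2fc": np.log2([2.0, 0.5, 1.0, 1.6, 1.2]),
            "p": [0.001, 0.2, 0.5, 0.01, 0.001],
            "fdr": [0.01, 0.4, 0.7, 0.05, 0.001],
            "tested": [True] * 5,
        },
        index=pd.Index(["g1", "g2", "g3", "g4", "g5"], name="gene"),
    )


def simulate_two_group(
    seed,
    n_genes=2000,
    phi=0.1,
    planted=None,
    mean_range=(5.0, 2000.0),
    depth_factors=(0.85, 1.0, 1.2, 0.9, 1.1, 1.05),
):
    """Direct NB simulation of a 3 vs 3 comparison (independent of the
    package's own generator). ``planted`` is a list of (slice, log2FC)
    pairs applied to the second (treated) group."""
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), n_genes))
    lfc = np.zeros(n_genes)
    for sl, value in planted or []:
        lfc[sl] = value
    r = 1.0 / phi
    counts = np.empty((n_genes, 6), dtype=np.int64)
    for j, f in enumerate(depth_factors):
        mean = mu * f * (2.0**lfc if j >= 3 else 1.0)
        counts[:, j] = rng.negative_binomial(r, r / (r + mean))
    return make_matrix(counts, groups=["CTL"] * 3 + ["TRT"] * 3), lfc
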