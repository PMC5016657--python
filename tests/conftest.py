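"""Shared fixtures: small genotype datasets built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from landgen.genotypes import MISSING, GenotypeDataset


def make_dataset(n_per_cell, n_loci=3, n_alleles=4, cells=("A", "B"),
                 seed=0, missing_rate=0.0) -> GenotypeDataset:
    """Random diploid dataset with uniform allele draws per locus."""
    rng = np.random.default_rng(seed)
    individuals, cell_col, rows, coords = [], [], [], []
    if np.isscalar(n_per_cell):
        n_per_cell = [n_per_cell] * len(cells)
    for c, n in zip(cells, n_per_cell):
        g = rng.integers(1, n_alleles + 1, size=(n, n_loci, 2)).astype(np.int32)
        if missing_rate:
            miss = rng.random((n, n_loci)) < missing_rate
            g[miss] = MISSING
        rows.append(g)
        individuals += [f"{c}{i}" for i in range(n)]
        cell_col += [c] * n
        coords.append(rng.random((n, 2)) * 1000)
    return GenotypeDataset(individuals, [f"L{j}" for j in range(n_loci)],
                           np.concatenate(rows), np.array(cell_col, object),
                           np.concatenate(coords))


def dataset_from_calls(calls, cells=None, coords=None) -> GenotypeDataset:
    """Dataset from an explicit (n, L, 2) call array."""
    calls = np.asarray(calls, dtype=np.int32)
    n, L = calls.shape[:2]
    if cells is None:
        cells = ["A"] * n
    if coords is None:
        coords = np.zeros((n, 2))
    return GenotypeDataset([f"i{k}" for k in range(n)],
                           [f"L{j}" for j in range(L)], calls,
                           np.array(cells, object), np.asarray(coords, float))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
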