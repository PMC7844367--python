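"""Shared fixtures: programmatic random matrices and signatures."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from reoscore import DirectedGenePair, ExpressionMatrix, ReversalSignature


def make_matrix(
    rng: np.random.Generator,
    n_genes: int,
    n_samples: int,
    missing_frac: float = 0.0,
    tie_frac: float = 0.0,
    label: str = "synthetic",
) -> ExpressionMatrix:
    """Random gene-by-sample matrix; optional missing cells and value
    rounding (rounding induces within-sample ties)."""
    values = rng.normal(0.0, 1.0, size=(n_genes, n_samples)) * 3.0
    if tie_frac > 0:
        mask = rng.random(values.shape) < tie_frac
        values[mask] = np.round(values[mask])
    if missing_frac > 0:
        values[rng.random(values.shape) < missing_frac] = np.nan
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{j:03d}" for j in range(n_samples)]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), label)


def make_random_signature(
    rng: np.random.Generator, genes: list[str], n_pairs: int
) -> ReversalSignature:
    """Signature over random distinct unordered pairs with random
    directions."""
    entries = []
    seen = set()
    genes = list(genes)
    if n_pairs > len(genes) * (len(genes) - 1) // 2:
        raise ValueError("n_pairs exceeds the number of unordered pairs")
    while len(entries) < n_pairs:
        a, b = rng.choice(len(genes), size=2, replace=False)
        key = tuple(sorted((genes[a], genes[b])))
        if key in seen:
            continue
        seen.add(key)
        direction = "greater" if rng.random() < 0.5 else "less"
        entries.append(DirectedGenePair(key[0], key[1], direction))
    return ReversalSignature(entries)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture
def small_matrix(rng) -> ExpressionMatrix:
    return make_matrix(rng, 12, 8)
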