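"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import product
from math import comb, factorial, prod

import numpy as np
import pytest

from isotrace.chem import IsotopeTable


@pytest.fixture
def zero_abundance_table() -> IsotopeTable:
    """Isotope table with no heavy isotopes: natural patterns are deltas."""
    return IsotopeTable({el: [(0, 1.0)] for el in ("C", "H", "N", "O", "P", "S")})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240712)


# ---------------------------------------------------------------------------
# Independent oracles (dict-based polynomial arithmetic; no numpy convolution)

def _compositions(n: int, k: int):
    """All ways to split n atoms over k isotope species."""
    if k == 1:
        yield (n,)
        return
    for i in range(n + 1):
        for rest in _compositions(n - i, k - 1):
            yield (i,) + rest


def oracle_element_dist(pairs: list[tuple[int, float]], n: int) -> dict[int, float]:
    """Shift distribution of n atoms by exhaustive multinomial enumeration."""
    dist: dict[int, float] = {}
    for counts in _compositions(n, len(pairs)):
        coef = factorial(n) // prod(factorial(c) for c in counts)
        prob = coef * prod(a**c for (_, a), c in zip(pairs, counts))
        shift = sum(s * c for (s, _), c in zip(pairs, counts))
        dist[shift] = dist.get(shift, 0.0) + prob
    return dist


def dict_convolve(a: dict[int, float], b: dict[int, float]) -> dict[int, float]:
    out: dict[int, float] = {}
    for (s1, p1), (s2, p2) in product(a.items(), b.items()):
        out[s1 + s2] = out.get(s1 + s2, 0.0) + p1 * p2
    return out


def oracle_natural_dist(counts: dict[str, int], isotopes: IsotopeTable) -> dict[int, float]:
    """Natural shift distribution of a formula by brute-force enumeration."""
    total = {0: 1.0}
    for element, n in counts.items():
        dense = isotopes.distribution(element)
        pairs = [(s, a) for s, a in enumerate(dense) if a > 0]
        total = dict_convolve(total, oracle_element_dist(pairs, n))
    return total


def oracle_impurity_dist(j: int, purity: float) -> dict[int, float]:
    """Binomial mass placement for j designated atoms at the given purity."""
    return {s: comb(j, s) * purity**s * (1 - purity) ** (j - s) for s in range(j + 1)}


def dict_to_vector(dist: dict[int, float], length: int) -> np.ndarray:
    vec = np.zeros(length)
    for s, p in dist.items():
        if s < length:
            vec[s] = p
    return vec


def oracle_correction_column(
    counts: dict[str, int],
    element: str,
    j: int,
    purity: float,
    isotopes: IsotopeTable,
    rows: int,
    mode: str,
) -> np.ndarray:
    """One correction-matrix column by exhaustive enumeration."""
    col = oracle_impurity_dist(j, purity)
    remaining = {element: counts[element] - j} if counts[element] - j > 0 else {}
    if mode == "nominal":
        remaining.update({el: n for el, n in counts.items() if el != element})
    if remaining:
        col = dict_convolve(col, oracle_natural_dist(remaining, isotopes))
    return dict_to_vector(col, rows)
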