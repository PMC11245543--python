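"""Formula parsing and natural-isotope convolution arithmetic."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isotrace.chem import (
    FormulaError,
    IsotopeTable,
    as_mid,
    convolve,
    natural_mid,
    parse_formula,
)

from conftest import dict_to_vector, oracle_natural_dist

A13C = 0.0107


@pytest.mark.parametrize(
    "text, expected",
    [
        ("C3H7NO3", {"C": 3, "H": 7, "N": 1, "O": 3}),  # serine
        ("C16H32O2", {"C": 16, "H": 32, "O": 2}),  # palmitate
        ("C6H13O9P", {"C": 6, "H": 13, "O": 9, "P": 1}),  # G6P
        ("C", {"C": 1}),
    ],
)
def test_parse_formula(text, expected):
    assert dict(parse_formula(text).items()) == expected


@pytest.mark.parametrize("bad", ["", "X2", "C0", "c3", "C3-H7", "3C"])
def test_parse_formula_rejects_malformed(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


def test_isotope_table_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        IsotopeTable({"C": [(0, 0.9), (1, 0.2)]})
    with pytest.raises(ValueError, match="shift-0"):
        IsotopeTable({"C": [(1, 1.0)]})
    with pytest.raises(ValueError, match="most abundant"):
        IsotopeTable({"C": [(0, 0.4), (1, 0.6)]})


def test_isotope_table_csv_round_trip(tmp_path):
    csv = tmp_path / "isotopes.csv"
    csv.write_text("element,mass_shift,abundance\nC,0,0.99\nC,1,0.01\n")
    table = IsotopeTable.from_csv(csv)
    np.testing.assert_allclose(table.distribution("C"), [0.99, 0.01])


def test_natural_mid_single_carbon():
    mid = natural_mid(parse_formula("C"), max_shift=1)
    np.testing.assert_allclose(mid, [1 - A13C, A13C], atol=1e-15)


def test_natural_mid_two_carbons_binomial():
    mid = natural_mid(parse_formula("C2"), max_shift=2)
    expected = [(1 - A13C) ** 2, 2 * A13C * (1 - A13C), A13C**2]
    np.testing.assert_allclose(mid, expected, atol=1e-15)


def test_natural_mid_excluding_all_atoms_is_delta():
    mid = natural_mid(parse_formula("C3"), max_shift=2, exclude=("C", 3))
    np.testing.assert_allclose(mid, [1.0])


def test_natural_mid_exclude_exceeding_count_raises():
    with pytest.raises(ValueError, match="exclude"):
        natural_mid(parse_formula("C3"), max_shift=2, exclude=("C", 4))


def test_natural_mid_truncation_drops_mass_without_renormalizing():
    serine = parse_formula("C3H7NO3")
    full = natural_mid(serine, max_shift=40)
    assert full.sum() == pytest.approx(1.0, abs=1e-12)
    truncated = natural_mid(serine, max_shift=1)
    assert truncated.sum() < 1.0
    np.testing.assert_allclose(truncated, full[:2])


def test_natural_mid_of_disjoint_union_is_convolution():
    a = natural_mid(parse_formula("C3"), max_shift=30)
    b = natural_mid(parse_formula("H7NO3"), max_shift=30)
    union = natural_mid(parse_formula("C3H7NO3"), max_shift=30)
    conv = np.convolve(a, b)[: union.size]
    np.testing.assert_allclose(union, conv, atol=1e-12)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([1.0], [0.7, 0.3], [0.7, 0.3]),
        ([0.5, 0.5], [0.5, 0.5], [0.25, 0.5, 0.25]),
        ([0.9, 0.1], [0.8, 0.2], [0.72, 0.26, 0.02]),
    ],
)
def test_convolve_examples(a, b, expected):
    np.testing.assert_allclose(convolve(a, b), expected, atol=1e-15)


mids = st.lists(st.floats(0.01, 1.0), min_size=1, max_size=5).map(
    lambda v: list(np.asarray(v) / np.sum(v))
)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(a=mids, b=mids, c=mids)
def test_convolve_commutative_associative(a, b, c):
    ab = convolve(a, b)
    np.testing.assert_allclose(ab, convolve(b, a), atol=1e-12)
    np.testing.assert_allclose(
        np.convolve(ab, c), np.convolve(np.asarray(a), convolve(b, c)), atol=1e-12
    )
    assert np.convolve(ab, c).sum() == pytest.approx(1.0, abs=1e-9)


def test_as_mid_rejects_invalid():
    with pytest.raises(ValueError):
        as_mid([0.5, 0.4])  # does not sum to 1
    with pytest.raises(ValueError):
        as_mid([1.5, -0.5])
    with pytest.raises(ValueError):
        as_mid([np.nan, 1.0])


def test_natural_mid_matches_multinomial_enumeration(rng):
    """Convolution engine against brute-force enumeration on small formulas."""
    isotopes = IsotopeTable.default()
    for _ in range(8):
        counts = {}
        budget = 12
        for el in rng.permutation(["C", "H", "N", "O", "S"])[:3]:
            n = int(rng.integers(1, budget + 1))
            counts[el] = n
            budget -= n
            if budget < 1:
                break
        formula = parse_formula("".join(f"{el}{n}" for el, n in counts.items()))
        mid = natural_mid(formula, max_shift=10, isotopes=isotopes)
        oracle = dict_to_vector(oracle_natural_dist(counts, isotopes), mid.size)
        np.testing.assert_allclose(mid, oracle, atol=1e-12)
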