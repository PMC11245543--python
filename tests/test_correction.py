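"""Correction-matrix construction and NNLS inversion."""

from __future__ import annotations

import numpy as np
import pytest

from isotrace.chem import IsotopeTable, natural_mid, parse_formula
from isotrace.correction import TracerSpec, build_correction_matrix, correct_intensities

from conftest import oracle_correction_column

A = 0.0107  # 13C natural abundance


def test_perfect_tracer_no_interference_gives_identity(zero_abundance_table):
    m = build_correction_matrix(
        parse_formula("C2"), TracerSpec("C", 2, 1.0), mode="nominal",
        isotopes=zero_abundance_table,
    )
    np.testing.assert_allclose(m.entries, np.eye(3), atol=1e-15)


def test_high_res_columns_are_binomial_in_unlabeled_carbons():
    m = build_correction_matrix(parse_formula("C2"), TracerSpec("C", 2, 1.0), mode="high_res")
    np.testing.assert_allclose(m.entries[:, 0], [(1 - A) ** 2, 2 * A * (1 - A), A**2], atol=1e-15)
    np.testing.assert_allclose(m.entries[:, 1], [0.0, 1 - A, A], atol=1e-15)
    np.testing.assert_allclose(m.entries[:, 2], [0.0, 0.0, 1.0], atol=1e-15)


def test_impurity_binomial_column(zero_abundance_table):
    m = build_correction_matrix(
        parse_formula("C"), TracerSpec("C", 1, 0.99), isotopes=zero_abundance_table
    )
    np.testing.assert_allclose(m.entries[:, 1], [0.01, 0.99], atol=1e-12)


def test_nominal_mode_includes_other_elements():
    serine = parse_formula("C3H7NO3")
    tracer = TracerSpec("C", 3, 1.0)
    nominal = build_correction_matrix(serine, tracer, mode="nominal")
    high_res = build_correction_matrix(serine, tracer, mode="high_res")
    # the fully labeled column picks up H/N/O interference only in nominal mode
    assert nominal.entries[3, 3] < high_res.entries[3, 3] == 1.0
    # untruncated columns carry all their mass
    full = build_correction_matrix(serine, tracer, mode="nominal", max_shift=40)
    np.testing.assert_allclose(full.entries.sum(axis=0), np.ones(4), atol=1e-9)
    assert np.all(nominal.entries.sum(axis=0) <= 1 + 1e-12)


def test_matrix_matches_enumeration_oracle(rng):
    isotopes = IsotopeTable.default()
    serine = parse_formula("C3H7NO3")
    for mode in ("nominal", "high_res"):
        for element, n in (("C", 3), ("H", 3)):
            tracer = TracerSpec(element, n, 0.97)
            m = build_correction_matrix(serine, tracer, mode=mode, max_shift=5, isotopes=isotopes)
            counts = dict(serine.items())
            for j in range(n + 1):
                expected = oracle_correction_column(counts, element, j, 0.97, isotopes, 6, mode)
                np.testing.assert_allclose(m.entries[:, j], expected, atol=1e-12)


def test_build_matrix_input_validation():
    with pytest.raises(ValueError, match="fewer than"):
        build_correction_matrix(parse_formula("C2"), TracerSpec("C", 3, 1.0))
    with pytest.raises(ValueError, match="max_shift"):
        build_correction_matrix(parse_formula("C2"), TracerSpec("C", 2, 1.0), max_shift=-1)
    with pytest.raises(ValueError, match="mode"):
        build_correction_matrix(parse_formula("C2"), TracerSpec("C", 2, 1.0), mode="orbitrap")


def test_correct_identity_matrix_returns_normalized_fractions(zero_abundance_table):
    m = build_correction_matrix(
        parse_formula("C"), TracerSpec("C", 1, 1.0), isotopes=zero_abundance_table
    )
    out = correct_intensities([80.0, 20.0], m)
    np.testing.assert_allclose(out.fractions, [0.8, 0.2], atol=1e-12)
    assert out.residual_norm == pytest.approx(0.0, abs=1e-9)
    assert out.raw_total == pytest.approx(100.0)


def test_unlabeled_standard_corrects_to_delta():
    m = build_correction_matrix(parse_formula("C2"), TracerSpec("C", 2, 1.0))
    raw = 1e6 * np.array([(1 - A) ** 2, 2 * A * (1 - A), A**2])
    out = correct_intensities(raw, m)
    np.testing.assert_allclose(out.fractions, [1.0, 0.0, 0.0], atol=1e-8)


def test_round_trip_recovery_across_scales(rng):
    """Noise-free forward simulations invert exactly over 6 orders of magnitude."""
    formulas = ["C3H7NO3", "C6H13O9P", "C16H32O2", "C2H5NO2"]
    for text in formulas:
        formula = parse_formula(text)
        for element in ("C", "H"):
            n = min(formula.get(element), 6)
            tracer = TracerSpec(element, n, 0.985)
            m = build_correction_matrix(formula, tracer, max_shift=n + 2)
            x_true = rng.dirichlet(np.ones(n + 1))
            for scale in (1e5, 1e6, 1e8):
                raw = scale * (m.entries @ x_true)
                out = correct_intensities(raw, m)
                np.testing.assert_allclose(out.fractions, x_true, atol=1e-7)
                assert out.residual_norm == pytest.approx(0.0, abs=1e-6 * scale)


def test_recovery_under_multiplicative_noise(rng):
    """Median |error| of recovered fractions < 0.01 at 2% intensity noise."""
    formula = parse_formula("C3H7NO3")
    tracer = TracerSpec("C", 3, 0.99)
    m = build_correction_matrix(formula, tracer)
    x_true = np.array([0.55, 0.25, 0.12, 0.08])
    cv = 0.02
    sigma = np.sqrt(np.log1p(cv**2))
    errors = []
    for _ in range(500):
        noise = rng.lognormal(-0.5 * sigma**2, sigma, size=4)
        raw = 1e6 * (m.entries @ x_true) * noise
        out = correct_intensities(raw, m)
        errors.append(np.abs(out.fractions - x_true).max())
    assert np.median(errors) < 0.01
    assert np.all([e >= 0 for e in errors])


def test_correct_intensities_input_validation():
    m = build_correction_matrix(parse_formula("C2"), TracerSpec("C", 2, 1.0))
    with pytest.raises(ValueError, match="length"):
        correct_intensities([1.0, 2.0], m)
    with pytest.raises(ValueError, match="all zero"):
        correct_intensities([0.0, 0.0, 0.0], m)
    with pytest.raises(ValueError, match="nonnegative"):
        correct_intensities([1.0, -2.0, 1.0], m)
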