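"""Forward simulator: determinism, conservation and round-trip recovery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from isotrace.chem import parse_formula
from isotrace.correction import TracerSpec, build_correction_matrix, correct_intensities
from isotrace.nadph import active_h_labeling
from isotrace.simulate import (
    GroupSpec,
    SimConfig,
    default_groups,
    simulate_cohort,
    simulate_measurement,
    simulate_nadph_pair,
    simulate_true_mid,
)


@pytest.mark.parametrize(
    "n, e, expected",
    [
        (3, 0.0, [1, 0, 0, 0]),
        (1, 0.4, [0.6, 0.4]),
        (2, 0.5, [0.25, 0.5, 0.25]),
    ],
)
def test_simulate_true_mid_binomial(n, e, expected):
    np.testing.assert_allclose(simulate_true_mid(n, e), expected, atol=1e-12)


def test_simulate_measurement_noise_free_is_proportional_to_forward_model():
    formula = parse_formula("C3H7NO3")
    tracer = TracerSpec("C", 3, 0.99)
    true_mid = simulate_true_mid(3, 0.2)
    raw = simulate_measurement(true_mid, formula, tracer, 0.0, np.random.default_rng(0))
    m = build_correction_matrix(formula, tracer, max_shift=3)
    expected = m.entries @ true_mid
    np.testing.assert_allclose(raw / raw.sum(), expected / expected.sum(), atol=1e-12)
    # and correction inverts it
    out = correct_intensities(raw, m)
    np.testing.assert_allclose(out.fractions, true_mid, atol=1e-7)


def test_simulate_measurement_deterministic_under_seed():
    formula = parse_formula("C3H7NO3")
    tracer = TracerSpec("C", 3, 0.99)
    true_mid = simulate_true_mid(3, 0.2)
    a = simulate_measurement(true_mid, formula, tracer, 0.05, np.random.default_rng(7))
    b = simulate_measurement(true_mid, formula, tracer, 0.05, np.random.default_rng(7))
    np.testing.assert_array_equal(a, b)


def test_nadph_pair_mixture_structure():
    nadp = np.array([0.8, 0.2])
    _, _, nadph_true = simulate_nadph_pair(nadp, 0.3, 0.0, np.random.default_rng(0))
    np.testing.assert_allclose(nadph_true, [0.56, 0.38, 0.06], atol=1e-12)
    _, _, unlabeled = simulate_nadph_pair(nadp, 0.0, 0.0, np.random.default_rng(0))
    np.testing.assert_allclose(unlabeled, [0.8, 0.2, 0.0], atol=1e-12)


def test_nadph_pair_full_round_trip_noise_free():
    """simulate -> correct -> deconvolve returns the true p exactly."""
    from isotrace.simulate import NADP_FORMULA, NADPH_FORMULA

    rng = np.random.default_rng(3)
    nadp_true = simulate_true_mid(2, 0.05)
    p_true = 0.12
    nadp_raw, nadph_raw, _ = simulate_nadph_pair(nadp_true, p_true, 0.0, rng, purity=0.99)
    m_nadp = build_correction_matrix(parse_formula(NADP_FORMULA), TracerSpec("H", 2, 0.99), max_shift=2)
    m_nadph = build_correction_matrix(parse_formula(NADPH_FORMULA), TracerSpec("H", 3, 0.99), max_shift=3)
    nadp_c = correct_intensities(nadp_raw, m_nadp).fractions
    nadph_c = correct_intensities(nadph_raw, m_nadph).fractions
    res = active_h_labeling(nadp_c, nadph_c)
    assert res.p == pytest.approx(p_true, abs=1e-7)


def test_simulated_intensities_are_nonnegative_and_true_mids_normalized(tmp_path):
    paths = simulate_cohort(SimConfig(seed=5, n_per_group=2), tmp_path / "cohort")
    for peaks in (paths.peaks_serine_c13, paths.peaks_nadph_h2, paths.peaks_fatty_acids_h2):
        df = pd.read_csv(peaks)
        values = df.drop(columns=["compound", "formula", "isotopeLabel"]).to_numpy()
        assert np.all(values >= 0)
    truth = pd.read_csv(paths.ground_truth)
    assert set(truth["group"]) == {"WT", "KO"}
    assert len(truth) == 4


def test_cohort_recovery_of_group_means(tmp_path):
    """p and enrichment group means recovered within 0.01 at the study conditions."""
    from isotrace.pipeline import run_pipeline

    paths = simulate_cohort(SimConfig(seed=11, n_per_group=8, noise_cv=0.02), tmp_path / "c")
    out = run_pipeline(paths.pipeline_config)
    summary = pd.read_csv(out / "active_h_summary.csv").set_index("group")
    assert summary.loc["WT", "mean_p"] == pytest.approx(0.05, abs=0.01)
    assert summary.loc["KO", "mean_p"] == pytest.approx(0.15, abs=0.01)
    metrics = pd.read_csv(out / "labeling_metrics.csv")
    serine = metrics[(metrics["track"] == "serine_c13") & (metrics["compound"] == "serine")]
    wt = serine[serine["sample"].str.startswith("WT")]["fractional_enrichment"].mean()
    assert wt == pytest.approx(0.15, abs=0.01)  # per-atom 13C enrichment of tumor serine


def test_identical_groups_show_no_systematic_p_difference(tmp_path):
    """Null cohort: the WT-KO difference in estimated p averages to zero."""
    from isotrace.pipeline import run_pipeline

    wt, ko = default_groups()
    null_ko = GroupSpec(**{**ko.__dict__, "p_active_h": wt.p_active_h})
    diffs = []
    for seed in range(4):
        cfg = SimConfig(seed=seed, n_per_group=4, groups=(wt, null_ko), noise_cv=0.02)
        paths = simulate_cohort(cfg, tmp_path / f"null_{seed}")
        out = run_pipeline(paths.pipeline_config)
        s = pd.read_csv(out / "active_h_summary.csv").set_index("group")
        diffs.append(s.loc["KO", "mean_p"] - s.loc["WT", "mean_p"])
    assert abs(np.mean(diffs)) < 0.005


def test_sim_config_validation():
    with pytest.raises(ValueError):
        SimConfig(n_per_group=0)
    with pytest.raises(ValueError):
        SimConfig(noise_cv=-0.1)
    with pytest.raises(ValueError):
        GroupSpec(
            name="bad", p_active_h=1.5, serum_enrichment=0.4,
            serine_c13_enrichment=0.1, serine_h2_enrichment=0.1,
            fa_new_fraction=0.1, fa_h2_incorporation=0.05,
        )
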