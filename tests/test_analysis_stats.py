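"""Binned summaries, ECDFs, stratified correlations, group tests, corners."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from polarix.analysis_stats import (
    CORNER_LABELS,
    binned_summary,
    classify_age_corners,
    ecdf,
    group_compare,
    run_full_analysis,
    snp_vs_background,
    stratified_correlation,
)


class TestBinnedSummary:
    def test_hand_computed_mean_and_sem(self):
        bs = binned_summary([1.0, 2.0, 3.0], [1, 1, 1])
        row = bs.table.iloc[0]
        assert (row["bin"], row["n"]) == (1, 3)
        assert row["mean"] == pytest.approx(2.0)
        assert row["sem"] == pytest.approx(1 / np.sqrt(3))

    def test_singleton_bin_has_undefined_sem(self):
        bs = binned_summary([5.0], [2])
        assert np.isnan(bs.table.iloc[0]["sem"])

    def test_constant_values_zero_sem(self):
        bs = binned_summary([4.0, 4.0, 4.0], [3, 3, 3])
        assert bs.table.iloc[0]["sem"] == 0.0

    def test_empty_bins_missing_not_zero(self):
        bs = binned_summary([1.0, 2.0], [1, 8])
        assert list(bs.table["bin"]) == [1, 8]

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            binned_summary([np.nan], [1])


class TestECDF:
    def test_jump_heights_with_ties(self):
        F = ecdf([1, 2, 2, 3])
        assert F(2) == 0.75
        assert F(0.5) == 0.0
        assert F(3) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ecdf([])

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=60))
    def test_is_a_valid_cdf(self, xs):
        F = ecdf(xs)
        grid = np.linspace(min(xs) - 1, max(xs) + 1, 50)
        vals = F(grid)
        assert (np.diff(vals) >= 0).all()
        assert 0 <= vals.min() and vals.max() == 1.0


class TestStratifiedCorrelation:
    def test_sign_flip_identity_case(self):
        rng = np.random.default_rng(0)
        daf = rng.uniform(0.01, 0.99, 400)
        score = -daf  # strictly decreasing in DAF, no noise
        maf = np.minimum(daf, 1 - daf)
        mid = daf <= 0.5
        t = stratified_correlation(maf, score, mid, daf).set_index("stratum")
        assert t.loc["derived_minor", "rho"] == pytest.approx(-1.0)
        assert t.loc["ancestral_minor", "rho"] == pytest.approx(1.0)
        assert t.loc["pooled_daf", "rho"] == pytest.approx(-1.0)

    def test_null_is_near_zero(self):
        rng = np.random.default_rng(1)
        maf = rng.uniform(0, 0.5, 1000)
        score = rng.normal(size=1000)
        mid = rng.random(1000) < 0.5
        t = stratified_correlation(maf, score, mid).set_index("stratum")
        assert abs(t.loc["derived_minor", "rho"]) < 0.1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            stratified_correlation(
                np.full(40, 0.2), np.arange(40.0), np.array([True] * 20 + [False] * 20)
            )

    def test_small_stratum_rejected(self):
        with pytest.raises(ValueError):
            stratified_correlation(
                np.linspace(0, 0.5, 12), np.arange(12.0),
                np.array([True] * 9 + [False] * 3),
            )


class TestGroupCompare:
    def test_identical_groups_null(self):
        vals = np.concatenate([np.arange(50.0), np.arange(50.0)])
        flag = np.array([True] * 50 + [False] * 50)
        stat, p, direction = group_compare(vals, flag)
        assert p > 0.9 and direction == "none"

    def test_label_swap_flips_direction_keeps_p(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(0, 1, 60), rng.normal(1, 1, 60)])
        flag = np.array([True] * 60 + [False] * 60)
        s1, p1, d1 = group_compare(vals, flag, test="t")
        s2, p2, d2 = group_compare(vals, ~flag, test="t")
        assert p1 == pytest.approx(p2)
        assert {d1, d2} == {"group_true_higher", "group_true_lower"}

    def test_wilcoxon_detects_shift(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0, 1, 200), rng.normal(0.8, 1, 200)])
        flag = np.array([True] * 200 + [False] * 200)
        _, p, direction = group_compare(vals, flag)
        assert p < 1e-6 and direction == "group_true_lower"

    def test_t_requires_two_per_group(self):
        with pytest.raises(ValueError):
            group_compare(np.array([1.0, 2.0, 3.0]), np.array([True, False, False]), "t")


class TestSnpVsBackground:
    def test_null_difference_near_zero(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=2000), rng.normal(size=2000)
        res = snp_vs_background(a, b)
        assert abs(res["background_minus_snp"]) < 0.15
        assert res["p"] > 0.001

    def test_reports_background_minus_snp(self):
        res = snp_vs_background(np.zeros(50) + 1.0, np.zeros(50) + 3.0)
        assert res["background_minus_snp"] == pytest.approx(2.0)


class TestCorners:
    @pytest.mark.parametrize(
        "age,daf,expected",
        [
            (200, 0.9, "quick_running"),
            (800, 0.1, "slow_running"),
            (800, 0.9, "old_high"),
            (200, 0.1, "young_low"),
            (500, 0.5, "interior"),
            (300, 0.9, "interior"),  # strict inequality at the age edge
            (200, 0.8, "interior"),  # strict inequality at the DAF edge
        ],
    )
    def test_labels(self, age, daf, expected):
        assert classify_age_corners(age, daf) == expected

    def test_missing_age_excluded(self):
        assert classify_age_corners(None, 0.5) is None
        assert classify_age_corners(float("nan"), 0.5) is None

    def test_labels_partition_plane(self):
        rng = np.random.default_rng(5)
        for _ in range(500):
            lab = classify_age_corners(rng.uniform(0, 1500), rng.uniform(0.01, 0.99))
            assert lab in CORNER_LABELS


def _toy_cohort(n=400, seed=0):
    rng = np.random.default_rng(seed)
    daf = rng.uniform(0.001, 0.999, n)
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(n)],
            "maf": np.minimum(daf, 1 - daf),
            "daf": daf,
            "minor_is_derived": daf <= 0.5,
            "site_class": rng.choice(["utr5", "utr3", "syn", "nonsyn"], n),
            "in_tis": rng.random(n) < 0.1,
            "in_ss": rng.random(n) < 0.05,
            "daf_bin": rng.integers(1, 9, n),
            "cons_score": 5 - 3 * daf + rng.normal(0, 1, n),
            "age_ky": (1000 * daf + rng.normal(0, 100, n)).clip(0, None),
            "grantham": np.where(
                rng.random(n) < 0.5, rng.exponential(50, n), np.nan
            ),
            "rel_entropy": rng.exponential(1, n),
            "mfe_gap": rng.exponential(1, n),
            "bpp_distance": rng.exponential(0.5, n),
            "delta_codon_optimality": rng.exponential(1, n),
            "hydrophobicity_delta": rng.exponential(0.5, n),
            "blosum62": rng.integers(-4, 5, n).astype(float),
            "omega_mouse": rng.lognormal(-2, 0.8, n),
            "essential": rng.random(n) < 0.1,
            "mendelian": rng.random(n) < 0.3,
        }
    )


class TestRunFullAnalysis:
    def test_six_tables_and_determinism(self):
        cohort = _toy_cohort()
        t1 = run_full_analysis(cohort)
        t2 = run_full_analysis(cohort.copy())
        assert list(t1) == [
            "score_correlations",
            "protein_effects_by_daf",
            "structure_effects_by_daf",
            "codon_optimality_by_daf",
            "regional_daf",
            "age_daf_corners",
        ]
        for name in t1:
            pd.testing.assert_frame_equal(t1[name], t2[name])

    def test_missing_column_names_the_column(self):
        with pytest.raises(KeyError, match="daf_bin"):
            run_full_analysis(_toy_cohort().drop(columns=["daf_bin"]))

    def test_background_contrast_present(self):
        cohort = _toy_cohort()
        bg = _toy_cohort(300, seed=1)
        bg["grantham"] = bg["grantham"] + 30  # background strictly larger
        tables = run_full_analysis(cohort, bg)
        prot = tables["protein_effects_by_daf"]
        row = prot[(prot["metric"] == "grantham") & (prot["kind"] == "snp_vs_background")]
        assert len(row) == 1
        assert row["value"].iloc[0] > 0
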