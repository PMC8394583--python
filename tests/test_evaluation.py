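"""Metrics, acquisition-time arithmetic and the ordinal statistics, with
brute-force enumeration oracles for the exact Wilcoxon null and hand-computed
confusion tables for kappa."""

import itertools

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from mskrecon.evaluation import (
    SequenceTiming,
    amplitude_fit,
    cohen_kappa,
    kappa_band,
    load_timing_table,
    nrmse,
    parse_ta,
    psnr,
    summarize_savings,
    time_saving,
    wilcoxon_signed_rank,
)


class TestImageMetrics:
    def test_identical_images(self):
        img = np.random.default_rng(0).random((16, 16))
        assert nrmse(img, img) == 0.0
        assert psnr(img, img) == 300.0

    def test_constant_offset_closed_form(self):
        b = np.full((10, 10), 2.0)
        a = b + 0.5
        assert nrmse(a, b) == pytest.approx(0.5 / 2.0)
        # PSNR with peak 2: 20 log10(2) - 10 log10(0.25)
        assert psnr(a, b) == pytest.approx(
            20 * np.log10(2.0) - 10 * np.log10(0.25)
        )

    def test_psnr_monotone_in_error(self):
        rng = np.random.default_rng(1)
        t = rng.random((32, 32))
        noisy = [t + s * rng.standard_normal(t.shape) for s in (0.01, 0.1, 0.5)]
        vals = [psnr(n, t) for n in noisy]
        assert vals[0] > vals[1] > vals[2]

    def test_amplitude_fit_removes_global_scale(self):
        rng = np.random.default_rng(2)
        t = rng.random((16, 16))
        assert np.allclose(amplitude_fit(3.7 * t, t), t)


class TestTimeSavings:
    def test_packaged_table_shape_and_extrema(self):
        table = load_timing_table()
        assert len(table) == 12
        s = summarize_savings(table)
        assert s["max_percent"] == 75  # hand coronal 2:23 -> 0:36
        assert s["min_percent"] == 2  # ankle sagittal 1:47 -> 1:45

    def test_hand_coronal_pair(self):
        t = SequenceTiming("hand", "PD FS", "coronal", parse_ta("2:23"), parse_ta("0:36"))
        assert time_saving(t) == pytest.approx(100 * (1 - 36 / 143))
        assert round(time_saving(t)) == 75

    def test_shoulder_axial_pair(self):
        t = SequenceTiming("shoulder", "PD FS", "axial", parse_ta("2:14"), parse_ta("1:10"))
        assert time_saving(t) == pytest.approx(100 * (1 - 70 / 134))

    def test_equal_times_zero_and_validation(self):
        t = SequenceTiming("x", "y", "z", 60, 60)
        assert time_saving(t) == 0.0
        with pytest.raises(ValueError):
            time_saving(SequenceTiming("x", "y", "z", 0, 10))

    def test_summary_permutation_invariant_and_single_entry(self):
        table = load_timing_table()
        fwd = summarize_savings(table)
        rev = summarize_savings(table[::-1])
        assert fwd["max_percent"] == rev["max_percent"]
        assert fwd["min_percent"] == rev["min_percent"]
        one = summarize_savings(table[:1])
        assert one["max_percent"] == one["min_percent"]


def brute_force_wilcoxon(a, b, alternative="two-sided"):
    """Enumerate all 2^n sign assignments of the ranked |differences|."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=len(d))
    ]
    ws = np.asarray(ws, float)
    ge = np.mean(ws >= w_obs - 1e-12)
    le = np.mean(ws <= w_obs + 1e-12)
    if alternative == "greater":
        return w_obs, ge
    if alternative == "less":
        return w_obs, le
    return w_obs, min(1.0, 2 * min(ge, le))


class TestWilcoxon:
    def test_six_positive_distinct_one_sided(self):
        a = np.array([2, 3, 4, 5, 6, 7], float)
        b = np.array([1, 1, 1, 1, 1, 1], float)
        res = wilcoxon_signed_rank(a, b, alternative="greater")
        assert res.statistic == 21.0
        assert res.p_value == pytest.approx(1 / 64)

    def test_all_tied_flagged(self):
        with pytest.raises(ValueError, match="tied"):
            wilcoxon_signed_rank(np.ones(6), np.ones(6))

    @settings(derandomize=True, max_examples=40)
    @given(
        scores=st.lists(
            st.tuples(st.integers(1, 4), st.integers(1, 4)), min_size=5, max_size=10
        ),
        alternative=st.sampled_from(["two-sided", "greater", "less"]),
    )
    def test_exact_matches_enumeration_on_ordinal_data(self, scores, alternative):
        a = np.array([s[0] for s in scores], float)
        b = np.array([s[1] for s in scores], float)
        if np.all(a == b):
            return
        res = wilcoxon_signed_rank(a, b, alternative)
        w, p = brute_force_wilcoxon(a, b, alternative)
        assert res.statistic == pytest.approx(w)
        assert res.p_value == pytest.approx(p)

    def test_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(12)
        b = rng.standard_normal(12)
        res = wilcoxon_signed_rank(a, b)
        ref = scipy.stats.wilcoxon(a, b, method="exact")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_invariant_under_monotone_affine_relabeling(self):
        rng = np.random.default_rng(1)
        a = rng.integers(1, 5, 10).astype(float)
        b = rng.integers(1, 5, 10).astype(float)
        if np.all(a == b):
            a[0] += 1
        base = wilcoxon_signed_rank(a, b)
        relab = wilcoxon_signed_rank(3 * a + 2, 3 * b + 2)
        assert base.statistic == relab.statistic
        assert base.p_value == relab.p_value

    def test_normal_approximation_close_to_exact_at_boundary(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(26) + 0.5  # just above the exact cutoff
        b = rng.standard_normal(26)
        res = wilcoxon_signed_rank(a, b)
        assert res.method == "normal"
        ref = scipy.stats.wilcoxon(a, b, method="approx", correction=True)
        assert res.p_value == pytest.approx(ref.pvalue, rel=0.02)


class TestCohenKappa:
    def test_perfect_agreement(self):
        r = np.array([1, 2, 3, 4, 1, 2])
        res = cohen_kappa(r, r)
        assert res.kappa == 1.0 and res.band == "(almost) perfect"

    def test_two_by_two_hand_formula(self):
        # 40 cases: 15 agree-A, 15 agree-B, 5+5 disagreements
        a = ["A"] * 15 + ["B"] * 15 + ["A"] * 5 + ["B"] * 5
        b = ["A"] * 15 + ["B"] * 15 + ["B"] * 5 + ["A"] * 5
        p_o = 30 / 40
        p_e = (20 / 40) ** 2 + (20 / 40) ** 2
        res = cohen_kappa(np.array(a), np.array(b))
        assert res.kappa == pytest.approx((p_o - p_e) / (1 - p_e))
        assert res.band == "moderate"

    def test_independence_structured_table_near_zero(self):
        # product-marginal table: every (i, j) cell count = row_i * col_j
        a, b = [], []
        for i, ni in enumerate([1, 2, 3]):
            for j, nj in enumerate([1, 2, 3]):
                a += [i] * (ni * nj)
                b += [j] * (ni * nj)
        res = cohen_kappa(np.array(a), np.array(b))
        assert abs(res.kappa) < 1e-12

    def test_symmetric_and_relabel_invariant(self):
        rng = np.random.default_rng(3)
        a = rng.integers(1, 5, 60)
        b = np.clip(a + rng.integers(-1, 2, 60), 1, 4)
        assert cohen_kappa(a, b).kappa == pytest.approx(cohen_kappa(b, a).kappa)
        relabel = {1: 10, 2: 20, 3: 30, 4: 40}
        a2 = np.array([relabel[v] for v in a])
        b2 = np.array([relabel[v] for v in b])
        assert cohen_kappa(a2, b2).kappa == pytest.approx(cohen_kappa(a, b).kappa)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(4)
        a = rng.integers(1, 5, 80)
        b = np.clip(a + rng.integers(-1, 2, 80), 1, 4)
        assert cohen_kappa(a, b).kappa == pytest.approx(cohen_kappa_score(a, b))

    def test_degenerate_constant_raters_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            cohen_kappa(np.ones(10, int), np.ones(10, int))

    def test_band_cut_points(self):
        assert kappa_band(0.10) == "poor"
        assert kappa_band(0.30) == "fair"
        assert kappa_band(0.55) == "moderate"
        assert kappa_band(0.634) == "substantial"
        assert kappa_band(0.923) == "(almost) perfect"
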