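"""Normalization, contrasts, BH correction, QC, ddCt."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressmir import CountMatrix, diffexpr, simulate
from stressmir.diffexpr import (
    bh_adjust,
    contrast,
    ddct_fold_change,
    estimate_dispersion,
    filter_detected,
    median_ratio_size_factors,
    replicate_qc,
    size_factors,
    volcano_table,
)


def brute_force_bh(p):
    """Independent step-up oracle: q(i) = min_{j>=i} p(j)*m/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def _cm(counts, conditions, replicates=None):
    counts = pd.DataFrame(counts)
    if replicates is None:
        replicates = []
        seen = {}
        for c in conditions:
            seen[c] = seen.get(c, 0) + 1
            replicates.append(seen[c])
    sheet = pd.DataFrame(
        {"condition": conditions, "replicate": replicates},
        index=counts.columns,
    )
    return CountMatrix(counts, sheet)


class TestFilterDetected:
    def test_zero_replicate_removed(self):
        cm = _cm(
            {
                "s1": [5, 2], "s2": [0, 2], "s3": [3, 2], "s4": [2, 2],
                "s5": [4, 2], "s6": [1, 2], "s7": [7, 2], "s8": [2, 2],
            },
            ["C0", "C0", "C1", "C1", "C2", "C2", "C3", "C3"],
        )
        out = filter_detected(cm)
        assert list(out.counts.index) == [1]

    def test_all_detected_retained(self, tiny_cm):
        out = filter_detected(tiny_cm)
        assert out.counts.shape == tiny_cm.counts.shape

    def test_empty_matrix(self, tiny_cm):
        cm = CountMatrix(tiny_cm.counts.iloc[:0], tiny_cm.samples)
        assert len(filter_detected(cm).counts) == 0

    def test_any_condition_mode(self):
        cm = _cm(
            {"s1": [1], "s2": [1], "s3": [0], "s4": [0],
             "s5": [1], "s6": [1], "s7": [1], "s8": [1]},
            ["C0", "C0", "C1", "C1", "C2", "C2", "C3", "C3"],
        )
        assert len(filter_detected(cm, mode="all_samples").counts) == 0
        assert len(filter_detected(cm, mode="any_condition").counts) == 1


class TestSizeFactors:
    def test_definition(self):
        cm = _cm(
            {"a": [60, 40], "b": [200, 100], "c": [100, 100], "d": [100, 100],
             "e": [100, 100], "f": [100, 100], "g": [100, 100], "h": [100, 100]},
            ["C0", "C0", "C1", "C1", "C2", "C2", "C3", "C3"],
        )
        f = size_factors(cm)
        totals = cm.counts.sum()
        np.testing.assert_allclose(f, totals / totals.mean())

    def test_equal_totals_unit_factors(self, tiny_cm):
        cm = CountMatrix(
            pd.DataFrame(
                np.ones((4, 8)) * 10, columns=tiny_cm.counts.columns
            ),
            tiny_cm.samples,
        )
        np.testing.assert_allclose(size_factors(cm), 1.0)

    def test_normalized_totals_equal(self, tiny_cm):
        f = size_factors(tiny_cm)
        norm = tiny_cm.counts / f
        np.testing.assert_allclose(norm.sum(), norm.sum().iloc[0])

    def test_zero_total_sample_raises(self, tiny_cm):
        counts = tiny_cm.counts.copy()
        counts.iloc[:, 0] = 0
        with pytest.raises(ValueError, match="zero-total"):
            size_factors(CountMatrix(counts, tiny_cm.samples))

    def test_median_ratio_recovers_depth_under_asymmetric_regulation(self):
        """Median-of-ratios ignores a regulated minority; totals do not."""
        rng = np.random.default_rng(2)
        n = 400
        base = rng.uniform(50, 500, n)
        depth = np.array([1.0, 1.0, 1.3, 1.3, 1.0, 1.0, 1.0, 1.0])
        mu = np.outer(base, depth)
        mu[:40, 4:] *= 8  # 10% of miRNAs strongly up in half the samples
        counts = rng.poisson(mu)
        cm = _cm(
            pd.DataFrame(counts, columns=list("abcdefgh")),
            ["C0", "C0", "C1", "C1", "C2", "C2", "C3", "C3"],
        )
        f = median_ratio_size_factors(cm)
        ratio = f.to_numpy() / depth
        assert np.allclose(ratio / ratio.mean(), 1.0, atol=0.05)


class TestContrast:
    def test_log2fc_arithmetic(self):
        cm = _cm(
            {"a": [50], "b": [50], "c": [200], "d": [200],
             "e": [50], "f": [50], "g": [50], "h": [50]},
            ["C0", "C0", "C1", "C1", "C2", "C2", "C3", "C3"],
        )
        res = contrast(cm, "C0", "C1", factors=pd.Series(1.0, index=cm.counts.columns))
        assert res["log2fc"].iloc[0] == pytest.approx(2.0)

    def test_zero_vs_zero_p_is_one(self):
        cm = _cm(
            {"a": [0, 5], "b": [0, 5], "c": [0, 5], "d": [0, 5],
             "e": [5, 5], "f": [5, 5], "g": [5, 5], "h": [5, 5]},
            ["C0", "C0", "C1", "C1", "C2", "C2", "C3", "C3"],
        )
        res = contrast(cm, "C0", "C1", factors=pd.Series(1.0, index=cm.counts.columns))
        assert res["pvalue"].iloc[0] == 1.0

    def test_ten_vs_zero_exact_tail(self):
        """Pooled 10 vs 0 at equal shares: two-sided p = 2 * 0.5^10."""
        cm = _cm(
            {"a": [5, 9], "b": [5, 9], "c": [0, 9], "d": [0, 9],
             "e": [5, 9], "f": [5, 9], "g": [5, 9], "h": [5, 9]},
            ["C0", "C0", "C1", "C1", "C2", "C2", "C3", "C3"],
        )
        res = contrast(cm, "C0", "C1", factors=pd.Series(1.0, index=cm.counts.columns))
        assert res["pvalue"].iloc[0] == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_antisymmetric_log2fc(self, tiny_cm):
        fwd = contrast(tiny_cm, "C0", "C1")
        rev = contrast(tiny_cm, "C1", "C0")
        np.testing.assert_array_equal(
            fwd["log2fc"].to_numpy(), -rev["log2fc"].to_numpy()
        )

    def test_p_symmetric_under_reversal(self, tiny_cm):
        fwd = contrast(tiny_cm, "C0", "C1")
        rev = contrast(tiny_cm, "C1", "C0")
        np.testing.assert_allclose(
            fwd["pvalue"].to_numpy(), rev["pvalue"].to_numpy(), rtol=1e-9
        )

    def test_unknown_condition_raises(self, tiny_cm):
        with pytest.raises(ValueError):
            contrast(tiny_cm, "C0", "C9")

    def test_q_at_least_p(self, tiny_cm):
        res = contrast(tiny_cm, "C0", "C1")
        assert (res["qvalue"] >= res["pvalue"] - 1e-15).all()

    def test_nb_wald_detects_large_effect(self):
        rng = np.random.default_rng(8)
        n = 200
        mu = np.full((n, 8), 500.0)
        mu[:20, 2:4] *= 8  # big effect in C1
        counts = rng.poisson(mu)
        cm = _cm(
            pd.DataFrame(counts, columns=list("abcdefgh")),
            ["C0", "C0", "C1", "C1", "C2", "C2", "C3", "C3"],
        )
        res = contrast(
            cm, "C0", "C1", method="nb_wald", factors=median_ratio_size_factors(cm)
        )
        assert (res["qvalue"].iloc[:20] < 0.05).all()
        assert (res["qvalue"].iloc[20:] < 0.05).mean() < 0.1

    def test_exact_null_calibration(self):
        """Under Poisson equal means, p-value rejection rate stays near alpha."""
        rng_counts = []
        frac = []
        for seed in range(5):
            cfg = simulate.DesignConfig(
                n_mirna=500,
                baseline_mean=100.0,
                dispersion=0.0,
                class_fractions={"unclassified": 1.0},
                seed=seed,
            )
            truth = simulate.generate_truth(cfg)
            cm = simulate.simulate_counts(truth, cfg)
            res = contrast(cm, "C0", "C1")
            frac.append((res["pvalue"] < 0.05).mean())
        assert np.mean(frac) <= 0.075


class TestBH:
    def test_worked_examples(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])
        np.testing.assert_allclose(bh_adjust([0.05, 0.01]), [0.05, 0.02])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_empty_vector(self):
        assert len(bh_adjust([])) == 0

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=120)
    )
    def test_matches_brute_force_and_is_monotone(self, pvals):
        q = bh_adjust(pvals)
        np.testing.assert_allclose(q, brute_force_bh(pvals), atol=1e-12)
        assert (q >= np.asarray(pvals) - 1e-15).all()
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestQC:
    def test_identical_replicates_r2_one(self, tiny_cm):
        counts = tiny_cm.counts.copy()
        for cond in ("C0", "C1", "C2", "C3"):
            cols = tiny_cm.condition_samples(cond)
            counts[cols[1]] = counts[cols[0]]
        qc = replicate_qc(CountMatrix(counts, tiny_cm.samples))
        for v in qc["r_squared"].values():
            assert v == pytest.approx(1.0)

    def test_independent_replicates_low_r2(self):
        rng = np.random.default_rng(12)
        counts = pd.DataFrame(
            rng.poisson(5, size=(10_000, 8)) + rng.integers(0, 50, size=(10_000, 8)),
            columns=list("abcdefgh"),
        )
        cm = _cm(counts, ["C0", "C0", "C1", "C1", "C2", "C2", "C3", "C3"])
        qc = replicate_qc(cm)
        assert all(v < 0.05 for v in qc["r_squared"].values())

    def test_identical_profiles_merge_first(self, tiny_cm):
        counts = tiny_cm.counts.copy()
        c0 = tiny_cm.condition_samples("C0")
        c1 = tiny_cm.condition_samples("C1")
        counts[c1[0]] = counts[c0[0]] * 2  # perfectly correlated pair
        counts[c1[1]] = counts[c0[1]]
        cm = CountMatrix(counts, tiny_cm.samples)
        qc = replicate_qc(cm)
        first = qc["linkage"][0]
        cols = list(cm.counts.columns)
        merged = {cols[int(first[0])], cols[int(first[1])]}
        assert first[2] == pytest.approx(0.0, abs=1e-9)
        assert merged <= {c0[0], c0[1], c1[0], c1[1]}

    def test_single_replicate_flagged(self, tiny_cm):
        keep = [s for s in tiny_cm.counts.columns if s != "s02"]
        cm = CountMatrix(tiny_cm.counts[keep], tiny_cm.samples.loc[keep])
        qc = replicate_qc(cm)
        assert qc["r_squared"]["hsf1_plus_noHS"] is None


class TestVolcano:
    def test_strict_threshold_and_caps(self):
        table = pd.DataFrame(
            {
                "mean_a": [1, 1, 1],
                "mean_b": [1, 1, 1],
                "log2fc": [1.0, -1.0, 0.0],
                "pvalue": [0.05, 0.01, 0.0],
                "qvalue": [0.05, 0.01, 1.0],
            },
            index=["a", "b", "c"],
        )
        res = diffexpr.ContrastResult("C0", "C1", table) if hasattr(diffexpr, "ContrastResult") else None
        from stressmir.data import ContrastResult

        res = ContrastResult("hsf1_plus_noHS", "hsf1_plus_HS", table)
        v = volcano_table(res)
        assert not v.loc["a", "significant"]  # q == 0.05 exactly: NOT significant
        assert v.loc["b", "significant"]
        assert v.loc["b", "neg_log10_q"] == pytest.approx(2.0)
        assert v.loc["c", "neg_log10_q"] == pytest.approx(0.0)

    def test_zero_q_capped(self):
        from stressmir.data import ContrastResult

        table = pd.DataFrame(
            {"mean_a": [1], "mean_b": [1], "log2fc": [1.0], "pvalue": [0.0], "qvalue": [0.0]},
            index=["a"],
        )
        v = volcano_table(ContrastResult("hsf1_plus_noHS", "hsf1_plus_HS", table))
        assert v["neg_log10_q"].iloc[0] == 300.0


class TestDdct:
    def test_equal_cts_fold_one(self):
        assert ddct_fold_change(20, 20, 20, 20) == pytest.approx(1.0)

    def test_worked_example(self):
        # ddCt = (20-15) - (22-15) = -2 -> fold 4
        assert ddct_fold_change(20, 15, 22, 15) == pytest.approx(4.0)

    def test_swap_inverts(self):
        f = ddct_fold_change(20, 15, 22, 16)
        g = ddct_fold_change(22, 16, 20, 15)
        assert f * g == pytest.approx(1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ddct_fold_change(np.nan, 1, 1, 1)


class TestDispersion:
    def test_poisson_data_near_zero(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.poisson(200, size=(500, 8)), columns=list("abcdefgh")
        )
        cm = _cm(counts, ["C0", "C0", "C1", "C1", "C2", "C2", "C3", "C3"])
        assert estimate_dispersion(cm) < 0.01

    def test_overdispersed_data_recovered(self):
        cfg = simulate.DesignConfig(
            n_mirna=800,
            baseline_mean=500.0,
            dispersion=0.05,
            class_fractions={"unclassified": 1.0},
            library_size_spread=0.0,
            seed=4,
        )
        truth = simulate.generate_truth(cfg)
        cm = simulate.simulate_counts(truth, cfg)
        est = estimate_dispersion(cm)
        assert 0.02 < est < 0.09
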