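import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methpanel.errors import ValidationError
from methpanel.panel_stats import (
    PanelConfig,
    calibrate_threshold,
    call_positive,
    fisher_exact,
    frequency_table,
    lymphoma_class,
    mann_whitney,
    panel_score,
    pooled_percent,
    roc_auc,
    validate_cohort,
)


class TestCalibrateThreshold:
    def test_control_range_0_to_3p7_gives_4(self):
        controls = np.linspace(0.0, 3.7, 49)
        assert calibrate_threshold(controls) == 4

    def test_all_zero_gives_zero(self):
        assert calibrate_threshold([0.0, 0.0, 0.0]) == 0

    def test_integral_max_unchanged(self):
        assert calibrate_threshold([1.2, 5.0]) == 5

    def test_empty_error(self):
        with pytest.raises(ValidationError):
            calibrate_threshold([])

    def test_negative_error(self):
        with pytest.raises(ValidationError):
            calibrate_threshold([-0.1, 2.0])


class TestCallPositive:
    def test_below_threshold_negative(self):
        assert not call_positive(3.7, PanelConfig(threshold=4))

    def test_at_threshold_positive(self):
        assert call_positive(4.0, PanelConfig(threshold=4))

    def test_zero_negative(self):
        assert not call_positive(0.0, 4)

    def test_accepts_bare_threshold(self):
        assert call_positive(5.0, 4.0)


def _cohort_and_calls(spec):
    """spec: list of (gene, group, series, methylated, analyzed)."""
    cohort_rows, call_rows = [], {}
    counters = {}
    samples_by_cell = {}
    for gene, group, series, m, n in spec:
        key = (group, series)
        if key not in samples_by_cell:
            start = counters.get(key, 0)
            ids = [f"{series}_{group}_{i}" for i in range(n)]
            samples_by_cell[key] = ids
            for s in ids:
                cohort_rows.append({"sample": s, "group": group, "series": series})
        ids = samples_by_cell[key]
        assert len(ids) >= n
        for i, s in enumerate(ids[:n]):
            call_rows.setdefault(gene, []).append(
                {"sample": s, "gene": gene, "positive": i < m}
            )
    calls = pd.DataFrame([r for rows in call_rows.values() for r in rows])
    cohort = pd.DataFrame(cohort_rows).drop_duplicates("sample")
    return calls, cohort


class TestFrequencyTable:
    def test_validation_pooling_91_percent(self):
        # per-group 7/8, 6/6, 2/2, 5/6 -> pooled 20/22 -> 91%
        spec = [
            ("CDH1", "ABC", "validation", 7, 8),
            ("CDH1", "GCB", "validation", 6, 6),
            ("CDH1", "FL", "validation", 2, 2),
            ("CDH1", "PMBL", "validation", 5, 6),
        ]
        calls, cohort = _cohort_and_calls(spec)
        table = frequency_table(calls, cohort)
        pooled = table[(table["series"] == "validation") & (table["group"] == "all")]
        assert pooled["methylated"].iloc[0] == 20
        assert pooled["analyzed"].iloc[0] == 22
        assert pooled["percent"].iloc[0] == 91

    def test_cross_series_pooling_94_percent(self):
        # 27/30 and 22/22 -> 49/52 -> 94%
        spec = [
            ("LRP12", "ABC", "test", 10, 10),
            ("LRP12", "GCB", "test", 7, 10),
            ("LRP12", "FL", "test", 10, 10),
            ("LRP12", "ABC", "validation", 8, 8),
            ("LRP12", "GCB", "validation", 6, 6),
            ("LRP12", "FL", "validation", 2, 2),
            ("LRP12", "PMBL", "validation", 6, 6),
        ]
        calls, cohort = _cohort_and_calls(spec)
        table = frequency_table(calls, cohort)
        overall = table[(table["series"] == "all") & (table["group"] == "all")]
        assert overall["methylated"].iloc[0] == 49
        assert overall["percent"].iloc[0] == 94

    def test_zero_positives_zero_rows(self):
        spec = [("G", "BL", "test", 0, 5), ("G", "FL", "test", 0, 4)]
        calls, cohort = _cohort_and_calls(spec)
        table = frequency_table(calls, cohort)
        assert (table["percent"] == 0).all()

    def test_controls_excluded_from_pool(self):
        spec = [("G", "BL", "test", 5, 5), ("G", "control:PBMC", "test", 0, 10)]
        calls, cohort = _cohort_and_calls(spec)
        table = frequency_table(calls, cohort)
        pooled = table[(table["group"] == "all") & (table["series"] == "test")]
        assert pooled["analyzed"].iloc[0] == 5
        assert pooled["percent"].iloc[0] == 100

    def test_pooled_counts_conserved(self):
        spec = [
            ("G", "BL", "test", 2, 5),
            ("G", "FL", "test", 3, 4),
            ("G", "ABC", "validation", 1, 6),
        ]
        calls, cohort = _cohort_and_calls(spec)
        table = frequency_table(calls, cohort)
        cells = table[(table["group"] != "all")]
        overall = table[(table["series"] == "all")].iloc[0]
        assert cells["methylated"].sum() == overall["methylated"]
        assert cells["analyzed"].sum() == overall["analyzed"]

    def test_orphan_sample_error(self):
        calls = pd.DataFrame(
            [{"sample": "ghost", "gene": "G", "positive": True}]
        )
        cohort = pd.DataFrame(
            [{"sample": "s1", "group": "BL", "series": "test"}]
        )
        with pytest.raises(ValidationError, match="ghost"):
            frequency_table(calls, cohort)

    def test_threshold_monotone(self):
        """Raising the positivity threshold never increases any frequency."""
        rng = np.random.default_rng(5)
        pmr = rng.uniform(0, 60, size=40)
        cohort = pd.DataFrame(
            {"sample": [f"s{i}" for i in range(40)], "group": "BL",
             "series": "test"}
        )
        prev = None
        for thr in (0, 4, 10, 30, 100):
            calls = pd.DataFrame(
                {"sample": cohort["sample"], "gene": "G",
                 "positive": pmr >= thr}
            )
            freq = frequency_table(calls, cohort)
            total = freq[freq["group"] == "all"].iloc[0]["methylated"]
            if prev is not None:
                assert total <= prev
            prev = total

    def test_pooled_percent_helper(self):
        assert pooled_percent([(27, 30), (22, 22)]) == 94


def _fisher_oracle(a, b, c, d):
    """Exact-rational enumeration over all tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return (
            Fraction(math.comb(r1, k))
            * Fraction(math.comb(r2, c1 - k))
            / Fraction(math.comb(n, c1))
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return float(sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs))


class TestFisherExact:
    def test_homogeneous_table_p1(self):
        assert fisher_exact(5, 5, 5, 5) == pytest.approx(1.0)

    def test_fully_separated(self):
        # (10,0,0,10): p = 2 / C(20,10)
        expected = 2 / math.comb(20, 10)
        assert fisher_exact(10, 0, 0, 10) == pytest.approx(expected, rel=1e-9)

    def test_matches_scipy(self):
        from scipy.stats import fisher_exact as scipy_fisher

        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 15, size=4)
            expected = scipy_fisher([[a, b], [c, d]]).pvalue
            assert fisher_exact(a, b, c, d) == pytest.approx(expected, rel=1e-9)

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    @settings(max_examples=100, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        n = a + b + c + d
        if n == 0 or (a + b) in (0, n) or (a + c) in (0, n):
            assert fisher_exact(a, b, c, d) == 1.0
        else:
            assert fisher_exact(a, b, c, d) == pytest.approx(
                _fisher_oracle(a, b, c, d), abs=1e-12
            )

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact(-1, 2, 3, 4)

    def test_double_convention_at_least_mass(self):
        p_mass = fisher_exact(8, 2, 3, 7)
        p_double = fisher_exact(8, 2, 3, 7, convention="double")
        assert p_double >= p_mass - 1e-12


def _mw_permutation_oracle(a, b):
    """Exhaustive permutation two-sided p for the midrank U statistic."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    n_a = len(a)
    n = len(pooled)
    ranks = rankdata(pooled)
    mu = n_a * (n - n_a) / 2

    def u_of(idx):
        return ranks[list(idx)].sum() - n_a * (n_a + 1) / 2

    u_obs = u_of(range(n_a))
    d_obs = abs(u_obs - mu)
    hits = total = 0
    for idx in itertools.combinations(range(n), n_a):
        total += 1
        if abs(u_of(idx) - mu) >= d_obs - 1e-9:
            hits += 1
    return u_obs, hits / total


class TestMannWhitney:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0]
        u, p = mann_whitney(a, list(a))
        assert u == pytest.approx(len(a) * len(a) / 2)
        assert p == pytest.approx(1.0)

    def test_fully_separated(self):
        u, p = mann_whitney([10, 11, 12], [1, 2, 3])
        assert u == 9.0
        assert p == pytest.approx(2 / math.comb(6, 3) * 1, rel=1e-9)  # 2*1/20

    def test_matches_permutation_oracle_small(self, rng):
        for _ in range(10):
            a = rng.integers(0, 6, size=5).astype(float)  # ties likely
            b = rng.integers(0, 6, size=4).astype(float)
            u, p = mann_whitney(a, b)
            u_exp, p_exp = _mw_permutation_oracle(a, b)
            assert u == pytest.approx(u_exp)
            assert p == pytest.approx(p_exp, abs=1e-12)

    def test_normal_approx_close_to_scipy(self, rng):
        from scipy.stats import mannwhitneyu

        a = rng.normal(0, 1, size=50)
        b = rng.normal(0.5, 1, size=40)
        u, p = mann_whitney(a, b, method="normal")
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_error(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])

    def test_all_tied_p1(self):
        u, p = mann_whitney([2.0] * 25, [2.0] * 25, method="normal")
        assert p == 1.0


class TestPanelScore:
    def pmr_frame(self, rows):
        return pd.DataFrame(rows, columns=["sample", "gene", "pmr"])

    def test_all_zero(self):
        pmrs = self.pmr_frame([("S", g, 0.0) for g in
                               ("LRP12", "CDH1", "BMPER", "DUSP4", "BMP7")])
        out = panel_score(pmrs)
        assert out["score"].iloc[0] == 0.0

    def test_sum(self):
        vals = dict(zip(("LRP12", "CDH1", "BMPER", "DUSP4", "BMP7"),
                        (10, 20, 0, 5, 15)))
        pmrs = self.pmr_frame([("S", g, v) for g, v in vals.items()])
        assert panel_score(pmrs)["score"].iloc[0] == 50.0

    def test_missing_gene_flagged(self):
        pmrs = self.pmr_frame(
            [("S", g, 10.0) for g in ("LRP12", "CDH1", "BMPER", "BMP7")]
        )
        out = panel_score(pmrs)
        assert out["score"].iloc[0] == 40.0
        assert out["missing_genes"].iloc[0] == "DUSP4"

    def test_strict_mode_raises_on_missing(self):
        pmrs = self.pmr_frame([("S", "LRP12", 10.0)])
        with pytest.raises(ValidationError):
            panel_score(pmrs, mode="strict")

    def test_all_missing_error(self):
        pmrs = self.pmr_frame([("S", "OTHER", 10.0)])
        with pytest.raises(ValidationError):
            panel_score(pmrs)


def _auc_pair_oracle(scores, labels):
    """Brute-force pair counting: wins + half-ties over all pos/neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = [10, 11, 12, 1, 2, 3]
        labels = [True, True, True, False, False, False]
        assert roc_auc(scores, labels).auc == 1.0

    def test_random_labels_expect_half(self, rng):
        aucs = []
        for _ in range(200):
            scores = rng.normal(size=20)
            labels = rng.permutation([True] * 10 + [False] * 10)
            aucs.append(roc_auc(scores, labels).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_51_of_52_above_all_controls(self):
        # one lymphoma sample below every control; 49 controls
        scores = [10.0] * 51 + [-1.0] + [5.0] * 49
        labels = [True] * 52 + [False] * 49
        expected = (51 * 49) / (52 * 49)
        assert roc_auc(scores, labels).auc == pytest.approx(expected, rel=1e-12)

    def test_matches_pair_counting_with_ties(self, rng):
        for _ in range(50):
            n1, n0 = rng.integers(2, 15, size=2)
            scores = rng.integers(0, 5, size=n1 + n0).astype(float)
            labels = [True] * n1 + [False] * n0
            roc = roc_auc(scores, labels)
            assert roc.auc == pytest.approx(
                _auc_pair_oracle(scores, labels), abs=1e-12
            )

    def test_auc_equals_u_over_n1n0(self, rng):
        for _ in range(50):
            scores = rng.integers(0, 8, size=30).astype(float)
            labels = rng.random(30) < 0.4
            if labels.all() or not labels.any():
                continue
            roc = roc_auc(scores, labels)
            u, _ = mann_whitney(scores[labels], scores[~labels], method="normal")
            assert roc.auc == pytest.approx(u / (roc.n_pos * roc.n_neg), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            scores = rng.integers(0, 6, size=40).astype(float)
            labels = rng.random(40) < 0.5
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_curve_monotone(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.5
        if labels.all() or not labels.any():
            labels[0] = True
            labels[1] = False
        roc = roc_auc(scores, labels)
        assert (np.diff(roc.fpr) >= 0).all()
        assert (np.diff(roc.tpr) >= 0).all()

    def test_one_class_error(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 2, 3], [True, True, True])


class TestCohort:
    def test_class_mapping(self):
        assert lymphoma_class("control:PBMC") == "non-lymphoma"
        assert lymphoma_class("FH") == "non-lymphoma"
        for g in ("BL", "ABC", "GCB", "FL", "PMBL"):
            assert lymphoma_class(g) == "lymphoma"

    def test_unknown_group_error(self):
        with pytest.raises(ValidationError):
            lymphoma_class("whatever")

    def test_duplicate_sample_error(self):
        cohort = pd.DataFrame(
            [{"sample": "s", "group": "BL", "series": "test"}] * 2
        )
        with pytest.raises(ValidationError):
            validate_cohort(cohort)
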