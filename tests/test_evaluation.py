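import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mcri.evaluation import (
    change_table,
    confusion_metrics,
    correlation_report,
    dichotomize_pgic,
    jonckheere_terpstra,
    optimal_cutoff,
    roc_auc,
)


def build_from_counts(tp, fn, fp, tn, cutoff=1.0):
    """Change/anchor arrays reproducing the requested confusion counts."""
    changes = np.concatenate(
        [
            np.full(tp, cutoff + 1.0), np.full(fn, cutoff - 1.0),
            np.full(fp, cutoff + 1.0), np.full(tn, cutoff - 1.0),
        ]
    )
    satisfied = np.concatenate(
        [np.ones(tp + fn, bool), np.zeros(fp + tn, bool)]
    )
    return changes, satisfied


class TestDichotomization:
    @pytest.mark.parametrize("pgic, expected", [(5, False), (6, True), (7, True), (1, False)])
    def test_satisfaction_threshold(self, pgic, expected):
        assert dichotomize_pgic(pgic) is expected

    def test_vectorized(self):
        assert np.array_equal(
            dichotomize_pgic(np.array([1, 5, 6, 7])), [False, False, True, True]
        )


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "counts, sens, spec",
        [
            ((24, 7, 19, 75), 77.4, 79.8),   # 12-month composite-index row
            ((16, 9, 29, 95), 64.0, 76.6),   # 3-month composite-index row
        ],
    )
    def test_published_count_arithmetic(self, counts, sens, spec):
        changes, satisfied = build_from_counts(*counts)
        res = confusion_metrics(changes, satisfied, 1.0)
        assert (res.tp, res.fn, res.fp, res.tn) == counts
        assert round(100 * res.sensitivity, 1) == sens
        assert round(100 * res.specificity, 1) == spec

    def test_perfect_separation(self):
        changes, satisfied = build_from_counts(10, 0, 0, 12)
        res = confusion_metrics(changes, satisfied, 1.0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0 and res.auc == 1.0

    def test_counts_sum_to_analyzable_records(self):
        rng = np.random.default_rng(3)
        changes = rng.standard_normal(80)
        satisfied = rng.random(80) < 0.3
        res = confusion_metrics(changes, satisfied, 0.2)
        assert res.n == 80

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.arange(5.0), np.ones(5, bool), 1.0)


def auc_allpairs_oracle(changes, satisfied):
    pos = changes[satisfied]
    neg = changes[~satisfied]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_separated_classes_give_one(self):
        c = np.array([1.0, 2, 3, 10, 11, 12])
        s = np.array([0, 0, 0, 1, 1, 1], bool)
        assert roc_auc(c, s) == 1.0

    def test_uninformative_labels_near_half(self):
        rng = np.random.default_rng(5)
        c = rng.standard_normal(20_000)
        s = rng.random(20_000) < 0.5
        assert roc_auc(c, s) == pytest.approx(0.5, abs=0.02)

    @given(st.integers(0, 2**31 - 1))
    def test_equals_allpairs_mann_whitney_count_exactly(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.integers(0, 6, size=30).astype(float)  # heavy ties
        s = np.zeros(30, bool)
        s[: rng.integers(1, 29)] = True
        rng.shuffle(s)
        assert roc_auc(c, s) == pytest.approx(auc_allpairs_oracle(c, s), abs=1e-12)

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(7)
        c = rng.standard_normal(200)
        s = rng.random(200) < 0.4
        assert roc_auc(np.exp(c), s) == pytest.approx(roc_auc(c, s), abs=1e-12)


class TestOptimalCutoff:
    def test_separable_example(self):
        res = optimal_cutoff(np.array([1.0, 2, 3, 4]), np.array([0, 0, 1, 1], bool))
        assert res.cutoff == pytest.approx(2.5)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(11)
        changes = rng.integers(-5, 6, 60).astype(float)
        satisfied = (changes + rng.standard_normal(60)) > 0.5
        if satisfied.all() or (~satisfied).all():
            pytest.skip("degenerate draw")
        res = optimal_cutoff(changes, satisfied)
        best = -np.inf
        for c in np.concatenate([changes - 1e-9, changes + 1e-9, [-np.inf, np.inf]]):
            improved = changes >= c
            sens = (improved & satisfied).sum() / satisfied.sum()
            spec = (~improved & ~satisfied).sum() / (~satisfied).sum()
            best = max(best, sens + spec)
        assert res.sensitivity + res.specificity == pytest.approx(best, abs=1e-12)

    def test_youden_never_negative_at_optimum(self):
        rng = np.random.default_rng(13)
        changes = rng.standard_normal(50)
        satisfied = rng.random(50) < 0.5  # anti-informative
        if satisfied.all() or (~satisfied).all():
            pytest.skip("degenerate draw")
        res = optimal_cutoff(changes, satisfied)
        assert res.sensitivity + res.specificity - 1 >= -1e-12


class TestJonckheereTerpstra:
    def test_two_groups_reduce_to_mann_whitney(self):
        rng = np.random.default_rng(17)
        a = rng.standard_normal(12)
        b = rng.standard_normal(15) + 0.5
        jt = jonckheere_terpstra([a, b])
        ref = stats.mannwhitneyu(b, a, alternative="greater",
                                 method="asymptotic", use_continuity=False)
        assert jt.statistic == pytest.approx(float(ref.statistic))
        assert jt.p_value == pytest.approx(float(ref.pvalue), abs=1e-10)

    def test_maximal_ordering_exact_enumeration(self):
        groups = [np.array([1.0, 2]), np.array([3.0, 4]), np.array([5.0, 6])]
        jt = jonckheere_terpstra(groups, method="exact")
        assert jt.statistic == 12  # maximum possible over 3 pairs of size 2x2
        assert jt.p_value == pytest.approx(1 / 90)

    def test_all_values_equal_centers_null(self):
        jt = jonckheere_terpstra([np.ones(4), np.ones(4), np.ones(4)])
        assert jt.z == 0.0 and jt.p_value == 0.5

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra([np.arange(5.0)])

    def test_normal_approximation_converges_to_permutation(self):
        rng = np.random.default_rng(19)
        groups = [rng.standard_normal(10) + shift for shift in (0, 0.4, 0.8)]
        asym = jonckheere_terpstra(groups)
        perm = jonckheere_terpstra(groups, method="permutation",
                                   n_resamples=50_000, seed=1)
        assert abs(asym.p_value - perm.p_value) < 0.01


class TestChangeTable:
    def _scored(self):
        return pd.DataFrame(
            {
                "patient_id": ["P1", "P1", "P2", "P2"],
                "visit": ["M0", "M12", "M0", "M12"],
                "MCRI": [3.0, 5.0, 6.0, 4.0],
                "ODI_pct": [50.0, 40.0, 30.0, 45.0],
                "EQ5D_index": [0.2, 0.5, 0.6, 0.4],
                "NPRS": [7, 4, 4, 6],
                "HADS_total": [20, 12, 10, 15],
                "PMI": [1000.0, 400.0, 300.0, 900.0],
                "PGIC": [np.nan, 6, np.nan, 2],
            }
        )

    def test_orientation_positive_means_improvement(self):
        ch = change_table(self._scored()).set_index("patient_id")
        p1 = ch.loc["P1"]
        assert p1["MCRI"] == 2.0 and p1["ODI"] == 10.0 and p1["EQ5D"] == pytest.approx(0.3)
        assert p1["NPRS"] == 3.0 and p1["HADS"] == 8.0 and p1["PMI"] == 600.0
        assert p1["satisfied"] is True or p1["satisfied"] == True  # noqa: E712
        p2 = ch.loc["P2"]
        assert p2["MCRI"] == -2.0 and p2["PMI"] == -600.0 and not p2["satisfied"]

    def test_change_requires_both_endpoints(self):
        scored = self._scored()
        scored["NPRS"] = scored["NPRS"].astype(float)
        scored.loc[scored["patient_id"] == "P2", "NPRS"] = [np.nan, 6.0]
        ch = change_table(scored).set_index("patient_id")
        assert np.isnan(ch.loc["P2", "NPRS"]) and ch.loc["P2", "ODI"] == -15.0


class TestCorrelationReport:
    def test_diagonal_and_sign_pattern_on_derived_cohort(self, default_cohort, derived):
        from mcri.pipeline import score_cohort

        table, _ = default_cohort
        scored = score_cohort(table, derived.factor_model, derived.composite_model)
        rho, disp, details = correlation_report(scored, "M0")
        assert (np.diag(rho.to_numpy()) == 1).all()
        assert rho.loc["MCRI", "ODI"] < 0
        assert rho.loc["MCRI", "NPRS"] < 0
        assert rho.loc["MCRI", "HADS"] < 0
        assert rho.loc["MCRI", "PMI"] < 0
        assert rho.loc["MCRI", "EQ5D"] > 0
        strong = details[("MCRI", "ODI")]
        assert strong.p_value < 0.001 and "***" in disp.loc["MCRI", "ODI"]
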