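"""ROC construction, AUC, cutoff selection, and screening classification,
checked against brute-force oracles and scikit-learn."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from psakit.derivatives import add_derivatives
from psakit.roc import (
    SingleClassError,
    build_roc,
    compare_sensitivity_bootstrap,
    confusion_at_cutoff,
    optimal_cutoff_upper_left,
    screening_classification,
    sensitivity_at_fixed_specificity,
    table3_report,
)

from conftest import make_record
from psakit.cohort import Cohort


def concordance_oracle(scores, labels):
    """Pair-counting AUC: fraction of (positive, negative) pairs ranked
    correctly, ties counting one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def upper_left_oracle(scores, labels):
    """Exhaustive search over all operating points (observed scores plus the
    all-negative threshold), with the documented tie-breaks."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    best = None
    for t in list(np.unique(scores)) + [np.inf]:
        called = scores >= t
        sens = np.sum(called & labels) / labels.sum()
        spec = np.sum(~called & ~labels) / (~labels).sum()
        key = ((1 - spec) ** 2 + (1 - sens) ** 2, -spec, -t)
        if best is None or key < best[0]:
            best = (key, t, sens, spec)
    return best[1], best[2], best[3]


def random_instance(rng, n_max=10, discrete=True):
    while True:
        n = rng.integers(2, n_max + 1)
        labels = rng.random(n) < 0.5
        if labels.any() and not labels.all():
            break
    if discrete:
        scores = rng.integers(0, 5, size=n).astype(float)
    else:
        scores = rng.normal(size=n)
    return scores, labels


class TestBuildRoc:
    def test_perfect_separation_auc_one(self):
        assert build_roc([1, 2, 3, 4], [False, False, True, True]).auc == 1.0

    def test_symmetric_labels_auc_half(self):
        # pos {1, 4} vs neg {2, 3}: 2 of 4 pairs concordant
        assert build_roc([1, 2, 3, 4], [True, False, False, True]).auc == 0.5

    def test_tied_scores_share_a_point(self):
        # pair-counting: (2>1) + (2==2)/2 + (3>1) + (3>2) over 4 pairs = 0.875
        roc = build_roc([1, 2, 2, 3], [False, True, False, True])
        assert roc.auc == pytest.approx(0.875)

    def test_single_class_error_names_the_class(self):
        with pytest.raises(SingleClassError, match="negative"):
            build_roc([1, 2], [True, True])
        with pytest.raises(SingleClassError, match="positive"):
            build_roc([1, 2], [False, False])

    def test_curve_spans_corners_and_is_monotone(self, rng):
        for _ in range(50):
            scores, labels = random_instance(rng)
            roc = build_roc(scores, labels)
            assert roc.sensitivity[0] == 1.0 and roc.specificity[0] == 0.0
            assert roc.sensitivity[-1] == 0.0 and roc.specificity[-1] == 1.0
            assert np.all(np.diff(roc.sensitivity) <= 0)
            assert np.all(np.diff(roc.specificity) >= 0)
            assert 0.0 <= roc.auc <= 1.0

    def test_auc_equals_concordance_oracle_exhaustively(self, rng):
        for _ in range(300):
            scores, labels = random_instance(rng, n_max=8)
            assert build_roc(scores, labels).auc == pytest.approx(
                concordance_oracle(scores, labels), abs=1e-12
            )

    def test_auc_matches_sklearn(self, rng):
        for _ in range(50):
            scores, labels = random_instance(rng, n_max=50, discrete=False)
            assert build_roc(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    @given(
        st.lists(st.integers(min_value=-100, max_value=100), min_size=4, max_size=20),
        st.randoms(use_true_random=False),
    )
    def test_auc_invariant_under_increasing_transform(self, scores, random):
        labels = np.array([random.random() < 0.5 for _ in scores])
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        scores = np.asarray(scores, dtype=float) / 4.0
        base = build_roc(scores, labels).auc
        assert build_roc(np.exp(scores / 25.0), labels).auc == pytest.approx(base, abs=1e-12)
        assert build_roc(3 * scores + 7, labels).auc == pytest.approx(base, abs=1e-12)


class TestOptimalCutoff:
    def test_perfectly_separating_threshold(self):
        cutoff, sens, spec = optimal_cutoff_upper_left(
            build_roc([0.1, 0.2, 0.3, 0.4], [False, False, True, True])
        )
        assert cutoff == pytest.approx(0.3)
        assert sens == 1.0 and spec == 1.0

    def test_matches_exhaustive_search(self, rng):
        for _ in range(300):
            scores, labels = random_instance(rng, n_max=10)
            roc = build_roc(scores, labels)
            got = optimal_cutoff_upper_left(roc)
            expected = upper_left_oracle(scores, labels)
            assert got[0] == expected[0]
            assert got[1] == pytest.approx(expected[1])
            assert got[2] == pytest.approx(expected[2])

    def test_youden_alternative_criterion(self):
        roc = build_roc([1, 2, 3, 4], [False, False, True, True])
        cutoff, sens, spec = optimal_cutoff_upper_left(roc, criterion="youden")
        assert cutoff == 3.0 and sens == 1.0 and spec == 1.0


class TestConfusion:
    def test_extreme_cutoffs(self):
        scores = [1, 2, 3, 4]
        labels = [False, False, True, True]
        low = confusion_at_cutoff(scores, labels, 0.5)
        assert low.sensitivity == 1.0 and low.specificity == 0.0
        assert low.npv is None  # nobody called negative
        high = confusion_at_cutoff(scores, labels, 5.0)
        assert high.sensitivity == 0.0 and high.specificity == 1.0
        assert high.ppv is None

    def test_perfect_cutoff(self):
        conf = confusion_at_cutoff([1, 2, 3, 4], [False, False, True, True], 3)
        assert (conf.sensitivity, conf.specificity, conf.ppv, conf.npv) == (1, 1, 1, 1)

    def test_counts_sum_and_bayes_identity(self, rng):
        for _ in range(50):
            scores, labels = random_instance(rng, n_max=30)
            cutoff = float(rng.choice(scores))
            conf = confusion_at_cutoff(scores, labels, cutoff)
            assert conf.tp + conf.fp + conf.tn + conf.fn == len(scores)
            if conf.ppv is not None:
                assert conf.ppv * (conf.tp + conf.fp) == pytest.approx(conf.tp)
            if conf.npv is not None:
                assert conf.npv * (conf.tn + conf.fn) == pytest.approx(conf.tn)


class TestFixedSpecificity:
    def test_perfect_curve_full_sensitivity(self):
        roc = build_roc([1, 2, 3, 4], [False, False, True, True])
        for target in (0.5, 0.8, 0.99):
            assert sensitivity_at_fixed_specificity(roc, target) == 1.0

    def test_null_scores_give_complementary_sensitivity(self, rng):
        # uninformative scores: at specificity 0.80 roughly 20% sensitivity
        n = 20000
        scores = rng.normal(size=n)
        labels = rng.random(n) < 0.4
        roc = build_roc(scores, labels)
        assert sensitivity_at_fixed_specificity(roc, 0.80) == pytest.approx(0.20, abs=0.02)

    def test_degenerate_attainment_gives_zero(self):
        # constant scores: only the all-negative point reaches the target
        roc = build_roc([2.0, 2.0, 2.0], [True, False, True])
        assert sensitivity_at_fixed_specificity(roc, 0.8) == 0.0


class TestBootstrapComparison:
    def test_identical_scores_null_result(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.5
        out = compare_sensitivity_bootstrap(scores, scores, labels, n_boot=200, seed=1)
        assert out["delta"] == 0.0
        assert out["p_value"] == 1.0

    def test_monotone_shift_is_rank_invariant(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.5
        out = compare_sensitivity_bootstrap(scores, scores + 5.0, labels, n_boot=200, seed=1)
        assert out["delta"] == 0.0

    def test_interval_covers_known_difference(self, rng):
        """Binormal pair with a known sensitivity difference at specificity
        0.80; the 95% percentile interval should cover it in >= 90% of
        replicate simulations."""
        from scipy.stats import norm

        mu_a, mu_b = 1.8, 1.0
        z80 = norm.ppf(0.80)
        true_delta = norm.cdf(mu_a - z80) - norm.cdf(mu_b - z80)
        n, covered, n_sim = 500, 0, 200
        for sim in range(n_sim):
            labels = np.zeros(n, bool)
            labels[: n // 2] = True
            noise_a = rng.normal(size=n)
            noise_b = rng.normal(size=n)
            scores_a = noise_a + mu_a * labels
            scores_b = noise_b + mu_b * labels
            out = compare_sensitivity_bootstrap(
                scores_a, scores_b, labels, n_boot=300, seed=int(rng.integers(2**31))
            )
            covered += out["ci_low"] <= true_delta <= out["ci_high"]
        assert covered / n_sim >= 0.90


def _toy_group_frame():
    from psakit.cohort import RaceEthnicity

    records = []
    for i, (psa, pw, tv) in enumerate(
        [(2, 40, 0.1), (3, 45, 0.2), (5, 50, 0.7), (7, 42, 1.2), (4, 48, 0.4), (6, 41, 0.9)]
    ):
        for group in ("NHW", "NHB"):
            records.append(
                make_record(
                    id=f"{group}{i}", psa=psa, prostate_weight=pw, tumor_volume=tv,
                    race_ethnicity=RaceEthnicity[group],
                )
            )
    return add_derivatives(Cohort(records=records).to_frame())


class TestTable3Report:
    def test_identical_groups_get_identical_rows(self):
        df = _toy_group_frame()
        reports = {r.group: r for r in table3_report(df, metrics=("psa", "psad"))}
        a, b = reports["NHW"], reports["NHB"]
        assert (a.cutoff, a.sensitivity, a.specificity, a.auc) == (
            b.cutoff, b.sensitivity, b.specificity, b.auc,
        )

    def test_perfectly_separable_group_reaches_100(self):
        df = _toy_group_frame()
        sub = df[df["race_ethnicity"] == "NHW"]
        reports = table3_report(sub, metrics=("psa",))
        assert reports[0].sensitivity == 100.0 and reports[0].specificity == 100.0

    def test_single_class_group_flagged_not_estimable(self):
        df = _toy_group_frame()
        df = df[df["tumor_volume"] < 0.5]
        reports = table3_report(df, metrics=("psad",))
        assert all(not r.estimable and r.cutoff is None for r in reports)


class TestScreeningClassification:
    @pytest.mark.parametrize("tv, expected", [(0.4, "FP"), (0.6, "TP")])
    def test_above_cutoff_labels(self, tv, expected):
        df = add_derivatives(
            Cohort(
                records=[
                    make_record(id="x", psa=0.16 * 44.9, prostate_weight=44.9, tumor_volume=tv),
                    make_record(id="y", psa=0.10 * 44.9, prostate_weight=44.9, tumor_volume=0.1),
                ]
            ).to_frame()
        )
        result = screening_classification(df, "psad", cutoff=0.15)
        assert result.labels.loc[0] == expected
        assert result.labels.loc[1] == "TN"

    def test_all_below_cutoff_no_positives(self, derived_frame):
        result = screening_classification(derived_frame, "psad", cutoff=1e9)
        assert result.counts["TP"] == 0 and result.counts["FP"] == 0

    def test_counts_partition_cohort(self, derived_frame):
        result = screening_classification(derived_frame, "psad", cutoff=0.15)
        assert sum(result.counts.values()) == int(derived_frame["significant"].notna().sum())
        assert result.by_pw_side.to_numpy().sum() == sum(result.counts.values())
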