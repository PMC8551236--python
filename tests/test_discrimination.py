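"""Tests for ROC/AUC, DeLong inference, cutoffs and the logistic model."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdgait import discrimination as disc
from pdgait.exceptions import DomainError


def brute_force_auc(pos, neg):
    """Exhaustive pairwise oracle: wins + half-ties over all pairs."""
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _labels(n_pos, n_neg):
    return np.array(["PD"] * n_pos + ["HS"] * n_neg)


class TestRocAuc:
    def test_perfect_separation(self):
        assert disc.roc_auc([4, 5, 6, 1, 2, 3], _labels(3, 3)) == 1.0

    def test_identical_distributions(self):
        assert disc.roc_auc([1, 2, 3, 1, 2, 3], _labels(3, 3)) == 0.5

    def test_tied_pair_example(self):
        # cases {2,4}, controls {1,2,3}: pairwise wins with tie = 1/2 give
        # (1 + 0.5 + 0 + 1 + 1 + 1) / 6
        auc = disc.roc_auc([2, 4, 1, 2, 3], _labels(2, 3))
        assert auc == pytest.approx(0.75, abs=1e-12)

    @given(
        n_pos=st.integers(2, 15),
        n_neg=st.integers(2, 15),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_brute_force_oracle(self, n_pos, n_neg, seed):
        rng = np.random.default_rng(seed)
        # integer scores to exercise ties
        pos = rng.integers(0, 8, n_pos).astype(float)
        neg = rng.integers(0, 8, n_neg).astype(float)
        scores = np.concatenate([pos, neg])
        auc = disc.roc_auc(scores, _labels(n_pos, n_neg))
        assert auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_monotone_transform_invariance_and_negation(self, rng):
        scores = rng.normal(size=40)
        labels = _labels(20, 20)
        base = disc.roc_auc(scores, labels)
        assert disc.roc_auc(np.exp(scores), labels) == pytest.approx(base)
        assert disc.roc_auc(-scores, labels) == pytest.approx(1 - base)

    def test_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        scores = np.round(rng.normal(size=200), 1)
        labels = _labels(120, 80)
        assert disc.roc_auc(scores, labels) == pytest.approx(
            sk.roc_auc_score(labels == "PD", scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            disc.roc_auc([1, 2], np.array(["PD", "PD"]))


class TestDelongCI:
    def test_perfect_separation_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = disc.auc_ci_delong([4, 5, 1, 2], _labels(2, 2))
        assert lo == hi == 1.0

    def test_duplication_narrows_ci(self, rng):
        scores = rng.normal(size=60) + np.r_[np.ones(30) * 0.8, np.zeros(30)]
        labels = _labels(30, 30)
        lo, hi = disc.auc_ci_delong(scores, labels)
        lo2, hi2 = disc.auc_ci_delong(np.tile(scores, 2), np.tile(labels, 2))
        assert disc.roc_auc(scores, labels) == disc.roc_auc(
            np.tile(scores, 2), np.tile(labels, 2)
        )
        assert (hi2 - lo2) < (hi - lo)

    def test_ci_contains_point_estimate(self, rng):
        scores = rng.normal(size=80) + np.r_[np.ones(40), np.zeros(40)]
        labels = _labels(40, 40)
        auc = disc.roc_auc(scores, labels)
        lo, hi = disc.auc_ci_delong(scores, labels)
        assert lo <= auc <= hi
        assert 0.0 <= lo and hi <= 1.0


class TestCompareAucs:
    def test_score_against_itself_is_null(self, rng):
        s = rng.normal(size=50)
        table = pd.DataFrame({"a": s, "b": s})
        chi2, p = disc.compare_aucs(table, _labels(25, 25))
        assert chi2 == 0.0 and p == 1.0

    def test_null_p_values_roughly_uniform(self):
        from scipy import stats

        root = np.random.SeedSequence(2024)
        pvals = []
        for ss in root.spawn(200):
            rng = np.random.default_rng(ss)
            table = pd.DataFrame(
                {"a": rng.normal(size=60), "b": rng.normal(size=60)}
            )
            pvals.append(disc.compare_aucs(table, _labels(30, 30))[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_informative_score_beats_noise(self):
        root = np.random.SeedSequence(7)
        wins = 0
        for ss in root.spawn(40):
            rng = np.random.default_rng(ss)
            labels = _labels(60, 60)
            signal = np.r_[rng.normal(2.0, 1, 60), rng.normal(0, 1, 60)]
            noise = rng.normal(size=120)
            table = pd.DataFrame({"signal": signal, "noise": noise})
            wins += disc.compare_aucs(table, labels)[1] < 0.05
        assert wins >= 32  # 80% power at this separation


class TestBestCutoff:
    def test_perfect_separation(self):
        cut, sens, spec, acc = disc.best_cutoff([4, 5, 1, 2], _labels(2, 2))
        assert (sens, spec, acc) == (100.0, 100.0, 100.0)
        assert 2 < cut < 4

    def test_brute_force_on_tied_example(self):
        scores = np.array([2.0, 4.0, 1.0, 2.0, 3.0])
        labels = _labels(2, 3)
        pos, neg = scores[:2], scores[2:]
        # enumerate every cutoff the implementation could choose
        cands = np.concatenate([[scores.min() - 1],
                                (np.unique(scores)[:-1] + np.unique(scores)[1:]) / 2,
                                [scores.max() + 1]])
        best = max(
            ((100 * (pos > c).mean() + 100 * (neg <= c).mean(),
              100 * (neg <= c).mean(), c) for c in cands)
        )
        cut, sens, spec, acc = disc.best_cutoff(scores, labels)
        assert sens + spec == pytest.approx(best[0])
        assert spec == pytest.approx(best[1])

    def test_score_negation_swaps_error_types(self, rng):
        scores = np.r_[rng.normal(1, 1, 30), rng.normal(0, 1, 30)]
        labels = _labels(30, 30)
        _, sens, spec, _ = disc.best_cutoff(scores, labels)
        flipped = np.array(["HS" if l == "PD" else "PD" for l in labels])
        _, sens2, spec2, _ = disc.best_cutoff(-scores, flipped)
        assert sens2 == pytest.approx(spec) and spec2 == pytest.approx(sens)


class TestBinormalAuc:
    def test_equal_means_chance(self):
        assert disc.binormal_auc(1.0, 2.0, 1.0, 3.0) == 0.5

    def test_published_gait_speed_parameters(self):
        auc = disc.binormal_auc(100.05, 30.42, 122.29, 17.7)
        assert auc == pytest.approx(0.736, abs=1e-3)

    def test_agrees_with_empirical_auc(self, rng):
        m1, s1, m2, s2 = 3.0, 2.0, 1.0, 1.5
        x = np.r_[rng.normal(m1, s1, 40000), rng.normal(m2, s2, 40000)]
        emp = disc.roc_auc(x, _labels(40000, 40000))
        assert emp == pytest.approx(disc.binormal_auc(m1, s1, m2, s2), abs=0.01)

    def test_bad_sd_rejected(self):
        with pytest.raises(DomainError):
            disc.binormal_auc(0, 0, 1, 1)


class TestAccuracyBand:
    @pytest.mark.parametrize(
        "auc,band",
        [(0.95, "high"), (0.901, "high"), (0.90, "moderate"), (0.70, "moderate"),
         (0.699, "low"), (0.50, "low"), (0.49, "chance")],
    )
    def test_printed_boundaries(self, auc, band):
        assert disc.accuracy_band(auc) == band


class TestFitLogistic:
    def _scores(self, rng, n=200, informative=("variability",)):
        labels = _labels(n // 2, n // 2)
        cols = {}
        for f in ("pace_rhythm", "variability", "asymmetry"):
            shift = 1.5 if f in informative else 0.0
            cols[f] = np.r_[rng.normal(shift, 1, n // 2), rng.normal(0, 1, n // 2)]
        return pd.DataFrame(cols), labels

    def test_permuted_labels_give_null_model(self, rng):
        table, labels = self._scores(rng, informative=())
        model = disc.fit_logistic(table, labels)
        assert model.converged
        assert np.abs(model.coefficients).max() < 0.5
        auc = disc.roc_auc(model.predict_proba(table), labels)
        assert abs(auc - 0.5) < 0.1

    def test_informative_factor_sign_and_mle_agreement(self, rng):
        sk = pytest.importorskip("sklearn.linear_model")
        table, labels = self._scores(rng)
        model = disc.fit_logistic(table, labels)
        assert model.coefficients["variability"] > 0
        oracle = sk.LogisticRegression(C=np.inf, max_iter=1000).fit(
            table.to_numpy(), labels == "PD"
        )
        assert np.allclose(model.coefficients, oracle.coef_.ravel(), atol=1e-3)
        assert model.intercept == pytest.approx(oracle.intercept_[0], abs=1e-3)

    def test_rescaling_invariance_of_fitted_probabilities(self, rng):
        table, labels = self._scores(rng)
        model = disc.fit_logistic(table, labels)
        doubled = table.copy()
        doubled["variability"] *= 2.0
        model2 = disc.fit_logistic(doubled, labels)
        assert model2.coefficients["variability"] == pytest.approx(
            model.coefficients["variability"] / 2, rel=1e-4
        )
        assert np.allclose(
            model.predict_proba(table), model2.predict_proba(doubled), atol=1e-6
        )

    def test_complete_separation_flagged(self):
        table = pd.DataFrame({
            "pace_rhythm": np.r_[np.ones(20), -np.ones(20)],
            "variability": np.zeros(40),
            "asymmetry": np.zeros(40),
        })
        model = disc.fit_logistic(table, _labels(20, 20))
        assert model.separation and not model.converged


def test_report_has_twelve_measures(staged_bundle):
    report = staged_bundle.report
    assert len(report) == 12
    assert set(report["band"]) <= {"high", "moderate", "low", "chance"}
    assert (report["ci_low"] <= report["auc"]).all()
    assert (report["auc"] <= report["ci_high"]).all()
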