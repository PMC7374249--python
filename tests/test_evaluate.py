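"""ROC/DeLong statistics, cutoff classification, kappa, drug models."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from tolsig.core import ValidationError, drug_design_matrix
from tolsig.evaluate import (
    auc_delong,
    auc_mann_whitney,
    cohens_kappa,
    delong_paired_test,
    dose_response,
    drug_influence,
    rank_sum_test,
    summarize_cycles,
    tol_cutoff_classify,
)


class TestAUC:
    def test_exhaustive_pair_counting(self):
        scores = np.array([0.9, 0.4, 0.6, 0.5, 0.1])
        labels = np.array([1, 1, 0, 0, 0])
        # pairs won: (0.9 beats all three) + (0.4 beats 0.1) = 4 of 6
        assert auc_mann_whitney(scores, labels) == pytest.approx(4 / 6)

    def test_perfect_separation(self):
        assert auc_mann_whitney([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_ties_count_half(self):
        # positive {2, 1} vs negative {1}: one win, one tie -> 0.75
        assert auc_mann_whitney([2, 1, 1], [1, 1, 0]) == pytest.approx(0.75)

    def test_matches_sklearn(self, rng):
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores)
        )

    def test_delong_ci_contains_auc_and_is_truncated(self, rng):
        scores = np.r_[rng.normal(1, 1, 30), rng.normal(0, 1, 100)]
        labels = np.r_[np.ones(30), np.zeros(100)]
        auc, lo, hi = auc_delong(scores, labels)
        assert 0 <= lo <= auc <= hi <= 1

    def test_delong_ci_matches_r_proc(self, tmp_path):
        rng = np.random.default_rng(7)
        scores = np.r_[rng.normal(1, 1, 18), rng.normal(0, 1, 60)]
        labels = np.r_[np.ones(18), np.zeros(60)]
        auc, lo, hi = auc_delong(scores, labels)
        df = pd.DataFrame({"score": scores, "label": labels})
        csv = tmp_path / "roc.csv"
        df.to_csv(csv, index=False)
        out = subprocess.run(
            ["Rscript", "-e",
             f"suppressMessages(library(pROC));"
             f"d <- read.csv('{csv}');"
             f"r <- roc(d$label, d$score, quiet=TRUE, direction='<');"
             f"ci <- ci.auc(r, method='delong');"
             f"cat(sprintf('%.12f %.12f %.12f', ci[1], ci[2], ci[3]))"],
            capture_output=True, text=True, check=True,
        )
        r_lo, r_auc, r_hi = map(float, out.stdout.split())
        assert auc == pytest.approx(r_auc, abs=1e-10)
        assert lo == pytest.approx(r_lo, abs=1e-6)
        assert hi == pytest.approx(r_hi, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auc_mann_whitney([1, 2], [1, 1])


class TestDeLongPairedTest:
    def test_identical_scores_p_one(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        assert delong_paired_test(scores, scores, labels) == 1.0

    def test_monotone_transform_p_one(self, rng):
        scores = rng.normal(size=60)
        labels = np.r_[np.ones(20), np.zeros(40)].astype(int)
        transformed = np.exp(2 * scores) + 5
        assert delong_paired_test(scores, transformed, labels) == pytest.approx(1.0)

    def test_strong_difference_detected(self, rng):
        labels = np.r_[np.ones(50), np.zeros(150)].astype(int)
        good = labels + rng.normal(0, 0.3, 200)
        noise = rng.normal(size=200)
        assert delong_paired_test(good, noise, labels) < 1e-4


class TestCutoffClassification:
    def _samples(self, groups):
        n = len(groups)
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "patient_id": [f"p{i}" for i in range(n)],
                "timepoint": ["T1"] * n,
                "group": groups,
                "pred": ["off"] * n,
                "cni": ["off"] * n,
                "ap": ["off"] * n,
            }
        )

    def test_even_tol_group_gives_half_sensitivity(self):
        samples = self._samples(["TOL"] * 4 + ["ST"] * 4)
        probs = pd.Series([0.2, 0.4, 0.6, 0.8, 0.1, 0.3, 0.5, 0.7],
                          index=samples["sample_id"])
        rep = tol_cutoff_classify(probs, samples)
        assert rep.cutoff == pytest.approx(0.5)
        assert rep.sensitivity == 0.5
        assert rep.tol_positive_st == 1  # only the 0.7 ST sample

    def test_sensitivity_exactly_half_for_any_even_tol_group(self, rng):
        for _ in range(20):
            n_tol = int(rng.integers(1, 10)) * 2
            probs_tol = rng.permutation(rng.uniform(0, 1, n_tol))
            samples = self._samples(["TOL"] * n_tol + ["CR"] * 5)
            probs = pd.Series(np.r_[probs_tol, rng.uniform(0, 1, 5)],
                              index=samples["sample_id"])
            rep = tol_cutoff_classify(probs, samples)
            assert rep.sensitivity == 0.5

    def test_strictly_greater_than_cutoff(self):
        samples = self._samples(["TOL", "TOL", "TOL", "ST"])
        probs = pd.Series([0.3, 0.5, 0.7, 0.5], index=samples["sample_id"])
        rep = tol_cutoff_classify(probs, samples)
        # ST sample sits exactly at the cutoff: negative
        assert rep.cutoff == 0.5
        assert not rep.positive.iloc[3]
        assert rep.specificity == 1.0

    def test_requires_tolerant_samples(self):
        samples = self._samples(["ST", "CR"])
        probs = pd.Series([0.1, 0.2], index=samples["sample_id"])
        with pytest.raises(ValidationError):
            tol_cutoff_classify(probs, samples)


class TestCohensKappa:
    def test_self_agreement_is_one(self, rng):
        a = rng.integers(0, 2, 50).astype(bool)
        assert cohens_kappa(a, a).kappa == 1.0

    def test_closed_form_example(self):
        # contingency a=4, b=1, c=1, d=4: p_o=0.8, p_e=0.5, kappa=0.6
        x = np.array([1] * 5 + [0] * 5, dtype=bool)
        y = np.array([1] * 4 + [0, 1] + [0] * 4, dtype=bool)
        rep = cohens_kappa(x, y)
        assert rep.counts == (4, 1, 1, 4)
        assert rep.kappa == pytest.approx(0.6)

    def test_symmetry(self, rng):
        a = rng.integers(0, 2, 100).astype(bool)
        b = rng.integers(0, 2, 100).astype(bool)
        assert cohens_kappa(a, b).kappa == pytest.approx(cohens_kappa(b, a).kappa)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.random(10_000) < 0.3
        b = rng.random(10_000) < 0.6
        assert abs(cohens_kappa(a, b).kappa) < 0.05

    def test_matches_sklearn(self, rng):
        a = rng.integers(0, 2, 200)
        b = (a + (rng.random(200) < 0.3)) % 2
        assert cohens_kappa(a, b).kappa == pytest.approx(
            cohen_kappa_score(a, b)
        )

    def test_both_constant_equal_defined_as_one(self):
        assert cohens_kappa([1, 1, 1], [1, 1, 1]).kappa == 1.0


def _treated_samples(rng, n=200):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "patient_id": [f"p{i}" for i in range(n)],
            "timepoint": ["T1"] * n,
            "group": rng.choice(["ST", "CR"], n, p=[0.85, 0.15]),
            "pred": rng.choice(["off", "on"], n),
            "cni": rng.choice(["off", "cyc", "tac"], n),
            "ap": rng.choice(["off", "aza", "mmf"], n),
        }
    )


class TestDrugInfluence:
    def test_regimen_independent_probabilities_have_tiny_r2(self, rng):
        samples = _treated_samples(rng)
        probs = pd.Series(rng.uniform(0.01, 0.4, len(samples)),
                          index=samples["sample_id"])
        rep = drug_influence(probs, samples)
        assert rep.r_squared < 0.08
        assert set(rep.coefficients.index) == {
            "pred_on", "cni_cyc", "cni_tac", "ap_aza", "ap_mmf"
        }

    def test_planted_drug_effect_detected(self, rng):
        samples = _treated_samples(rng)
        eta = -2.0 - 1.5 * (samples["pred"] == "on").to_numpy() \
            + rng.normal(0, 0.3, len(samples))
        probs = pd.Series(1 / (1 + np.exp(-eta)), index=samples["sample_id"])
        rep = drug_influence(probs, samples)
        assert rep.r_squared > 0.5
        assert rep.coefficients.loc["pred_on", "p"] < 1e-10
        assert rep.coefficients.loc["pred_on", "coef"] == pytest.approx(
            -1.5, abs=0.2
        )


class TestDoseResponse:
    def _cohort_with_dose_effect(self, rng, slope=0.01, n=200):
        samples = _treated_samples(rng, n)
        dose = np.where(samples["cni"] == "tac",
                        rng.lognormal(np.log(4), 0.4, n), np.nan)
        samples["dose_tac"] = dose
        values = pd.Series(
            slope * np.nan_to_num(dose) + rng.normal(0, 0.05, n),
            index=samples["sample_id"],
        )
        return samples, values

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(4)
        samples, values = self._cohort_with_dose_effect(rng, slope=0.01)
        slope, p = dose_response(values, samples, "tac")
        assert slope == pytest.approx(0.01, abs=0.004)
        assert p < 0.01

    def test_cyc_treated_samples_excluded_from_tac_model(self):
        rng = np.random.default_rng(4)
        samples, values = self._cohort_with_dose_effect(rng)
        # poison the CYC-treated samples: if included, the slope explodes
        poisoned = values.copy()
        cyc = (samples["cni"] == "cyc").to_numpy()
        poisoned[cyc] = 1e6
        slope, _ = dose_response(poisoned, samples, "tac")
        ref_slope, _ = dose_response(values, samples, "tac")
        assert slope == pytest.approx(ref_slope)

    def test_constant_dose_rejected(self, rng):
        samples = _treated_samples(rng, 40)
        samples["dose_tac"] = np.where(samples["cni"] == "tac", 4.0, np.nan)
        samples.loc[samples["cni"] == "cyc", "cni"] = "off"
        values = pd.Series(rng.normal(size=40), index=samples["sample_id"])
        with pytest.raises(ValidationError):
            dose_response(values, samples, "pred")


class TestRankSum:
    def test_exact_small_sample(self):
        # U = 0; 6 equally likely orderings; two-sided p = 2/6
        assert rank_sum_test([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_multisets_p_one(self):
        assert rank_sum_test([1, 2, 3] * 20, [1, 2, 3] * 20) > 0.99

    def test_location_shift_detected(self, rng):
        a = rng.normal(0, 1, 100)
        b = rng.normal(1.5, 1, 100)
        assert rank_sum_test(a, b) < 1e-10


class TestSummaries:
    def test_median_convention_even_count(self):
        med, lo, hi = summarize_cycles(range(1, 101))
        assert med == 50.5
        assert lo == pytest.approx(np.percentile(range(1, 101), 2.5))

    def test_constant_zero_width(self):
        med, lo, hi = summarize_cycles([0.4] * 7)
        assert med == lo == hi == 0.4

    def test_single_value(self):
        assert summarize_cycles([3.0]) == (3.0, 3.0, 3.0)
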