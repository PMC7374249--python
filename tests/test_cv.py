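"""Outer cross-validation engine: structure, determinism, leakage."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from tolsig import evaluate, signatures
from tolsig.core import ValidationError
from tolsig.cv import (
    CVConfig,
    SignatureCV,
    finalize_signature,
    predict_cohort,
    run_cv,
    stratified_folds,
)


@pytest.fixture(scope="module")
def small_cv(small_cohort):
    """A reduced drug-adjusted CV run shared by the structural tests."""
    samples, expr = small_cohort
    spec = signatures.get_signature("COMBINED-g7")
    est = SignatureCV(spec, outer_folds=3, outer_repeats=2, inner_repeats=1,
                      random_state=1).fit(expr, samples)
    return samples, expr, spec, est


class TestStratifiedFolds:
    def test_tolerant_patients_spread_evenly(self, default_cohort):
        samples, _ = default_cohort
        ktr = samples[samples["group"].isin(["TOL", "ST", "CR"])]
        folds = stratified_folds(ktr, 6, seed=0)
        tol_ids = ktr.loc[ktr["group"] == "TOL", "sample_id"]
        counts = folds.loc[tol_ids].value_counts()
        assert sorted(counts) == [3] * 6  # 18 tolerant into 6 folds

    def test_partition_and_determinism(self, default_cohort):
        samples, _ = default_cohort
        ktr = samples[samples["group"].isin(["TOL", "ST", "CR"])]
        f1 = stratified_folds(ktr, 6, seed=42)
        f2 = stratified_folds(ktr, 6, seed=42)
        pd.testing.assert_series_equal(f1, f2)
        assert set(f1.index) == set(ktr["sample_id"])
        assert set(f1.unique()) == set(range(6))

    def test_fold_sizes_within_stratum_differ_by_at_most_one(
        self, default_cohort
    ):
        samples, _ = default_cohort
        ktr = samples[samples["group"].isin(["TOL", "ST", "CR"])]
        folds = stratified_folds(ktr, 6, seed=3)
        for group in ("TOL", "ST", "CR"):
            ids = ktr.loc[ktr["group"] == group, "sample_id"]
            sizes = folds.loc[ids].value_counts(sort=False)
            assert sizes.max() - sizes.min() <= 1

    def test_k_below_two_rejected(self, default_cohort):
        samples, _ = default_cohort
        with pytest.raises(ValidationError):
            stratified_folds(samples, 1, seed=0)


class TestRunCV:
    def test_structural_counts(self, small_cv):
        samples, expr, spec, est = small_cv
        ens = est.ensemble_
        n_ktr = (samples["group"].isin(["TOL", "ST", "CR"])
                 & (samples["timepoint"] == "T1")).sum()
        assert ens.probabilities.shape == (n_ktr, 2)
        assert len(ens.models) == 6  # 2 repeats x 3 folds
        assert not ens.probabilities.isna().to_numpy().any()
        assert ens.adjustment_r2.shape == (6, 7)
        for arr in ens.adjustment_coefs.values():
            assert arr.shape == (6, 6)

    def test_each_sample_predicted_once_per_repeat(self, small_cv):
        *_, est = small_cv
        ens = est.ensemble_
        for rep in range(2):
            folds = ens.fold_assignments[rep]
            assert set(np.unique(folds)) == {0, 1, 2}

    def test_same_seed_reproduces_probabilities(self, small_cohort):
        samples, expr = small_cohort
        spec = signatures.get_signature("GAMSTER-g4")
        kwargs = dict(outer_folds=3, outer_repeats=1, inner_repeats=1,
                      random_state=9)
        a = SignatureCV(spec, **kwargs).fit(expr, samples)
        b = SignatureCV(spec, **kwargs).fit(expr, samples)
        pd.testing.assert_frame_equal(a.ensemble_.probabilities,
                                      b.ensemble_.probabilities)

    def test_no_leakage_from_test_samples(self, small_cohort):
        """Corrupting a held-out sample's expression changes only its own
        prediction: the fold's model never saw it."""
        samples, expr = small_cohort
        spec = signatures.get_signature("COMBINED-g7")
        config = CVConfig(outer_folds=3, outer_repeats=1, inner_repeats=1,
                          seed=5)
        base = run_cv(expr, samples, spec, config)
        victim = base.probabilities.index[10]
        corrupted = expr.copy()
        corrupted.loc[victim] = corrupted.loc[victim] + 25.0
        probe = run_cv(corrupted, samples, spec, config)
        same_fold = base.fold_assignments[0] == base.fold_assignments[0][
            list(base.probabilities.index).index(victim)
        ]
        others = base.probabilities.index[same_fold] != victim
        fold_ids = base.probabilities.index[same_fold][others]
        np.testing.assert_allclose(
            probe.probabilities.loc[fold_ids, "rep0"],
            base.probabilities.loc[fold_ids, "rep0"],
            rtol=1e-12,
        )
        assert probe.probabilities.loc[victim, "rep0"] != pytest.approx(
            base.probabilities.loc[victim, "rep0"]
        )

    def test_unadjusted_signature_skips_adjustment(self, small_cohort):
        samples, expr = small_cohort
        spec = signatures.get_signature("NEWELL-g2")
        ens = run_cv(expr, samples, spec,
                     CVConfig(outer_folds=3, outer_repeats=1,
                              inner_repeats=1, seed=0))
        assert ens.adjustment_r2 is None
        assert ens.adjustment_coefs == {}

    def test_too_few_tolerant_for_folds_rejected(self, small_cohort):
        samples, expr = small_cohort
        few_tol = samples[~((samples["group"] == "TOL")
                            & (samples["patient_id"] > "TOL002"))]
        few_tol = few_tol[few_tol["timepoint"] == "T1"]
        spec = signatures.get_signature("GAMSTER-g4")
        with pytest.raises(ValidationError, match="fewer"):
            run_cv(expr.loc[few_tol["sample_id"]], few_tol, spec,
                   CVConfig(outer_folds=3, outer_repeats=1, inner_repeats=1))


class TestFinalize:
    def test_cutoff_is_median_tol_probability(self, small_cv):
        samples, expr, spec, est = small_cv
        probs = predict_cohort(est.bundle_, expr, samples)
        t1 = samples[(samples["timepoint"] == "T1")]
        tol_ids = t1.loc[t1["group"] == "TOL", "sample_id"]
        assert est.bundle_.cutoff == pytest.approx(
            float(np.median(probs.loc[tol_ids]))
        )

    def test_bundle_round_trips_and_rescored(self, small_cv, tmp_path):
        from tolsig.core import read_model_bundle, write_model_bundle

        samples, expr, spec, est = small_cv
        path = tmp_path / "bundle.json"
        write_model_bundle(est.bundle_, path)
        back = read_model_bundle(path)
        p1 = predict_cohort(est.bundle_, expr, samples)
        p2 = predict_cohort(back, expr, samples)
        np.testing.assert_allclose(p1, p2, rtol=1e-10)

    def test_adjustment_variants_both_exported(self, small_cv):
        *_, est = small_cv
        assert set(est.bundle_.adjustment_models) == {"full_data", "cv_median"}
        for models in est.bundle_.adjustment_models.values():
            assert set(models) == set(est.bundle_.signature.genes)

    def test_median_coefficients_match_ensemble(self, small_cv):
        *_, est = small_cv
        coefs = np.array([m.coef for m in est.ensemble_.models])
        np.testing.assert_allclose(est.bundle_.enet.coef,
                                   np.median(coefs, axis=0))


class TestPredictCohort:
    def test_t2_and_hc_scored_off_treatment(self, small_cohort):
        samples, expr = small_cohort
        spec = signatures.get_signature("COMBINED-g7")
        est = SignatureCV(spec, outer_folds=3, outer_repeats=2,
                          inner_repeats=1, random_state=1).fit(expr, samples)
        probs = predict_cohort(est.bundle_, expr, samples)
        assert probs.index.equals(expr.index)
        assert ((probs > 0) & (probs < 1)).all()

    def test_t1_t2_agreement_above_chance(self):
        """Unchanged biology at follow-up: TOL-positivity agreement between
        baseline and six-month samples is clearly above chance. Pooled over
        cohorts because a 12-patient tolerant group makes single-cohort
        kappa estimates unstable."""
        from tolsig import simulate

        spec = signatures.get_signature("COMBINED-g7")
        pos_t1, pos_t2 = [], []
        for seed in (13, 29, 47):
            samples, expr = simulate.generate_cohort(
                simulate.default_config(), seed=seed, include_t2=True)
            est = SignatureCV(spec, outer_repeats=3, inner_repeats=1,
                              random_state=2).fit(expr, samples)
            probs = predict_cohort(est.bundle_, expr, samples)
            t2 = samples[samples["timepoint"] == "T2"]
            pos_t1.extend(probs.loc[t2["patient_id"] + "_T1"] > est.cutoff_)
            pos_t2.extend(probs.loc[t2["sample_id"]] > est.cutoff_)
        rep = evaluate.cohens_kappa(pos_t1, pos_t2)
        assert rep.kappa > 0.3

    def test_missing_gene_rejected(self, small_cv):
        samples, expr, spec, est = small_cv
        with pytest.raises(ValidationError, match="lacks genes"):
            predict_cohort(est.bundle_, expr.drop(columns=["CD40"]), samples)


def test_cycle_auc_summaries_shape(small_cv):
    *_, est = small_cv
    aucs = evaluate.cycle_aucs(est.ensemble_)
    assert aucs.shape == (2,)
    med, lo, hi = evaluate.summarize_cycles(aucs)
    assert lo <= med <= hi
    assert med > 0.8  # planted consensus signal is strong
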