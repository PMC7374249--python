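"""Outer repeated stratified cross-validation of signature calibration.

Each cross-validation cycle splits the baseline (T1) kidney-transplant
recipients at random, in strata by clinical group (TOL/ST/CR), into k
folds. Every calibration step — fitting the per-gene drug-adjustment
models on the treated non-tolerant training samples, selecting the
elastic-net penalty by internal cross-validation, fitting the penalized
logistic model — is performed inside the training subset only; the
held-out fold receives a predicted probability of tolerance from a
model that never saw it. With the defaults (100 repeats of six-fold
cycles) this produces 100 out-of-fold probability vectors, 600 elastic
net models, and 600 drug-adjustment models per gene. The final model is
the coefficient-wise median of the ensemble, and the classification
cut-off is the median predicted probability among tolerant recipients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._folds import stratified_assign
from .adjust import DrugAdjuster
from .core import (
    DRUG_DUMMIES,
    DrugAdjustmentModel,
    ElasticNetModel,
    ModelBundle,
    SignatureSpec,
    ValidationError,
)
from .enet import ElasticNetLogitCV, median_model, predict_probability

KTR_GROUPS = ("TOL", "ST", "CR")


@dataclass(frozen=True)
class CVConfig:
    """Settings of the outer cross-validation engine.

    ``inner_repeats`` controls the internal lambda-selection search in
    each outer training fold; 10 is the library default, the full
    100-repeat search and a reduced single-repeat search are available
    through this switch.
    """

    outer_folds: int = 6
    outer_repeats: int = 100
    inner_folds: int = 6
    inner_repeats: int = 10
    n_lambdas: int = 100
    lambda_rule: str = "min"
    seed: int = 0

    def __post_init__(self):
        if self.outer_folds < 2:
            raise ValidationError("outer_folds must be >= 2")
        if self.outer_repeats < 1:
            raise ValidationError("outer_repeats must be >= 1")


@dataclass
class CVEnsemble:
    """Everything collected across the cross-validation cycles."""

    signature: SignatureSpec
    config: CVConfig
    labels: pd.Series  # 1 = TOL, indexed by sample_id (T1 KTRs)
    probabilities: pd.DataFrame  # samples x repeats, out-of-fold
    models: list[ElasticNetModel]  # folds*repeats models, repeat-major
    fold_assignments: np.ndarray  # repeats x samples
    adjustment_coefs: dict = field(default_factory=dict)  # gene -> (models, 6)
    adjustment_r2: pd.DataFrame | None = None  # models x genes
    adjustment_n_fit: np.ndarray | None = None  # per model

    @property
    def coefficients(self) -> pd.DataFrame:
        """Per-model elastic-net coefficients (models x genes + intercept)."""
        rows = [list(m.coef) + [m.intercept] for m in self.models]
        return pd.DataFrame(
            rows, columns=list(self.signature.genes) + ["(intercept)"]
        )

    @property
    def lambdas(self) -> np.ndarray:
        return np.array([m.lam for m in self.models])


def stratified_folds(samples: pd.DataFrame, k: int, seed=None) -> pd.Series:
    """Deal T1 samples into k folds, stratified by clinical group."""
    rng = np.random.default_rng(seed)
    folds = stratified_assign(samples["group"].to_numpy(), k, rng)
    return pd.Series(folds, index=samples["sample_id"].to_numpy(), name="fold")


def _cohort_views(expr: pd.DataFrame, samples: pd.DataFrame,
                  spec: SignatureSpec):
    missing = [g for g in spec.genes if g not in expr.columns]
    if missing:
        raise ValidationError(f"expression matrix lacks genes: {missing}")
    mask = samples["group"].isin(KTR_GROUPS) & (samples["timepoint"] == "T1")
    sub = samples.loc[mask].reset_index(drop=True)
    X = expr.loc[sub["sample_id"], list(spec.genes)]
    if X.isna().to_numpy().any():
        raise ValidationError("expression has missing values; impute first")
    y = (sub["group"] == "TOL").astype(int)
    return sub, X, y


def run_cv(expr: pd.DataFrame, samples: pd.DataFrame, spec: SignatureSpec,
           config: CVConfig | None = None) -> CVEnsemble:
    """Run the repeated stratified outer cross-validation for one signature.

    Healthy controls are neither trained on nor predicted here; they are
    scored only by the final model (see :func:`predict_cohort`).
    """
    if config is None:
        config = CVConfig()
    sub, X, y = _cohort_views(expr, samples, spec)
    n = len(sub)
    strata = sub["group"].to_numpy()

    probs = np.full((n, config.outer_repeats), np.nan)
    models: list[ElasticNetModel] = []
    fold_assignments = np.empty((config.outer_repeats, n), dtype=np.int64)
    adj_coefs = {g: [] for g in spec.genes} if spec.drug_adjusted else {}
    adj_r2_rows = []
    adj_n_fit = []

    for rep in range(config.outer_repeats):
        rng = np.random.default_rng([config.seed, rep])
        folds = stratified_assign(strata, config.outer_folds, rng)
        fold_assignments[rep] = folds
        for f in range(config.outer_folds):
            test = folds == f
            train = ~test
            y_train = y.to_numpy()[train]
            if (y_train == 1).sum() < 2:
                raise ValidationError(
                    "a training fold has fewer than 2 tolerant samples; "
                    "use fewer folds or more tolerant samples"
                )
            X_train = X.iloc[train]
            X_test = X.iloc[test]
            if spec.drug_adjusted:
                adjuster = DrugAdjuster().fit(X_train, sub.loc[train])
                X_train = adjuster.transform(X_train, sub.loc[train])
                X_test = adjuster.transform(X_test, sub.loc[test])
                for g in spec.genes:
                    m = adjuster.models_[g]
                    adj_coefs[g].append(
                        [m.intercept, m.pred_on, m.cni_cyc, m.cni_tac,
                         m.ap_aza, m.ap_mmf]
                    )
                adj_r2_rows.append(adjuster.r_squared_.to_numpy())
                adj_n_fit.append(next(iter(adjuster.models_.values())).n_fit)
            inner_seed = int(rng.integers(0, 2**31 - 1))
            est = ElasticNetLogitCV(
                alpha=spec.alpha,
                n_folds=config.inner_folds,
                n_repeats=config.inner_repeats,
                n_lambdas=config.n_lambdas,
                lambda_rule=config.lambda_rule,
                random_state=inner_seed,
            ).fit(X_train.to_numpy(), y_train)
            models.append(est.to_model(spec.genes))
            probs[test, rep] = est.predict_proba(X_test.to_numpy())[:, 1]

    ensemble = CVEnsemble(
        signature=spec,
        config=config,
        labels=pd.Series(y.to_numpy(), index=X.index, name="tol"),
        probabilities=pd.DataFrame(
            probs, index=X.index,
            columns=[f"rep{r}" for r in range(config.outer_repeats)],
        ),
        models=models,
        fold_assignments=fold_assignments,
    )
    if spec.drug_adjusted:
        ensemble.adjustment_coefs = {
            g: np.asarray(v) for g, v in adj_coefs.items()
        }
        ensemble.adjustment_r2 = pd.DataFrame(
            np.asarray(adj_r2_rows), columns=list(spec.genes)
        )
        ensemble.adjustment_n_fit = np.asarray(adj_n_fit)
    return ensemble


def _median_adjustment_models(
    ensemble: CVEnsemble,
) -> dict[str, DrugAdjustmentModel]:
    n_fit = int(np.median(ensemble.adjustment_n_fit))
    out = {}
    for gene, arr in ensemble.adjustment_coefs.items():
        med = np.median(arr, axis=0)
        r2 = float(np.median(ensemble.adjustment_r2[gene]))
        out[gene] = DrugAdjustmentModel(
            gene_id=gene,
            intercept=float(med[0]),
            **{name: float(v) for name, v in zip(DRUG_DUMMIES, med[1:])},
            r_squared=r2,
            n_fit=n_fit,
        )
    return out


def finalize_signature(expr: pd.DataFrame, samples: pd.DataFrame,
                       spec: SignatureSpec, ensemble: CVEnsemble) -> ModelBundle:
    """Aggregate the CV ensemble into the final exportable model.

    The elastic-net coefficients are the coefficient-wise medians of the
    ensemble. Two drug-adjustment variants are stored: the full-data fit
    on all treated non-tolerant baseline samples and the coefficient-wise
    CV medians (the default for prediction). The cut-off is the median
    predicted probability of tolerance among TOL recipients.
    """
    enet = median_model(ensemble.models)
    adjustment = {}
    if spec.drug_adjusted:
        sub, X, _ = _cohort_views(expr, samples, spec)
        full = DrugAdjuster().fit(X, sub)
        adjustment = {
            "full_data": full.models_,
            "cv_median": _median_adjustment_models(ensemble),
        }
    bundle = ModelBundle(
        signature=spec,
        enet=enet,
        cutoff=0.5,  # provisional; replaced below
        adjustment_models=adjustment,
    )
    probs = predict_cohort(bundle, expr, samples)
    sub, _, y = _cohort_views(expr, samples, spec)
    tol_probs = probs.loc[sub.loc[y == 1, "sample_id"]]
    bundle.cutoff = float(np.median(tol_probs))
    return bundle


def predict_cohort(bundle: ModelBundle, expr: pd.DataFrame,
                   samples: pd.DataFrame) -> pd.Series:
    """Score any cohort (including T2 and healthy controls) with a bundle.

    Drug-adjusted signatures residualize first with the stored
    coefficients; tolerant recipients and healthy controls are evaluated
    off treatment by construction of their indicator columns.
    """
    genes = list(bundle.signature.genes)
    missing = [g for g in genes if g not in expr.columns]
    if missing:
        raise ValidationError(f"expression matrix lacks genes: {missing}")
    samples = samples.set_index("sample_id").loc[expr.index].reset_index()
    X = expr.loc[:, genes]
    if bundle.signature.drug_adjusted:
        X = DrugAdjuster.from_models(bundle.active_adjustment).transform(X, samples)
    p = predict_probability(bundle.enet, X)
    return pd.Series(p, index=expr.index, name="prob_tol")


class SignatureCV(BaseEstimator):
    """Estimator wrapper: calibrate one signature by repeated CV.

    ``fit(expr, samples)`` runs the outer cross-validation and
    finalizes the model. Fitted attributes: ``ensemble_`` (the
    :class:`CVEnsemble`), ``bundle_`` (the exportable model),
    ``cutoff_``.
    """

    def __init__(self, signature: SignatureSpec, outer_folds: int = 6,
                 outer_repeats: int = 100, inner_folds: int = 6,
                 inner_repeats: int = 10, n_lambdas: int = 100,
                 lambda_rule: str = "min", random_state: int = 0):
        self.signature = signature
        self.outer_folds = outer_folds
        self.outer_repeats = outer_repeats
        self.inner_folds = inner_folds
        self.inner_repeats = inner_repeats
        self.n_lambdas = n_lambdas
        self.lambda_rule = lambda_rule
        self.random_state = random_state

    def _config(self) -> CVConfig:
        return CVConfig(
            outer_folds=self.outer_folds,
            outer_repeats=self.outer_repeats,
            inner_folds=self.inner_folds,
            inner_repeats=self.inner_repeats,
            n_lambdas=self.n_lambdas,
            lambda_rule=self.lambda_rule,
            seed=self.random_state,
        )

    def fit(self, expr: pd.DataFrame, samples: pd.DataFrame):
        self.ensemble_ = run_cv(expr, samples, self.signature, self._config())
        self.bundle_ = finalize_signature(expr, samples, self.signature,
                                          self.ensemble_)
        self.cutoff_ = self.bundle_.cutoff
        return self

    def predict_proba(self, expr: pd.DataFrame, samples: pd.DataFrame) -> pd.Series:
        return predict_cohort(self.bundle_, expr, samples)

    def predict(self, expr: pd.DataFrame, samples: pd.DataFrame) -> pd.Series:
        p = self.predict_proba(expr, samples)
        return (p > self.cutoff_).astype(int)
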