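"""In-silico drug withdrawal: per-gene linear adjustment for IS therapy.

For each gene an ordinary least-squares model

    -dCt_gene ~ pred_on + cni_cyc + cni_tac + ap_aza + ap_mmf

is fitted on treated non-tolerant recipients (the only samples where
drug indicators vary). Drug-adjusted expression is the residual: the
observed value minus the regimen-predicted value, with tolerant
recipients and healthy controls evaluated "off treatment" (all
indicators zero, residual = observed - intercept). Residuals capture
the variability in expression not explained by immunosuppression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .core import (
    DRUG_DUMMIES,
    DrugAdjustmentModel,
    ValidationError,
    drug_design_matrix,
)


def _check_full_rank(design: np.ndarray, columns) -> None:
    X = np.column_stack([np.ones(design.shape[0]), design])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending column(s): zero variance or duplicated
        bad = [c for j, c in enumerate(columns) if design[:, j].std() == 0]
        if not bad:
            bad = ["(linear combination of columns)"]
        raise ValidationError(
            f"drug design matrix is rank deficient on the fit set; "
            f"collinear/constant columns: {bad}"
        )


def _ols_fit(Y: np.ndarray, design: np.ndarray):
    """Vectorized OLS of each column of Y on [1, design].

    Returns (coefs with intercept first, shape (G, 6)) and per-gene R^2.
    """
    n = design.shape[0]
    X = np.column_stack([np.ones(n), design])
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ coef
    rss = ((Y - fitted) ** 2).sum(axis=0)
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
    return coef.T, np.clip(r2, 0.0, 1.0)


class DrugAdjuster(BaseEstimator, TransformerMixin):
    """Residualizing transformer for immunosuppressive-drug effects.

    ``fit`` takes the expression matrix together with the clinical
    table, selects the fit set (by default treated non-tolerant baseline
    samples: groups ST/CR at T1), and fits one OLS model per gene.
    ``transform`` residualizes any cohort — including follow-up samples
    and healthy controls — using the stored coefficients.

    ``drop_absent_levels`` controls how drug levels with no sample on
    the fit set are handled: strictly (rank-deficiency error, the
    default) or by fixing their coefficient at zero — structurally
    absent levels are not evidence of collinearity.

    Attributes
    ----------
    models_ : dict gene -> :class:`DrugAdjustmentModel`.
    r_squared_ : Series of fit-set R^2 per gene.
    """

    def __init__(self, fit_groups=("ST", "CR"), timepoint: str | None = "T1",
                 drop_absent_levels: bool = False):
        self.fit_groups = fit_groups
        self.timepoint = timepoint
        self.drop_absent_levels = drop_absent_levels

    def _fit_mask(self, samples: pd.DataFrame) -> np.ndarray:
        mask = samples["group"].isin(self.fit_groups).to_numpy()
        if self.timepoint is not None:
            mask &= (samples["timepoint"] == self.timepoint).to_numpy()
        return mask

    def fit(self, expr: pd.DataFrame, samples: pd.DataFrame):
        if not expr.index.equals(pd.Index(samples["sample_id"])):
            samples = samples.set_index("sample_id").loc[expr.index].reset_index()
        mask = self._fit_mask(samples)
        n_fit = int(mask.sum())
        design_full = drug_design_matrix(samples.loc[mask]).to_numpy()
        present = design_full.std(axis=0) > 0
        if self.drop_absent_levels and not present.all():
            design = design_full[:, present]
            columns = [c for c, keep in zip(DRUG_DUMMIES, present) if keep]
        else:
            design = design_full
            columns = list(DRUG_DUMMIES)
        n_params = len(columns) + 1
        if n_fit <= n_params:
            raise ValidationError(
                f"fit set has {n_fit} samples for {n_params} parameters; "
                "need more samples than parameters (7 for the full design)"
            )
        _check_full_rank(design, columns)
        Y = expr.to_numpy(dtype=float)[mask]
        if np.isnan(Y).any():
            raise ValidationError("expression matrix has missing values; impute first")
        coefs_fit, r2 = _ols_fit(Y, design)
        coefs = np.zeros((expr.shape[1], 6))
        coefs[:, 0] = coefs_fit[:, 0]
        cols_idx = [DRUG_DUMMIES.index(c) + 1 for c in columns]
        coefs[:, cols_idx] = coefs_fit[:, 1:]
        self.models_ = {
            gene: DrugAdjustmentModel(
                gene_id=gene,
                intercept=float(coefs[g, 0]),
                pred_on=float(coefs[g, 1]),
                cni_cyc=float(coefs[g, 2]),
                cni_tac=float(coefs[g, 3]),
                ap_aza=float(coefs[g, 4]),
                ap_mmf=float(coefs[g, 5]),
                r_squared=float(r2[g]),
                n_fit=n_fit,
            )
            for g, gene in enumerate(expr.columns)
        }
        self.r_squared_ = pd.Series(r2, index=expr.columns, name="r_squared")
        self.n_features_in_ = expr.shape[1]
        return self

    def transform(self, expr: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
        return residualize(expr, samples, self.models_)

    @classmethod
    def from_models(cls, models: dict[str, DrugAdjustmentModel]) -> "DrugAdjuster":
        est = cls()
        est.models_ = dict(models)
        est.r_squared_ = pd.Series({g: m.r_squared for g, m in models.items()})
        est.n_features_in_ = len(models)
        return est


def fit_adjustment(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    gene: str,
    fit_groups=("ST", "CR"),
    timepoint: str | None = "T1",
) -> DrugAdjustmentModel:
    """Fit the drug-adjustment OLS model for a single gene."""
    if gene not in expr.columns:
        raise ValidationError(f"gene {gene!r} not in expression matrix")
    adj = DrugAdjuster(fit_groups=fit_groups, timepoint=timepoint)
    adj.fit(expr[[gene]], samples)
    return adj.models_[gene]


def residualize(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    models: dict[str, DrugAdjustmentModel],
) -> pd.DataFrame:
    """Subtract the regimen-predicted expression from every sample.

    TOL and HC samples carry all-zero drug indicators (validated
    upstream), so their residual is observed minus the model intercept.
    """
    missing = [g for g in expr.columns if g not in models]
    if missing:
        raise ValidationError(f"no adjustment model for genes: {missing}")
    if not expr.index.equals(pd.Index(samples["sample_id"])):
        samples = samples.set_index("sample_id").loc[expr.index].reset_index()
    design = drug_design_matrix(samples).to_numpy()
    genes = list(expr.columns)
    intercepts = np.array([models[g].intercept for g in genes])
    coefs = np.array([models[g].coefficients for g in genes])  # (G, 5)
    predicted = intercepts[None, :] + design @ coefs.T
    out = expr - predicted
    out.attrs.update(expr.attrs)
    out.attrs["drug_adjusted"] = True
    return out


def explained_variability(models_per_gene: dict[str, list[float]]) -> pd.DataFrame:
    """Summarize drug-model R^2 ensembles per gene.

    Input maps gene -> R^2 values across cross-validation refits;
    returns median and the 2.5th-97.5th centile range per gene, the
    convention used to annotate per-gene drug influence.
    """
    rows = {}
    for gene, values in models_per_gene.items():
        values = np.asarray(list(values), dtype=float)
        if values.size == 0:
            raise ValidationError(f"gene {gene!r}: empty R^2 ensemble")
        rows[gene] = {
            "median": float(np.median(values)),
            "p2.5": float(np.percentile(values, 2.5)),
            "p97.5": float(np.percentile(values, 97.5)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
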