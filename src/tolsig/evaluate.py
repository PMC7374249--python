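"""Evaluation battery: ROC/AUC with DeLong statistics, median-cutoff
classification, Cohen's kappa, drug-influence and dose-response models,
rank-sum comparisons, and per-cycle centile summaries.

The AUC is the Mann-Whitney statistic (ties count one half); its
variance uses DeLong's structural components, which also provide the
paired test comparing two ROC curves computed on the same samples.
Classification uses a conservative uniform cut-off — the median
predicted probability among tolerant recipients — which fixes
sensitivity at 50% whenever the tolerant group has an even size with
distinct probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import DRUG_DUMMIES, ValidationError, drug_design_matrix

LOGIT_CLIP = 1e-12


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------


def _placements(scores: np.ndarray, labels: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes must be present")
    # psi(x, y) = 1 if x > y, 0.5 if tie, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01


def auc_mann_whitney(scores, labels) -> float:
    """AUC by exhaustive pair counting (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    v10, _ = _placements(scores, labels)
    return float(v10.mean())


def auc_delong(scores, labels) -> tuple[float, float, float]:
    """AUC with a 95% DeLong confidence interval, truncated to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    v10, v01 = _placements(scores, labels)
    m, n = v10.size, v01.size
    if m < 2 or n < 2:
        raise ValidationError("need at least 2 samples per class for a CI")
    auc = float(v10.mean())
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    half = stats.norm.ppf(0.975) * np.sqrt(var)
    return auc, float(max(0.0, auc - half)), float(min(1.0, auc + half))


def delong_paired_test(scores_a, scores_b, labels) -> float:
    """Two-sided DeLong test for paired ROC curves (same samples/labels)."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValidationError("paired scores and labels must share length")
    va10, va01 = _placements(scores_a, labels)
    vb10, vb01 = _placements(scores_b, labels)
    m, n = va10.size, va01.size
    auc_a, auc_b = va10.mean(), vb10.mean()
    s10 = np.cov(va10, vb10, ddof=1)
    s01 = np.cov(va01, vb01, ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# classification at the median-TOL cutoff
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassificationReport:
    cutoff: float
    positive: pd.Series  # boolean, prob strictly above cutoff
    sensitivity: float
    specificity: float
    tol_positive_st: int
    tol_positive_cr: int


def tol_cutoff_classify(probs: pd.Series, samples: pd.DataFrame,
                        cutoff: float | None = None) -> ClassificationReport:
    """Classify at the median tolerant-group probability (strictly above).

    ``cutoff=None`` derives it from the given cohort's TOL samples; a
    stored cut-off (e.g. from the calibration cohort) can be supplied
    for follow-up cohorts. Specificity is computed over treated
    non-tolerant recipients (ST/CR); healthy controls are ignored.
    """
    samples = samples.set_index("sample_id").loc[probs.index]
    tol = samples["group"] == "TOL"
    if cutoff is None:
        if tol.sum() < 2:
            raise ValidationError("need >= 2 tolerant samples to set a cutoff")
        cutoff = float(np.median(probs[tol]))
    positive = probs > cutoff
    non_tol = samples["group"].isin(["ST", "CR"])
    sens = float(positive[tol].mean()) if tol.any() else float("nan")
    spec = float((~positive[non_tol]).mean()) if non_tol.any() else float("nan")
    return ClassificationReport(
        cutoff=cutoff,
        positive=positive,
        sensitivity=sens,
        specificity=spec,
        tol_positive_st=int(positive[samples["group"] == "ST"].sum()),
        tol_positive_cr=int(positive[samples["group"] == "CR"].sum()),
    )


@dataclass(frozen=True)
class AgreementReport:
    kappa: float
    counts: tuple[int, int, int, int]  # a=both pos, b=a-only, c=b-only, d=both neg


def cohens_kappa(class_a, class_b) -> AgreementReport:
    """Chance-corrected agreement of two binary classifications."""
    a = np.asarray(class_a).astype(bool)
    b = np.asarray(class_b).astype(bool)
    if a.shape != b.shape:
        raise ValidationError("classifications must share length")
    n = a.size
    both = int((a & b).sum())
    a_only = int((a & ~b).sum())
    b_only = int((~a & b).sum())
    neither = int((~a & ~b).sum())
    p_o = (both + neither) / n
    p_a1, p_b1 = a.mean(), b.mean()
    p_e = p_a1 * p_b1 + (1 - p_a1) * (1 - p_b1)
    if p_e >= 1.0:
        kappa = 1.0  # both raters constant and equal
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    return AgreementReport(float(kappa), (both, a_only, b_only, neither))


# ---------------------------------------------------------------------------
# drug influence on predictions, dose response
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugInfluenceReport:
    r_squared: float
    coefficients: pd.DataFrame  # per dummy: coef, se, p (Wald)
    n: int


def log_odds(probs) -> np.ndarray:
    p = np.clip(np.asarray(probs, dtype=float), LOGIT_CLIP, 1 - LOGIT_CLIP)
    return np.log(p / (1 - p))


def drug_influence(probs: pd.Series, samples: pd.DataFrame,
                   fit_groups=("ST", "CR"),
                   timepoint: str | None = "T1") -> DrugInfluenceReport:
    """Regress predicted log-odds of tolerance on the drug indicators.

    Reports the fraction of variability in the predictions explained by
    the immunosuppressive regimen (R^2) with per-drug Wald p-values,
    over treated non-tolerant baseline samples.
    """
    samples = samples.set_index("sample_id").loc[probs.index].reset_index()
    mask = samples["group"].isin(fit_groups)
    if timepoint is not None:
        mask &= samples["timepoint"] == timepoint
    sub = samples.loc[mask]
    y = log_odds(probs.to_numpy()[mask.to_numpy()])
    design = drug_design_matrix(sub)
    X = sm.add_constant(design.to_numpy())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("drug design matrix is rank deficient")
    fit = sm.OLS(y, X).fit()
    coefs = pd.DataFrame(
        {
            "coef": fit.params[1:],
            "se": fit.bse[1:],
            "p": fit.pvalues[1:],
        },
        index=list(DRUG_DUMMIES),
    )
    return DrugInfluenceReport(float(fit.rsquared), coefs, int(mask.sum()))


#: paired same-class drugs excluded from each other's dose models
_PAIRED = {"cyc": "tac", "tac": "cyc", "aza": "mmf", "mmf": "aza"}
_DUMMY_OF = {"pred": "pred_on", "cyc": "cni_cyc", "tac": "cni_tac",
             "aza": "ap_aza", "mmf": "ap_mmf"}


def dose_response(values: pd.Series, samples: pd.DataFrame, drug: str,
                  fit_groups=("ST", "CR"), timepoint: str | None = "T1",
                  top_centile: float = 2.5) -> tuple[float, float]:
    """Dose effect of one drug on expression or predicted log-odds.

    The categorical indicator of ``drug`` is replaced by the continuous
    dose (mg/day, zero when off the drug); samples on the paired
    same-class drug and samples with dose in the top centiles are
    excluded; the remaining drug-class dummies stay as covariates.
    Returns (slope per mg/day, Wald p).
    """
    if drug not in _DUMMY_OF:
        raise ValidationError(f"unknown drug {drug!r}")
    samples = samples.set_index("sample_id").loc[values.index].reset_index()
    mask = samples["group"].isin(fit_groups)
    if timepoint is not None:
        mask &= samples["timepoint"] == timepoint
    paired = _PAIRED.get(drug)
    if paired is not None:
        indicator, level = {"cyc": ("cni", "cyc"), "tac": ("cni", "tac"),
                            "aza": ("ap", "aza"), "mmf": ("ap", "mmf")}[paired]
        mask &= samples[indicator] != level
    dose_col = f"dose_{drug}"
    if dose_col not in samples.columns:
        raise ValidationError(f"clinical table lacks {dose_col}")
    dose = pd.to_numeric(samples[dose_col], errors="coerce").fillna(0.0)
    on = dose > 0
    if (on & mask).any():
        ceiling = np.percentile(dose[mask & on], 100 - top_centile)
        mask &= ~(on & (dose > ceiling))
    sub = samples.loc[mask]
    if len(sub) < 10:
        raise ValidationError(f"only {len(sub)} samples after exclusions (<10)")
    d = dose[mask].to_numpy()
    if d.std() == 0:
        raise ValidationError("dose has no variance after exclusions")
    design = drug_design_matrix(sub)
    drop = [_DUMMY_OF[drug]] + ([_DUMMY_OF[paired]] if paired else [])
    covars = design.drop(columns=drop)
    covars = covars.loc[:, covars.std() > 0]
    X = sm.add_constant(np.column_stack([d, covars.to_numpy()]))
    fit = sm.OLS(values.to_numpy()[mask.to_numpy()], X).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


# ---------------------------------------------------------------------------
# generic comparisons and summaries
# ---------------------------------------------------------------------------


def rank_sum_test(values_a, values_b) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value.

    Exact enumeration for small tie-free samples (<= 25 total),
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= 25 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=(method == "asymptotic"))
    return float(min(1.0, res.pvalue))


def summarize_cycles(values) -> tuple[float, float, float]:
    """Median and empirical 2.5th/97.5th centiles (linear interpolation)."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValidationError("no values to summarize")
    return (
        float(np.median(values)),
        float(np.percentile(values, 2.5)),
        float(np.percentile(values, 97.5)),
    )


def cycle_aucs(ensemble) -> np.ndarray:
    """Per-repeat AUC of the out-of-fold probabilities of a CV ensemble."""
    y = ensemble.labels.to_numpy()
    return np.array([
        auc_mann_whitney(ensemble.probabilities[col].to_numpy(), y)
        for col in ensemble.probabilities.columns
    ])


def cycle_specificities(ensemble) -> np.ndarray:
    """Per-repeat specificity at that repeat's median-TOL cutoff."""
    y = ensemble.labels.to_numpy()
    out = []
    for col in ensemble.probabilities.columns:
        p = ensemble.probabilities[col].to_numpy()
        cutoff = np.median(p[y == 1])
        out.append(float((p[y == 0] <= cutoff).mean()))
    return np.array(out)


@dataclass(frozen=True)
class EvaluationReport:
    """Final-model performance in the shape of the comparison tables."""

    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    tol_positive_st: int
    tol_positive_cr: int
    cv_auc_median: float | None = None
    cv_auc_p2_5: float | None = None
    cv_auc_p97_5: float | None = None

    def __post_init__(self):
        if not (self.ci_low - 1e-12 <= self.auc <= self.ci_high + 1e-12):
            raise ValidationError("confidence interval does not contain the AUC")


def evaluate_predictions(probs: pd.Series, samples: pd.DataFrame,
                         cutoff: float | None = None,
                         ensemble=None) -> EvaluationReport:
    """Assemble the per-signature evaluation row.

    AUC discriminates TOL from treated non-tolerant recipients; when a
    CV ensemble is given, its per-cycle AUC summary (median, 2.5-97.5
    centiles) is included.
    """
    samples_idx = samples.set_index("sample_id").loc[probs.index]
    ktr = samples_idx["group"].isin(["TOL", "ST", "CR"])
    y = (samples_idx.loc[ktr, "group"] == "TOL").astype(int).to_numpy()
    p = probs[ktr].to_numpy()
    auc, lo, hi = auc_delong(p, y)
    cls = tol_cutoff_classify(probs[ktr.to_numpy()], samples, cutoff=cutoff)
    cv_stats = (None, None, None)
    if ensemble is not None:
        cv_stats = summarize_cycles(cycle_aucs(ensemble))
    return EvaluationReport(
        auc=auc, ci_low=lo, ci_high=hi,
        cutoff=cls.cutoff,
        sensitivity=cls.sensitivity,
        specificity=cls.specificity,
        tol_positive_st=cls.tol_positive_st,
        tol_positive_cr=cls.tol_positive_cr,
        cv_auc_median=cv_stats[0], cv_auc_p2_5=cv_stats[1],
        cv_auc_p97_5=cv_stats[2],
    )
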