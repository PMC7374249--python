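"""Retention-frequency consensus gene selection.

All genes from the examined signatures enter one drug-adjusted model
with a sparsity-favouring penalty (alpha near lasso); genes whose
coefficient stays non-zero in at least a threshold fraction of the
cross-validation elastic-net models form the parsimonious consensus
set, which is then re-calibrated from scratch with a retention-favouring
penalty (alpha near ridge).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import ModelBundle, SignatureSpec, ValidationError
from .cv import CVConfig, CVEnsemble, SignatureCV
from .signatures import ALPHA_CALIBRATE, ALPHA_SELECT

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusReport:
    """Retention frequencies and the selected consensus gene list."""

    frequencies: pd.Series  # per gene, fraction of models with non-zero coef
    selected: tuple[str, ...]
    threshold: float
    n_models: int


def retention_frequency(ensemble: CVEnsemble) -> pd.Series:
    """Fraction of CV models in which each gene kept a non-zero coefficient."""
    if not ensemble.models:
        raise ValidationError("empty model ensemble")
    coefs = np.array([m.coef for m in ensemble.models])
    freq = (coefs != 0).mean(axis=0)
    return pd.Series(freq, index=list(ensemble.signature.genes),
                     name="retention_frequency")


def select_consensus(frequencies: pd.Series, threshold: float = 0.75) -> list[str]:
    """Genes retained in at least ``threshold`` of the models (inclusive)."""
    selected = [g for g in frequencies.index if frequencies[g] >= threshold]
    if not selected:
        logger.warning(
            "no gene reached retention frequency %.2f; empty consensus set",
            threshold,
        )
    return selected


class ConsensusSelector(BaseEstimator):
    """Two-stage consensus pipeline over the union gene set.

    Stage 1 runs a drug-adjusted CV at a sparsity-favouring alpha over
    all genes; stage 2 computes retention frequencies and keeps genes at
    or above the threshold; stage 3 re-runs a fresh drug-adjusted CV at
    a retention-favouring alpha restricted to the selected genes.

    The selection stage uses the one-standard-error lambda rule by
    default: stability selection asks which genes survive a genuinely
    sparse model, and the deviance-minimizing lambda is liberal enough
    to keep chance associations of the small tolerant group. The final
    calibration stage uses the deviance-minimizing rule.

    Fitted attributes: ``report_`` (:class:`ConsensusReport`),
    ``bundle_`` (the parsimonious final model), ``selection_ensemble_``
    and ``final_ensemble_`` (the two CV ensembles).
    """

    def __init__(self, threshold: float = 0.75, alpha_select: float = ALPHA_SELECT,
                 alpha_final: float = ALPHA_CALIBRATE, housekeeping=("HPRT",),
                 outer_folds: int = 6, outer_repeats: int = 100,
                 inner_folds: int = 6, inner_repeats: int = 10,
                 n_lambdas: int = 100, lambda_rule_select: str = "1se",
                 lambda_rule_final: str = "min", random_state: int = 0):
        self.threshold = threshold
        self.alpha_select = alpha_select
        self.alpha_final = alpha_final
        self.housekeeping = housekeeping
        self.outer_folds = outer_folds
        self.outer_repeats = outer_repeats
        self.inner_folds = inner_folds
        self.inner_repeats = inner_repeats
        self.n_lambdas = n_lambdas
        self.lambda_rule_select = lambda_rule_select
        self.lambda_rule_final = lambda_rule_final
        self.random_state = random_state

    def _cv(self, spec: SignatureSpec, seed: int, lambda_rule: str) -> SignatureCV:
        return SignatureCV(
            spec,
            outer_folds=self.outer_folds,
            outer_repeats=self.outer_repeats,
            inner_folds=self.inner_folds,
            inner_repeats=self.inner_repeats,
            n_lambdas=self.n_lambdas,
            lambda_rule=lambda_rule,
            random_state=seed,
        )

    def fit(self, expr: pd.DataFrame, samples: pd.DataFrame,
            all_signatures: list[SignatureSpec] | None = None):
        if all_signatures is None:
            from .signatures import PUBLISHED, SIGNATURES

            all_signatures = [SIGNATURES[n] for n in PUBLISHED]
        union: list[str] = []
        for s in all_signatures:
            union.extend(g for g in s.genes if g not in union)
        combined = SignatureSpec(
            "COMBINED-all", tuple(union), tuple(self.housekeeping),
            drug_adjusted=True, alpha=self.alpha_select,
        )
        stage1 = self._cv(combined, self.random_state,
                          self.lambda_rule_select).fit(expr, samples)
        self.selection_ensemble_ = stage1.ensemble_
        freq = retention_frequency(stage1.ensemble_)
        selected = select_consensus(freq, self.threshold)
        self.report_ = ConsensusReport(
            frequencies=freq,
            selected=tuple(selected),
            threshold=self.threshold,
            n_models=len(stage1.ensemble_.models),
        )
        if not selected:
            self.bundle_ = None
            self.final_ensemble_ = None
            return self
        parsimonious = SignatureSpec(
            "CONSENSUS", tuple(selected), tuple(self.housekeeping),
            drug_adjusted=True, alpha=self.alpha_final,
        )
        stage2 = self._cv(parsimonious, self.random_state + 1,
                          self.lambda_rule_final).fit(expr, samples)
        self.final_ensemble_ = stage2.ensemble_
        self.bundle_ = stage2.bundle_
        return self


def build_combined_pipeline(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    all_signatures: list[SignatureSpec] | None = None,
    config: CVConfig | None = None,
    threshold: float = 0.75,
    alpha_select: float = ALPHA_SELECT,
    alpha_final: float = ALPHA_CALIBRATE,
) -> tuple[ConsensusReport, ModelBundle | None]:
    """Functional wrapper over :class:`ConsensusSelector`."""
    config = config or CVConfig()
    sel = ConsensusSelector(
        threshold=threshold,
        alpha_select=alpha_select,
        alpha_final=alpha_final,
        outer_folds=config.outer_folds,
        outer_repeats=config.outer_repeats,
        inner_folds=config.inner_folds,
        inner_repeats=config.inner_repeats,
        n_lambdas=config.n_lambdas,
        random_state=config.seed,
    ).fit(expr, samples, all_signatures)
    return sel.report_, sel.bundle_
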