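"""Ct to -dCt conversion, gene-level QC, outlier recoding, imputation.

Relative expression is computed on the log2 scale with the comparative
-dCt method: -dCt(gene, sample) = Ct_ref(sample) - Ct_gene(sample),
where Ct_ref is the housekeeping Ct, or the arithmetic mean of several
housekeeping Cts (equivalent to the geometric mean of linear expression).
Higher -dCt means higher expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .core import ValidationError


@dataclass(frozen=True)
class QCReport:
    """Per-gene fraction of samples failing the Ct ceiling.

    A gene is flagged when the fraction of samples with Ct strictly
    above ``ct_threshold`` (missing Ct counted as above: non-amplification
    is the failure mode screened for) exceeds ``max_fraction``.
    """

    fractions: pd.Series
    flagged: tuple[str, ...]
    ct_threshold: float
    max_fraction: float


def compute_delta_ct(
    ct: pd.DataFrame,
    hk_map: dict[str, tuple[str, ...]] | list[str] | tuple[str, ...],
) -> pd.DataFrame:
    """Convert a Ct matrix to -dCt relative expression.

    Parameters
    ----------
    ct : samples x genes Ct matrix (housekeeping genes included).
    hk_map : either a single housekeeping gene list applied to every
        target gene, or a mapping target gene -> housekeeping gene list.
        Target genes are the mapping keys (or all non-housekeeping
        columns when a single list is given).

    Missing target Ct stays missing; a missing housekeeping Ct is an
    error naming the sample, since the reference must exist for every
    sample.
    """
    if not isinstance(hk_map, dict):
        hk = tuple(hk_map)
        targets = [g for g in ct.columns if g not in set(hk)]
        hk_map = {g: hk for g in targets}

    out = {}
    ref_cache: dict[tuple[str, ...], pd.Series] = {}
    for gene, hk in hk_map.items():
        hk = tuple(hk)
        if gene not in ct.columns:
            raise ValidationError(f"target gene {gene!r} not in Ct matrix")
        missing_hk = [h for h in hk if h not in ct.columns]
        if missing_hk:
            raise ValidationError(f"housekeeping genes {missing_hk} not in Ct matrix")
        if hk not in ref_cache:
            ref_block = ct.loc[:, list(hk)]
            bad = ref_block.isna().any(axis=1)
            if bad.any():
                sid = ref_block.index[bad][0]
                raise ValidationError(
                    f"sample {sid!r}: missing housekeeping Ct for {hk}"
                )
            ref_cache[hk] = ref_block.mean(axis=1)
        out[gene] = ref_cache[hk] - ct[gene]
    df = pd.DataFrame(out, index=ct.index)
    df.attrs["layout"] = "delta_ct"
    return df


def qc_flag_genes(
    ct: pd.DataFrame, ct_threshold: float = 35.0, max_fraction: float = 0.10
) -> QCReport:
    """Flag genes too often above the conventional Ct ceiling.

    The exceedance is strict (Ct > threshold); a gene at exactly the
    threshold does not count. The default ceiling of 35 cycles marks
    expression too low for reliable routine RT-qPCR quantification.
    """
    values = ct.to_numpy(dtype=float)
    above = np.isnan(values) | (values > ct_threshold)
    fractions = pd.Series(above.mean(axis=0), index=ct.columns, name="fraction_above")
    flagged = tuple(fractions.index[fractions > max_fraction])
    return QCReport(fractions, flagged, ct_threshold, max_fraction)


def recode_outliers(expr: pd.DataFrame, k_iqr: float = 3.0) -> pd.DataFrame:
    """Recode extreme expression values to the next highest/lowest value.

    Per gene, values outside the Tukey outer fences
    (Q1 - k_iqr*IQR, Q3 + k_iqr*IQR) are replaced by the most extreme
    observed value inside the fences on that side. Idempotent; never
    creates values outside the observed range; missing values pass
    through untouched.
    """
    out = expr.copy()
    for gene in expr.columns:
        col = expr[gene].to_numpy(dtype=float)
        obs = col[~np.isnan(col)]
        if obs.size < 4:
            raise ValidationError(
                f"gene {gene!r}: {obs.size} non-missing values (< 4), cannot "
                "estimate outlier fences"
            )
        q1, q3 = np.percentile(obs, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - k_iqr * iqr, q3 + k_iqr * iqr
        inside = obs[(obs >= lo) & (obs <= hi)]
        if inside.size == 0:  # cannot happen: quartiles are inside the fences
            continue
        lo_repl, hi_repl = inside.min(), inside.max()
        new = col.copy()
        new[col < lo] = lo_repl
        new[col > hi] = hi_repl
        out[gene] = new
    out.attrs.update(expr.attrs)
    return out


def impute_knn(expr: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill missing cells with the k-nearest-neighbour mean in gene space.

    Each missing (gene, sample) cell becomes the unweighted mean over
    the k genes closest to it (Euclidean distance across commonly
    observed samples) of their values at that sample — the convention of
    gene-expression KNN imputation. Non-missing entries are unchanged.
    """
    values = expr.to_numpy(dtype=float)
    if not np.isnan(values).any():
        return expr.copy()
    all_missing = np.isnan(values).all(axis=0)
    if all_missing.any():
        gene = expr.columns[all_missing][0]
        raise ValidationError(f"gene {gene!r} entirely missing, cannot impute")
    n_genes = values.shape[1]
    if k >= n_genes:
        raise ValidationError(f"k={k} requires more than {n_genes} genes")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    # gene-space neighbourhoods: genes are rows for the imputer
    filled = imputer.fit_transform(values.T).T
    out = pd.DataFrame(filled, index=expr.index, columns=expr.columns)
    out.attrs.update(expr.attrs)
    out.attrs["imputed_count"] = int(np.isnan(values).sum())
    return out
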