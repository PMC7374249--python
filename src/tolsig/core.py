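"""Domain types, validation, and readers/writers.

The package works with three tabular objects, all held as pandas objects:

* an expression matrix — samples x genes, either raw qPCR Ct cycles or
  log2 relative expression (-dCt, reference Ct minus target Ct);
* a clinical sample table — one row per (patient, timepoint) with the
  clinical group (TOL tolerant / ST stable / CR chronic rejector / HC
  healthy control) and the immunosuppressive regimen: prednisolone
  (off/on), calcineurin inhibitor (off/cyclosporine/tacrolimus) and
  antiproliferative agent (off/azathioprine/mycophenolate mofetil),
  with optional daily doses in mg/day;
* a model bundle — everything needed to score a new cohort: the
  signature definition, per-gene drug-adjustment coefficients, the
  logistic elastic-net coefficients, and the probability cut-off.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("TOL", "ST", "CR", "HC")
TIMEPOINTS = ("T1", "T2")
PRED_LEVELS = ("off", "on")
CNI_LEVELS = ("off", "cyc", "tac")
AP_LEVELS = ("off", "aza", "mmf")

#: drugs with a dose column, keyed by the indicator level that enables it
DOSE_FIELDS = {
    "pred": ("pred", "on"),
    "cyc": ("cni", "cyc"),
    "tac": ("cni", "tac"),
    "aza": ("ap", "aza"),
    "mmf": ("ap", "mmf"),
}

REQUIRED_CLINICAL_COLUMNS = (
    "sample_id",
    "patient_id",
    "timepoint",
    "group",
    "pred",
    "cni",
    "ap",
)

#: design-matrix columns of the drug-adjustment model, in canonical order
DRUG_DUMMIES = ("pred_on", "cni_cyc", "cni_tac", "ap_aza", "ap_mmf")


class ValidationError(ValueError):
    """Raised when an input table violates a domain invariant."""


# ---------------------------------------------------------------------------
# signature definitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignatureSpec:
    """A gene-expression signature definition.

    Parameters
    ----------
    name : identifier of the signature.
    genes : target genes, order is the coefficient order of fitted models.
    housekeeping : reference gene(s); several references are combined by
        the arithmetic mean of their Ct (geometric mean on the linear
        expression scale).
    drug_adjusted : whether expression is residualized against the
        immunosuppressive regimen before model calibration.
    alpha : elastic-net mixing parameter in (0, 1); small values favour
        gene retention (near ridge), large values favour exclusion
        (near lasso).
    """

    name: str
    genes: tuple[str, ...]
    housekeeping: tuple[str, ...]
    drug_adjusted: bool
    alpha: float = 0.05

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"signature {self.name}: empty gene list")
        if set(self.genes) & set(self.housekeeping):
            raise ValidationError(
                f"signature {self.name}: genes overlap housekeeping references"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(
                f"signature {self.name}: alpha={self.alpha} outside (0, 1)"
            )
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "housekeeping", tuple(self.housekeeping))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "genes": list(self.genes),
            "housekeeping": list(self.housekeeping),
            "drug_adjusted": self.drug_adjusted,
            "alpha": self.alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureSpec":
        return cls(
            name=d["name"],
            genes=tuple(d["genes"]),
            housekeeping=tuple(d["housekeeping"]),
            drug_adjusted=bool(d["drug_adjusted"]),
            alpha=float(d["alpha"]),
        )


# ---------------------------------------------------------------------------
# fitted-model records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugAdjustmentModel:
    """Per-gene OLS fit of -dCt on the drug-regimen indicators.

    Coefficients are on the -dCt (log2 expression) scale. ``r_squared``
    is 1 - RSS/TSS on the samples the model was fitted on (treated
    non-tolerant recipients).
    """

    gene_id: str
    intercept: float
    pred_on: float
    cni_cyc: float
    cni_tac: float
    ap_aza: float
    ap_mmf: float
    r_squared: float
    n_fit: int

    def __post_init__(self):
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValidationError(
                f"{self.gene_id}: r_squared={self.r_squared} outside [0, 1]"
            )
        if self.n_fit < 2:
            # the fitter enforces "more samples than parameters" (7 for
            # the full five-dummy design); the record only sanity-checks
            raise ValidationError(f"{self.gene_id}: n_fit={self.n_fit} < 2")

    @property
    def coefficients(self) -> np.ndarray:
        """Drug coefficients in :data:`DRUG_DUMMIES` order."""
        return np.array(
            [self.pred_on, self.cni_cyc, self.cni_tac, self.ap_aza, self.ap_mmf]
        )

    def predict(self, design_row: np.ndarray) -> float:
        return float(self.intercept + design_row @ self.coefficients)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DrugAdjustmentModel":
        return cls(**d)


@dataclass(frozen=True)
class ElasticNetModel:
    """A fitted penalized logistic signature model.

    ``coef`` are on the input (-dCt or residual) scale; ``mean``/``sd``
    record the internal standardization (population SD) used during
    fitting, for provenance only.
    """

    genes: tuple[str, ...]
    alpha: float
    lam: float
    intercept: float
    coef: tuple[float, ...]
    mean: tuple[float, ...] = ()
    sd: tuple[float, ...] = ()

    def __post_init__(self):
        if len(self.genes) != len(self.coef):
            raise ValidationError("gene list and coefficient vector differ in length")
        if self.lam < 0:
            raise ValidationError(f"lambda={self.lam} negative")
        if not all(math.isfinite(b) for b in self.coef) or not math.isfinite(
            self.intercept
        ):
            raise ValidationError("non-finite coefficient")
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "coef", tuple(float(b) for b in self.coef))
        object.__setattr__(self, "mean", tuple(float(v) for v in self.mean))
        object.__setattr__(self, "sd", tuple(float(v) for v in self.sd))

    def linear_predictor(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ np.asarray(self.coef)

    def predict_probability(self, X) -> np.ndarray:
        from scipy.special import expit

        return expit(self.linear_predictor(X))

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "alpha": self.alpha,
            "lambda": self.lam,
            "intercept": self.intercept,
            "coef": list(self.coef),
            "mean": list(self.mean),
            "sd": list(self.sd),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElasticNetModel":
        return cls(
            genes=tuple(d["genes"]),
            alpha=float(d["alpha"]),
            lam=float(d["lambda"]),
            intercept=float(d["intercept"]),
            coef=tuple(d["coef"]),
            mean=tuple(d.get("mean", ())),
            sd=tuple(d.get("sd", ())),
        )


@dataclass
class ModelBundle:
    """Everything needed to score a new cohort with a calibrated signature.

    ``adjustment_models`` carries two variants of the per-gene drug
    models: ``"full_data"`` (fitted once on all treated non-tolerant
    baseline samples) and ``"cv_median"`` (coefficient-wise medians over
    the cross-validation refits). ``adjustment_variant`` selects the one
    used for prediction. For unadjusted signatures both are empty.
    """

    signature: SignatureSpec
    enet: ElasticNetModel
    cutoff: float
    adjustment_models: dict[str, dict[str, DrugAdjustmentModel]] = field(
        default_factory=dict
    )
    adjustment_variant: str = "cv_median"

    def __post_init__(self):
        if not 0.0 < self.cutoff < 1.0:
            raise ValidationError(f"cutoff={self.cutoff} outside (0, 1)")
        if tuple(self.enet.genes) != tuple(self.signature.genes):
            raise ValidationError("elastic-net gene order differs from signature")
        if self.signature.drug_adjusted:
            for variant, models in self.adjustment_models.items():
                missing = set(self.signature.genes) - set(models)
                if missing:
                    raise ValidationError(
                        f"adjustment variant {variant!r} lacks models for {sorted(missing)}"
                    )

    @property
    def active_adjustment(self) -> dict[str, DrugAdjustmentModel]:
        if not self.signature.drug_adjusted:
            return {}
        return self.adjustment_models[self.adjustment_variant]

    def to_dict(self) -> dict:
        return {
            "signature": self.signature.to_dict(),
            "enet": self.enet.to_dict(),
            "cutoff": self.cutoff,
            "adjustment_variant": self.adjustment_variant,
            "adjustment_models": {
                variant: {g: m.to_dict() for g, m in models.items()}
                for variant, models in self.adjustment_models.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelBundle":
        try:
            return cls(
                signature=SignatureSpec.from_dict(d["signature"]),
                enet=ElasticNetModel.from_dict(d["enet"]),
                cutoff=float(d["cutoff"]),
                adjustment_variant=d.get("adjustment_variant", "cv_median"),
                adjustment_models={
                    variant: {
                        g: DrugAdjustmentModel.from_dict(m) for g, m in models.items()
                    }
                    for variant, models in d.get("adjustment_models", {}).items()
                },
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"model bundle schema mismatch: {exc}") from exc


def write_model_bundle(bundle: ModelBundle, path) -> None:
    """Serialize a bundle to JSON (lossless to 12+ significant digits)."""
    Path(path).write_text(json.dumps(bundle.to_dict(), indent=2))


def read_model_bundle(path) -> ModelBundle:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"model bundle is not valid JSON: {exc}") from exc
    if not isinstance(d, dict):
        raise ValidationError("model bundle JSON must be an object")
    return ModelBundle.from_dict(d)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


#: cell contents treated as missing in expression tables
MISSING_TOKENS = {"", "NA", "NaN", "nan", "N/A", "Undetermined", "undetermined"}


def read_expression(path, layout: str = "ct") -> pd.DataFrame:
    """Read a wide samples x genes expression table.

    First column is the sample identifier, remaining columns are gene
    symbols. Empty, ``NA`` and ``Undetermined`` cells become missing
    (NaN); the number of missing cells is logged and recorded in
    ``df.attrs["missing_count"]``.

    Parameters
    ----------
    layout : ``"ct"`` for raw Ct cycles, ``"delta_ct"`` for -dCt values.
    """
    if layout not in {"ct", "delta_ct"}:
        raise ValueError(f"unknown layout {layout!r}")
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise ValidationError(f"{path}: expected sample_id plus gene columns")
    sample_ids = raw.iloc[:, 0]
    dups = sample_ids[sample_ids.duplicated()].unique()
    if len(dups):
        raise ValidationError(f"{path}: duplicate sample ids: {list(dups)}")
    values = raw.iloc[:, 1:].copy()
    missing_count = 0
    data = {}
    for col in values.columns:
        cells = values[col].str.strip()
        is_missing = cells.isin(MISSING_TOKENS)
        missing_count += int(is_missing.sum())
        numeric = pd.to_numeric(cells.where(~is_missing), errors="coerce")
        bad = (~is_missing) & numeric.isna()
        if bad.any():
            row = sample_ids[bad].iloc[0]
            raise ValidationError(
                f"{path}: non-numeric value {cells[bad].iloc[0]!r} "
                f"at sample {row!r}, gene {col!r}"
            )
        data[col] = numeric.to_numpy(dtype=float)
    df = pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id"))
    df = df.astype(float)
    if not np.isfinite(df.to_numpy()[~np.isnan(df.to_numpy())]).all():
        raise ValidationError(f"{path}: non-finite expression value")
    df.attrs["layout"] = layout
    df.attrs["missing_count"] = missing_count
    if missing_count:
        logger.info("%s: %d missing expression values", path, missing_count)
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df.to_csv(path, sep=sep, index_label="sample_id")


# ---------------------------------------------------------------------------
# clinical sample tables
# ---------------------------------------------------------------------------


def validate_sample_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a clinical sample table.

    Enforced invariants:

    * required columns present, enum levels valid;
    * TOL and HC samples are off all drugs ("off treatment");
    * a dose is present if and only if the matching indicator is on,
      and doses are non-negative;
    * sample ids unique and (patient_id, timepoint) unique.
    """
    df = df.copy()
    missing_cols = [c for c in REQUIRED_CLINICAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"clinical table lacks columns {missing_cols}")
    for col in REQUIRED_CLINICAL_COLUMNS:
        df[col] = df[col].astype(str).str.strip()
    for col, levels in (
        ("timepoint", TIMEPOINTS),
        ("group", GROUPS),
        ("pred", PRED_LEVELS),
        ("cni", CNI_LEVELS),
        ("ap", AP_LEVELS),
    ):
        bad = ~df[col].isin(levels)
        if bad.any():
            raise ValidationError(
                f"column {col!r}: invalid value {df.loc[bad, col].iloc[0]!r} "
                f"(allowed: {levels})"
            )

    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sample ids: {sorted(dup.unique())}")
    pair_dup = df.duplicated(subset=["patient_id", "timepoint"])
    if pair_dup.any():
        rows = df.loc[pair_dup, ["patient_id", "timepoint"]].iloc[0]
        raise ValidationError(
            f"duplicate (patient_id, timepoint): {tuple(rows)}"
        )

    untreated = df["group"].isin(["TOL", "HC"])
    on_drugs = (df["pred"] != "off") | (df["cni"] != "off") | (df["ap"] != "off")
    bad = untreated & on_drugs
    if bad.any():
        sid = df.loc[bad, "sample_id"].iloc[0]
        raise ValidationError(
            f"sample {sid!r}: TOL/HC samples must be off all drugs"
        )

    for drug, (indicator, level) in DOSE_FIELDS.items():
        col = f"dose_{drug}"
        if col not in df.columns:
            continue
        dose = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        nonnum = df[col].replace("", np.nan).notna() & dose.isna()
        if nonnum.any():
            raise ValidationError(f"column {col!r}: non-numeric dose")
        on = df[indicator] == level
        orphan = dose.notna() & ~on
        if orphan.any():
            sid = df.loc[orphan, "sample_id"].iloc[0]
            raise ValidationError(
                f"sample {sid!r}: {col} given while {indicator} != {level!r}"
            )
        absent = on & dose.isna()
        if absent.any():
            sid = df.loc[absent, "sample_id"].iloc[0]
            raise ValidationError(
                f"sample {sid!r}: {indicator}={level!r} but {col} missing"
            )
        if (dose.dropna() < 0).any():
            raise ValidationError(f"column {col!r}: negative dose")
        df[col] = dose

    if "egfr" in df.columns:
        df["egfr"] = pd.to_numeric(df["egfr"].replace("", np.nan), errors="coerce")
    return df.reset_index(drop=True)


def read_clinical(path) -> pd.DataFrame:
    """Read and validate a clinical sample table (CSV/TSV)."""
    return validate_sample_table(_read_table(path))


def write_clinical(df: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df.to_csv(path, sep=sep, index=False)


def drug_design_matrix(samples: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code the regimen as the 5-column adjustment design.

    Three-level factors (CNI, AP) become two dummies each with "off" as
    the reference level; TOL/HC rows are all-zero ("off treatment") by
    the validated invariants.
    """
    d = pd.DataFrame(
        {
            "pred_on": (samples["pred"] == "on").astype(float),
            "cni_cyc": (samples["cni"] == "cyc").astype(float),
            "cni_tac": (samples["cni"] == "tac").astype(float),
            "ap_aza": (samples["ap"] == "aza").astype(float),
            "ap_mmf": (samples["ap"] == "mmf").astype(float),
        },
        index=samples.index,
    )
    return d
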