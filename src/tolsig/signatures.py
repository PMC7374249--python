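"""Published signature gene-sets of operational tolerance.

Five previously published peripheral-blood signatures are compared by
the pipeline, plus two combined sets: the union of all 24 genes fitted
with a sparsity-favouring penalty (used for consensus selection) and the
seven-gene consensus signature itself. Housekeeping references follow
the original assays: HPRT for most sets, GAPDH for the two-gene B-cell
set, and the arithmetic-mean Ct of ACTB/B2M/GAPDH/HPRT1 (geometric mean
on the linear scale) for the six-gene set.
"""

from __future__ import annotations

from .core import SignatureSpec

GAMBIT_G9 = (
    "ATXN3",
    "BCL2A1",
    "EEF1A1",
    "GEMIN7A",
    "IGLC1",
    "MS4A4A",
    "NFKBIA",
    "RAB40C",
    "TNFAIP3",
)
GAMSTER_G4 = ("H6PD", "HSD11B1", "NR3C1", "NR3C2")
ROEDDER_G3 = ("BNC2", "CYP1B1", "KLF6")
NEWELL_G2 = ("IGKV1D-13", "IGKV4-1")
DANGER_G6 = ("AKR1C3", "CD40", "CTLA4", "ID3", "MZB1", "TCL1A")

#: union of the five published sets, in signature order (24 genes)
ALL_GENES = GAMBIT_G9 + GAMSTER_G4 + ROEDDER_G3 + NEWELL_G2 + DANGER_G6

CONSENSUS_G7 = ("CD40", "CTLA4", "HSD11B1", "IGKV4-1", "MZB1", "NR3C2", "RAB40C")

HOUSEKEEPING_GENES = ("HPRT", "GAPDH", "ACTB", "B2M", "HPRT1")

#: elastic-net mixing defaults: near-ridge for calibration of a fixed
#: gene-set, near-lasso for consensus gene selection
ALPHA_CALIBRATE = 0.05
ALPHA_SELECT = 0.95

SIGNATURES: dict[str, SignatureSpec] = {
    "GAMBIT-g9": SignatureSpec(
        "GAMBIT-g9", GAMBIT_G9, ("HPRT",), drug_adjusted=True, alpha=ALPHA_CALIBRATE
    ),
    "GAMSTER-g4": SignatureSpec(
        "GAMSTER-g4", GAMSTER_G4, ("HPRT",), drug_adjusted=True, alpha=ALPHA_CALIBRATE
    ),
    "ROEDDER-g3": SignatureSpec(
        "ROEDDER-g3", ROEDDER_G3, ("HPRT",), drug_adjusted=False, alpha=ALPHA_CALIBRATE
    ),
    "NEWELL-g2": SignatureSpec(
        "NEWELL-g2", NEWELL_G2, ("GAPDH",), drug_adjusted=False, alpha=ALPHA_CALIBRATE
    ),
    "DANGER-g6": SignatureSpec(
        "DANGER-g6",
        DANGER_G6,
        ("ACTB", "B2M", "GAPDH", "HPRT1"),
        drug_adjusted=False,
        alpha=ALPHA_CALIBRATE,
    ),
    "COMBINED-all": SignatureSpec(
        "COMBINED-all", ALL_GENES, ("HPRT",), drug_adjusted=True, alpha=ALPHA_SELECT
    ),
    "COMBINED-g7": SignatureSpec(
        "COMBINED-g7", CONSENSUS_G7, ("HPRT",), drug_adjusted=True, alpha=ALPHA_CALIBRATE
    ),
}

#: the five published signatures entering the consensus analysis
PUBLISHED = ("GAMBIT-g9", "GAMSTER-g4", "ROEDDER-g3", "NEWELL-g2", "DANGER-g6")


def get_signature(name: str) -> SignatureSpec:
    try:
        return SIGNATURES[name]
    except KeyError:
        raise KeyError(
            f"unknown signature {name!r}; available: {sorted(SIGNATURES)}"
        ) from None


def housekeeping_map(signature: SignatureSpec) -> dict[str, tuple[str, ...]]:
    """Per-gene housekeeping references for one signature."""
    return {g: signature.housekeeping for g in signature.genes}
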