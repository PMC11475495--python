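"""Bookkeeping for the reference NSCLC cohort (TCGA-LUAD + TCGA-LUSC, n = 624).

These are the published summary counts of the cohort the pipeline was
designed around: per-block feature counts after preprocessing, per-block
chi-square-selected feature counts, and the clinical characteristics table.
They serve as inputs for consistency arithmetic — merged feature totals,
per-combination feature counts (clinical contributes its fixed 11 columns),
and cohort percentages — not as measured outputs of this package.
"""

from __future__ import annotations

from .cohort import BLOCK_ORDER
from .exceptions import ConfigurationError

#: features per omics block after preprocessing (before the chi-square screen)
PREPROCESSED_FEATURES = {"mrna": 32766, "mirna": 757, "meth": 135007}

#: features retained by the chi-square screen (clinical bypasses the screen)
SELECTED_FEATURES = {"mrna": 2945, "mirna": 77, "meth": 13046, "clinical": 11}

#: clinical characteristics: category -> patient count (n = 624)
CLINICAL_COUNTS = {
    "total": 624,
    "gender": {"male": 370, "female": 254},
    "prior_malignancy": {"yes": 86, "no": 537},
    "synchronous_malignancy": {"yes": 13, "no": 568},
    "prior_treatment": {"yes": 3, "no": 621},
    "primary_diagnosis": {"adenocarcinoma": 348, "squamous cell carcinoma": 276},
    "t_stage": {"T1": 209, "T2": 319, "T3": 78, "T4": 15, "TX": 3},
    "n_stage": {"N0": 433, "N1": 127, "N2": 51, "N3": 11, "NX": 1},
    "m_stage": {"M0": 428, "M1": 12, "MX": 180},
    "tissue_organ": {
        "upper lobe, lung": 361,
        "lower lobe, lung": 214,
        "middle lobe, lung": 21,
        "lung, nos": 14,
        "overlapping lesion of lung": 8,
        "main bronchus": 6,
    },
}


def merged_feature_count(per_block=PREPROCESSED_FEATURES) -> int:
    """Total features after merging the omics blocks by sample ID."""
    return int(sum(per_block.values()))


def combination_feature_count(blocks, selected=SELECTED_FEATURES) -> int:
    """Feature count of a block combination: sum of per-block selected counts."""
    blocks = set(blocks)
    unknown = blocks - set(BLOCK_ORDER)
    if unknown:
        raise ConfigurationError(f"unknown blocks: {sorted(unknown)}")
    return int(sum(selected[b] for b in blocks))


def cohort_percentage(characteristic: str, category: str, ndigits: int = 2) -> float:
    """Percentage of the cohort in one clinical category, from the raw counts."""
    counts = CLINICAL_COUNTS[characteristic]
    return round(100.0 * counts[category] / CLINICAL_COUNTS["total"], ndigits)
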