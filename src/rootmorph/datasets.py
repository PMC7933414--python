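"""Published summary tables of the EDAR 370V/A dental cohort.

These are the printed genotype-by-root-class counts and logistic effect
sizes of a genotyped cohort of 255 Japanese patients (the individual-level
records themselves were never deposited); they serve as canonical inputs
for the exact tests and rank correlations and as the calibration targets of
the synthetic-cohort generator.
"""

from __future__ import annotations

import pandas as pd

from .association_stats import CLASS_ORDER, GENOTYPES

__all__ = ["GENOTYPE_COUNTS", "root_genotype_counts",
           "logistic_effects", "LOGISTIC_EFFECTS"]

#: genotype counts among the 255 genotyped individuals: 25 VV, 120 VA, 112 AA
GENOTYPE_COUNTS = {"VV": 25, "VA": 120, "AA": 112}

# rows: dichotomized class (first = the class listed first in CLASS_ORDER),
# columns: VV, VA, AA
_ROOT_COUNTS = {
    "UP1": [[12, 63, 80], [9, 48, 26]],
    "UP2": [[18, 97, 93], [1, 7, 5]],
    "UM2": [[1, 16, 12], [21, 94, 92]],
    "LM1": [[18, 89, 73], [2, 25, 32]],
    "LM2": [[3, 39, 57], [15, 72, 47]],
}

#: per-allele (and per-covariate) log odds ratios from the cohort's logistic
#: regressions of the dichotomized root phenotype on age, sex (male = 0,
#: female = 1), region (0-4 grandparents from the Ryukyu Islands) and EDAR
#: genotype dosage; the modelled outcome ("test" class) is single-rooted UP1,
#: three-rooted LM1, and C-shaped LM2.
LOGISTIC_EFFECTS = {
    "UP1": {"age": 0.074, "sex": 0.520, "region": 0.096, "genotype": 0.666},
    "LM1": {"age": -0.043, "sex": 0.162, "region": -0.003, "genotype": 0.529},
    "LM2": {"age": 0.026, "sex": 0.558, "region": 0.087, "genotype": 0.858},
}

#: which dichotomized class each logistic model treats as the outcome (=1)
LOGISTIC_TEST_CLASS = {"UP1": "1", "LM1": "3", "LM2": "C"}


def root_genotype_counts(tooth: str) -> pd.DataFrame:
    """Genotype x root-class counts for one tooth, rows VV/VA/AA."""
    cols = CLASS_ORDER[tooth]
    df = pd.DataFrame(_ROOT_COUNTS[tooth], index=list(cols),
                      columns=list(GENOTYPES)).T
    return df[list(cols)]


def logistic_effects(tooth: str) -> dict[str, float]:
    return dict(LOGISTIC_EFFECTS[tooth])
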