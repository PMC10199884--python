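"""Controlled vocabularies and table schemas shared across the pipeline.

The pipeline moves three flat tables between stages:

``insurees.csv``
    one row per covered person: demographics, matching covariates, study arm.
``assessments.csv``
    one row per app photo assessment: CNN rating plus the teledermatologist
    override, if any.
``claims.csv``
    one row per healthcare claim: diagnosis category, intervention type,
    care setting, calendar year, cost in euros.
"""

from __future__ import annotations

# Diagnosis categories (insurer diagnosis groups collapsed to the five the
# analysis uses; "unrelated_dermatology" is the internal-validity control,
# e.g. varicose veins).
CATEGORIES = (
    "premalignant",
    "malignant",
    "nevus",
    "benign_tumor",
    "unrelated_dermatology",
)

# Categories pooled for the detection proxy (persons with >=1 such claim).
PREMALIGNANT_MALIGNANT = ("premalignant", "malignant")
BENIGN_NEVUS = ("nevus", "benign_tumor")

# Diagnostic / therapeutic intervention labels attached to claims.
# "none" covers consultations, chemotherapy, ward admission etc.
INTERVENTIONS = (
    "none",
    "gp_biopsy_excision",
    "gp_teledermatology",
    "mohs",
    "hospital_excision_benign",
    "hospital_excision_premalignant",
)

# GP-based interventions are primary care; everything else in the claims
# data is dermatologist-based secondary/tertiary care.
INTERVENTION_SETTING = {
    "none": "secondary",
    "gp_biopsy_excision": "primary",
    "gp_teledermatology": "primary",
    "mohs": "secondary",
    "hospital_excision_benign": "secondary",
    "hospital_excision_premalignant": "secondary",
}

SETTINGS = ("primary", "secondary")

SEXES = ("male", "female")
SES_LEVELS = ("low", "middle", "high", "missing")
ARMS = ("user", "control-pool")

# CNN photo ratings. "low_symptoms" is a sub-label of low risk (the user
# reported symptoms); it is treated exactly like "low" downstream.
CNN_RESULTS = ("low", "low_symptoms", "high", "failed")
TELEDERM_RESULTS = ("low", "high", "none")

INSUREE_COLUMNS = (
    "person_id",
    "age",
    "sex",
    "ses",
    "region",
    "history_premalignancy",
    "n_comorbidities",
    "arm",
)

ASSESSMENT_COLUMNS = (
    "person_id",
    "assessment_index",
    "cnn_result",
    "telederm_result",
)

CLAIM_COLUMNS = (
    "person_id",
    "category",
    "intervention",
    "setting",
    "year",
    "cost",
)


def is_cnn_low(cnn_result) -> bool:
    """True for either flavour of a low-risk CNN rating."""
    return cnn_result in ("low", "low_symptoms")
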