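"""Column layout of the dyad table.

One row per parent-offspring pair. Raw questionnaire items are stored
per respondent (mother, father, offspring); mediators and confounders
are one column each. Derived loneliness scores/classes are appended by
:mod:`dyadlink.scales` under the documented names below.
"""

from __future__ import annotations

MOTHER_ITEMS = ["mother_item1", "mother_item2", "mother_item3"]
FATHER_ITEMS = ["father_item1", "father_item2", "father_item3"]
OFFSPRING_ITEMS = ["offspring_item1", "offspring_item2", "offspring_item3"]

#: The five offspring (G1) mediators, in reporting order.
MEDIATORS = ["subj_ses", "sociability", "cognition", "depressive", "anxiety"]

#: Confounders shared by exposure and outcome (both generations).
CONFOUNDERS = [
    "g0_age",
    "g1_age",
    "sex",
    "marital",
    "n_children",
    "n_siblings",
    "education_years",
    "parental_education_years",
    "income",
]

#: Covariate set for the mediator (linear) models: both generations' age
#: plus offspring sex, education and income.
MEDIATOR_MODEL_COVARIATES = ["g0_age", "g1_age", "sex", "education_years", "income"]

#: Covariate set for the outcome (logistic) models: the full confounder list.
OUTCOME_MODEL_COVARIATES = list(CONFOUNDERS)

#: Shared covariate set of the two mediation models (both generations'
#: age, offspring sex, marital status, number of children, income and
#: education).
MEDIATION_COVARIATES = [
    "g0_age",
    "g1_age",
    "sex",
    "marital",
    "n_children",
    "income",
    "education_years",
]

#: Variables summarised in the group-descriptives table.
DESCRIPTIVE_CONTINUOUS = [
    "g1_age",
    "g0_age",
    "parental_education_years",
    "n_siblings",
    "n_children",
    "education_years",
    "income",
    "subj_ses",
    "sociability",
    "depressive",
    "anxiety",
    "cognition",
]
DESCRIPTIVE_CATEGORICAL = ["sex", "marital"]

#: Derived loneliness columns written by scales.score_dyad_table.
DERIVED_LONELINESS = [
    "g0_mother_lonely_raw",
    "g0_mother_lonely_class",
    "g0_father_lonely_raw",
    "g0_father_lonely_class",
    "g0_parent_lonely_raw",
    "g0_parent_lonely_class",
    "g1_lonely_raw",
    "g1_lonely_class",
]

OUTCOME = "g1_lonely_class"

#: Exposure column per analysis variant (binary class / continuous raw).
EXPOSURE_CLASS = {
    "parental": "g0_parent_lonely_class",
    "mother": "g0_mother_lonely_class",
    "father": "g0_father_lonely_class",
}
EXPOSURE_RAW = {
    "parental": "g0_parent_lonely_raw",
    "mother": "g0_mother_lonely_raw",
    "father": "g0_father_lonely_raw",
}

ITEM_COLUMNS = MOTHER_ITEMS + FATHER_ITEMS + OFFSPRING_ITEMS

#: Loneliness variables (items and derived scores): excluded from the
#: imputation predictor set, mirroring the analysis protocol.
LONELINESS_COLUMNS = ITEM_COLUMNS + DERIVED_LONELINESS

ALL_RAW_COLUMNS = (
    ["pair_id"] + ITEM_COLUMNS + MEDIATORS + CONFOUNDERS
)
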