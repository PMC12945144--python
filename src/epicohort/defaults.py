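"""Default cohort parameters for a two-group epigenetic-ageing study.

The defaults emulate a case-control design comparing men living with HIV on
integrase-inhibitor-based antiretroviral therapy (n=48) against uninfected
controls (n=50): ten ordinal lifestyle questionnaire variables, eighteen
continuous covariates (anthropometry, blood counts, lipids, smoking
quantities, sleep), three lymphocyte counts measured only in the HIV+ group,
and eight epigenetic outcome variables (MeDIP-qPCR percent-recovery
methylation at five loci and ddCt relative expression of three DNA
methyltransferase genes).

Percentages for ordinal categories and group means/SDs for continuous
variables follow the published study-population summaries.  Right-skewed
variables (triglycerides, CRP, the smoking quantities and every epigenetic
outcome, all of which fail Shapiro-Wilk normality decisively) use
moment-matched lognormal margins; the remaining laboratory values use normal
margins.  Two correlation blocks reproduce the observed covariate clusters:
body size (height/weight/BMI) and smoking (status plus the three smoking
quantities), each with a target Spearman rank correlation of 0.8.
"""

from __future__ import annotations

from .simulate import CohortConfig, CovariateSpec, EffectSpec

#: ordinal covariates: (name, first category code, group1 %, group2 %)
#: Rows whose printed percentages do not sum to 100 are renormalized.
ORDINAL_COVARIATES = [
    ("alcohol_freq", 0, (10, 44, 44, 2), (22, 36, 42, 0), None),
    ("fast_food_freq", 1, (52, 42, 4, 2), (46, 48, 4, 2), None),
    ("fatty_food_freq", 1, (11, 46, 22, 22), (10, 36, 38, 16), None),
    ("iv_drug_use", 0, (96, 4, 0), (100, 0, 0), None),
    ("inhaled_drug_use", 0, (69, 21, 10), (82, 12, 6), None),
    ("physical_activity_freq", 1, (15, 35, 23, 27), (14, 34, 22, 30), None),
    ("coping_with_stress", 1, (5, 23, 43, 30), (2, 20, 44, 32), None),
    ("stress_level", 0, (38, 2, 23, 19, 12), (34, 12, 22, 24, 6), None),
    ("fruit_veg_freq", 1, (0, 7, 11, 80), (2, 28, 12, 58), None),
    ("smoking_status", 0, (29, 27, 44), (72, 22, 6), "smoking"),
]

#: continuous covariates: (name, family, (mean1, sd1), (mean2, sd2), block)
CONTINUOUS_COVARIATES = [
    ("age", "normal", (33.96, 4.021), (29.76, 4.732), None),
    ("height", "normal", (180.0, 6.738), (181.2, 7.280), "body"),
    ("weight", "normal", (79.81, 13.73), (80.67, 15.28), "body"),
    ("bmi", "normal", (24.60, 3.774), (24.47, 3.836), "body"),
    ("hgb", "normal", (15.23, 1.120), (14.90, 0.870), None),
    ("wbc", "normal", (6.300, 1.483), (6.981, 1.479), None),
    ("plt", "normal", (241.3, 54.49), (247.2, 58.23), None),
    ("creatinine", "normal", (0.955, 0.139), (0.916, 0.147), None),
    ("glucose", "normal", (86.72, 9.582), (88.48, 15.83), None),
    ("total_cholesterol", "normal", (189.0, 41.43), (193.4, 37.97), None),
    ("hdl", "normal", (49.97, 10.71), (49.64, 8.461), None),
    ("ldl", "normal", (122.9, 40.03), (120.8, 33.57), None),
    ("triglycerides", "lognormal", (138.3, 98.15), (153.8, 87.52), None),
    ("crp", "lognormal", (1.757, 1.646), (2.316, 4.301), None),
    ("years_smoking", "lognormal", (6.295, 6.522), (1.163, 2.664), "smoking"),
    ("cigarettes_per_day", "lognormal", (7.064, 6.947), (1.410, 2.969), "smoking"),
    ("pack_years", "lognormal", (3.187, 4.998), (0.301, 0.867), "smoking"),
    ("sleep_hours", "normal", (7.120, 1.009), (7.275, 0.977), None),
]

#: lymphocyte subsets measured only within the HIV+ group
RESTRICTED_COVARIATES = [
    ("cd3", "normal", (1599.0, 401.8)),
    ("cd4", "normal", (762.0, 231.9)),
    ("cd8", "normal", (747.8, 243.2)),
]

#: epigenetic outcomes: (name, (mean1, sd1), (mean2, sd2)); all right-skewed
EFFECTS = [
    ("global_methylation", (2.874, 2.778), (5.777, 2.137)),
    ("CNOT2_methylation", (2.428, 2.297), (13.55, 41.10)),
    ("DPP6_methylation", (59.71, 150.7), (2.845, 3.950)),
    ("FOXG1_methylation", (2.186, 5.428), (2.210, 5.677)),
    ("NPTX2_methylation", (6.830, 10.59), (0.713, 0.862)),
    ("DNMT1_expression", (10.11, 4.366), (1.277, 0.946)),
    ("DNMT3a_expression", (1.281, 0.669), (1.174, 0.837)),
    ("DNMT3b_expression", (0.794, 0.398), (1.221, 0.841)),
]


def _normalize(pcts: tuple) -> tuple:
    total = float(sum(pcts))
    return tuple(p / total for p in pcts)


def default_cohort_config(
    master_seed: int = 0, n_noise_covariates: int = 0
) -> CohortConfig:
    """The study-default cohort: 48 + 50 participants, 28 covariates,
    3 group-restricted lymphocyte counts and 8 epigenetic outcomes.

    ``n_noise_covariates`` appends standard-normal covariates with identical
    per-group parameters (inert padding, e.g. to reach a 32-covariate roster).
    """
    covariates = []
    for name, first, p1, p2, block in ORDINAL_COVARIATES:
        categories = tuple(range(first, first + len(p1)))
        covariates.append(
            CovariateSpec(
                name=name,
                kind="ordinal",
                categories=categories,
                probs_group1=_normalize(p1),
                probs_group2=_normalize(p2),
                block=block,
            )
        )
    for name, family, (m1, s1), (m2, s2), block in CONTINUOUS_COVARIATES:
        covariates.append(
            CovariateSpec(
                name=name,
                kind="continuous",
                family=family,
                mean_group1=m1,
                sd_group1=s1,
                mean_group2=m2,
                sd_group2=s2,
                block=block,
            )
        )
    for name, family, (m1, s1) in RESTRICTED_COVARIATES:
        covariates.append(
            CovariateSpec(
                name=name,
                kind="continuous",
                family=family,
                mean_group1=m1,
                sd_group1=s1,
                mean_group2=m1,
                sd_group2=s1,
                restricted_to_group1=True,
            )
        )
    for i in range(n_noise_covariates):
        covariates.append(
            CovariateSpec(
                name=f"noise_{i + 1}",
                kind="continuous",
                family="normal",
                mean_group1=0.0,
                sd_group1=1.0,
                mean_group2=0.0,
                sd_group2=1.0,
            )
        )
    effects = [
        EffectSpec(name=name, family="lognormal",
                   mean_group1=m1, sd_group1=s1, mean_group2=m2, sd_group2=s2)
        for name, (m1, s1), (m2, s2) in EFFECTS
    ]
    return CohortConfig(
        n_group1=48,
        n_group2=50,
        covariates=covariates,
        effects=effects,
        master_seed=master_seed,
    )
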