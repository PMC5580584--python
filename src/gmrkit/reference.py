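"""Published demographic summary of the smoking-cessation study cohort.

These constants transcribe the demographic tables of the clinical study the
package models: 259 Japanese dental patients (19-79 years), split into
former and current smokers and into five 10-year age bins.  They serve two
roles: (a) defaults for the synthetic cohort generator, so simulated cohorts
have the study's cell structure, and (b) inputs to the arithmetic
consistency checks that pool subgroup cells back into the printed group and
total summaries.

Cell lists are ordered by age bin: 19-29, 30-39, 40-49, 50-59, 60+.
"""

from __future__ import annotations

from .types import AGE_GROUPS

# ---- subgroup (status x age bin) cells -------------------------------------

#: Number of subjects per cell.
SUBGROUP_N = {
    "former": (13, 32, 29, 32, 27),
    "current": (17, 26, 32, 36, 15),
}

#: Number of males per cell (females = n - males).
SUBGROUP_MALES = {
    "former": (8, 23, 21, 16, 20),
    "current": (11, 18, 19, 23, 8),
}

#: Mean duration of smoking (years) per cell.
SUBGROUP_SMOKING_DURATION = {
    "former": (9.5, 18.3, 26.1, 32.5, 41.4),
    "current": (9.0, 17.9, 27.7, 37.2, 43.3),
}

#: Mean follow-up period (years) per cell.
SUBGROUP_FOLLOWUP = {
    "former": (5.01, 4.40, 4.73, 4.19, 4.47),
    "current": (3.60, 4.00, 3.52, 3.78, 4.22),
}

#: Mean duration of smoking cessation (years), former smokers only.
SUBGROUP_CESSATION = (2.62, 2.75, 3.31, 3.38, 3.67)

# ---- group-level (former / current / total) summaries, mean +/- sd ---------

GROUP_N = {"former": 133, "current": 126, "total": 259}
GROUP_MALES = {"former": 88, "current": 79, "total": 167}
GROUP_AGE = {"former": (46.8, 13.4), "current": (44.6, 13.0), "total": (45.9, 13.2)}
GROUP_SMOKING_DURATION = {
    "former": (27.3, 12.6),
    "current": (27.7, 12.4),
    "total": (27.5, 12.5),
}
GROUP_GMR = {"former": (26.0, 18.4), "current": (27.5, 21.1), "total": (26.7, 19.8)}
GROUP_FOLLOWUP = {"former": (4.50, 2.15), "current": (3.79, 1.17)}
GROUP_CESSATION = (3.14, 1.95)

#: Pooled mean follow-up period across both groups (years).
TOTAL_FOLLOWUP_MEAN = 4.15

#: Reported Spearman rank correlation between age and smoking duration.
AGE_DURATION_SPEARMAN = 0.85


def subgroup_cells():
    """Iterate (status, age_group, n, n_males) over the ten cells."""
    for status, ns in SUBGROUP_N.items():
        for age_group, n, m in zip(AGE_GROUPS, ns, SUBGROUP_MALES[status]):
            yield status, age_group, n, m
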