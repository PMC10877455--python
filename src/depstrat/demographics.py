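"""Published demographic characteristics of the UK Biobank
lifetime-depression groups.

These counts parameterize the synthetic cohort generator (criterion
marginal prevalences, female/male split, age and education moments) and
serve as arithmetic ground truth: the percentage columns printed in the
source cohort description are exactly recomputable from the counts.

Rows: the six operational criteria (subjects meeting each, overlapping),
the six exact-k groups (disjoint), the full depression group and the
healthy-control group.
"""

from __future__ import annotations

import pandas as pd

#: (row, total, n_female, printed female %, n_male, printed male %,
#:  mean age, sd age, mean education years, sd education years)
_ROWS = [
    ("helpseek",  19182, 11828, 61.7, 7354, 38.3, 63.91, 7.60, 16.65, 3.82),
    ("selfrep",    4691,  2879, 61.4, 1812, 38.6, 63.98, 7.62, 16.64, 3.82),
    ("antidep",    4222,  2602, 61.6, 1620, 38.4, 63.98, 7.64, 16.65, 3.81),
    ("smith",      3166,  1963, 62.0, 1203, 38.0, 63.99, 7.67, 16.65, 3.83),
    ("icd10",      1605,   990, 61.7,  615, 38.3, 64.04, 7.67, 16.67, 3.83),
    ("cidisf",     3571,  2200, 61.6, 1371, 38.4, 63.99, 7.66, 16.66, 3.82),
    ("k1",        10977,  6487, 59.1, 4490, 40.9, 64.54, 7.57, 16.52, 3.90),
    ("k2",         5233,  3307, 63.2, 1926, 36.8, 63.62, 7.53, 16.77, 3.76),
    ("k3",         2574,  1691, 65.7,  883, 34.3, 63.02, 7.58, 16.77, 3.74),
    ("k4",         1275,   859, 67.4,  416, 32.6, 62.40, 7.55, 16.80, 3.76),
    ("k5",          378,   270, 71.4,  108, 28.6, 61.79, 7.70, 17.39, 3.27),
    ("k6",           47,    31, 66.0,   16, 34.0, 59.22, 6.76, 17.81, 2.35),
    ("depression", 20484, 12645, 61.7, 7839, 38.3, 63.91, 7.60, 16.65, 3.82),
    ("controls",   25462, 11384, 44.7, 14078, 55.3, 65.05, 7.80, 16.69, 3.77),
]

_COLUMNS = [
    "group", "total", "n_female", "pct_female_printed", "n_male",
    "pct_male_printed", "age_mean", "age_sd", "education_mean", "education_sd",
]


def reference_table() -> pd.DataFrame:
    """The published group-level demographic table."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def recompute_sex_percentages(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute one-decimal female/male percentages from the raw counts."""
    t = reference_table() if table is None else table.copy()
    t["pct_female_computed"] = (100.0 * t["n_female"] / t["total"]).round(1)
    t["pct_male_computed"] = (100.0 * t["n_male"] / t["total"]).round(1)
    return t


def criterion_population_prevalences() -> dict[str, float]:
    """Criterion marginals over the pooled imaged sample (cases + controls).

    These are the basis for the simulator's default prevalence vector.
    """
    t = reference_table().set_index("group")
    pooled = float(
        t.loc["depression", "total"] + t.loc["controls", "total"]
    )
    crits = ["helpseek", "selfrep", "antidep", "smith", "icd10", "cidisf"]
    return {c: float(t.loc[c, "total"]) / pooled for c in crits}
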