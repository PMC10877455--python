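"""Per-criterion effect-size attribution.

For a given significance mask, every retained criteria constellation has a
Cohen's d. Each of the six criteria splits the constellations into those
containing the criterion and those lacking it; the *difference in effect
size* is the unweighted mean d of the containing constellations minus the
unweighted mean d of the lacking ones. Six such values per mask quantify
how strongly each criterion is associated with the observed alteration; a
summary over the masks of a modality family is reported as median [IQR].

Means are unweighted across constellations (not subject-weighted); a
subject-count-weighted variant is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .criteria import CRITERIA


@dataclass(frozen=True)
class AttributionResult:
    mask_id: str
    criterion: str
    delta_es: float      # NaN when undefined (one side empty)
    n_with: int
    n_without: int

    @property
    def defined(self) -> bool:
        return self.n_with > 0 and self.n_without > 0


def attribute_criteria(
    effect_records: pd.DataFrame, weighted: bool = False
) -> list[AttributionResult]:
    """Difference in effect size for each (mask, criterion) pair.

    ``effect_records`` is a constellation-level effect table with columns
    ``mask_id, constellation_id, cohens_d`` (and ``n_case`` when
    ``weighted``). For each mask and criterion: mean d over constellations
    containing the criterion minus mean d over those lacking it. Pairs where
    one side has no retained constellation are flagged undefined (NaN), not
    fabricated.
    """
    required = {"mask_id", "constellation_id", "cohens_d"}
    if not required.issubset(effect_records.columns):
        raise ValueError(f"effect table needs columns {sorted(required)}")
    results: list[AttributionResult] = []
    for mask_id, sub in effect_records.groupby("mask_id", sort=True):
        cids = sub["constellation_id"].to_numpy(dtype=int)
        d = sub["cohens_d"].to_numpy(dtype=float)
        w = sub["n_case"].to_numpy(dtype=float) if weighted else np.ones(len(sub))
        for i, crit in enumerate(CRITERIA):
            has = (cids >> i) & 1 == 1
            n_with, n_without = int(has.sum()), int((~has).sum())
            if n_with == 0 or n_without == 0:
                delta = np.nan
            else:
                delta = float(
                    np.average(d[has], weights=w[has])
                    - np.average(d[~has], weights=w[~has])
                )
            results.append(
                AttributionResult(
                    mask_id=str(mask_id),
                    criterion=crit,
                    delta_es=delta,
                    n_with=n_with,
                    n_without=n_without,
                )
            )
    return results


def attribution_frame(results: list[AttributionResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def summarize_attribution(
    results: list[AttributionResult] | pd.DataFrame,
    scope: list[str] | None = None,
) -> pd.DataFrame:
    """Median and quartiles of delta_es per criterion over a set of masks.

    ``scope`` restricts to the given mask ids (e.g. all functional-decrease
    masks); default is every mask present. Quartiles use linear
    interpolation. Undefined deltas are dropped; a criterion with no defined
    delta in scope raises.
    """
    df = results if isinstance(results, pd.DataFrame) else attribution_frame(results)
    if scope is not None:
        if len(scope) == 0:
            raise ValueError("empty scope")
        df = df[df["mask_id"].isin(scope)]
    if df.empty:
        raise ValueError("no attribution results in scope")
    rows = []
    for crit in CRITERIA:
        vals = df.loc[df["criterion"] == crit, "delta_es"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError(f"no defined delta_es for criterion {crit!r} in scope")
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "criterion": crit,
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "n_masks": len(vals),
            }
        )
    return pd.DataFrame(rows)


def rank_criteria(results: list[AttributionResult] | pd.DataFrame) -> pd.DataFrame:
    """Criteria ordered by median delta_es (most negative first)."""
    summary = summarize_attribution(results)
    return summary.sort_values("median").reset_index(drop=True)
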