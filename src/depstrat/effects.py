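"""Stage-2 mask-based effect sizes.

For every significance mask from stage 1, each subject is reduced to the
mean of their (smoothed) measure map over the mask voxels. Cohen's d with
the pooled SD then quantifies each depression group — an exact-k stratum or
an individual criteria constellation — against the single pooled control
group. Constellations with fewer than ``min_n`` available participants are
excluded (and logged) for stability of the estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .criteria import constellation_label, popcount

logger = logging.getLogger(__name__)

#: Default minimum group size for a constellation to be retained.
MIN_GROUP_N = 10


def mask_mean(values: np.ndarray, mask: np.ndarray) -> float:
    """Mean of a 3D map over the voxels of a binary mask."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("map and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    return float(values[mask].mean())


def mask_means_stack(stack: np.ndarray, mask_flat: np.ndarray) -> np.ndarray:
    """Per-subject mask means from an (n_subjects, n_voxels) stack."""
    mask_flat = np.asarray(mask_flat, dtype=bool)
    if not mask_flat.any():
        raise ValueError("mask is empty")
    return np.asarray(stack, dtype=float)[:, mask_flat].mean(axis=1)


@dataclass(frozen=True)
class EffectSizeRecord:
    mask_id: str
    group: str                # "k3" or a constellation label
    constellation_id: int | None
    k: int | None
    n_case: int
    n_control: int
    cohens_d: float
    ci_low: float
    ci_high: float


def cohens_d(
    case_values: np.ndarray,
    control_values: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    ci: bool = True,
    hedges: bool = False,
    analytic_ci: bool = False,
) -> tuple[float, float, float]:
    """Cohen's d with pooled SD and a 95% CI.

    d = (mean_case - mean_control) / s_pooled with
    s_pooled = sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)).

    The CI is a seeded percentile bootstrap over subjects (default 1000
    resamples); ``analytic_ci`` switches to the noncentral-t interval.
    ``hedges`` applies the small-sample bias correction factor.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 values")
    d = _point_d(x, y, hedges)
    if not ci:
        return d, np.nan, np.nan
    if analytic_ci:
        lo, hi = _analytic_ci(d, n1, n2)
    else:
        rng = np.random.default_rng(seed)
        xb = x[rng.integers(0, n1, (n_boot, n1))]
        yb = y[rng.integers(0, n2, (n_boot, n2))]
        s2 = (
            (n1 - 1) * xb.var(axis=1, ddof=1) + (n2 - 1) * yb.var(axis=1, ddof=1)
        ) / (n1 + n2 - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            boots = (xb.mean(axis=1) - yb.mean(axis=1)) / np.sqrt(s2)
        if hedges:
            boots = boots * (1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0))
        boots = boots[np.isfinite(boots)]
        lo, hi = np.percentile(boots, [2.5, 97.5])
    return d, float(lo), float(hi)


def _point_d(x, y, hedges: bool, allow_zero_sd: bool = False) -> float:
    n1, n2 = len(x), len(y)
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        if allow_zero_sd:
            return np.nan
        raise ValueError("pooled SD is zero")
    d = (x.mean() - y.mean()) / np.sqrt(s2)
    if hedges:
        df = n1 + n2 - 2
        d *= 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(d)


def _analytic_ci(d: float, n1: int, n2: int) -> tuple[float, float]:
    from scipy import stats as sps

    scale = np.sqrt(1.0 / n1 + 1.0 / n2)
    nc = d / scale
    df = n1 + n2 - 2
    lo = sps.nct.ppf(0.025, df, nc) * scale
    hi = sps.nct.ppf(0.975, df, nc) * scale
    return float(lo), float(hi)


def effect_table(
    subjects: pd.DataFrame,
    mask_means: pd.DataFrame,
    grouping: str = "constellations",
    min_n: int = MIN_GROUP_N,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohen's d for every (group, mask) pair against the pooled controls.

    ``mask_means`` holds one column per mask id, rows aligned with
    ``subjects`` (the per-subject mean of the modality map matching each
    mask). ``grouping`` is ``'strata'`` (exact-k groups) or
    ``'constellations'`` (individual criteria subsets); groups with fewer
    than ``min_n`` cases are omitted and logged.
    """
    if grouping not in ("strata", "constellations"):
        raise ValueError("grouping must be 'strata' or 'constellations'")
    if mask_means.shape[1] == 0:
        raise ValueError("no masks available")
    if len(mask_means) != len(subjects):
        raise ValueError("mask_means rows do not align with subjects")

    is_case = (subjects["group"] == "case").to_numpy()
    control_idx = np.flatnonzero(~is_case)

    if grouping == "strata":
        keys = [(f"k{k}", None, k, subjects["k"].to_numpy() == k) for k in range(1, 7)]
    else:
        cids = sorted(subjects.loc[is_case, "constellation_id"].unique())
        cc = subjects["constellation_id"].to_numpy()
        keys = [
            (constellation_label(int(c)), int(c), popcount(int(c)), cc == c)
            for c in cids
        ]

    records = []
    for gi, (name, cid, k, member) in enumerate(keys):
        case_idx = np.flatnonzero(member & is_case)
        if len(case_idx) < min_n:
            logger.info(
                "group %s omitted: %d cases < min_n=%d", name, len(case_idx), min_n
            )
            continue
        for mi, mask_id in enumerate(mask_means.columns):
            vals = mask_means[mask_id].to_numpy(dtype=float)
            d, lo, hi = cohens_d(
                vals[case_idx],
                vals[control_idx],
                n_boot=n_boot,
                seed=seed + 1000 * gi + mi,
            )
            records.append(
                EffectSizeRecord(
                    mask_id=mask_id,
                    group=name,
                    constellation_id=cid,
                    k=k,
                    n_case=len(case_idx),
                    n_control=len(control_idx),
                    cohens_d=d,
                    ci_low=lo,
                    ci_high=hi,
                )
            )
    return pd.DataFrame([r.__dict__ for r in records])
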