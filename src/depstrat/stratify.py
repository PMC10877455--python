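"""Exact-k strata, criteria constellations, and control-group strategies.

Cases are partitioned by the *exact* number of criteria met (k = 1..6), so
the six strata are disjoint. Each case also belongs to exactly one of the
63 non-empty criteria subsets ("constellations"). Two control strategies are
supported: the single pooled control group (strategy 1, primary) and 1:1
matched controls (strategy 2, control analysis) matched exactly on sex and
by nearest neighbor on z-scored age and years of education.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .criteria import CRITERIA_COLUMNS, N_CRITERIA


def enumerate_constellations(n_criteria: int = N_CRITERIA) -> list[int]:
    """All non-empty criteria subsets as integer bit patterns.

    Ordered canonically by (popcount, numeric value); for 6 criteria this
    yields 63 patterns.
    """
    if n_criteria < 1:
        raise ValueError("need at least 1 criterion")
    ids = list(range(1, 1 << n_criteria))
    ids.sort(key=lambda c: (c.bit_count(), c))
    return ids


def assign_strata(subjects: pd.DataFrame) -> pd.DataFrame:
    """Assign each case to its exact-k stratum and constellation.

    Returns a table with columns ``subject_id, k, constellation_id``. Raises
    if any case meets no criterion.
    """
    cases = subjects[subjects["group"] == "case"]
    bits = cases[list(CRITERIA_COLUMNS)].to_numpy(dtype=int)
    k = bits.sum(axis=1)
    if (k == 0).any():
        bad = cases.loc[k == 0, "subject_id"].tolist()
        raise ValueError(f"cases with all-false criteria profile: {bad}")
    cid = (bits * (1 << np.arange(N_CRITERIA))).sum(axis=1)
    return pd.DataFrame(
        {
            "subject_id": cases["subject_id"].to_numpy(),
            "k": k,
            "constellation_id": cid,
        }
    )


@dataclass
class MatchedPairs:
    """Result of 1:1 case-control matching without replacement."""

    pairs: list[tuple[str, str]]
    unmatched_cases: list[str]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["case_id", "control_id"])


def match_controls(
    cases: pd.DataFrame,
    control_pool: pd.DataFrame,
    continuous_vars: tuple[str, ...] = ("age", "education_years"),
    exact_vars: tuple[str, ...] = ("sex",),
    seed: int = 0,
    method: str = "greedy",
) -> MatchedPairs:
    """1:1 matching of controls to cases without replacement.

    Matching is exact on ``exact_vars`` and minimizes Euclidean distance on
    z-scored ``continuous_vars`` (z-scores from the combined sample). With
    ``method='greedy'`` cases are processed in a seeded random order, each
    taking its nearest remaining control; ``method='optimal'`` solves the
    assignment problem minimizing the total distance within each exact
    stratum. Cases left over when a stratum's pool is exhausted are reported
    as unmatched.
    """
    if control_pool.empty:
        raise ValueError("control pool is empty")
    if method not in ("greedy", "optimal"):
        raise ValueError(f"unknown matching method {method!r}")

    combined = pd.concat([cases, control_pool], ignore_index=True)
    mu = combined[list(continuous_vars)].mean()
    sd = combined[list(continuous_vars)].std(ddof=0).replace(0.0, 1.0)

    def z(df: pd.DataFrame) -> np.ndarray:
        return ((df[list(continuous_vars)] - mu) / sd).to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []

    case_groups = cases.groupby(list(exact_vars), sort=True)
    pool_groups = dict(iter(control_pool.groupby(list(exact_vars), sort=True)))

    for key, cgrp in case_groups:
        pgrp = pool_groups.get(key)
        if pgrp is None or pgrp.empty:
            unmatched.extend(cgrp["subject_id"].tolist())
            continue
        cz, pz = z(cgrp), z(pgrp)
        cids = cgrp["subject_id"].to_numpy()
        pids = pgrp["subject_id"].to_numpy()
        dist = np.linalg.norm(cz[:, None, :] - pz[None, :, :], axis=2)
        if method == "optimal":
            ri, ci = linear_sum_assignment(dist)
            pairs.extend((cids[r], pids[c]) for r, c in zip(ri, ci))
            unmatched.extend(cids[r] for r in range(len(cids)) if r not in set(ri))
        else:
            order = rng.permutation(len(cids))
            taken = np.zeros(len(pids), dtype=bool)
            for idx in order:
                if taken.all():
                    unmatched.append(cids[idx])
                    continue
                d = np.where(taken, np.inf, dist[idx])
                j = int(np.argmin(d))
                taken[j] = True
                pairs.append((cids[idx], pids[j]))

    return MatchedPairs(pairs=pairs, unmatched_cases=unmatched)
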