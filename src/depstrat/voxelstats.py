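"""Stage-1 voxel-wise group inference with cluster-level FWE control.

Per contrast (exact-k stratum x modality x direction), the pipeline

1. residualizes the per-subject measure maps on the nuisance design
   [1, age, age^2, sex, TIV] fitted on the combined sample,
2. computes a voxel-wise Welch (unequal-variance) two-sample t map with
   Satterthwaite degrees of freedom, signed depression-minus-control,
3. forms candidate clusters from voxels with one-sided p below the
   cluster-forming threshold (default .001) under 26-connectivity, and
4. controls family-wise error over clusters with a permutation null of the
   maximum cluster extent: group labels are permuted on the residualized
   data (Freedman-Lane style — the nuisance fit is held fixed), the same
   cluster-forming rule is applied, and the corrected p of an observed
   cluster of size s is (1 + #{permutation max >= s}) / (1 + n_perm).

Clusters with corrected p below the cluster alpha (default .05) form the
binary significance mask consumed by the stage-2 effect-size analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .core import MODALITIES, VolumeGrid

logger = logging.getLogger(__name__)

DIRECTIONS = ("increase", "decrease")
STRATEGIES = ("pool", "matched")

#: Default thresholds.
ALPHA_VOXEL = 0.001
ALPHA_CLUSTER = 0.05

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class ContrastSpec:
    """One directional test: exact-k stratum vs controls for one modality."""

    k: int
    modality: str
    direction: str
    strategy: str = "pool"

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 6:
            raise ValueError("stratum k must be 1..6")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")

    @property
    def mask_id(self) -> str:
        return f"{self.modality}_{self.direction}_k{self.k}"


def enumerate_contrasts(strategy: str = "pool") -> list[ContrastSpec]:
    """The full stage-1 design: 6 strata x 4 modalities x 2 directions."""
    return [
        ContrastSpec(k, mod, direction, strategy)
        for k in range(1, 7)
        for mod in MODALITIES
        for direction in DIRECTIONS
    ]


# ---------------------------------------------------------------------------
# nuisance regression
# ---------------------------------------------------------------------------

def nuisance_design(covariates: pd.DataFrame) -> np.ndarray:
    """Design matrix [1, age_c, age_c^2, sex, TIV]; age centered for conditioning."""
    age = covariates["age"].to_numpy(dtype=float)
    age_c = age - age.mean()
    return np.column_stack(
        [
            np.ones(len(covariates)),
            age_c,
            age_c**2,
            covariates["sex"].to_numpy(dtype=float),
            covariates["tiv_ml"].to_numpy(dtype=float),
        ]
    )


def residualize(stack: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """Residuals of each voxel column after least-squares fit on the nuisance
    design, fitted on the combined (case + control) sample.

    ``stack`` is ``(n_subjects, n_voxels)``; rows must align with the
    covariate table. The group indicator is never part of the design.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.shape[0] != len(covariates):
        raise ValueError("covariate rows do not align with subjects")
    design = nuisance_design(covariates)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("nuisance design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(design, stack, rcond=None)
    return stack - design @ beta


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------

def welch_t(
    stack: np.ndarray, case_labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise Welch two-sample t and Satterthwaite df.

    Sign convention: case minus control, so negative t means reduced in the
    depression group. Voxels with zero variance in both groups get t = 0
    (flagged via a warning) and df = n - 2.
    """
    t, df = _welch_batch(
        np.asarray(stack, dtype=float),
        np.asarray(case_labels, dtype=bool)[None, :],
    )
    return t[0], df[0]


def _welch_batch(
    stack: np.ndarray, case_indicator: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Welch t/df for B label vectors at once: inputs (n, V) and (B, n)."""
    n = stack.shape[0]
    n1 = int(case_indicator[0].sum())
    n2 = n - n1
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 subjects")
    if not np.all(case_indicator.sum(axis=1) == n1):
        raise ValueError("all label vectors must have the same group sizes")

    X = stack
    X2 = X * X
    S = X.sum(axis=0)
    Q = X2.sum(axis=0)
    C = case_indicator.astype(X.dtype)
    S1 = C @ X
    Q1 = C @ X2
    S2 = S - S1
    Q2 = Q - Q1
    m1, m2 = S1 / n1, S2 / n2
    v1 = np.maximum(Q1 - n1 * m1 * m1, 0.0) / (n1 - 1)
    v2 = np.maximum(Q2 - n2 * m2 * m2, 0.0) / (n2 - 1)
    a1, a2 = v1 / n1, v2 / n2
    se2 = a1 + a2
    degenerate = se2 == 0
    if degenerate.any():
        logger.warning(
            "%d voxel/permutation cells with zero variance in both groups; t set to 0",
            int(degenerate.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2 * se2 / (a1 * a1 / (n1 - 1) + a2 * a2 / (n2 - 1))
    t[degenerate] = 0.0
    df[~np.isfinite(df)] = n - 2
    return t, df


def _suprathreshold(
    t: np.ndarray, df: np.ndarray, p_voxel: float, direction: str
) -> np.ndarray:
    """One-sided p < p_voxel in the stated direction, per-voxel df.

    Exact t survival probabilities are only evaluated on voxels exceeding
    the most liberal possible critical value (that of the largest df), which
    keeps the cost negligible under permutation.
    """
    s = t if direction == "increase" else -t
    floor = sps.t.isf(p_voxel, np.nanmax(df))
    out = np.zeros(t.shape, dtype=bool)
    cand = s > floor
    if cand.any():
        out[cand] = sps.t.sf(s[cand], df[cand]) < p_voxel
    return out


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    cluster_id: int
    size: int
    voxels: np.ndarray        # (size, 3) integer coordinates
    max_abs_t: float
    peak_voxel: tuple[int, int, int]


def form_clusters(
    t_map: np.ndarray,
    df_map: np.ndarray,
    grid: VolumeGrid,
    p_voxel: float = ALPHA_VOXEL,
    direction: str = "decrease",
    connectivity: int = 26,
) -> tuple[list[Cluster], np.ndarray]:
    """Group suprathreshold voxels into connected clusters.

    ``t_map``/``df_map`` are full 3D fields; only in-mask voxels are eligible.
    Returns the clusters (sorted by decreasing size) and the integer label
    volume.
    """
    if not 0 < p_voxel < 1:
        raise ValueError("p_voxel must lie in (0, 1)")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    t_flat = grid.flatten(t_map)
    df_flat = grid.flatten(df_map)
    supra_flat = _suprathreshold(t_flat, df_flat, p_voxel, direction)
    supra = grid.unflatten(supra_flat.astype(float)) > 0
    labels, n_lab = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    clusters: list[Cluster] = []
    for lab in range(1, n_lab + 1):
        vox = np.argwhere(labels == lab)
        tvals = t_map[labels == lab]
        peak = vox[np.argmax(np.abs(tvals))]
        clusters.append(
            Cluster(
                cluster_id=lab,
                size=len(vox),
                voxels=vox,
                max_abs_t=float(np.max(np.abs(tvals))),
                peak_voxel=tuple(int(x) for x in peak),
            )
        )
    clusters.sort(key=lambda c: (-c.size, c.cluster_id))
    return clusters, labels


def _max_cluster_sizes(
    supra_flat: np.ndarray, grid: VolumeGrid, structure: np.ndarray
) -> int:
    """Largest connected-component size of a flat in-mask boolean map."""
    if not supra_flat.any():
        return 0
    vol = grid.unflatten(supra_flat.astype(float)) > 0
    labels, n_lab = ndimage.label(vol, structure=structure)
    if n_lab == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


# ---------------------------------------------------------------------------
# cluster-level FWE by permutation
# ---------------------------------------------------------------------------

@dataclass
class StatResult:
    """Voxel-wise t map plus surviving-cluster mask for one contrast."""

    contrast: ContrastSpec | None
    t_map: np.ndarray
    df_map: np.ndarray
    cluster_table: pd.DataFrame
    significance_mask: np.ndarray
    n_perm: int
    perm_max_sizes: np.ndarray

    @property
    def n_significant(self) -> int:
        return int((self.cluster_table["p_corrected"] < ALPHA_CLUSTER).sum()) if len(
            self.cluster_table
        ) else 0


def cluster_fwe(
    adjusted_stack: np.ndarray,
    case_labels: np.ndarray,
    grid: VolumeGrid,
    direction: str = "decrease",
    p_voxel: float = ALPHA_VOXEL,
    alpha_cluster: float = ALPHA_CLUSTER,
    n_perm: int = 1000,
    seed: int = 0,
    connectivity: int = 26,
    contrast: ContrastSpec | None = None,
) -> StatResult:
    """Cluster-level FWE control via the max-cluster-extent permutation null.

    ``adjusted_stack`` is the residualized ``(n_subjects, n_voxels)`` data;
    ``case_labels`` marks the depression group. Corrected p-values use the
    add-one estimator ``(1 + #{perm max >= size}) / (1 + n_perm)`` and can
    therefore never be smaller than ``1/(n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if 1.0 / (n_perm + 1) > alpha_cluster:
        raise ValueError(
            f"n_perm={n_perm} cannot resolve alpha_cluster={alpha_cluster}"
        )
    labels = np.asarray(case_labels, dtype=bool)
    stack = np.asarray(adjusted_stack, dtype=float)
    if stack.shape[0] != labels.shape[0]:
        raise ValueError("labels do not align with subjects")
    structure = _STRUCTURES[connectivity]

    t_flat, df_flat = welch_t(stack, labels)
    t_map = grid.unflatten(t_flat)
    df_map = grid.unflatten(df_flat, fill=np.nan)
    clusters, _ = form_clusters(t_map, df_map, grid, p_voxel, direction, connectivity)

    rng = np.random.default_rng(seed)
    perm_max = np.zeros(n_perm, dtype=int)
    chunk = 100
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = rng.permuted(np.tile(labels, (b, 1)), axis=1)
        t_b, df_b = _welch_batch(stack, perms)
        for i in range(b):
            supra = _suprathreshold(t_b[i], df_b[i], p_voxel, direction)
            perm_max[done + i] = _max_cluster_sizes(supra, grid, structure)
        done += b

    rows = []
    mask = np.zeros(grid.shape, dtype=bool)
    for c in clusters:
        p_corr = (1.0 + np.sum(perm_max >= c.size)) / (1.0 + n_perm)
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "size": c.size,
                "max_abs_t": c.max_abs_t,
                "peak_i": c.peak_voxel[0],
                "peak_j": c.peak_voxel[1],
                "peak_k": c.peak_voxel[2],
                "p_corrected": p_corr,
            }
        )
        if p_corr < alpha_cluster:
            mask[tuple(c.voxels.T)] = True
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "size", "max_abs_t", "peak_i", "peak_j", "peak_k",
            "p_corrected",
        ],
    )
    return StatResult(
        contrast=contrast,
        t_map=t_map,
        df_map=df_map,
        cluster_table=table,
        significance_mask=mask,
        n_perm=n_perm,
        perm_max_sizes=perm_max,
    )
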