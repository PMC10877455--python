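"""End-to-end orchestration: simulate -> measures -> stratify -> stage 1 ->
stage 2 -> attribution, under a single reproducible configuration.

The pipeline operates on in-memory ``(n_subjects, n_voxels)`` stacks per
modality; :func:`run_all` additionally persists every tabular output (TSV),
the stage-1 masks (NIfTI) and a manifest with the config hash, derived
seeds and output checksums, so identical configs reproduce identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    PlantedEffect,
    SimulationConfig,
    record_from_row,
    simulate_cohort_table,
    simulate_subject_volumes,
)
from .core import MODALITIES, BandSpec, VolumeGrid
from .effects import effect_table, mask_means_stack
from .attribution import attribute_criteria, attribution_frame, summarize_attribution
from .measures import (
    DEFAULT_LCOR_FWHM,
    compute_falff,
    compute_gcor,
    compute_lcor,
    compute_relative_gmv,
    smooth_map,
)
from .seeding import derive_seed
from .stratify import assign_strata, match_controls
from .voxelstats import (
    ALPHA_CLUSTER,
    ALPHA_VOXEL,
    ContrastSpec,
    StatResult,
    cluster_fwe,
    enumerate_contrasts,
    residualize,
)

logger = logging.getLogger(__name__)

_EFFECT_COLUMNS = [
    "mask_id", "group", "constellation_id", "k", "n_case", "n_control",
    "cohens_d", "ci_low", "ci_high",
]


def _listify(obj):
    """Recursively convert tuples to lists for YAML/JSON serialization."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


@dataclass
class RunConfig:
    """Full configuration of one pipeline run.

    Defaults follow the analysis design: 0.008-0.09 Hz band, 8-mm smoothing,
    voxel threshold .001, cluster alpha .05, minimum group size 10. The
    permutation count (500) and bootstrap count (1000) are desk-scale
    choices; every stochastic step derives its seed from ``seed``.
    """

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    band_low: float = 0.008
    band_high: float = 0.09
    smooth_fwhm: float = 8.0          # mm, applied to all measure maps
    lcor_fwhm: float = DEFAULT_LCOR_FWHM
    alpha_voxel: float = ALPHA_VOXEL
    alpha_cluster: float = ALPHA_CLUSTER
    n_perm: int = 500
    connectivity: int = 26
    min_group_n: int = 10
    n_boot: int = 1000
    strategy: str = "pool"            # "pool" | "matched" for stage 1
    modalities: tuple[str, ...] = MODALITIES
    directions: tuple[str, ...] = ("increase", "decrease")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("pool", "matched"):
            raise ValueError("strategy must be 'pool' or 'matched'")
        bad = set(self.modalities) - set(MODALITIES)
        if bad:
            raise ValueError(f"unknown modalities: {sorted(bad)}")
        if set(self.directions) - {"increase", "decrease"}:
            raise ValueError("directions must be 'increase'/'decrease'")
        # all randomness flows from the global run seed
        self.sim = self.sim.with_(seed=derive_seed(self.seed, "sim"))

    @property
    def band(self) -> BandSpec:
        return BandSpec(self.band_low, self.band_high)

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["effects"] = {
            mod: [
                {
                    "center": list(e.center),
                    "radius": e.radius,
                    "amplitudes": list(e.amplitudes),
                }
                for e in effs
            ]
            for mod, effs in self.sim.effects.items()
        }
        return _listify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("sim", {}))
        if "effects" in sim:
            sim["effects"] = {
                mod: tuple(
                    PlantedEffect(
                        tuple(e["center"]), float(e["radius"]), tuple(e["amplitudes"])
                    )
                    for e in effs
                )
                for mod, effs in sim["effects"].items()
            }
        for key in ("grid_shape", "voxel_size_mm", "prevalences", "age_mean",
                    "age_range", "tiv_mean_by_sex"):
            if key in sim and sim[key] is not None:
                sim[key] = tuple(sim[key])
        d["sim"] = SimulationConfig(**sim)
        for key in ("modalities", "directions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# measure stacks
# ---------------------------------------------------------------------------

def compute_measure_stacks(
    subjects: pd.DataFrame, config: RunConfig, grid: VolumeGrid | None = None
) -> dict[str, np.ndarray]:
    """Per-modality ``(n_subjects, n_voxels)`` stacks of smoothed measure maps.

    Simulates each subject's volumes, computes the requested measures and
    applies the common smoothing kernel. Rows align with ``subjects``.
    """
    if grid is None:
        grid = config.sim.grid()
    band = config.band
    stacks = {mod: np.empty((len(subjects), grid.n_voxels)) for mod in config.modalities}
    for i, (_, row) in enumerate(subjects.iterrows()):
        rec = record_from_row(row)
        func, struct = simulate_subject_volumes(rec, config.sim, grid)
        maps = {}
        if "falff" in config.modalities:
            maps["falff"] = compute_falff(func, band, config.sim.tr, grid, rec.subject_id)
        if "lcor" in config.modalities:
            maps["lcor"] = compute_lcor(func, grid, config.lcor_fwhm, rec.subject_id)
        if "gcor" in config.modalities:
            maps["gcor"] = compute_gcor(func, grid, rec.subject_id)
        if "gmv" in config.modalities:
            _, maps["gmv"] = compute_relative_gmv(struct, rec.tiv, grid, rec.subject_id)
        for mod, m in maps.items():
            sm = smooth_map(m, config.smooth_fwhm, grid)
            stacks[mod][i] = sm.masked()
    return stacks


# ---------------------------------------------------------------------------
# stage 1
# ---------------------------------------------------------------------------

def run_stage1(
    subjects: pd.DataFrame,
    stacks: dict[str, np.ndarray],
    config: RunConfig,
    grid: VolumeGrid,
) -> dict[str, StatResult]:
    """All stage-1 contrasts for the configured strategy.

    Returns a mapping from mask id (``modality_direction_kN``) to
    :class:`StatResult` for every contrast whose stratum has at least two
    cases. For the matched strategy, each stratum is compared with its own
    1:1 matched controls; for the pool strategy, with all controls.
    """
    is_case = (subjects["group"] == "case").to_numpy()
    control_rows = np.flatnonzero(~is_case)
    k_col = subjects["k"].to_numpy()
    results: dict[str, StatResult] = {}

    matched_rows: dict[int, np.ndarray] = {}
    if config.strategy == "matched":
        pool = subjects[~is_case]
        id_to_row = {sid: i for i, sid in enumerate(subjects["subject_id"])}
        for k in range(1, 7):
            cases_k = subjects[is_case & (k_col == k)]
            if len(cases_k) == 0:
                continue
            mp = match_controls(
                cases_k, pool, seed=derive_seed(config.seed, "match", k)
            )
            matched_rows[k] = np.array(
                [id_to_row[c] for _, c in mp.pairs], dtype=int
            )

    contrasts = [c for c in enumerate_contrasts(config.strategy)
                 if c.modality in config.modalities
                 and c.direction in config.directions]
    for spec in contrasts:
        case_rows = np.flatnonzero(is_case & (k_col == spec.k))
        if len(case_rows) < 2:
            logger.info("contrast %s skipped: %d cases", spec.mask_id, len(case_rows))
            continue
        ctrl = matched_rows.get(spec.k, control_rows) if config.strategy == "matched" \
            else control_rows
        if len(ctrl) < 2:
            continue
        rows = np.concatenate([case_rows, ctrl])
        sub = subjects.iloc[rows]
        try:
            adjusted = residualize(stacks[spec.modality][rows], sub)
        except ValueError as exc:
            # e.g. a tiny matched stratum cannot support the nuisance design
            logger.warning("contrast %s skipped: %s", spec.mask_id, exc)
            continue
        labels = np.zeros(len(rows), dtype=bool)
        labels[: len(case_rows)] = True
        res = cluster_fwe(
            adjusted,
            labels,
            grid,
            direction=spec.direction,
            p_voxel=config.alpha_voxel,
            alpha_cluster=config.alpha_cluster,
            n_perm=config.n_perm,
            seed=derive_seed(config.seed, "stage1", spec.mask_id),
            connectivity=config.connectivity,
            contrast=spec,
        )
        results[spec.mask_id] = res
        logger.info(
            "contrast %s: %d candidate clusters, %d significant",
            spec.mask_id, len(res.cluster_table), res.n_significant,
        )
    return results


def significance_masks(results: dict[str, StatResult]) -> dict[str, np.ndarray]:
    """Non-empty stage-1 masks, keyed by mask id (empty masks are absent)."""
    return {
        mid: r.significance_mask
        for mid, r in results.items()
        if r.significance_mask.any()
    }


# ---------------------------------------------------------------------------
# stage 2 + attribution
# ---------------------------------------------------------------------------

def run_stage2(
    subjects: pd.DataFrame,
    stacks: dict[str, np.ndarray],
    masks: dict[str, np.ndarray],
    config: RunConfig,
    grid: VolumeGrid,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask means and Cohen's d for strata and constellations vs pooled controls.

    Returns ``(strata_table, constellation_table)``. Each mask's means are
    taken from the measure stack of the mask's own modality.
    """
    if not masks:
        raise ValueError("no stage-1 masks available")
    subjects = subjects.copy()
    if "constellation_id" not in subjects.columns:
        strata = assign_strata(subjects)
        subjects = subjects.merge(
            strata[["subject_id", "constellation_id"]], on="subject_id", how="left"
        )
        subjects["constellation_id"] = (
            subjects["constellation_id"].fillna(0).astype(int)
        )
    mm = pd.DataFrame(index=subjects.index)
    for mask_id, mask in masks.items():
        modality = mask_id.split("_")[0]
        mm[mask_id] = mask_means_stack(stacks[modality], grid.flatten(mask) > 0)
    strata_tbl = effect_table(
        subjects, mm, grouping="strata", min_n=config.min_group_n,
        n_boot=config.n_boot, seed=derive_seed(config.seed, "stage2", "strata"),
    )
    const_tbl = effect_table(
        subjects, mm, grouping="constellations", min_n=config.min_group_n,
        n_boot=config.n_boot, seed=derive_seed(config.seed, "stage2", "const"),
    )
    return strata_tbl, const_tbl


def run_attribution(
    constellation_table: pd.DataFrame, weighted: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attribution deltas per (mask, criterion) plus the per-criterion summary."""
    results = attribute_criteria(constellation_table, weighted=weighted)
    frame = attribution_frame(results)
    summary = summarize_attribution(frame)
    return frame, summary


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_all(config: RunConfig, out_dir) -> dict:
    """Execute every stage in order and persist outputs plus a manifest.

    Returns the manifest dict. Re-running with an identical config
    reproduces identical tabular outputs (checksums recorded in the
    manifest).
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "checksums": {},
    }
    grid = config.sim.grid()

    def _stage(name):
        t0 = time.time()
        logger.info("stage %s ...", name)
        return t0

    def _done(name, t0):
        manifest["stages"][name] = round(time.time() - t0, 2)
        logger.info("stage %s done in %.1fs", name, manifest["stages"][name])

    try:
        t0 = _stage("simulate")
        subjects = simulate_cohort_table(config.sim)
        strata = assign_strata(subjects)
        subjects = subjects.merge(
            strata[["subject_id", "constellation_id"]], on="subject_id", how="left"
        )
        subjects["constellation_id"] = subjects["constellation_id"].fillna(0).astype(int)
        _write_tsv(out / "subjects.tsv", subjects, manifest)
        _done("simulate", t0)

        t0 = _stage("measures")
        stacks = compute_measure_stacks(subjects, config, grid)
        _done("measures", t0)

        t0 = _stage("stage1")
        results = run_stage1(subjects, stacks, config, grid)
        cluster_rows = []
        for mid, res in results.items():
            if len(res.cluster_table):
                tbl = res.cluster_table.copy()
                tbl.insert(0, "mask_id", mid)
                cluster_rows.append(tbl)
        clusters = (
            pd.concat(cluster_rows, ignore_index=True)
            if cluster_rows
            else pd.DataFrame(columns=["mask_id", "cluster_id", "size", "p_corrected"])
        )
        _write_tsv(out / "clusters.tsv", clusters, manifest)
        masks = significance_masks(results)
        for mid, mask in masks.items():
            nib.save(
                nib.Nifti1Image(mask.astype(np.uint8), grid.affine),
                out / f"mask_{mid}.nii.gz",
            )
        _done("stage1", t0)

        t0 = _stage("stage2")
        if masks:
            strata_tbl, const_tbl = run_stage2(subjects, stacks, masks, config, grid)
        else:
            logger.warning("no significant clusters; stage 2 and attribution empty")
            strata_tbl = pd.DataFrame(columns=_EFFECT_COLUMNS)
            const_tbl = pd.DataFrame(columns=_EFFECT_COLUMNS)
        _write_tsv(out / "effects_strata.tsv", strata_tbl, manifest)
        _write_tsv(out / "effects_constellations.tsv", const_tbl, manifest)
        _done("stage2", t0)

        t0 = _stage("attribute")
        if len(const_tbl):
            attr, summary = run_attribution(const_tbl)
        else:
            attr = pd.DataFrame(
                columns=["mask_id", "criterion", "delta_es", "n_with", "n_without"]
            )
            summary = pd.DataFrame(
                columns=["criterion", "median", "q1", "q3", "n_masks"]
            )
        _write_tsv(out / "attribution.tsv", attr, manifest)
        _write_tsv(out / "attribution_summary.tsv", summary, manifest)
        _done("attribute", t0)
    except Exception as exc:  # record the failing stage, then re-raise
        manifest["failed"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _write_tsv(path: Path, df: pd.DataFrame, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    manifest["checksums"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
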