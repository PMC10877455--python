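"""Synthetic case-control cohorts with planted, criterion-linked voxel effects.

This module generates everything the downstream analysis consumes: a subject
table (six binary depression criteria, demographics, covariates, group label)
and per-subject images (a 4D resting-state series and a 3D gray-matter
volume) on a small shared grid.

Criteria dependence model
-------------------------
The six criteria are heavily overlapping in real cohorts (a person with a
hospital diagnosis usually also self-reports and takes antidepressants), so
the bits are drawn from a single-factor probit model: each subject has one
latent standard-normal "severity" ``z``; criterion ``i`` fires when

    loading * z + sqrt(1 - loading^2) * e_i  >  Phi^-1(1 - p_i)

with independent standard-normal ``e_i``. The marginal prevalence of
criterion ``i`` is exactly ``p_i`` and the shared factor induces positive
pairwise dependence, which makes the count of subjects meeting exactly ``k``
criteria fall off with ``k`` (the shape observed in large biobank samples).

Planted voxel effects
---------------------
Each modality has a spherical effect region and a signed per-criterion
amplitude vector. A subject's effect strength in a region is the sum of the
amplitudes of the criteria they meet, so effects accumulate with more (and
more specific) criteria:

* fALFF - a sinusoid is added to the region's time series: out-of-band
  (suppresses the low-frequency fraction) for negative strength, in-band for
  positive strength.
* LCOR - a region-wide shared signal raises local correlation; with a
  checkerboard sign flip it drives neighboring voxels apart (negative LCOR
  shift).
* GCOR - the baseline series couples every in-mask voxel to a subject-level
  global signal; the planted strength adds to that coupling weight inside
  the region, moving global correlation up or down.
* GMV - an additive gray-matter density offset inside the structural region.

Controls (and cases meeting no loaded criterion) receive pure baseline
volumes, so all group differences are attributable to the planted
amplitudes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import MODALITIES, VolumeGrid
from .criteria import CRITERIA_COLUMNS, N_CRITERIA, constellation_id
from .seeding import derive_seed

logger = logging.getLogger(__name__)

SUBJECT_TABLE_COLUMNS = (
    ("subject_id",)
    + CRITERIA_COLUMNS
    + ("k", "age", "sex", "education_years", "tiv_ml", "group")
)


@dataclass(frozen=True)
class CriteriaProfile:
    """An ordered 6-tuple of criteria indicators."""

    bits: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != N_CRITERIA:
            raise ValueError(f"expected {N_CRITERIA} bits, got {len(self.bits)}")
        object.__setattr__(self, "bits", tuple(bool(b) for b in self.bits))

    @property
    def k(self) -> int:
        """Number of criteria met (exact count, 0-6)."""
        return sum(self.bits)

    @property
    def constellation_id(self) -> int:
        return constellation_id(self.bits)


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    profile: CriteriaProfile
    age: float
    sex: int              # 0 = male, 1 = female
    education: float      # years
    tiv: float            # total intracranial volume, mL
    group: str            # "case" | "control"

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ValueError(f"group must be 'case' or 'control', got {self.group!r}")
        if self.group == "control" and self.profile.k != 0:
            raise ValueError("controls must meet no criterion")
        if self.group == "case" and self.profile.k == 0:
            raise ValueError("a subject meeting no criterion cannot be a case")


@dataclass(frozen=True)
class PlantedEffect:
    """A spherical effect region with signed per-criterion amplitudes."""

    center: tuple[int, int, int]
    radius: float                  # voxels
    amplitudes: tuple[float, ...]  # one signed amplitude per criterion

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("effect radius must be >= 1 voxel")
        if len(self.amplitudes) != N_CRITERIA:
            raise ValueError(f"need {N_CRITERIA} amplitudes")
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))

    def strength(self, profile: CriteriaProfile) -> float:
        """Summed amplitude of the criteria this subject meets."""
        return float(sum(a for a, b in zip(self.amplitudes, profile.bits) if b))

    def indicator(self, shape: tuple[int, int, int]) -> np.ndarray:
        return sphere_mask(shape, self.center, self.radius)


def sphere_mask(
    shape: tuple[int, int, int], center: tuple[float, float, float], radius: float
) -> np.ndarray:
    """Boolean sphere of the given radius (in voxels) on a grid."""
    ii, jj, kk = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (
        (ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2
    )
    return d2 <= radius**2


def _default_effects() -> dict[str, tuple[PlantedEffect, ...]]:
    # Functional decreases carried by antidepressant use (bit 2) and ICD-10
    # (bit 4); structural effects weak and bidirectional. Amplitudes are in
    # the units of the respective mechanism (sinusoid SD, coupling weight,
    # gray-matter density) and were fixed once to give small-to-moderate
    # standardized group differences at the default noise level.
    a = (0.0, 0.0, -1.0, 0.0, -1.0, 0.0)
    return {
        "falff": (PlantedEffect((12, 12, 12), 4.0, tuple(1.1 * x for x in a)),),
        "lcor": (PlantedEffect((6, 12, 12), 3.0, tuple(0.45 * x for x in a)),),
        "gcor": (PlantedEffect((17, 12, 12), 3.0, tuple(0.25 * x for x in a)),),
        "gmv": (
            PlantedEffect((12, 7, 12), 3.0, tuple(0.03 * x for x in a)),
            PlantedEffect((12, 17, 12), 3.0, (0.0, 0.015, 0.0, 0.0, 0.0, 0.0)),
        ),
    }


def _default_prevalences() -> tuple[float, ...]:
    # Population marginals (cases + controls pooled) patterned on the
    # help-seeking >> self-report > antidepressant > CIDI-SF > Smith > ICD-10
    # ordering of large biobank samples.
    return (0.417, 0.102, 0.092, 0.069, 0.035, 0.078)


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a synthetic cohort.

    The defaults define the reference study conditions used by the test
    suite: a 24^3 grid at 4 mm with a spherical analysis mask, 120 timepoints
    at TR 0.735 s (the low-frequency band sits well below Nyquist), biobank-
    shaped criteria prevalences with a latent loading of 0.75, and functional
    decreases planted on the antidepressant-use and ICD-10 criteria only.
    """

    n_cases: int = 60
    n_controls: int = 60
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    mask_radius: float | None = 10.5   # voxels; None = full grid
    n_timepoints: int = 120
    tr: float = 0.735                  # seconds
    prevalences: tuple[float, ...] = field(default_factory=_default_prevalences)
    loading: float = 0.75              # latent-factor loading in [0, 1]
    effects: dict[str, tuple[PlantedEffect, ...]] = field(
        default_factory=_default_effects
    )
    noise_sd: float = 1.0              # functional white-noise SD
    global_coupling: float = 0.4       # baseline weight of the global signal
    gm_baseline: float = 0.55          # mean gray-matter density in mask
    gm_noise_sd: float = 0.06
    female_rate_case: float = 0.617
    female_rate_control: float = 0.447
    age_mean: tuple[float, float] = (63.9, 65.1)   # (case, control)
    age_sd: float = 7.7
    age_range: tuple[float, float] = (45.0, 80.0)
    education_mean: float = 16.7
    education_sd: float = 3.8
    tiv_mean_by_sex: tuple[float, float] = (1550.0, 1400.0)  # (male, female) mL
    tiv_sd: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.prevalences) != N_CRITERIA:
            raise ValueError(f"need {N_CRITERIA} prevalences")
        if not all(0 <= p < 1 for p in self.prevalences):
            raise ValueError("prevalences must lie in [0, 1)")
        if not 0 <= self.loading <= 1:
            raise ValueError("loading must lie in [0, 1]")
        if self.n_timepoints < 32:
            raise ValueError("need at least 32 timepoints")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for mod, effs in self.effects.items():
            if mod not in MODALITIES:
                raise ValueError(f"unknown modality in effects: {mod!r}")
            for e in effs:
                if e.radius < 1:
                    raise ValueError("effect radius must be >= 1 voxel")

    def grid(self) -> VolumeGrid:
        shape = tuple(self.grid_shape)
        if self.mask_radius is None:
            mask = np.ones(shape, dtype=bool)
        else:
            center = tuple((s - 1) / 2.0 for s in shape)
            mask = sphere_mask(shape, center, self.mask_radius)
        return VolumeGrid(shape, tuple(self.voxel_size_mm), mask)

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def subject_seed(global_seed: int, subject_id: str) -> int:
    """Stable per-subject seed below 2^31, derived from the global seed."""
    return derive_seed(global_seed, "subject", subject_id)


# ---------------------------------------------------------------------------
# criteria and demographics
# ---------------------------------------------------------------------------

def sample_criteria(
    config: SimulationConfig, n: int, rng: np.random.Generator | None = None
) -> list[CriteriaProfile]:
    """Draw ``n`` criteria profiles from the single-factor probit model.

    Marginal prevalence of criterion ``i`` is exactly ``config.prevalences[i]``;
    the latent loading controls how strongly the criteria co-occur. With
    loading 1 and equal prevalences every profile is all-true or all-false.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lam = config.loading
    z = rng.standard_normal((n, 1))
    e = rng.standard_normal((n, N_CRITERIA))
    x = lam * z + math.sqrt(max(0.0, 1 - lam**2)) * e
    thresholds = sps.norm.isf(np.asarray(config.prevalences))  # p=0 -> +inf
    bits = x > thresholds
    return [CriteriaProfile(tuple(row)) for row in bits]


def _sample_demographics(
    rng: np.random.Generator, config: SimulationConfig, n: int, is_case: bool
) -> dict[str, np.ndarray]:
    female_rate = config.female_rate_case if is_case else config.female_rate_control
    sex = (rng.random(n) < female_rate).astype(int)  # 1 = female
    mu_age = config.age_mean[0] if is_case else config.age_mean[1]
    age = np.clip(
        rng.normal(mu_age, config.age_sd, n), *config.age_range
    )
    edu = np.clip(rng.normal(config.education_mean, config.education_sd, n), 7.0, 25.0)
    tiv_mu = np.where(sex == 1, config.tiv_mean_by_sex[1], config.tiv_mean_by_sex[0])
    tiv = np.clip(rng.normal(tiv_mu, config.tiv_sd), 1000.0, 2100.0)
    return {"sex": sex, "age": age, "education": edu, "tiv": tiv}


def simulate_cohort_table(config: SimulationConfig) -> pd.DataFrame:
    """Sample the full subject table (no images).

    Cases are profiles with ``k >= 1`` (rejection-sampled from the criteria
    model); controls carry the all-false profile. Deterministic in
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)

    profiles: list[CriteriaProfile] = []
    while len(profiles) < config.n_cases:
        batch = sample_criteria(config, max(64, config.n_cases), rng=rng)
        profiles.extend(p for p in batch if p.k >= 1)
    profiles = profiles[: config.n_cases]

    rows = []
    demo = _sample_demographics(rng, config, config.n_cases, is_case=True)
    for i, prof in enumerate(profiles):
        rows.append(
            _row(f"case{i:04d}", prof, demo, i, "case")
        )
    demo = _sample_demographics(rng, config, config.n_controls, is_case=False)
    null_profile = CriteriaProfile((False,) * N_CRITERIA)
    for i in range(config.n_controls):
        rows.append(_row(f"ctrl{i:04d}", null_profile, demo, i, "control"))

    df = pd.DataFrame(rows, columns=list(SUBJECT_TABLE_COLUMNS))
    counts = df.loc[df["group"] == "case", "k"].value_counts().sort_index()
    logger.info("cohort: %d cases / %d controls; cases per exact-k: %s",
                config.n_cases, config.n_controls, counts.to_dict())
    return df


def _row(sid, prof, demo, i, group):
    return (
        (sid,)
        + tuple(int(b) for b in prof.bits)
        + (
            prof.k,
            round(float(demo["age"][i]), 2),
            int(demo["sex"][i]),
            round(float(demo["education"][i]), 2),
            round(float(demo["tiv"][i]), 1),
            group,
        )
    )


def record_from_row(row: pd.Series) -> SubjectRecord:
    """Build a :class:`SubjectRecord` from one subject-table row."""
    bits = tuple(bool(row[c]) for c in CRITERIA_COLUMNS)
    return SubjectRecord(
        subject_id=str(row["subject_id"]),
        profile=CriteriaProfile(bits),
        age=float(row["age"]),
        sex=int(row["sex"]),
        education=float(row["education_years"]),
        tiv=float(row["tiv_ml"]),
        group=str(row["group"]),
    )


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def simulate_subject_volumes(
    record: SubjectRecord,
    config: SimulationConfig,
    grid: VolumeGrid | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one subject's 4D functional series and 3D gray-matter volume.

    Returns ``(functional, structural)`` with shapes ``grid.shape + (T,)``
    and ``grid.shape``. Fully deterministic given ``config.seed`` and
    ``record.subject_id``.
    """
    if grid is None:
        grid = config.grid()
    if tuple(grid.shape) != tuple(config.grid_shape):
        raise ValueError("grid does not match config grid_shape")
    rng = np.random.default_rng(subject_seed(config.seed, record.subject_id))
    T = config.n_timepoints
    shape = tuple(grid.shape)
    mask = grid.mask

    # noise is generated for in-mask voxels only (out-of-mask voxels never
    # enter the analysis); the volume outside the mask stays zero
    func = np.zeros(shape + (T,), dtype=np.float32)
    noise = rng.standard_normal((int(mask.sum()), T), dtype=np.float32)
    noise *= config.noise_sd
    global_sig = rng.standard_normal(T).astype(np.float32)
    noise += config.global_coupling * global_sig
    func[mask] = noise

    t_sec = np.arange(T, dtype=np.float32) * config.tr

    for eff in config.effects.get("falff", ()):
        a = eff.strength(record.profile)
        if a != 0.0:
            region = eff.indicator(shape) & mask
            nvox = int(region.sum())
            freq = 0.25 if a < 0 else 0.04   # Hz: out-of-band vs in-band
            phase = rng.uniform(0, 2 * np.pi, nvox).astype(np.float32)
            wave = np.sin(
                2 * np.pi * freq * t_sec[None, :] + phase[:, None]
            )
            func[region] += (abs(a) * math.sqrt(2)) * wave

    for eff in config.effects.get("lcor", ()):
        a = eff.strength(record.profile)
        if a != 0.0:
            region = eff.indicator(shape) & mask
            shared = rng.standard_normal(T).astype(np.float32)
            if a > 0:
                func[region] += a * shared
            else:
                ii, jj, kk = np.indices(shape)
                sign = np.where((ii + jj + kk) % 2 == 0, 1.0, -1.0)[region]
                func[region] += abs(a) * sign[:, None] * shared[None, :]

    for eff in config.effects.get("gcor", ()):
        a = eff.strength(record.profile)
        if a != 0.0:
            region = eff.indicator(shape) & mask
            func[region] += a * global_sig

    struct = np.zeros(shape, dtype=np.float32)
    struct[mask] = config.gm_baseline
    struct += rng.standard_normal(shape).astype(np.float32) * config.gm_noise_sd
    struct[~mask] = 0.0
    for eff in config.effects.get("gmv", ()):
        a = eff.strength(record.profile)
        if a != 0.0:
            region = eff.indicator(shape) & mask
            struct[region] += a
    np.clip(struct, 0.0, None, out=struct)

    return func, struct


def generate_cohort(config: SimulationConfig, out_dir) -> pd.DataFrame:
    """Write the subject table (TSV) and all per-subject NIfTI volumes.

    Produces ``subjects.tsv`` plus ``<subject>_func.nii.gz`` (4D) and
    ``<subject>_anat.nii.gz`` (3D) per subject, all sharing one affine.
    Returns the subject table.
    """
    import nibabel as nib
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = simulate_cohort_table(config)
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in generated table")
    df.to_csv(out / "subjects.tsv", sep="\t", index=False)

    grid = config.grid()
    affine = grid.affine
    for _, row in df.iterrows():
        rec = record_from_row(row)
        func, struct = simulate_subject_volumes(rec, config, grid)
        nib.save(nib.Nifti1Image(func, affine), out / f"{rec.subject_id}_func.nii.gz")
        nib.save(
            nib.Nifti1Image(struct, affine), out / f"{rec.subject_id}_anat.nii.gz"
        )
    logger.info("wrote cohort to %s (%d subjects)", out, len(df))
    return df
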