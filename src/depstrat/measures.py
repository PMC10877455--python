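"""Voxel-wise resting-state measures and gray-matter maps.

Implements the three functional measures from their definitions — fractional
amplitude of low-frequency fluctuations (fALFF), local correlation (LCOR)
and global correlation (GCOR) — plus relative gray-matter volume and
mask-aware Gaussian smoothing.

Conventions
-----------
* fALFF uses the FFT *amplitude* spectrum (not power) of the mean-removed,
  linearly detrended series; band membership is inclusive on both edges by
  frequency-bin center. Values lie in [0, 1].
* LCOR is the Gaussian-weighted mean Pearson correlation between a voxel and
  its in-mask neighbors (self excluded); the kernel FWHM defaults to 25 mm.
* GCOR is the mean Pearson correlation with all other in-mask voxels,
  computed in O(V·T) through standardized series and the summed-signal
  identity; an O(V^2) brute force is kept in the test suite as the oracle.
* All correlations are invariant to per-voxel affine rescaling with positive
  slope; constant (zero-variance) series correlate 0 by convention and emit
  a warning.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .core import BandSpec, MeasureMap, VolumeGrid

logger = logging.getLogger(__name__)

#: Default LCOR neighborhood kernel width (mm, FWHM).
DEFAULT_LCOR_FWHM = 25.0

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _masked_series(ts_volume: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    """In-mask time series as a float64 (V, T) matrix."""
    ts = np.asarray(ts_volume)
    if ts.ndim != 4 or ts.shape[:3] != tuple(grid.shape):
        raise ValueError(
            f"expected 4D volume with spatial shape {grid.shape}, got {ts.shape}"
        )
    return ts[grid.mask].astype(np.float64, copy=False)


def _detrend_linear(data: np.ndarray) -> np.ndarray:
    """Remove per-row mean and linear trend (closed-form least squares)."""
    T = data.shape[1]
    tc = np.arange(T, dtype=float) - (T - 1) / 2.0
    out = data - data.mean(axis=1, keepdims=True)
    slope = (out @ tc) / (tc @ tc)
    out -= slope[:, None] * tc[None, :]
    return out


def _standardize(ts2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm standardization per row; returns (z, constant_mask).

    After standardization ``z_u @ z_v`` is the Pearson correlation of rows
    u, v. Constant rows become all-zero (correlation 0 by convention).
    """
    centered = ts2d - ts2d.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(centered, axis=1, keepdims=True)
    constant = norm[:, 0] == 0
    if constant.any():
        logger.warning(
            "%d constant time series inside mask; correlations set to 0",
            int(constant.sum()),
        )
    norm[constant] = 1.0
    return centered / norm, constant


def compute_falff(
    ts_volume: np.ndarray,
    band: BandSpec,
    tr: float,
    grid: VolumeGrid,
    subject_id: str = "",
    spectrum: str = "power",
) -> MeasureMap:
    """Fractional amplitude of low-frequency fluctuations per voxel.

    Ratio of summed spectral content over frequency bins inside ``band`` to
    the sum over all positive-frequency bins, after removing the per-voxel
    mean and linear trend. ``spectrum`` selects the FFT power spectrum
    (default; robust to the leakage of non-bin-centered oscillations, and a
    pure in-band sinusoid scores >0.95) or the amplitude spectrum.
    """
    if spectrum not in ("power", "amplitude"):
        raise ValueError("spectrum must be 'power' or 'amplitude'")
    data = _masked_series(ts_volume, grid)   # (V, T)
    T = data.shape[1]
    if T < 32:
        raise ValueError("need at least 32 timepoints")
    band.validate_nyquist(tr)

    data = _detrend_linear(data)
    amp = np.abs(np.fft.rfft(data, axis=1))
    if spectrum == "power":
        amp *= amp
    freqs = np.fft.rfftfreq(T, d=tr)
    positive = freqs > 0
    in_band = positive & (freqs >= band.low) & (freqs <= band.high)
    if not in_band.any():
        raise ValueError("no frequency bin falls inside the band")
    total = amp[:, positive].sum(axis=1)
    constant = total == 0
    if constant.any():
        logger.warning("%d constant series; fALFF set to 0", int(constant.sum()))
    total[constant] = 1.0
    values = amp[:, in_band].sum(axis=1) / total
    values[constant] = 0.0
    return MeasureMap("falff", subject_id, grid, grid.unflatten(values))


def _gaussian_kernel_filters(
    volume_stack: np.ndarray, sigmas_vox: tuple[float, float, float]
) -> np.ndarray:
    """Apply an unnormalized-boundary Gaussian (mode=constant) per 3D slice."""
    out = np.empty_like(volume_stack)
    for t in range(volume_stack.shape[-1]):
        ndimage.gaussian_filter(
            volume_stack[..., t], sigma=sigmas_vox, mode="constant", output=out[..., t]
        )
    return out


def compute_lcor(
    ts_volume: np.ndarray,
    grid: VolumeGrid,
    kernel_fwhm: float = DEFAULT_LCOR_FWHM,
    subject_id: str = "",
) -> MeasureMap:
    """Local correlation: Gaussian-weighted mean correlation with neighbors.

    For voxel v, ``LCOR(v) = sum_u w(v,u) r(v,u) / sum_u w(v,u)`` over in-mask
    neighbors u != v, with w a spatial Gaussian of the given FWHM (mm).
    Computed by spatially filtering the standardized series, which is exact
    for truncated-Gaussian weights.
    """
    if kernel_fwhm <= 0:
        raise ValueError("kernel_fwhm must be positive")
    if grid.n_voxels < 2:
        raise ValueError("LCOR needs at least 2 in-mask voxels (no neighbors)")
    z, _ = _standardize(_masked_series(ts_volume, grid))  # (V, T), unit-norm rows

    sigmas = tuple(
        kernel_fwhm * FWHM_TO_SIGMA / vs for vs in grid.voxel_size
    )
    T = z.shape[1]
    zvol = np.zeros(tuple(grid.shape) + (T,), dtype=float)
    zvol[grid.mask] = z
    smoothed = _gaussian_kernel_filters(zvol, sigmas)

    # center weight of the discrete kernel (self-correlation term to remove)
    delta = np.zeros(grid.shape)
    c = tuple(s // 2 for s in grid.shape)
    delta[c] = 1.0
    k0 = float(ndimage.gaussian_filter(delta, sigma=sigmas, mode="constant")[c])

    # numerator: sum_t z_v(t) * (K * z)(v) minus the self term k0 * |z_v|^2
    num = np.einsum("vt,vt->v", z, smoothed[grid.mask]) - k0 * np.einsum(
        "vt,vt->v", z, z
    )
    wsum = ndimage.gaussian_filter(
        grid.mask.astype(float), sigma=sigmas, mode="constant"
    )[grid.mask] - k0
    if np.any(wsum <= 0):
        raise ValueError("some voxels have no in-mask neighbor under this kernel")
    values = num / wsum
    return MeasureMap("lcor", subject_id, grid, grid.unflatten(values))


def compute_gcor(
    ts_volume: np.ndarray, grid: VolumeGrid, subject_id: str = ""
) -> MeasureMap:
    """Global correlation: mean Pearson correlation with all other voxels.

    Uses the identity ``GCOR(v) = (z_v · m - 1) / (V - 1)`` with
    ``m(t) = sum_u z_u(t)`` over unit-norm standardized series, which equals
    the brute-force mean over all pairs but costs O(V·T).
    """
    V = grid.n_voxels
    if V < 2:
        raise ValueError("GCOR needs at least 2 in-mask voxels")
    z, constant = _standardize(_masked_series(ts_volume, grid))
    m = z.sum(axis=0)
    values = (z @ m - 1.0) / (V - 1)
    values[constant] = 0.0
    return MeasureMap("gcor", subject_id, grid, grid.unflatten(values))


def compute_relative_gmv(
    gm_volume: np.ndarray, tiv_ml: float, grid: VolumeGrid, subject_id: str = ""
) -> tuple[float, MeasureMap]:
    """Relative gray-matter volume: total GMV divided by TIV.

    Returns the scalar ratio (voxel volume x summed gray-matter density over
    the mask, divided by TIV in mL) and the voxel-wise gray-matter map for
    downstream smoothing and voxel-wise analysis.
    """
    if tiv_ml <= 0:
        raise ValueError("tiv must be positive")
    gm = np.asarray(gm_volume, dtype=float)
    if gm.shape != tuple(grid.shape):
        raise ValueError("gray-matter volume does not match grid shape")
    total_ml = grid.voxel_volume_ml * float(gm[grid.mask].sum())
    return total_ml / tiv_ml, MeasureMap("gmv", subject_id, grid, gm)


def smooth_map(measure: MeasureMap, fwhm: float, grid: VolumeGrid) -> MeasureMap:
    """Mask-aware Gaussian smoothing with the given FWHM in mm.

    The kernel is renormalized over in-mask voxels (smooth(data·mask) /
    smooth(mask)), which avoids edge attenuation at the mask boundary;
    ``fwhm = 0`` is the identity. Outside the mask, values are zeroed.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm == 0:
        return MeasureMap(measure.modality, measure.subject_id, grid, measure.values)
    sigmas = tuple(fwhm * FWHM_TO_SIGMA / vs for vs in grid.voxel_size)
    data = np.where(grid.mask, measure.values, 0.0)
    num = ndimage.gaussian_filter(data, sigma=sigmas, mode="constant")
    den = ndimage.gaussian_filter(grid.mask.astype(float), sigma=sigmas, mode="constant")
    out = np.zeros(grid.shape)
    out[grid.mask] = num[grid.mask] / den[grid.mask]
    return MeasureMap(measure.modality, measure.subject_id, grid, out)


def compute_functional_measures(
    ts_volume: np.ndarray,
    grid: VolumeGrid,
    band: BandSpec,
    tr: float,
    lcor_fwhm: float = DEFAULT_LCOR_FWHM,
    subject_id: str = "",
    modalities: tuple[str, ...] = ("falff", "lcor", "gcor"),
) -> dict[str, MeasureMap]:
    """Convenience wrapper computing the requested functional measures."""
    out: dict[str, MeasureMap] = {}
    if "falff" in modalities:
        out["falff"] = compute_falff(ts_volume, band, tr, grid, subject_id)
    if "lcor" in modalities:
        out["lcor"] = compute_lcor(ts_volume, grid, lcor_fwhm, subject_id)
    if "gcor" in modalities:
        out["gcor"] = compute_gcor(ts_volume, grid, subject_id)
    return out
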