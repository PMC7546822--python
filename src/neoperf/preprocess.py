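"""PASL series preprocessing: motion correction, smoothing, pairwise
subtraction, outlier rejection and temporal averaging.

The chain mirrors the common ASL-toolbox recipe: each volume of the 4D
series is rigidly aligned to the time-mean volume, optionally smoothed with
a spatial Gaussian, control−label difference images are formed per pair, and
acquisition time points whose spatial-mean difference deviates grossly from
the across-pair median are discarded before the temporal mean is taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "ASLSeries",
    "DifferenceSeries",
    "PreprocessConfig",
    "brain_mask_from_m0",
    "motion_correct",
    "smooth",
    "subtract_pairs",
    "clean_outliers",
    "mean_difference",
    "run_preprocess",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ASLSeries:
    """An ordered 4D label/control series.

    ``data`` has shape (n_volumes, nx, ny, nz); volumes alternate between
    label and control, the role of volume 0 given by ``order``
    ("label-first" or "control-first").
    """

    data: np.ndarray
    order: str = "label-first"
    tr_ms: float = 2600.0
    te_ms: float = 14.0
    voxel_size_mm: tuple[float, float, float] = (2.8, 2.8, 6.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                f"ASL series must be 4D (volumes, x, y, z); got {self.data.ndim}D"
            )
        if self.data.shape[0] % 2:
            raise ValueError(
                f"unpaired volume: series has {self.data.shape[0]} volumes "
                f"(volume index {self.data.shape[0] - 1} has no partner)"
            )
        if self.order not in ("label-first", "control-first"):
            raise ValueError(f"unknown volume order {self.order!r}")

    @property
    def n_pairs(self) -> int:
        return self.data.shape[0] // 2

    @property
    def pair_index(self) -> list[tuple[int, str]]:
        first, second = (
            ("label", "control") if self.order == "label-first" else ("control", "label")
        )
        return [(i // 2, first if i % 2 == 0 else second) for i in range(self.data.shape[0])]

    def labels(self) -> np.ndarray:
        offset = 0 if self.order == "label-first" else 1
        return self.data[offset::2]

    def controls(self) -> np.ndarray:
        offset = 1 if self.order == "label-first" else 0
        return self.data[offset::2]


@dataclass
class DifferenceSeries:
    """Per-pair control−label volumes with a retained flag per pair."""

    diffs: np.ndarray  # (n_pairs, nx, ny, nz)
    retained: np.ndarray  # (n_pairs,) bool

    def __post_init__(self) -> None:
        self.diffs = np.asarray(self.diffs, dtype=float)
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.retained.shape != (self.diffs.shape[0],):
            raise ValueError("retained flags must have one entry per pair")


@dataclass
class PreprocessConfig:
    """Knobs of the preprocessing chain.

    Defaults suit series that are already spatially aligned (as the
    synthetic generator emits): motion correction and spatial smoothing are
    off, outlier rejection at 2.5 robust SDs is on.  ``temporal_window``
    enables an optional moving average over the retained difference series.
    """

    smooth_fwhm_mm: float = 0.0
    outlier_k: float = 2.5
    motion_correct: bool = False
    max_iter: int = 200
    tol: float = 1e-4
    temporal_window: int = 1
    n_passes: int = 2  # register-to-mean passes

    def __post_init__(self) -> None:
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be >= 0")
        if not self.outlier_k > 0:
            raise ValueError("outlier_k must be > 0")
        if self.temporal_window < 1:
            raise ValueError("temporal_window must be >= 1")


def brain_mask_from_m0(m0_image: np.ndarray, fraction: float = 0.2) -> np.ndarray:
    """Brain mask: voxels above ``fraction`` of the robust (99th pct) max."""
    m0_image = np.asarray(m0_image, dtype=float)
    robust_max = float(np.percentile(m0_image, 99))
    return m0_image > fraction * robust_max


# ---------------------------------------------------------------------------
# rigid registration


def _rigid_resample(
    volume: np.ndarray, params6: np.ndarray, voxel_size: Iterable[float]
) -> np.ndarray:
    """Resample ``volume`` under a 6-DOF rigid transform (trilinear).

    ``params6`` = (tx, ty, tz) in mm then (rx, ry, rz) in radians; rotations
    are about the volume center.  The transform maps output coordinates to
    input coordinates, so the returned image is the input *moved by* the
    inverse of ``params6`` — i.e. applying the estimated parameters of a
    moved volume brings it back into alignment.
    """
    t_mm = np.asarray(params6[:3], dtype=float)
    rx, ry, rz = (float(a) for a in params6[3:])
    voxel = np.asarray(list(voxel_size), dtype=float)

    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    rot_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rot_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rot_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    rot = rot_z @ rot_y @ rot_x

    # voxel-space matrix: scale to mm, rotate, scale back
    matrix = np.diag(1.0 / voxel) @ rot @ np.diag(voxel)
    center = (np.asarray(volume.shape) - 1) / 2.0
    offset = center - matrix @ center - t_mm / voxel
    return ndimage.affine_transform(volume, matrix, offset=offset, order=1, mode="constant")


def _coarse_translation(volume: np.ndarray, reference: np.ndarray, max_shift: int = 4) -> np.ndarray:
    """Axis-wise integer-voxel search minimizing MSE to the reference."""
    shift = np.zeros(3, dtype=int)
    current = volume
    for axis in range(3):
        costs = []
        for s in range(-max_shift, max_shift + 1):
            rolled = np.roll(current, s, axis=axis)
            costs.append(np.mean((rolled - reference) ** 2))
        best = int(np.argmin(costs)) - max_shift
        shift[axis] = best
        current = np.roll(current, best, axis=axis)
    return shift


def _register_volume(
    volume: np.ndarray,
    reference: np.ndarray,
    voxel_size: Iterable[float],
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, bool]:
    voxel = np.asarray(list(voxel_size), dtype=float)
    coarse_vox = _coarse_translation(volume, reference)
    # np.roll moves content by +s; the aligning resample translation is +s*voxel
    x0 = np.concatenate([coarse_vox * voxel, np.zeros(3)])

    def cost(p: np.ndarray) -> float:
        moved = _rigid_resample(volume, p, voxel)
        return float(np.mean((moved - reference) ** 2))

    res = optimize.minimize(
        cost,
        x0,
        method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": tol, "fatol": tol * 1e-3},
    )
    return res.x, bool(res.success)


def motion_correct(
    series: ASLSeries, config: PreprocessConfig | None = None
) -> tuple[ASLSeries, list[dict]]:
    """Rigidly align every volume of the series to the time-mean volume.

    Two passes are used by default: after the first alignment the mean is
    recomputed and each volume re-registered, which removes the bias a
    moved volume exerts on the initial mean.  Returns the aligned series and
    a per-volume report of the cumulative estimated parameters.
    """
    config = config or PreprocessConfig()
    if series.data.shape[0] < 2:
        raise ValueError("motion correction needs at least 2 volumes")
    if not config.motion_correct:
        return series, [
            {"volume": i, "params_mm_rad": [0.0] * 6, "converged": True, "skipped": True}
            for i in range(series.data.shape[0])
        ]

    data = series.data.copy()
    cumulative = np.zeros((data.shape[0], 6))
    converged = np.ones(data.shape[0], dtype=bool)
    for _ in range(max(1, config.n_passes)):
        reference = data.mean(axis=0)
        for i in range(data.shape[0]):
            try:
                params, ok = _register_volume(
                    series.data[i], reference, series.voxel_size_mm, config.max_iter, config.tol
                )
            except Exception as exc:  # optimizer failure: pass through unaligned
                warnings.warn(
                    f"registration failed for volume {i}: {exc}", RuntimeWarning, stacklevel=2
                )
                converged[i] = False
                continue
            converged[i] &= ok
            cumulative[i] = params
            data[i] = _rigid_resample(series.data[i], params, series.voxel_size_mm)

    report = [
        {
            "volume": i,
            "params_mm_rad": [float(v) for v in cumulative[i]],
            "converged": bool(converged[i]),
            "skipped": False,
        }
        for i in range(data.shape[0])
    ]
    aligned = replace(series, data=data)
    return aligned, report


# ---------------------------------------------------------------------------
# smoothing / subtraction / cleaning


def smooth(obj, config: PreprocessConfig | None = None, voxel_size_mm=(2.8, 2.8, 6.0)):
    """Volume-wise spatial Gaussian smoothing; FWHM 0 is the identity.

    Accepts an :class:`ASLSeries`, a :class:`DifferenceSeries` or a bare 3D
    array and returns the same type.  For bare arrays and difference series
    the voxel size must be supplied (an ASL series carries its own).
    """
    config = config or PreprocessConfig()
    fwhm = config.smooth_fwhm_mm
    if isinstance(obj, ASLSeries):
        voxel_size_mm = obj.voxel_size_mm
    sigma_vox = [fwhm * _FWHM_TO_SIGMA / v for v in voxel_size_mm]
    if isinstance(obj, ASLSeries):
        if fwhm == 0:
            return replace(obj, data=obj.data.copy())
        data = np.stack([ndimage.gaussian_filter(v, sigma_vox) for v in obj.data])
        return replace(obj, data=data)
    if isinstance(obj, DifferenceSeries):
        if fwhm == 0:
            return DifferenceSeries(obj.diffs.copy(), obj.retained.copy())
        diffs = np.stack([ndimage.gaussian_filter(v, sigma_vox) for v in obj.diffs])
        return DifferenceSeries(diffs, obj.retained.copy())
    volume = np.asarray(obj, dtype=float)
    if fwhm == 0:
        return volume.copy()
    return ndimage.gaussian_filter(volume, sigma_vox)


def subtract_pairs(series: ASLSeries) -> DifferenceSeries:
    """Per-pair control−label difference volumes, all pairs retained."""
    diffs = series.controls() - series.labels()
    return DifferenceSeries(diffs=diffs, retained=np.ones(series.n_pairs, dtype=bool))


def _robust_sd(values: np.ndarray) -> tuple[float, float]:
    median = float(np.median(values))
    mad = float(np.median(np.abs(values - median)))
    return median, 1.4826 * mad


def clean_outliers(
    diffs: DifferenceSeries,
    config: PreprocessConfig | None = None,
    mask: np.ndarray | None = None,
) -> DifferenceSeries:
    """Flag acquisition time points whose spatial-mean difference is an outlier.

    The statistic is each pair's mean difference over the brain mask; pairs
    deviating from the across-pair median by more than ``outlier_k`` robust
    SDs (1.4826·MAD) are dropped.  Statistics are always computed from all
    pairs, so the operation is idempotent.  At least two pairs are kept.
    """
    config = config or PreprocessConfig()
    if diffs.diffs.shape[0] < 3:
        raise ValueError("outlier cleaning needs at least 3 pairs")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        stats = diffs.diffs[:, mask].mean(axis=1)
    else:
        stats = diffs.diffs.reshape(diffs.diffs.shape[0], -1).mean(axis=1)

    median, rsd = _robust_sd(stats)
    deviation = np.abs(stats - median)
    if rsd > 0 and np.isfinite(config.outlier_k):
        retained = deviation <= config.outlier_k * rsd
    else:
        retained = np.ones_like(deviation, dtype=bool)

    if retained.sum() < 2:  # over-flagging guard: keep the two closest to median
        retained = np.zeros_like(retained)
        retained[np.argsort(deviation)[:2]] = True
    return DifferenceSeries(diffs=diffs.diffs.copy(), retained=retained)


def _temporal_smooth(diffs: DifferenceSeries, window: int) -> DifferenceSeries:
    """Moving average over the retained difference series (odd window)."""
    if window <= 1:
        return diffs
    kept = np.flatnonzero(diffs.retained)
    data = diffs.diffs.copy()
    half = window // 2
    smoothed = data[kept].copy()
    for j, _ in enumerate(kept):
        lo, hi = max(0, j - half), min(len(kept), j + half + 1)
        smoothed[j] = data[kept[lo:hi]].mean(axis=0)
    data[kept] = smoothed
    return DifferenceSeries(diffs=data, retained=diffs.retained.copy())


def mean_difference(diffs: DifferenceSeries) -> np.ndarray:
    """Voxelwise mean over retained pairs only."""
    if not diffs.retained.any():
        raise ValueError("no retained pairs to average")
    return diffs.diffs[diffs.retained].mean(axis=0)


def run_preprocess(
    series: ASLSeries,
    config: PreprocessConfig | None = None,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, DifferenceSeries, dict]:
    """Full chain: motion correct, smooth, subtract, clean, average.

    Returns the mean difference image, the (cleaned) difference series and a
    machine-readable report.
    """
    config = config or PreprocessConfig()
    aligned, motion_report = motion_correct(series, config)
    smoothed = smooth(aligned, config)
    diffs = subtract_pairs(smoothed)
    diffs = clean_outliers(diffs, config, mask=mask)
    diffs = _temporal_smooth(diffs, config.temporal_window)
    mean = mean_difference(diffs)
    report = {
        "n_pairs": int(diffs.retained.size),
        "retained_pairs": int(diffs.retained.sum()),
        "flagged_pairs": [int(i) for i in np.flatnonzero(~diffs.retained)],
        "smooth_fwhm_mm": config.smooth_fwhm_mm,
        "motion": {
            "enabled": config.motion_correct,
            "n_volumes": len(motion_report),
            "n_failed": sum(1 for r in motion_report if not r["converged"]),
        },
    }
    return mean, diffs, report
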