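"""Single-compartment PASL perfusion quantification.

The cerebral blood flow of a voxel is obtained from the time-averaged
control−label difference signal ``dM`` with the single-compartment pulsed
ASL model

    CBF = 6000 * lambda * dM * exp(TI / T1b) / (2 * alpha * TI1 * M0b)

in ml/100 g/min, where ``lambda`` is the blood–brain partition coefficient,
``TI`` the inversion time, ``TI1`` the bolus duration, ``T1b`` the
longitudinal relaxation time of arterial blood, ``alpha`` the labeling
efficiency and the factor 6000 converts ml/g/s to ml/100 g/min.

``M0b``, the relaxed equilibrium magnetization of arterial blood, is
calibrated per tissue class from a proton-density image ``M0``:

    M0b_i = R_i * M0_i * exp(TE / T2_i - TE / T2b),   i in {CSF, WM, GM}

where ``M0_i`` is the mean M0 intensity over tissue ``i`` and ``R_i`` the
proton-density signal ratio of tissue ``i`` to blood.  Tissue classes come
from intensity thresholds on a T2-weighted image aligned to M0 space; in the
neonatal brain CSF is brightest on T2, unmyelinated white matter brighter
than gray matter.

All default parameter values are neonate calibrations at 3 T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "QuantParams",
    "TissueSegmentation",
    "M0bMap",
    "CBFMap",
    "TISSUES",
    "TISSUE_CODES",
    "segment_tissues",
    "compute_m0b",
    "compute_cbf",
    "delta_m_from_cbf",
    "cbf_scale_factor",
    "quantify_subject",
]

TISSUES = ("CSF", "WM", "GM")

#: integer codes used in :class:`TissueSegmentation.class_volume`
TISSUE_CODES: Mapping[str, int] = {"CSF": 1, "WM": 2, "GM": 3}
CLASS_BACKGROUND = 0


@dataclass(frozen=True)
class QuantParams:
    """Constants of the quantification model (neonatal 3 T defaults).

    Times are in milliseconds throughout; the model formula consumes them in
    the same unit they are stated in, which is the convention this package
    (and its synthetic-data inverse) adheres to.
    """

    lambda_blood: float = 1.10      # blood-brain partition coefficient, mL/g
    t1b_ms: float = 1825.0          # longitudinal relaxation of blood
    t2b_ms: float = 191.0           # transverse relaxation of blood
    alpha: float = 0.98             # PASL labeling efficiency
    ti1_ms: float = 700.0           # bolus duration
    ti_ms: float = 1800.0           # inversion time
    te_ms: float = 14.0             # echo time
    ratios: Mapping[str, float] = field(
        default_factory=lambda: {"CSF": 0.87, "WM": 1.19, "GM": 0.98}
    )
    t2_tissue_ms: Mapping[str, float] = field(
        default_factory=lambda: {"CSF": 250.0, "WM": 222.0, "GM": 143.0}
    )
    csf_threshold: float = 0.95     # normalized T2 intensity >= -> CSF
    wm_threshold: float = 0.75      # normalized T2 intensity >= -> WM
    unit_factor: float = 6000.0     # ml/g/s -> ml/100 g/min

    def __post_init__(self) -> None:
        for name in ("t1b_ms", "t2b_ms", "ti1_ms", "ti_ms", "lambda_blood"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.te_ms < 0:
            raise ValueError("te_ms must be nonnegative")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not self.csf_threshold > self.wm_threshold:
            raise ValueError("csf_threshold must exceed wm_threshold")
        for tissue in TISSUES:
            if tissue not in self.ratios or tissue not in self.t2_tissue_ms:
                raise ValueError(f"missing ratio/T2 for tissue {tissue!r}")
            if not self.t2_tissue_ms[tissue] > 0:
                raise ValueError(f"T2 of {tissue} must be positive")

    def replace(self, **updates) -> "QuantParams":
        from dataclasses import replace

        return replace(self, **updates)


@dataclass
class TissueSegmentation:
    """Voxelwise tissue labels: 0 background, 1 CSF, 2 WM, 3 GM."""

    class_volume: np.ndarray

    def tissue_mask(self, tissue: str) -> np.ndarray:
        return self.class_volume == TISSUE_CODES[tissue]


@dataclass
class M0bMap:
    """Equilibrium blood magnetization: per-tissue scalars and voxel map."""

    per_tissue: dict[str, float]
    m0_means: dict[str, float]
    volume: np.ndarray


@dataclass
class CBFMap:
    """A 3D perfusion volume in ml/100 g/min, NaN outside the brain mask."""

    volume: np.ndarray
    mask: np.ndarray
    n_undefined: int = 0
    provenance: dict = field(default_factory=dict)


def cbf_scale_factor(params: QuantParams) -> float:
    """Multiplier mapping ``dM / M0b`` to CBF in ml/100 g/min."""
    return (
        params.unit_factor
        * params.lambda_blood
        * np.exp(params.ti_ms / params.t1b_ms)
        / (2.0 * params.alpha * params.ti1_ms)
    )


def segment_tissues(
    t2_aligned: np.ndarray, mask: np.ndarray, params: QuantParams | None = None
) -> TissueSegmentation:
    """Threshold-segment a T2 image (in M0 space) into CSF, WM and GM.

    Intensities inside the mask are rescaled by their robust maximum (99th
    percentile); voxels at or above ``csf_threshold`` become CSF, those in
    ``[wm_threshold, csf_threshold)`` WM, the rest GM.  Both interval lower
    bounds are closed.  Voxels outside the mask are background.
    """
    params = params or QuantParams()
    t2_aligned = np.asarray(t2_aligned, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if t2_aligned.shape != mask.shape:
        raise ValueError(
            f"T2 grid {t2_aligned.shape} does not match mask grid {mask.shape}"
        )
    if not mask.any():
        raise ValueError("brain mask is empty; cannot segment")

    inside = t2_aligned[mask]
    robust_max = float(np.percentile(inside, 99))
    if robust_max <= 0 or np.ptp(inside) == 0:
        warnings.warn(
            "T2 image is constant inside the mask; assigning a single class",
            RuntimeWarning,
            stacklevel=2,
        )
        robust_max = robust_max if robust_max > 0 else 1.0

    norm = np.zeros_like(t2_aligned)
    norm[mask] = t2_aligned[mask] / robust_max

    classes = np.full(t2_aligned.shape, CLASS_BACKGROUND, dtype=np.int8)
    classes[mask] = TISSUE_CODES["GM"]
    classes[mask & (norm >= params.wm_threshold)] = TISSUE_CODES["WM"]
    classes[mask & (norm >= params.csf_threshold)] = TISSUE_CODES["CSF"]
    return TissueSegmentation(class_volume=classes)


def compute_m0b(
    m0_image: np.ndarray, seg: TissueSegmentation, params: QuantParams | None = None
) -> M0bMap:
    """Tissue-wise equilibrium blood magnetization from the M0 image.

    ``M0_i`` is the mean M0 intensity over each tissue class; an empty class
    falls back to the whole-brain mean (with a warning) so the voxel map is
    always defined inside the brain.
    """
    params = params or QuantParams()
    m0_image = np.asarray(m0_image, dtype=float)
    if m0_image.shape != seg.class_volume.shape:
        raise ValueError(
            f"M0 grid {m0_image.shape} does not match segmentation grid "
            f"{seg.class_volume.shape}"
        )
    brain = seg.class_volume != CLASS_BACKGROUND
    if not brain.any():
        raise ValueError("segmentation contains no brain voxels")
    whole_brain_mean = float(m0_image[brain].mean())

    per_tissue: dict[str, float] = {}
    m0_means: dict[str, float] = {}
    volume = np.zeros_like(m0_image)
    for tissue in TISSUES:
        sel = seg.tissue_mask(tissue)
        if sel.any():
            m0_i = float(m0_image[sel].mean())
        else:
            warnings.warn(
                f"no voxels classified as {tissue}; using whole-brain mean M0",
                RuntimeWarning,
                stacklevel=2,
            )
            m0_i = whole_brain_mean
        m0b_i = (
            params.ratios[tissue]
            * m0_i
            * np.exp(
                params.te_ms / params.t2_tissue_ms[tissue]
                - params.te_ms / params.t2b_ms
            )
        )
        m0_means[tissue] = m0_i
        per_tissue[tissue] = float(m0b_i)
        volume[sel] = m0b_i
    return M0bMap(per_tissue=per_tissue, m0_means=m0_means, volume=volume)


def compute_cbf(
    delta_m: np.ndarray,
    m0b: M0bMap | np.ndarray,
    params: QuantParams | None = None,
    mask: np.ndarray | None = None,
) -> CBFMap:
    """Voxelwise CBF from the mean difference signal and the M0b map.

    Voxels whose M0b falls below 1e-6 of the brain-median M0b are reported
    undefined (NaN) rather than clipped; their count is kept on the result.
    """
    params = params or QuantParams()
    delta_m = np.asarray(delta_m, dtype=float)
    m0b_volume = m0b.volume if isinstance(m0b, M0bMap) else np.asarray(m0b, float)
    if delta_m.shape != m0b_volume.shape:
        raise ValueError(
            f"dM grid {delta_m.shape} does not match M0b grid {m0b_volume.shape}"
        )
    if mask is None:
        mask = m0b_volume > 0
    mask = np.asarray(mask, dtype=bool)

    inside = m0b_volume[mask]
    if inside.size == 0:
        raise ValueError("brain mask is empty")
    guard = 1e-6 * float(np.median(inside))
    defined = mask & (m0b_volume > max(guard, 0.0))

    volume = np.full(delta_m.shape, np.nan)
    factor = cbf_scale_factor(params)
    volume[defined] = factor * delta_m[defined] / m0b_volume[defined]
    n_undefined = int(mask.sum() - defined.sum())
    return CBFMap(volume=volume, mask=mask, n_undefined=n_undefined)


def delta_m_from_cbf(
    cbf: np.ndarray | float,
    m0b: np.ndarray | float,
    params: QuantParams | None = None,
) -> np.ndarray | float:
    """Invert the kinetic model: the difference signal a given CBF produces.

    This is the exact inverse of :func:`compute_cbf` and is what the
    synthetic-data generator uses to plant recoverable ground truth.
    """
    params = params or QuantParams()
    return np.asarray(cbf) * np.asarray(m0b) / cbf_scale_factor(params)


def quantify_subject(
    asl,
    m0_image: np.ndarray,
    t2_image: np.ndarray,
    params: QuantParams | None = None,
    preprocess_config=None,
) -> CBFMap:
    """Full per-subject chain: preprocess -> segment -> M0b -> CBF.

    ``asl`` is an :class:`~neoperf.preprocess.ASLSeries`; M0 and T2 images
    must be co-registered with it.  Provenance (retained-pair count,
    undefined-voxel count, parameters) is attached to the returned map.
    """
    from . import preprocess as pp

    params = params or QuantParams()
    config = preprocess_config or pp.PreprocessConfig()

    mask = pp.brain_mask_from_m0(m0_image)
    mean_diff, diffs, report = pp.run_preprocess(asl, config, mask=mask)
    seg = segment_tissues(np.asarray(t2_image, float), mask, params)
    m0b = compute_m0b(np.asarray(m0_image, float), seg, params)
    cbf = compute_cbf(mean_diff, m0b, params, mask=mask)
    cbf.provenance = {
        "retained_pairs": int(np.count_nonzero(diffs.retained)),
        "total_pairs": int(diffs.retained.size),
        "n_undefined": cbf.n_undefined,
        "params": {
            "lambda_blood": params.lambda_blood,
            "t1b_ms": params.t1b_ms,
            "t2b_ms": params.t2b_ms,
            "alpha": params.alpha,
            "ti1_ms": params.ti1_ms,
            "ti_ms": params.ti_ms,
            "te_ms": params.te_ms,
        },
        "preprocess": report,
    }
    return cbf
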