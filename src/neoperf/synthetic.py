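"""Synthetic neonatal PASL cohorts with exactly recoverable ground truth.

No patient images are distributed with the study this pipeline emulates, so
this module generates complete, co-registered synthetic subjects: a toy
region atlas, per-subject label/control ASL series, proton-density (M0) and
T2-weighted images, demographics and Bayley-style outcome scores.

The signal model *inverts* the quantification model: for every voxel the
planted regional CBF is converted to the control−label difference signal
that the single-compartment formula maps back to it, using the same
tissue-wise M0b calibration the quantifier will compute.  With zero noise
the full pipeline therefore recovers the planted regional perfusion to
floating-point precision, which is what makes every downstream stage
testable without real data.

Covariate effects: age and sex modulate *gray-matter* perfusion only
(postnatal perfusion maturation is fastest in cortical/deep gray matter).
A global multiplicative covariate effect would be removed entirely by the
whole-brain normalization downstream and would be untestable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .preprocess import ASLSeries
from .quantify import QuantParams, delta_m_from_cbf

__all__ = [
    "SimulationConfig",
    "ToyAtlas",
    "SyntheticSubject",
    "make_atlas",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
]

# region id, name, tissue class, in-plane box edge, z extent, baseline CBF
# (ml/100 g/min).  Perfusion baselines follow neonatal contrast: deep gray
# and cerebellum highest, white matter lower, CSF spaces nominal-positive.
_REGION_SPECS: tuple[tuple[int, str, str, int, int, float], ...] = (
    (1, "lateral ventricle L", "CSF", 4, 4, 3.0),
    (2, "lateral ventricle R", "CSF", 4, 4, 3.0),
    (3, "anterior corona radiata", "WM", 4, 3, 10.0),
    (4, "superior fronto-occipital fasciculus", "WM", 4, 3, 9.0),
    (5, "posterior corona radiata", "WM", 5, 4, 10.0),
    (6, "corpus callosum", "WM", 5, 4, 9.0),
    (7, "caudate", "GM", 4, 3, 20.0),
    (8, "superior frontal gyrus", "GM", 4, 3, 18.0),
    (9, "precentral gyrus", "GM", 4, 3, 22.0),
    (10, "thalamus", "GM", 7, 5, 25.0),
    (11, "putamen", "GM", 6, 5, 22.0),
    (12, "cerebellum", "GM", 8, 5, 24.0),
    (13, "brainstem", "GM", 5, 5, 20.0),
    (14, "occipital cortex", "GM", 7, 5, 21.0),
)

#: regions carrying the default hypoperfusion effect in the HIE groups
DEFAULT_DEFICIT_REGIONS = (3, 4, 7, 8, 9)


def _default_region_effects() -> dict[int, dict[str, float]]:
    effects: dict[int, dict[str, float]] = {
        3: {"hie_neg": 0.75, "hie_pos": 0.75},
        4: {"hie_neg": 0.85, "hie_pos": 0.85},
        7: {"hie_neg": 0.80, "hie_pos": 0.80},
        8: {"hie_neg": 0.85, "hie_pos": 0.85},
        9: {"hie_neg": 0.80, "hie_pos": 1.15},  # sensorimotor hyperperfusion
        14: {"hie_pos": 1.30},                  # occipital hyperperfusion
    }
    return effects


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the acquisition and cohort the pipeline targets: a
    64-matrix-derived reduced grid, 2.8x2.8x6.0 mm voxels, 45 label/control
    pairs, and three groups of 18 controls, 40 HIE with normal conventional
    MRI ("hie_neg") and 15 HIE with abnormal conventional MRI ("hie_pos").
    """

    grid_shape: tuple[int, int, int] = (32, 32, 14)
    voxel_size_mm: tuple[float, float, float] = (2.8, 2.8, 6.0)
    n_pairs: int = 45
    groups: tuple[tuple[str, int], ...] = (("control", 18), ("hie_neg", 40), ("hie_pos", 15))
    region_effects: Mapping[int, Mapping[str, float]] = field(
        default_factory=_default_region_effects
    )
    age_slope: float = 0.005      # relative GM perfusion change per day
    sex_offset: float = 0.03      # relative GM perfusion offset for females
    noise_sd: float = 10.0        # additive Gaussian SD on signal intensities
    subject_cv: float = 0.15      # between-subject lognormal CV of regional CBF
    outlier_rate: float = 0.0     # probability a pair is an outlier
    outlier_scale: float = 5.0    # SD multiplier for outlier pairs
    outcome_weights: Mapping[int, float] = field(
        default_factory=lambda: {7: 30.0, 9: 25.0}
    )
    outcome_noise_sd: float = 10.0
    outcome_intercept: float = 100.0  # Bayley composite scale (mean ~100)
    age_range_days: tuple[float, float] = (1.0, 30.0)
    seed: int = 0
    # tissue baselines chosen so that robust-max T2 normalization puts
    # CSF >= 0.95, WM in [0.75, 0.95), GM < 0.75
    t2_intensity: Mapping[str, float] = field(
        default_factory=lambda: {"CSF": 1000.0, "WM": 850.0, "GM": 600.0}
    )
    m0_intensity: Mapping[str, float] = field(
        default_factory=lambda: {"CSF": 1200.0, "WM": 900.0, "GM": 1000.0}
    )
    quant_params: QuantParams = field(default_factory=QuantParams)

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be three positive counts")
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if any(n < 1 for _, n in self.groups):
            raise ValueError("every group needs at least one subject")
        if self.noise_sd < 0 or self.outcome_noise_sd < 0 or self.subject_cv < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must be in [0, 1)")
        for rid, per_group in self.region_effects.items():
            for g, eff in per_group.items():
                if not np.isfinite(eff) or eff <= 0:
                    raise ValueError(f"effect for region {rid}, group {g} must be finite > 0")

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.groups)


@dataclass
class ToyAtlas:
    """Integer-labeled region atlas (0 = background) with metadata."""

    label_volume: np.ndarray
    region_names: dict[int, str]
    tissue_class: dict[int, str]
    base_cbf: dict[int, float]
    voxel_size_mm: tuple[float, float, float] = (2.8, 2.8, 6.0)

    @property
    def region_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.region_names))

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.label_volume == region_id

    @property
    def brain_mask(self) -> np.ndarray:
        return self.label_volume > 0

    def voxel_counts(self) -> dict[int, int]:
        return {r: int((self.label_volume == r).sum()) for r in self.region_ids}


@dataclass
class SyntheticSubject:
    subject_id: str
    age_days: float
    sex: str  # "M" or "F"
    group: str
    asl: ASLSeries
    m0_image: np.ndarray
    t2_image: np.ndarray
    true_regional_cbf: dict[int, float]
    outcomes: dict[str, float] | None = None
    outlier_pairs: tuple[int, ...] = ()


def _pack_boxes(grid_shape: Sequence[int]) -> dict[int, tuple[slice, slice, slice]]:
    """Shelf-pack the region boxes into the grid with 1-voxel margins."""
    nx, ny, nz = grid_shape
    placements: dict[int, tuple[slice, slice, slice]] = {}
    x, y, row_height = 1, 1, 0
    for rid, _name, _tissue, edge, depth, _cbf in _REGION_SPECS:
        if depth > nz:
            raise ValueError(f"grid too small: region {rid} needs {depth} slices, grid has {nz}")
        if x + edge > nx - 1 + 1:  # allow to touch the far edge
            x = 1
            y += row_height + 1
            row_height = 0
        if x + edge > nx or y + edge > ny:
            raise ValueError(
                f"grid {tuple(grid_shape)} too small to host all regions (failed at region {rid})"
            )
        z0 = (nz - depth) // 2
        placements[rid] = (slice(x, x + edge), slice(y, y + edge), slice(z0, z0 + depth))
        x += edge + 1
        row_height = max(row_height, edge)
    return placements


def make_atlas(config: SimulationConfig) -> ToyAtlas:
    """Deterministic toy atlas of disjoint box regions covering all tissues."""
    labels = np.zeros(config.grid_shape, dtype=np.int16)
    placements = _pack_boxes(config.grid_shape)
    names, tissues, base = {}, {}, {}
    for rid, name, tissue, _edge, _depth, cbf in _REGION_SPECS:
        sl = placements[rid]
        labels[sl] = rid
        names[rid] = name
        tissues[rid] = tissue
        base[rid] = cbf
    return ToyAtlas(
        label_volume=labels,
        region_names=names,
        tissue_class=tissues,
        base_cbf=base,
        voxel_size_mm=config.voxel_size_mm,
    )


def _tissue_lut(atlas: ToyAtlas, values: Mapping[str, float]) -> np.ndarray:
    """Look-up array mapping region label -> a per-tissue value (0 for bg)."""
    lut = np.zeros(max(atlas.region_ids) + 1)
    for rid in atlas.region_ids:
        lut[rid] = values[atlas.tissue_class[rid]]
    return lut


def planted_regional_cbf(
    config: SimulationConfig,
    atlas: ToyAtlas,
    group: str,
    age_days: float,
    sex: str,
    jitter: Mapping[int, float] | None = None,
) -> dict[int, float]:
    """Ground-truth regional CBF for one subject (before any noise)."""
    out: dict[int, float] = {}
    for rid in atlas.region_ids:
        cbf = atlas.base_cbf[rid]
        cbf *= float(config.region_effects.get(rid, {}).get(group, 1.0))
        if atlas.tissue_class[rid] == "GM":
            cbf *= 1.0 + config.age_slope * age_days
            if sex == "F":
                cbf *= 1.0 + config.sex_offset
        if jitter is not None:
            cbf *= jitter[rid]
        if not np.isfinite(cbf) or cbf <= 0:
            raise ValueError(f"non-finite or nonpositive planted CBF for region {rid}")
        out[rid] = float(cbf)
    return out


def _whole_brain_mean(atlas: ToyAtlas, regional: Mapping[int, float]) -> float:
    counts = atlas.voxel_counts()
    total = sum(counts.values())
    return sum(counts[r] * regional[r] for r in atlas.region_ids) / total


def simulate_subject(
    config: SimulationConfig,
    atlas: ToyAtlas,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "sub-000",
    age_days: float | None = None,
    sex: str | None = None,
) -> SyntheticSubject:
    """Generate one subject's co-registered images, truth and outcomes."""
    if group not in config.group_names:
        raise ValueError(f"unknown group {group!r}; config defines {config.group_names}")
    if age_days is None:
        age_days = float(rng.uniform(*config.age_range_days))
    if sex is None:
        sex = "F" if rng.random() < 0.5 else "M"

    if config.subject_cv > 0:
        sigma = np.sqrt(np.log(1.0 + config.subject_cv**2))
        draws = rng.normal(size=len(atlas.region_ids))
        jitter = {
            rid: float(np.exp(sigma * d - 0.5 * sigma**2))
            for rid, d in zip(atlas.region_ids, draws)
        }
    else:
        rng.normal(size=len(atlas.region_ids))  # keep stream layout stable
        jitter = {rid: 1.0 for rid in atlas.region_ids}

    regional = planted_regional_cbf(config, atlas, group, age_days, sex, jitter)

    labels_vol = atlas.label_volume
    brain = atlas.brain_mask
    params = config.quant_params

    # noiseless anatomical baselines; the quantifier's M0b calibration on
    # these exact intensities reproduces the M0b used to invert the model
    t2_clean = _tissue_lut(atlas, config.t2_intensity)[labels_vol]
    m0_clean = _tissue_lut(atlas, config.m0_intensity)[labels_vol]

    m0b_per_tissue = {
        t: params.ratios[t]
        * config.m0_intensity[t]
        * np.exp(params.te_ms / params.t2_tissue_ms[t] - params.te_ms / params.t2b_ms)
        for t in ("CSF", "WM", "GM")
    }
    m0b_vol = _tissue_lut(atlas, m0b_per_tissue)[labels_vol]

    cbf_lut = np.zeros(max(atlas.region_ids) + 1)
    for rid, value in regional.items():
        cbf_lut[rid] = value
    cbf_vol = cbf_lut[labels_vol]
    delta_m = np.asarray(delta_m_from_cbf(cbf_vol, m0b_vol, params))
    delta_m[~brain] = 0.0

    n_pairs = config.n_pairs
    outlier = rng.random(n_pairs) < config.outlier_rate
    nx, ny, nz = config.grid_shape
    data = np.empty((2 * n_pairs, nx, ny, nz))
    data[0::2] = m0_clean - delta_m
    data[1::2] = m0_clean
    if config.noise_sd > 0:
        noise = rng.normal(size=(2 * n_pairs, nx, ny, nz)) * brain
        sd_label = np.where(outlier, config.noise_sd * config.outlier_scale, config.noise_sd)
        data[0::2] += sd_label[:, None, None, None] * noise[0::2]
        data[1::2] += config.noise_sd * noise[1::2]
        t2_img = t2_clean + config.noise_sd * rng.normal(size=(nx, ny, nz)) * brain
        m0_img = m0_clean + config.noise_sd * rng.normal(size=(nx, ny, nz)) * brain
    else:
        t2_img = t2_clean.copy()
        m0_img = m0_clean.copy()

    wb = _whole_brain_mean(atlas, regional)
    normalized = {rid: regional[rid] / wb for rid in atlas.region_ids}
    score_noise = rng.normal(size=3)
    outcomes = {}
    for k, name in enumerate(("cognitive", "language", "motor")):
        signal = sum(w * normalized[rid] for rid, w in config.outcome_weights.items())
        outcomes[name] = float(
            config.outcome_intercept + signal + config.outcome_noise_sd * score_noise[k]
        )

    asl = ASLSeries(
        data=data,
        order="label-first",
        te_ms=params.te_ms,
        voxel_size_mm=config.voxel_size_mm,
    )
    return SyntheticSubject(
        subject_id=subject_id,
        age_days=age_days,
        sex=sex,
        group=group,
        asl=asl,
        m0_image=m0_img,
        t2_image=t2_img,
        true_regional_cbf=regional,
        outcomes=outcomes,
        outlier_pairs=tuple(int(i) for i in np.flatnonzero(outlier)),
    )


def simulate_cohort(
    config: SimulationConfig, atlas: ToyAtlas | None = None
) -> tuple[list[SyntheticSubject], ToyAtlas]:
    """Generate the full cohort across groups, deterministically from the seed."""
    atlas = atlas or make_atlas(config)
    root = np.random.default_rng(config.seed)
    n_total = sum(n for _, n in config.groups)
    streams = root.spawn(n_total)
    subjects: list[SyntheticSubject] = []
    idx = 0
    for group, n in config.groups:
        for _ in range(n):
            rng = streams[idx]
            subject = simulate_subject(
                config, atlas, group, rng, subject_id=f"sub-{idx + 1:03d}"
            )
            subjects.append(subject)
            idx += 1
    return subjects, atlas


def write_cohort(
    subjects: Sequence[SyntheticSubject],
    atlas: ToyAtlas,
    out_dir: str | Path,
    config: SimulationConfig | None = None,
    write_images: bool = True,
) -> dict[str, Path]:
    """Write the cohort to disk in the pipeline's on-disk layout.

    Per subject: ``asl_4d.nii.gz`` (volumes ordered label, control, ...),
    ``m0.nii.gz``, ``t2.nii.gz``.  Cohort level: ``atlas.nii.gz``,
    ``regions.tsv``, ``cohort.csv``, ``outcomes.csv`` and ``truth.json``.
    """
    import pandas as pd

    from .io import write_image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    voxel = atlas.voxel_size_mm
    affine = np.diag([voxel[0], voxel[1], voxel[2], 1.0])

    artifacts: dict[str, Path] = {}
    if write_images:
        for s in subjects:
            sdir = out_dir / s.subject_id
            sdir.mkdir(exist_ok=True)
            asl_img = np.moveaxis(s.asl.data, 0, -1)  # NIfTI wants time last
            write_image(asl_img, affine, sdir / "asl_4d.nii.gz",
                        description=f"order={s.asl.order}")
            write_image(s.m0_image, affine, sdir / "m0.nii.gz")
            write_image(s.t2_image, affine, sdir / "t2.nii.gz")
        write_image(atlas.label_volume.astype(np.int16), affine, out_dir / "atlas.nii.gz")
        artifacts["atlas"] = out_dir / "atlas.nii.gz"

    regions = pd.DataFrame(
        {
            "region_id": list(atlas.region_ids),
            "name": [atlas.region_names[r] for r in atlas.region_ids],
            "tissue_class": [atlas.tissue_class[r] for r in atlas.region_ids],
        }
    )
    regions.to_csv(out_dir / "regions.tsv", sep="\t", index=False)
    artifacts["regions"] = out_dir / "regions.tsv"

    cohort = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "age_days": [s.age_days for s in subjects],
            "sex": [s.sex for s in subjects],
            "group": [s.group for s in subjects],
        }
    )
    cohort.to_csv(out_dir / "cohort.csv", index=False)
    artifacts["cohort"] = out_dir / "cohort.csv"

    outcomes = pd.DataFrame(
        [
            {"subject_id": s.subject_id, **s.outcomes}
            for s in subjects
            if s.outcomes is not None
        ]
    )
    outcomes.to_csv(out_dir / "outcomes.csv", index=False)
    artifacts["outcomes"] = out_dir / "outcomes.csv"

    truth = {
        "regional_cbf": {
            s.subject_id: {str(r): v for r, v in s.true_regional_cbf.items()}
            for s in subjects
        },
        "outcome_weights": (
            {str(r): w for r, w in config.outcome_weights.items()} if config else None
        ),
        "outlier_pairs": {s.subject_id: list(s.outlier_pairs) for s in subjects},
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    artifacts["truth"] = out_dir / "truth.json"
    return artifacts
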