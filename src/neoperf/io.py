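"""Shared I/O: NIfTI images, tables, configuration and provenance.

All images travel as NIfTI-1 (plain or gzipped) via nibabel, preserving the
affine; 4D ASL series carry their label/control volume ordering in the
header description field so the reader can recover it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .preprocess import ASLSeries, PreprocessConfig
from .quantify import QuantParams
from .synthetic import SimulationConfig, ToyAtlas

__all__ = [
    "read_image",
    "write_image",
    "read_asl_series",
    "read_atlas",
    "check_same_grid",
    "PipelineConfig",
    "make_provenance",
    "file_digest",
]


def read_image(path: str | Path) -> tuple[np.ndarray, np.ndarray, nib.Nifti1Header]:
    """Load a NIfTI image; returns (data, affine, header)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    return data, img.affine, img.header


def write_image(
    data: np.ndarray,
    affine: np.ndarray,
    path: str | Path,
    description: str = "",
) -> Path:
    """Write a NIfTI-1 image, preserving the affine exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float))
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))
    return path


def check_same_grid(name_a: str, shape_a, name_b: str, shape_b) -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise ValueError(
            f"grid mismatch: {name_a} has shape {tuple(shape_a)} but "
            f"{name_b} has shape {tuple(shape_b)}"
        )


def read_asl_series(path: str | Path, order: str | None = None) -> ASLSeries:
    """Read a 4D ASL NIfTI into an :class:`ASLSeries`.

    The volume order ("label-first" / "control-first") is taken from the
    header description when not given explicitly; label-first is the
    package convention and final fallback.
    """
    data, affine, header = read_image(path)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D ASL series at {path}, got {data.ndim}D")
    if order is None:
        descrip = header["descrip"].tobytes().decode(errors="ignore").strip("\x00")
        if "order=control-first" in descrip:
            order = "control-first"
        else:
            order = "label-first"
    voxel = tuple(float(v) for v in header.get_zooms()[:3])
    return ASLSeries(
        data=np.moveaxis(data, -1, 0), order=order, voxel_size_mm=voxel
    )


def read_atlas(nifti_path: str | Path, regions_tsv: str | Path) -> ToyAtlas:
    """Read an integer-label atlas plus its region-name table."""
    data, _affine, header = read_image(nifti_path)
    if data.ndim != 3:
        raise ValueError(f"atlas must be 3D, got {data.ndim}D")
    labels = np.rint(data).astype(np.int16)
    regions = pd.read_csv(regions_tsv, sep="\t")
    for col in ("region_id", "name", "tissue_class"):
        if col not in regions.columns:
            raise ValueError(f"regions table lacks column {col!r}")
    names = dict(zip(regions["region_id"].astype(int), regions["name"]))
    tissues = dict(zip(regions["region_id"].astype(int), regions["tissue_class"]))
    present = set(int(v) for v in np.unique(labels)) - {0}
    unnamed = present - set(names)
    if unnamed:
        raise ValueError(f"atlas labels without names in regions table: {sorted(unnamed)}")
    voxel = tuple(float(v) for v in header.get_zooms()[:3])
    return ToyAtlas(
        label_volume=labels,
        region_names=names,
        tissue_class=tissues,
        base_cbf={r: float("nan") for r in names},
        voxel_size_mm=voxel,
    )


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def make_provenance(config: dict, inputs: dict[str, str | Path] | None = None) -> dict:
    """Provenance record attached to every pipeline artifact set."""
    from . import __version__

    record = {
        "tool": "neoperf",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "input_digests": {},
    }
    for name, path in (inputs or {}).items():
        record["input_digests"][name] = file_digest(path)
    return record


@dataclass
class PipelineConfig:
    """Resolved configuration of the end-to-end pipeline run."""

    out_dir: str = "neoperf_out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    quant: QuantParams = field(default_factory=QuantParams)
    n_permutations: int = 2000
    alpha: float = 0.05
    adjust_covariates: bool = True
    k_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    cv_unit: str = "subject"
    seed: int = 0
    write_images: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "simulation" in kwargs and isinstance(kwargs["simulation"], dict):
            sim = dict(kwargs["simulation"])
            for key in ("grid_shape", "voxel_size_mm", "age_range_days"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "groups" in sim:
                sim["groups"] = tuple((str(g), int(n)) for g, n in sim["groups"])
            if "region_effects" in sim:
                sim["region_effects"] = {
                    int(r): {str(g): float(e) for g, e in eff.items()}
                    for r, eff in sim["region_effects"].items()
                }
            if "outcome_weights" in sim:
                sim["outcome_weights"] = {
                    int(r): float(w) for r, w in sim["outcome_weights"].items()
                }
            if "quant_params" in sim and isinstance(sim["quant_params"], dict):
                sim["quant_params"] = QuantParams(**sim["quant_params"])
            kwargs["simulation"] = SimulationConfig(**sim)
        if "preprocess" in kwargs and isinstance(kwargs["preprocess"], dict):
            kwargs["preprocess"] = PreprocessConfig(**kwargs["preprocess"])
        if "quant" in kwargs and isinstance(kwargs["quant"], dict):
            kwargs["quant"] = QuantParams(**kwargs["quant"])
        if "k_grid" in kwargs:
            kwargs["k_grid"] = tuple(int(k) for k in kwargs["k_grid"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = asdict(self)
        return json.loads(json.dumps(out, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return str(obj)
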