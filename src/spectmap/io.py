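"""File I/O: NIfTI images, CSV sinograms/profiles, YAML experiment specs."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import PhantomSpec, Primitive
from .projector import DetectorResponse, Geometry, Sinogram
from .priors import PotentialSpec
from .recon import ReconConfig


def save_nifti_2d(path: str | Path, arr: np.ndarray, pixel_size_cm: float) -> None:
    """Write a 2D array as a NIfTI image with isotropic pixel size (mm)."""
    affine = np.diag([pixel_size_cm * 10.0, pixel_size_cm * 10.0, 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(arr)[..., None], affine), str(path))


def load_nifti_2d(path: str | Path) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).dataobj)
    return np.squeeze(data)


def save_sinogram_csv(path: str | Path, sino: Sinogram) -> None:
    df = pd.DataFrame(sino.values)
    df.index.name = "view"
    df.to_csv(path)


def load_sinogram_csv(path: str | Path, is_counts: bool = True) -> Sinogram:
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy()
    if is_counts:
        values = np.round(values).astype(np.int64)
    return Sinogram(values, is_counts=is_counts)


def save_provenance(path: str | Path, result) -> None:
    """JSON sidecar with the settings that determine an experiment's output."""
    spec = result.spec
    doc = {
        "seed": spec.seed,
        "total_counts": spec.total_counts,
        "count_scale": result.count_scale,
        "grid_side": spec.phantom.grid_side,
        "pixel_size_cm": spec.phantom.pixel_size_cm,
        "n_views": spec.geometry.n_views,
        "angular_range_deg": spec.geometry.angular_range_deg,
        "algorithms": {
            name: {
                "algorithm": cfg.algorithm,
                "n_iterations": cfg.n_iterations,
                "n_subsets": cfg.n_subsets,
                "beta": cfg.beta,
                "gamma": cfg.gamma,
                "checkpoints": list(cfg.checkpoints),
            }
            for name, cfg in spec.configs.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def phantom_spec_to_yaml(spec: PhantomSpec, path: str | Path) -> None:
    doc = {
        "grid_side": spec.grid_side,
        "pixel_size_cm": spec.pixel_size_cm,
        "tumor_to_liver_ratio": spec.tumor_to_liver_ratio,
        "attenuation_inside_body": spec.attenuation_inside_body,
        "primitives": [asdict(p) for p in spec.primitives],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def phantom_spec_from_yaml(path: str | Path) -> PhantomSpec:
    doc = yaml.safe_load(Path(path).read_text())
    prims = tuple(
        Primitive(
            shape=p["shape"],
            center=tuple(p["center"]),
            semi_axes=tuple(p["semi_axes"]),
            angle_deg=p.get("angle_deg", 0.0),
            activity=p.get("activity", 0.0),
            label=p.get("label", "body"),
        )
        for p in doc.get("primitives", [])
    )
    return PhantomSpec(
        grid_side=doc.get("grid_side", 128),
        pixel_size_cm=doc.get("pixel_size_cm", 0.4),
        primitives=prims,
        tumor_to_liver_ratio=doc.get("tumor_to_liver_ratio", 1.6),
        attenuation_inside_body=doc.get("attenuation_inside_body", 0.15),
    )


def recon_config_from_dict(doc: dict) -> ReconConfig:
    """Build a ReconConfig from a plain dict (YAML-friendly subset).

    The adaptive local-regularization block is not expressible here because
    it needs an organ mask image; use the library API for that.
    """
    kwargs = dict(doc)
    if "potential" in kwargs:
        kwargs["potential"] = PotentialSpec(**kwargs["potential"])
    if "checkpoints" in kwargs:
        kwargs["checkpoints"] = tuple(kwargs["checkpoints"])
    return ReconConfig(**kwargs)


def geometry_from_dict(doc: dict) -> Geometry:
    return Geometry(**doc)


def response_from_dict(doc: dict | None) -> DetectorResponse | None:
    if doc is None:
        return None
    return DetectorResponse(**doc)
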