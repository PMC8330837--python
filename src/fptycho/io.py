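"""File formats: measurement stacks, reconstruction results, manifests.

Two stack containers are supported:

* multi-page float32 TIFF + a YAML sidecar (``<stem>.yaml``) holding the
  system config, illumination ordering and any embedded ground truth
  (ground-truth object stored as an amplitude/phase TIFF pair
  ``<stem>_truth.tif``);
* a single HDF5 file with groups ``images``, ``illumination``,
  ``ground_truth`` and the config as root attributes.

Reconstruction results are written as amplitude/phase TIFFs, a complex
HDF5 object, a coefficients CSV, a loss-history CSV and a YAML run
manifest sufficient to reproduce the run.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .fields import ComplexField
from .optics import IlluminationSet, SystemConfig
from .reconstruct import ReconResult
from .simulate import GroundTruth, MeasurementStack
from .zernike import CoeffVector

__all__ = ["save_stack", "load_stack", "save_result", "write_manifest",
           "read_manifest"]


def _illum_to_dict(illum: IlluminationSet) -> dict:
    return {"na_shifts": illum.na_shifts.tolist(),
            "pixel_shifts": illum.pixel_shifts.tolist(),
            "ordering": [list(rc) for rc in illum.ordering]}


def _illum_from_dict(d: dict) -> IlluminationSet:
    return IlluminationSet(na_shifts=np.array(d["na_shifts"]),
                           pixel_shifts=np.array(d["pixel_shifts"]),
                           ordering=[tuple(rc) for rc in d["ordering"]])


def _coeffs_to_dict(c: CoeffVector) -> dict:
    return {"values": c.values.tolist(),
            "index_scheme": [list(nm) for nm in c.index_scheme]}


def _coeffs_from_dict(d: dict) -> CoeffVector:
    return CoeffVector(np.array(d["values"]),
                       [tuple(nm) for nm in d["index_scheme"]])


def save_stack(stack: MeasurementStack, path: str | Path) -> None:
    """Write a stack as ``.tif``/``.tiff`` (+ YAML sidecar) or ``.h5``."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _save_stack_h5(stack, path)
    elif path.suffix in (".tif", ".tiff"):
        _save_stack_tiff(stack, path)
    else:
        raise ValueError(f"unsupported stack container {path.suffix!r}")


def load_stack(path: str | Path) -> MeasurementStack:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _load_stack_h5(path)
    if path.suffix in (".tif", ".tiff"):
        return _load_stack_tiff(path)
    raise ValueError(f"unsupported stack container {path.suffix!r}")


def _save_stack_tiff(stack: MeasurementStack, path: Path) -> None:
    tifffile.imwrite(path, stack.images.astype(np.float32))
    side = {"config": stack.config.to_dict(),
            "illumination": _illum_to_dict(stack.illumination)}
    if stack.ground_truth is not None:
        truth_path = path.with_name(path.stem + "_truth.tif")
        obj = stack.ground_truth.object.values
        tifffile.imwrite(truth_path, np.stack(
            [np.abs(obj), np.angle(obj)]).astype(np.float32))
        side["ground_truth"] = {
            "object_tif": truth_path.name,
            "coeffs": _coeffs_to_dict(stack.ground_truth.coeffs)}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(side, sort_keys=False))


def _load_stack_tiff(path: Path) -> MeasurementStack:
    sidecar = path.with_suffix(".yaml")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar} for stack {path}")
    side = yaml.safe_load(sidecar.read_text())
    images = np.asarray(tifffile.imread(path), dtype=float)
    cfg = SystemConfig(**side["config"])
    illum = _illum_from_dict(side["illumination"])
    truth = None
    if "ground_truth" in side:
        gt = side["ground_truth"]
        pages = np.asarray(tifffile.imread(path.with_name(gt["object_tif"])),
                           dtype=float)
        obj = ComplexField(pages[0] * np.exp(1j * pages[1]),
                           plane="object-spatial",
                           pitch_um=cfg.highres_pixel_um)
        truth = GroundTruth(obj, _coeffs_from_dict(gt["coeffs"]))
    return MeasurementStack(images=images, illumination=illum, config=cfg,
                            ground_truth=truth)


def _save_stack_h5(stack: MeasurementStack, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=stack.images.astype(np.float32))
        g = f.create_group("illumination")
        g.create_dataset("na_shifts", data=stack.illumination.na_shifts)
        g.create_dataset("pixel_shifts", data=stack.illumination.pixel_shifts)
        g.create_dataset("ordering", data=np.array(stack.illumination.ordering))
        for k, v in stack.config.to_dict().items():
            f.attrs[k] = v
        if stack.ground_truth is not None:
            t = f.create_group("ground_truth")
            t.create_dataset("object", data=stack.ground_truth.object.values)
            t.create_dataset("coeff_values",
                             data=stack.ground_truth.coeffs.values)
            t.create_dataset("coeff_nm",
                             data=np.array(stack.ground_truth.coeffs.index_scheme))


def _load_stack_h5(path: Path) -> MeasurementStack:
    with h5py.File(path, "r") as f:
        cfg = SystemConfig(**{k: (int(v) if isinstance(v, np.integer) else
                                  float(v) if isinstance(v, np.floating) else v)
                              for k, v in f.attrs.items()})
        illum = IlluminationSet(
            na_shifts=f["illumination/na_shifts"][()],
            pixel_shifts=f["illumination/pixel_shifts"][()],
            ordering=[tuple(int(x) for x in rc)
                      for rc in f["illumination/ordering"][()]])
        images = f["images"][()].astype(float)
        truth = None
        if "ground_truth" in f:
            obj = ComplexField(f["ground_truth/object"][()],
                               plane="object-spatial",
                               pitch_um=cfg.highres_pixel_um)
            coeffs = CoeffVector(
                f["ground_truth/coeff_values"][()],
                [tuple(int(x) for x in nm)
                 for nm in f["ground_truth/coeff_nm"][()]])
            truth = GroundTruth(obj, coeffs)
    return MeasurementStack(images=images, illumination=illum, config=cfg,
                            ground_truth=truth)


def save_result(result: ReconResult, out_dir: str | Path) -> dict:
    """Write a reconstruction result directory; returns the file layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    obj = result.object.values
    layout = {"amplitude_tif": "amplitude.tif", "phase_tif": "phase.tif",
              "object_h5": "object.h5", "loss_csv": "loss.csv"}
    tifffile.imwrite(out / layout["amplitude_tif"],
                     np.abs(obj).astype(np.float32))
    tifffile.imwrite(out / layout["phase_tif"],
                     np.angle(obj).astype(np.float32))
    with h5py.File(out / layout["object_h5"], "w") as f:
        f.create_dataset("object", data=obj)
        f.create_dataset("pupil", data=result.pupil_complex)
    pd.DataFrame(result.loss_history).to_csv(out / layout["loss_csv"],
                                             index=False)
    if result.coeffs is not None:
        layout["coeffs_csv"] = "coeffs.csv"
        result.coeffs.to_csv(out / layout["coeffs_csv"])
    return layout


def write_manifest(out_dir: str | Path, manifest: dict) -> None:
    Path(out_dir, "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=False))


def read_manifest(out_dir: str | Path) -> dict:
    return yaml.safe_load(Path(out_dir, "manifest.yaml").read_text())
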