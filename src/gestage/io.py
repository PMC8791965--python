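"""Readers and writers: image stacks (NIfTI / DICOM series / PNG or JPG
stacks), cohort manifests, and YAML run configuration.

The canonical age unit in every file is days (column ``age_days``);
week-valued inputs are converted on read. Intensities are floats in
memory; exports quantize to 16-bit (NIfTI) or 8-bit (PNG).
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
import yaml
from PIL import Image
from pydicom.dataset import FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .phantom import PLANES, PhantomSubject

__all__ = ["read_volume", "write_nifti_stack", "write_png_stack",
           "write_dicom_series", "export_cohort", "read_manifest",
           "write_manifest", "load_config", "save_config", "config_hash"]

_NATURAL = re.compile(r"(\d+)")


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok.lower()
            for tok in _NATURAL.split(name)]


# -- volume readers --------------------------------------------------------

def read_volume(path) -> np.ndarray:
    """Read an image stack as (slices, height, width) floats.

    Accepts a NIfTI file (slices along the third axis), a directory of
    DICOM files (ordered by slice position, falling back to instance
    number), or a directory of numbered PNG/JPG slices (natural filename
    order).
    """
    path = Path(path)
    if path.is_file() and path.suffix in (".nii", ".gz") or \
            str(path).endswith(".nii.gz"):
        vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
        if vol.ndim != 3:
            raise ValueError(f"{path}: expected a 3-D NIfTI volume")
        return np.transpose(vol, (2, 0, 1))
    if path.is_dir():
        dicoms = sorted(path.glob("*.dcm"))
        if dicoms:
            return _read_dicom_series(path, dicoms)
        images = sorted(
            [p for p in path.iterdir()
             if p.suffix.lower() in (".png", ".jpg", ".jpeg")],
            key=lambda p: _natural_key(p.name))
        if images:
            slices = [np.asarray(Image.open(p).convert("F"), dtype=np.float64)
                      for p in images]
            shapes = {s.shape for s in slices}
            if len(shapes) != 1:
                raise ValueError(f"{path}: slices have inconsistent shapes")
            return np.stack(slices)
        raise ValueError(f"{path}: no DICOM or PNG/JPG slices found")
    raise ValueError(f"{path}: not a NIfTI file or a slice directory")


def _read_dicom_series(path: Path, files) -> np.ndarray:
    datasets = [pydicom.dcmread(str(f)) for f in files]
    series = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(series) > 1:
        raise ValueError(f"{path}: directory mixes {len(series)} DICOM series")

    def position(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=position)
    slices = [ds.pixel_array.astype(np.float64) for ds in datasets]
    if len({s.shape for s in slices}) != 1:
        raise ValueError(f"{path}: DICOM slices have inconsistent shapes")
    return np.stack(slices)


# -- writers ---------------------------------------------------------------

def write_nifti_stack(stack: np.ndarray, path) -> None:
    """Quantize a [0, 1] float stack to 16 bit and save as NIfTI
    (slices become the volume's third axis)."""
    stack = np.asarray(stack, dtype=np.float64)
    data = np.round(np.clip(stack, 0, 1) * 65535).astype(np.uint16)
    vol = np.transpose(data, (1, 2, 0))
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def write_png_stack(stack: np.ndarray, directory) -> list[Path]:
    """Quantize to 8 bit and write numbered PNG slices (s01.png, ...)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, sl in enumerate(np.asarray(stack, dtype=np.float64)):
        img = np.round(np.clip(sl, 0, 1) * 255).astype(np.uint8)
        p = directory / f"s{i + 1:02d}.png"
        Image.fromarray(img, mode="L").save(p)
        paths.append(p)
    return paths


def write_dicom_series(stack: np.ndarray, directory,
                       shuffle_names: bool = False,
                       seed: int = 0) -> list[Path]:
    """Write a [0, 1] float stack as a minimal 16-bit DICOM series with
    slice-position tags. ``shuffle_names`` stores files under permuted
    names so readers must sort by position, not filename."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = np.asarray(stack, dtype=np.float64)
    series_uid = generate_uid()
    n = stack.shape[0]
    order = np.arange(n)
    if shuffle_names:
        order = np.random.default_rng(seed).permutation(n)
    paths = []
    for slice_idx, name_idx in enumerate(order):
        data = np.round(np.clip(stack[slice_idx], 0, 1) * 65535
                        ).astype(np.uint16)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = pydicom.Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "MR"
        ds.InstanceNumber = slice_idx + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(slice_idx) * 4.0]
        ds.Rows, ds.Columns = data.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = data.tobytes()
        p = directory / f"im{name_idx + 1:03d}.dcm"
        ds.save_as(str(p), enforce_file_format=True)
        paths.append(p)
    return paths


# -- cohort export / manifest ---------------------------------------------

def export_cohort(subjects: list[PhantomSubject], directory,
                  image_format: str = "nifti") -> pd.DataFrame:
    """Write each subject's plane stacks plus a manifest CSV; returns the
    manifest frame (columns: subject_id, age_days, per-plane path,
    site_tag)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in subjects:
        row = {"subject_id": sub.subject_id, "age_days": sub.age_days,
               "site_tag": sub.site_tag}
        for plane in PLANES:
            stack = sub.planes[plane]
            if image_format == "nifti":
                rel = f"{sub.subject_id}_{plane}.nii.gz"
                write_nifti_stack(stack, directory / rel)
            elif image_format == "png":
                rel = f"{sub.subject_id}_{plane}"
                write_png_stack(stack, directory / rel)
            else:
                raise ValueError(f"unknown image format {image_format!r}")
            row[f"path_{plane}"] = rel
        rows.append(row)
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, directory / "manifest.csv")
    return manifest


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV.

    Requires unique subject_id, positive age (``age_days``, or
    ``age_weeks`` converted on read), and at least one plane path column.
    """
    manifest = pd.read_csv(path)
    if "age_days" not in manifest.columns:
        if "age_weeks" in manifest.columns:
            manifest["age_days"] = manifest["age_weeks"] * 7.0
        else:
            raise ValueError("manifest needs an age_days (or age_weeks) column")
    if "subject_id" not in manifest.columns:
        raise ValueError("manifest needs a subject_id column")
    if manifest["subject_id"].duplicated().any():
        raise ValueError("manifest has duplicate subject_id values")
    if (manifest["age_days"] <= 0).any():
        raise ValueError("age_days must be positive")
    plane_cols = [c for c in manifest.columns if c.startswith("path_")]
    if not plane_cols:
        raise ValueError("manifest has no path_<plane> columns")
    if manifest[plane_cols].isna().all(axis=1).any():
        raise ValueError("every subject needs at least one plane path")
    return manifest


# -- configuration ---------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping; changes iff any
    field changes."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]
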