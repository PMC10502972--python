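"""Image and table I/O: grayscale PNG/TIFF B-scans with plain-text
sidecar metadata, dataset manifests, and measurement CSVs."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .phantom import BScan
from .postprocess import SfChTMeasurement

__all__ = [
    "read_image", "write_scan", "read_sidecar", "write_measurements",
    "read_manifest", "write_manifest",
]

_SIDECAR_SUFFIX = ".meta"


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + _SIDECAR_SUFFIX)


def read_sidecar(image_path) -> dict:
    """Read the key=value sidecar next to an image, if present."""
    meta_path = _sidecar_path(Path(image_path))
    meta: dict = {}
    if meta_path.exists():
        for line in meta_path.read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def read_image(path) -> BScan:
    """Load a single-channel PNG/TIFF as a BScan with intensities
    rescaled to [0, 1]; sidecar metadata supplies the axial pitch and
    orientation when available."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-channel image, got shape "
            f"{arr.shape} (multi-channel images are rejected)")
    if arr.dtype == np.uint8:
        pixels = arr / 255.0
    elif arr.dtype == np.uint16:
        pixels = arr / 65535.0
    else:
        pixels = arr.astype(float)
        if pixels.min() < 0 or pixels.max() > 1:
            raise ValueError(f"{path.name}: float image outside [0, 1]")
    meta = read_sidecar(path)
    return BScan(
        pixels,
        axial_scale=float(meta.get("axial_scale", 3.87)),
        orientation=meta.get("orientation", "horizontal"),
    )


def write_scan(bscan: BScan, mask: np.ndarray | None, stem,
               extra_meta: dict | None = None) -> dict:
    """Write a B-scan as 16-bit grayscale PNG (plus its mask as 8-bit
    0/255 PNG and a key=value sidecar).  Returns the written paths."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    img_path = stem.with_suffix(".png")
    iio.imwrite(img_path, np.round(bscan.pixels * 65535).astype(np.uint16))
    meta = {"axial_scale": bscan.axial_scale,
            "orientation": bscan.orientation}
    meta.update(extra_meta or {})
    _sidecar_path(img_path).write_text(
        "".join(f"{k}={v}\n" for k, v in meta.items()))
    paths = {"image": img_path}
    if mask is not None:
        mask_path = stem.with_name(stem.name + "_mask.png")
        iio.imwrite(mask_path, (np.asarray(mask) * 255).astype(np.uint8))
        paths["mask"] = mask_path
    return paths


def write_measurements(measurements: list[SfChTMeasurement], path) -> None:
    """Write per-scan SfChT values plus a per-visit mean row to CSV.

    Columns: subject, visit, scan_id, orientation, fovea_col, sfcht_um,
    mean_sfcht_um; the scan-level cells of the mean row are empty."""
    if not measurements:
        raise ValueError("no measurements to write")
    rows = []
    for m in measurements:
        mean = round(m.mean_um, 2)
        for j, (v, col, ori) in enumerate(
                zip(m.per_scan_um, m.fovea_columns, m.orientations)):
            rows.append({"subject": m.subject, "visit": m.visit,
                         "scan_id": j, "orientation": ori, "fovea_col": col,
                         "sfcht_um": round(v, 2), "mean_sfcht_um": ""})
        rows.append({"subject": m.subject, "visit": m.visit, "scan_id": "",
                     "orientation": "", "fovea_col": "", "sfcht_um": "",
                     "mean_sfcht_um": mean})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_manifest(entries: list[dict], path) -> None:
    """Write a dataset manifest (image_path, mask_path, orientation,
    axial_scale) as CSV."""
    pd.DataFrame(entries)[
        ["image_path", "mask_path", "orientation", "axial_scale"]
    ].to_csv(path, index=False)


def read_manifest(path) -> list[tuple[BScan, np.ndarray | None]]:
    """Load (BScan, mask) pairs listed in a manifest CSV."""
    df = pd.read_csv(path)
    root = Path(path).parent
    pairs = []
    for _, row in df.iterrows():
        img_path = Path(row["image_path"])
        if not img_path.is_absolute():
            img_path = root / img_path
        bscan = read_image(img_path)
        bscan.orientation = str(row.get("orientation", bscan.orientation))
        if "axial_scale" in row and not pd.isna(row["axial_scale"]):
            bscan.axial_scale = float(row["axial_scale"])
        mask = None
        if "mask_path" in row and isinstance(row["mask_path"], str):
            mask_path = Path(row["mask_path"])
            if not mask_path.is_absolute():
                mask_path = root / mask_path
            raw = iio.imread(mask_path)
            mask = (raw > 127).astype(np.uint8)
        pairs.append((bscan, mask))
    return pairs
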