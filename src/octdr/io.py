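"""Scan, label-map, manifest and config I/O plus the shared coordinate
convention.

Convention: images are row-major, 0-based numpy arrays; the row index grows
with depth, so the vitreous is at the top of the array and the choroid at
the bottom.  Every module of the package consumes this convention.

Label maps use 0 for non-retina and 1..12 for the layers NFL..RPE; within
every column the rows of label k must lie entirely above the rows of
label k+1 (the anatomical ordering, e.g. NFL above GCL).  Label maps are
stored canonically as NPY (lossless); an 8-bit PNG copy can be written for
viewing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import LAYER_NAMES

MIN_HEIGHT = 64
MIN_WIDTH = 64

#: label -> layer-name legend shared by all modules
LABEL_LEGEND = {0: "background", **{k + 1: n for k, n in enumerate(LAYER_NAMES)}}


@dataclass
class BScan:
    """One grayscale OCT cross-section with optional metadata."""

    pixels: np.ndarray
    subject_id: str | None = None
    eye: str | None = None
    class_label: str | None = None
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("BScan pixels must be a 2-D grid")
        h, w = self.pixels.shape
        if h < MIN_HEIGHT or w < MIN_WIDTH:
            raise ValueError(
                f"scan {h}x{w} below minimum {MIN_HEIGHT}x{MIN_WIDTH} "
                "(required for multiresolution steps)")
        if np.any(np.asarray(self.pixels, dtype=float) < 0):
            raise ValueError("gray values must be non-negative")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LabelMap:
    """Per-pixel layer assignment aligned to a BScan."""

    labels: np.ndarray
    legend: dict = field(default_factory=lambda: dict(LABEL_LEGEND))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be a 2-D grid")
        validate_labels(self.labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def validate_labels(labels: np.ndarray) -> None:
    """Validate label range and the column-wise topological ordering.

    Raises ``ValueError`` naming the offending columns when, in any column,
    a pixel of layer k+j appears above a pixel of layer k.
    """
    labels = np.asarray(labels).astype(np.int64)  # signed: diff must not wrap
    if labels.min() < 0 or labels.max() > 12:
        raise ValueError("labels must lie in 0..12")
    bad: list[int] = []
    for c in range(labels.shape[1]):
        col = labels[:, c]
        nz = col[col > 0]
        if nz.size and np.any(np.diff(nz) < 0):
            bad.append(c)
    if bad:
        head = ", ".join(map(str, bad[:10]))
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise ValueError(
            f"label topological order violated in columns [{head}]{more}: "
            "layer k rows must lie above layer k+1 rows")


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Luminance conversion of RGB(A) input; grayscale passes through.

    Coefficients (ITU-R 601) are renormalized to sum exactly to 1 so that an
    RGB image with equal channels reads identically to its single-channel
    form; integer inputs are rounded back to their dtype.
    """
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        w = np.array([0.299, 0.587, 0.114])
        w = w / w.sum()
        lum = arr[..., :3].astype(float) @ w
        if np.issubdtype(arr.dtype, np.integer):
            return np.rint(lum).astype(arr.dtype)
        return lum
    raise ValueError(f"unsupported image shape {arr.shape}")


def read_scan(path: str | Path, manifest_row: dict | pd.Series | None = None
              ) -> BScan:
    """Read a PNG/TIFF raster as a BScan; 16-bit values are preserved.

    ``manifest_row`` (mapping with subject_id/eye/class keys) attaches
    metadata.
    """
    path = Path(path)
    try:
        import imageio.v3 as iio
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap decoder errors with the path
        raise OSError(f"cannot decode raster {path}: {exc}") from exc
    pixels = _to_grayscale(np.asarray(arr))
    meta = dict(manifest_row) if manifest_row is not None else {}
    return BScan(
        pixels=pixels,
        subject_id=meta.get("subject_id"),
        eye=meta.get("eye"),
        class_label=meta.get("class", meta.get("class_label")),
        source_path=str(path),
    )


def write_scan(path: str | Path, scan: BScan | np.ndarray) -> None:
    """Write a scan as 8-bit PNG (values clamped/rounded) or 16-bit TIFF."""
    pixels = scan.pixels if isinstance(scan, BScan) else np.asarray(scan)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, pixels.astype(np.uint16))
    else:
        import imageio.v3 as iio
        iio.imwrite(path, np.clip(np.rint(pixels), 0, 255).astype(np.uint8))


def write_label_map(path: str | Path, label_map: LabelMap | np.ndarray,
                    png_copy: bool = False) -> None:
    """Write a label map as NPY (canonical); optionally an 8-bit PNG copy."""
    labels = label_map.labels if isinstance(label_map, LabelMap) else np.asarray(label_map)
    validate_labels(labels)
    path = Path(path)
    np.save(path.with_suffix(".npy"), labels.astype(np.uint8))
    if png_copy:
        import imageio.v3 as iio
        # spread 0..12 over the 8-bit range for viewing
        iio.imwrite(path.with_suffix(".png"),
                    (labels.astype(np.uint16) * 255 // 12).astype(np.uint8))


def read_label_map(path: str | Path) -> LabelMap:
    """Read an NPY (or viewable PNG) label raster and validate it."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        labels = np.load(path)
    else:
        import imageio.v3 as iio
        arr = np.asarray(iio.imread(path))
        labels = np.rint(arr.astype(float) * 12 / 255).astype(np.uint8)
    return LabelMap(labels=labels)


MANIFEST_COLUMNS = ("subject_id", "eye", "scan_path", "label_path", "class")


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    if "subject_id" not in manifest.columns:
        raise ValueError("manifest must carry subject_id")
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in manifest.columns:
        raise ValueError("manifest must carry subject_id")
    return manifest


def load_config(path: str | Path) -> dict:
    import yaml
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(path: str | Path, config: dict) -> None:
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
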