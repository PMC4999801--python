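"""Raster image I/O and color-plane decomposition.

The pipeline consumes 24-bit RGB brightfield fields of DAB (brown) +
hematoxylin (blue) stained tissue and works in exactly two informative
channels: the raw blue intensity I_b (RGB B channel, 0-255) and the hue
angle I_h (HSV H channel, degrees in [0, 360)).  Brown chromogen has a
very low blue component and a hue near 0-30 deg; the hematoxylin
counterstain sits near hue 240 with a high blue component, so these two
planes separate the three pixel populations (DAB nuclei, hematoxylin
nuclei, background) better than any other channel pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from skimage.color import rgb2hsv

from .errors import DimensionError, InputError

# Per-pixel tissue classes.  Background is 0 so class maps double as masks.
CLASS_BACKGROUND = 0
CLASS_DAB = 1
CLASS_HEMATOXYLIN = 2

CLASS_NAMES = {
    CLASS_BACKGROUND: "BACKGROUND",
    CLASS_DAB: "DAB",
    CLASS_HEMATOXYLIN: "HEMATOXYLIN",
}

#: Overlay colors approximating the conventional rendering: DAB nuclei in
#: orange, hematoxylin nuclei in purple; background is left untouched.
DEFAULT_OVERLAY_COLORS = {
    CLASS_DAB: (230, 126, 34),
    CLASS_HEMATOXYLIN: (142, 68, 173),
}

MIN_SIDE = 3  # 3x3 feature windows need at least this much support


@dataclass(frozen=True)
class ChannelPlanes:
    """The two informative channels of a stained field.

    Attributes
    ----------
    b_plane : (H, W) float64
        Raw blue intensities in [0, 255].
    h_plane : (H, W) float64
        HSV hue angles in degrees, [0, 360); achromatic pixels get hue 0.
    """

    b_plane: np.ndarray
    h_plane: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.b_plane.shape


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.dtype != np.uint8:
        raise InputError(f"expected H x W x 3 uint8 RGB image, got {img.shape} {img.dtype}")
    if img.shape[0] < MIN_SIDE or img.shape[1] < MIN_SIDE:
        raise DimensionError(
            f"image {img.shape[0]}x{img.shape[1]} is smaller than the minimum "
            f"{MIN_SIDE}x{MIN_SIDE} required by the 3x3 feature windows"
        )
    return img


def load_rgb(path: str | Path) -> np.ndarray:
    """Load a JPEG/PNG/TIFF image as an (H, W, 3) uint8 RGB array.

    Grayscale inputs are replicated to three channels; alpha is dropped.
    Raises :class:`InputError` for unreadable files and
    :class:`DimensionError` for images smaller than 3x3.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"))
    except FileNotFoundError as exc:
        raise InputError(f"cannot read image: {path} does not exist") from exc
    except (UnidentifiedImageError, OSError) as exc:
        raise InputError(f"cannot decode image file {path}: {exc}") from exc
    return _validate_rgb(arr)


def to_channel_planes(img: np.ndarray) -> ChannelPlanes:
    """Decompose an RGB image into the blue-intensity and hue planes.

    Hue follows the standard hexcone conversion, expressed in degrees on
    [0, 360); pixels with max(R,G,B) == min(R,G,B) are achromatic and get
    hue exactly 0, which keeps the bright near-gray background far from
    hematoxylin's hue of ~240 in feature space.
    """
    img = _validate_rgb(img)
    b_plane = img[:, :, 2].astype(np.float64)
    h_plane = rgb2hsv(img)[:, :, 0] * 360.0
    # rgb2hsv already yields 0 for achromatic pixels; guard the upper edge
    h_plane = np.where(h_plane >= 360.0, h_plane - 360.0, h_plane)
    return ChannelPlanes(b_plane=b_plane, h_plane=h_plane)


def write_label_png(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label map as a lossless 16-bit grayscale PNG."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > 65535:
        raise InputError("label map exceeds 16-bit range")
    Image.fromarray(labels.astype(np.uint16)).save(Path(path))


def read_label_png(path: str | Path) -> np.ndarray:
    """Read a 16-bit label map PNG back to an int32 array."""
    with Image.open(Path(path)) as im:
        return np.asarray(im).astype(np.int32)


def render_overlay(
    img: np.ndarray,
    class_map: np.ndarray,
    colors: dict[int, tuple[int, int, int]] | None = None,
) -> np.ndarray:
    """Paint nuclear classes over the original image; background untouched."""
    colors = colors or DEFAULT_OVERLAY_COLORS
    out = _validate_rgb(img).copy()
    for cls, rgb in colors.items():
        out[class_map == cls] = np.asarray(rgb, dtype=np.uint8)
    return out


def nucleus_table_frame(records) -> pd.DataFrame:
    """Convert NucleusRecord objects to the canonical CSV table layout."""
    rows = [
        {
            "id": r.id,
            "class": r.cls,
            "area_px": r.area,
            "centroid_x": r.centroid[1],
            "centroid_y": r.centroid[0],
            "circularity": r.circularity,
            "mean_Ib": r.mean_Ib,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["id", "class", "area_px", "centroid_x", "centroid_y", "circularity", "mean_Ib"],
    )


def write_outputs(
    img: np.ndarray,
    class_map: np.ndarray,
    nucleus_labels: np.ndarray,
    records,
    report: dict,
    out_dir: str | Path,
    overlay_colors: dict[int, tuple[int, int, int]] | None = None,
    stem: str = "field",
) -> dict[str, Path]:
    """Write the four per-field artifacts and return their paths.

    Artifacts: class overlay PNG, 16-bit nucleus label PNG, nucleus table
    CSV, and the field report JSON.  Output bytes depend only on the
    inputs (fixed float formatting, sorted JSON keys).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "overlay": out_dir / f"{stem}.overlay.png",
            "labels": out_dir / f"{stem}.labels.png",
            "table": out_dir / f"{stem}.nuclei.csv",
            "report": out_dir / f"{stem}.report.json",
        }
        Image.fromarray(render_overlay(img, class_map, overlay_colors)).save(paths["overlay"])
        write_label_png(nucleus_labels, paths["labels"])
        nucleus_table_frame(records).to_csv(paths["table"], index=False, float_format="%.6f")
        paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise InputError(f"cannot write outputs under {out_dir}: {exc}") from exc
    return paths
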