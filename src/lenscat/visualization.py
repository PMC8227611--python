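"""Diagnostic renderings: contrast stretch, false coloring, ROI overlay.

Dark-field lens images occupy a narrow low band of the 8-bit range, so a
linear min-max contrast stretch ("histogram linearization") makes the
scattering structure visible, and a false-color lookup table makes small
intensity differences easy to compare between the before and after panels.
The detected scoring region is drawn as a red circle.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np

from .errors import FormatError, ParameterError, ValidationError
from .io_formats import GreyImage
from .segmentation import CircleROI

DEFAULT_OVERLAY_COLOR = (255, 0, 0)
DEFAULT_OVERLAY_THICKNESS = 3


@dataclass(frozen=True)
class ColorImage:
    """RGB render with a record of how it was produced."""

    pixels: np.ndarray
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
            raise ValidationError(f"RGB image must be (h, w, 3) uint8, got {px.shape} {px.dtype}")
        object.__setattr__(self, "pixels", px)


def histogram_linearize(img: GreyImage) -> GreyImage:
    """Linear min-max contrast stretch to the full 8-bit range.

    v -> round((v - min) * 255 / (max - min)), rounding half away from
    zero, so the observed minimum maps to 0 and the maximum to 255.
    Idempotent: a stretched image is its own stretch.
    """
    px = img.pixels
    lo = int(px.min())
    hi = int(px.max())
    if hi == lo:
        raise ValidationError("zero dynamic range: constant image cannot be stretched")
    stretched = (px.astype(np.float64) - lo) * 255.0 / (hi - lo)
    out = np.floor(stretched + 0.5).astype(np.uint8)  # half away from zero (values >= 0)
    return GreyImage(pixels=out, source_path=img.source_path)


def histogram_equalize(img: GreyImage) -> GreyImage:
    """Histogram equalization, offered for comparison with the linear stretch."""
    px = img.pixels
    if px.min() == px.max():
        raise ValidationError("zero dynamic range")
    hist = np.bincount(px.ravel(), minlength=256)
    cdf = np.cumsum(hist).astype(np.float64)
    cdf = (cdf - cdf[cdf > 0][0]) / (cdf[-1] - cdf[cdf > 0][0])
    lut = np.floor(255.0 * np.clip(cdf, 0, 1) + 0.5).astype(np.uint8)
    return GreyImage(pixels=lut[px], source_path=img.source_path)


def default_lut() -> np.ndarray:
    """256-entry RGB table from a perceptually ordered colormap."""
    cmap = matplotlib.colormaps["inferno"]
    rgba = cmap(np.linspace(0.0, 1.0, 256))
    return np.floor(rgba[:, :3] * 255.0 + 0.5).astype(np.uint8)


def grey_lut() -> np.ndarray:
    """Identity-grey table (i, i, i)."""
    ramp = np.arange(256, dtype=np.uint8)
    return np.stack([ramp, ramp, ramp], axis=1)


def apply_false_color(img: GreyImage, lut: np.ndarray | None = None) -> ColorImage:
    """Pure lookup: ``output[r, c] = lut[input[r, c]]``."""
    if lut is None:
        lut = default_lut()
    lut = np.asarray(lut)
    if lut.shape != (256, 3):
        raise FormatError(f"LUT must have shape (256, 3), got {lut.shape}")
    if lut.dtype != np.uint8:
        if np.issubdtype(lut.dtype, np.integer) and lut.min() >= 0 and lut.max() <= 255:
            lut = lut.astype(np.uint8)
        else:
            raise FormatError("LUT entries must be integers in [0, 255]")
    return ColorImage(pixels=lut[img.pixels], provenance=(img.source_path, "false_color"))


def overlay_circle(
    img: GreyImage | ColorImage,
    roi: CircleROI,
    color: tuple[int, int, int] = DEFAULT_OVERLAY_COLOR,
    thickness: int = DEFAULT_OVERLAY_THICKNESS,
) -> ColorImage:
    """Draw the detection circle as an annulus of the given thickness.

    Pixels whose center distance to the ROI center lies within
    ``[r - t/2, r + t/2]`` take ``color``; all others are untouched.  The
    circle is silently clipped at the image bounds.
    """
    if thickness < 1:
        raise ParameterError(f"thickness must be >= 1, got {thickness}")
    if isinstance(img, GreyImage):
        rgb = np.repeat(img.pixels[:, :, None], 3, axis=2).copy()
        provenance = (img.source_path, "overlay_circle")
    else:
        rgb = img.pixels.copy()
        provenance = img.provenance + ("overlay_circle",)
    rows = np.arange(rgb.shape[0], dtype=float)[:, None]
    cols = np.arange(rgb.shape[1], dtype=float)[None, :]
    dist = np.hypot(cols - roi.center_x, rows - roi.center_y)
    ring = np.abs(dist - roi.radius) <= thickness / 2.0
    rgb[ring] = np.asarray(color, dtype=np.uint8)
    return ColorImage(pixels=rgb, provenance=provenance)


def render_panel(
    img: GreyImage,
    roi: CircleROI | None = None,
    linearize: bool = True,
    lut: np.ndarray | None = None,
) -> ColorImage:
    """Standard diagnostic panel: stretch, false-color, then circle overlay."""
    work = histogram_linearize(img) if linearize else img
    colored = apply_false_color(work, lut=lut)
    if roi is not None:
        return overlay_circle(colored, roi)
    return colored
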