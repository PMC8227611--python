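"""Lens detection in dark-field images.

A dark-field acquisition shows the lens as a bright scattering disc on a
near-black background.  Detection follows the classic chain: Gaussian
low-pass -> global threshold -> largest connected component -> robust
circle fit.  The scored region is the *rasterized fitted circle*, not the
raw thresholded blob: the circle deliberately includes interior dark
(clear) lens pixels, so a clear lens contributes a small but well-defined
pixel sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ParameterError, SegmentationError
from .io_formats import GreyImage

#: Default Gaussian bandwidth at full 1920x1080 resolution.
DEFAULT_SIGMA = 5.0

#: Reference frame width the default sigma is tuned for.
REFERENCE_WIDTH = 1920

#: Default threshold rule: Otsu's criterion on log-compressed intensities.
#: Dark-field foregrounds are strongly skewed once opacities appear; on the
#: linear scale a bright opacity texture drags the Otsu threshold upward and
#: shrinks the detected blob, while on the log scale the background/lens
#: split is insensitive to foreground brightness structure.
DEFAULT_RULE = "otsu-log"

#: A fitted circle covering more than this fraction of the frame is treated
#: as an illumination fault rather than a lens.
MAX_FRAME_FRACTION = 0.95

MIN_COMPONENT_PIXELS = 10
MIN_MASK_PIXELS = 100

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class CircleROI:
    """Circular region of interest in continuous (x, y) pixel coordinates."""

    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ParameterError(f"radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class LensMask:
    """Boolean scoring mask (rasterized circle) plus how it was obtained."""

    mask: np.ndarray
    roi: CircleROI
    sigma: float
    threshold_value: float
    threshold_rule: str


def default_sigma_for(width: int) -> float:
    """Resolution-scaled Gaussian bandwidth (default sigma at 1920 px width)."""
    return DEFAULT_SIGMA * width / REFERENCE_WIDTH


def smooth_image(img: GreyImage, sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Gaussian low-pass of the image; real-valued output, reflective border.

    The smoothed grid is only used for detection; scoring always reads the
    raw 8-bit intensities.
    """
    if not sigma > 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    return ndimage.gaussian_filter(img.pixels.astype(np.float64), sigma=sigma, mode="reflect")


def threshold_foreground(smoothed: np.ndarray, rule: str = "otsu") -> tuple[np.ndarray, float]:
    """Binarize a smoothed grid; returns ``(binary, threshold_value)``.

    ``rule`` is ``"otsu"`` (Otsu on the linear scale), ``"otsu-log"``
    (Otsu on log1p-compressed intensities, mapped back to the linear
    scale; robust when opacity textures skew the foreground mode), or
    ``"fixed:<value>"``.  Pixels strictly above the returned linear-scale
    threshold are foreground.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if rule in ("otsu", "otsu-log"):
        if np.ptp(smoothed) == 0:
            raise SegmentationError("degenerate histogram: constant image under otsu")
        if rule == "otsu":
            value = float(threshold_otsu(smoothed))
        else:
            value = float(np.expm1(threshold_otsu(np.log1p(smoothed))))
    elif rule.startswith("fixed:"):
        try:
            value = float(rule.split(":", 1)[1])
        except ValueError as exc:
            raise ParameterError(f"bad fixed threshold in rule {rule!r}") from exc
    else:
        raise ParameterError(f"unknown threshold rule {rule!r} (use otsu or fixed:<v>)")
    return smoothed > value, value


def largest_component(binary: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Size ties are broken by the component whose lexicographically smallest
    (row, col) pixel comes first.
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        raise SegmentationError("no foreground")
    labels, n = ndimage.label(binary, structure=_EIGHT_CONN)
    if n == 1:
        return binary
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    candidates = np.flatnonzero(sizes == sizes.max()) + 1
    if candidates.size == 1:
        best = int(candidates[0])
    else:
        # raster-scan position of each candidate's first pixel = its
        # lexicographically smallest (row, col)
        firsts = [int(np.argmax(labels.ravel() == c)) for c in candidates]
        best = int(candidates[int(np.argmin(firsts))])
    return labels == best


def fit_circle(component: np.ndarray) -> CircleROI:
    """Fit a circle to a boolean component.

    Center is the pixel centroid; radius is the 99th percentile of
    pixel-center distances to the centroid, which ignores thin radial
    spikes (cortical-opacity edges) while tracking the disc rim.
    """
    component = np.asarray(component, dtype=bool)
    rows, cols = np.nonzero(component)
    if rows.size < MIN_COMPONENT_PIXELS:
        raise SegmentationError(
            f"component too small: {rows.size} pixels < {MIN_COMPONENT_PIXELS}"
        )
    cy = float(rows.mean())
    cx = float(cols.mean())
    dist = np.hypot(cols - cx, rows - cy)
    radius = float(np.percentile(dist, 99))
    if radius <= 0:
        raise SegmentationError("degenerate component: zero radius")
    h, w = component.shape
    if not (0 <= cx < w and 0 <= cy < h):
        raise SegmentationError("fitted center outside image bounds")
    return CircleROI(center_x=cx, center_y=cy, radius=radius)


def rasterize_circle(shape: tuple[int, int], roi: CircleROI) -> np.ndarray:
    """Boolean grid of pixel centers within ``roi`` (distance <= radius)."""
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    return (cols - roi.center_x) ** 2 + (rows - roi.center_y) ** 2 <= roi.radius**2


def segment_lens(
    img: GreyImage, sigma: float | None = None, rule: str = DEFAULT_RULE
) -> LensMask:
    """Detect the lens and return its circular scoring mask.

    Composition: smooth -> threshold -> largest component -> circle fit ->
    rasterize.  ``sigma=None`` scales the default bandwidth with the frame
    width (5 px at 1920).  Deterministic for identical input and parameters.
    """
    if sigma is None:
        sigma = default_sigma_for(img.width)
    smoothed = smooth_image(img, sigma=sigma)
    binary, value = threshold_foreground(smoothed, rule=rule)
    if not binary.any():
        raise SegmentationError("no foreground")
    component = largest_component(binary)
    roi = fit_circle(component)
    frame_area = img.height * img.width
    if np.pi * roi.radius**2 > MAX_FRAME_FRACTION * frame_area:
        raise SegmentationError(
            "fitted circle covers > 95% of the frame; illumination fault suspected"
        )
    mask = rasterize_circle(img.pixels.shape, roi)
    if mask.sum() < MIN_MASK_PIXELS:
        raise SegmentationError(
            f"scoring mask too small: {int(mask.sum())} < {MIN_MASK_PIXELS} pixels"
        )
    return LensMask(mask=mask, roi=roi, sigma=sigma, threshold_value=value, threshold_rule=rule)
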