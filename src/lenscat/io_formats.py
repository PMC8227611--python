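"""Reading and writing the pipeline's standard artifacts.

Dark-field acquisitions are 8-bit single-channel images (BMP as acquired;
PNG/TIFF accepted as interchangeable lossless carriers).  Transmission
spectra travel as two-column CSV (``wavelength_nm,transmission``) covering
the visible range 380-780 nm.  A cohort manifest maps each lens to its
irradiation group and its four measurement files.

Coordinate convention used throughout the package: 0-based row/column
indices, origin at the top-left, circle centers in continuous
(col, row) = (x, y) pixel coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Closed set of cohort group labels: UVB at 311 nm, UVA at 370 nm,
#: blue light at 460 nm, and the non-irradiated control group.
GROUPS = ("UVB311", "UVA370", "BLUE460", "CONTROL")

#: Wavelength range of the transmission measurement, nm.
WAVELENGTH_MIN = 380.0
WAVELENGTH_MAX = 780.0

#: Transmission above this is treated as a blanking/referencing fault.
TRANSMISSION_CEILING = 1.5

MIN_IMAGE_SIDE = 16


@dataclass(frozen=True)
class GreyImage:
    """A 2-D 8-bit intensity grid, the unit of dark-field acquisition.

    Parameters
    ----------
    pixels
        ``(rows, cols)`` array of uint8 intensities.
    source_path
        Where the image was read from; empty for in-memory images.
    """

    pixels: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"grey image must be 2-D, got shape {px.shape}")
        if px.shape[0] < MIN_IMAGE_SIDE or px.shape[1] < MIN_IMAGE_SIDE:
            raise ValidationError(
                f"image too small: {px.shape}, need at least "
                f"{MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}"
            )
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise ValidationError(
                    f"intensities must be integers in [0, 255], dtype {px.dtype}"
                )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class TransmissionSpectrum:
    """Per-wavelength transmission of one lens at one timepoint.

    ``wavelengths`` is strictly ascending within [380, 780] nm;
    ``transmission`` is a unitless fraction (1.0 = fully transparent).
    """

    wavelengths: np.ndarray
    transmission: np.ndarray
    lens_id: str = ""
    timepoint: str = "before"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        tr = np.asarray(self.transmission, dtype=float)
        if wl.shape != tr.shape or wl.ndim != 1:
            raise ValidationError("wavelengths and transmission must be equal-length 1-D")
        if wl.size == 0:
            raise ValidationError("empty spectrum")
        order = np.argsort(wl, kind="stable")
        wl, tr = wl[order], tr[order]
        if np.any(np.diff(wl) == 0):
            dup = wl[np.flatnonzero(np.diff(wl) == 0)[0]]
            raise FormatError(f"duplicate wavelength {dup:g} nm")
        if wl[0] < WAVELENGTH_MIN or wl[-1] > WAVELENGTH_MAX:
            raise ValidationError(
                f"wavelengths outside [{WAVELENGTH_MIN:g}, {WAVELENGTH_MAX:g}] nm"
            )
        if np.any(tr < 0):
            raise ValidationError("negative transmission value")
        if np.any(tr > TRANSMISSION_CEILING):
            raise ValidationError(
                f"transmission > {TRANSMISSION_CEILING} suggests a referencing fault"
            )
        if self.timepoint not in ("before", "after"):
            raise ValidationError(f"timepoint must be before/after, got {self.timepoint!r}")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "transmission", tr)

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass(frozen=True)
class ManifestRecord:
    lens_id: str
    group: str
    before_image: str
    after_image: str
    before_spectrum: str
    after_spectrum: str
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass(frozen=True)
class CohortManifest:
    """Validated assignment of lenses to groups and measurement files.

    Paths in records are interpreted relative to ``root`` (the directory
    the manifest file lives in) unless absolute.
    """

    records: tuple[ManifestRecord, ...]
    root: str = "."

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("no records")
        seen: set[str] = set()
        for rec in self.records:
            if rec.lens_id in seen:
                raise ValidationError(f"duplicate lens_id {rec.lens_id!r}")
            seen.add(rec.lens_id)
            if rec.group not in GROUPS:
                raise ValidationError(
                    f"unknown group {rec.group!r} for lens {rec.lens_id!r}; "
                    f"allowed: {', '.join(GROUPS)}"
                )
            if not rec.excluded:
                missing = [
                    name
                    for name in ("before_image", "after_image", "before_spectrum", "after_spectrum")
                    if not getattr(rec, name)
                ]
                if missing:
                    raise ValidationError(
                        f"lens {rec.lens_id!r} not excluded but missing {', '.join(missing)}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def group_counts(self) -> dict[str, int]:
        """Total records per group, exclusions included."""
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.group] = counts.get(rec.group, 0) + 1
        return counts

    def effective_counts(self) -> dict[str, int]:
        """Records per group after removing excluded lenses."""
        counts: dict[str, int] = {}
        for rec in self.records:
            if not rec.excluded:
                counts[rec.group] = counts.get(rec.group, 0) + 1
        return counts

    def active_records(self) -> tuple[ManifestRecord, ...]:
        return tuple(r for r in self.records if not r.excluded)

    def resolve(self, path: str) -> Path:
        p = Path(path)
        return p if p.is_absolute() else Path(self.root) / p


# ---------------------------------------------------------------------------
# images


def read_grey_image(path: str | Path) -> GreyImage:
    """Read an 8-bit grey image (BMP/PNG/TIFF).

    Multi-channel files whose channels are identical (a grey acquisition
    saved as RGB) are collapsed to one channel; genuinely colored input is
    rejected.  Higher bit depths are rescaled to 8 bits by integer right
    shift, with a warning.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except (OSError, ValueError, RuntimeError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop fully-opaque alpha
            if np.all(arr[:, :, 3] == arr[0, 0, 3]):
                arr = arr[:, :, :3]
            else:
                raise FormatError(f"{path}: alpha channel varies; not a grey acquisition")
        if not np.all(arr[:, :, :1] == arr):
            raise FormatError(
                f"{path}: RGB channels differ; expected a single-channel acquisition"
            )
        arr = arr[:, :, 0]
    elif arr.ndim != 2:
        raise FormatError(f"{path}: unsupported dimensionality {arr.ndim}")
    if arr.dtype == np.uint16:
        logger.warning("%s: 16-bit input right-shifted to 8 bits", path)
        arr = (arr >> 8).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise FormatError(f"{path}: unsupported pixel dtype {arr.dtype}")
    return GreyImage(pixels=arr, source_path=str(path))


def write_grey_image(img: GreyImage, path: str | Path) -> None:
    """Write a grey image losslessly (format chosen by extension)."""
    iio.imwrite(Path(path), img.pixels)


# ---------------------------------------------------------------------------
# spectra


def read_spectrum_csv(
    path: str | Path, lens_id: str = "", timepoint: str = "before"
) -> TransmissionSpectrum:
    """Read a ``wavelength_nm,transmission`` CSV into an ascending spectrum.

    Rows outside 380-780 nm are dropped (instrument padding); non-numeric
    cells raise :class:`ParseError` with the offending row number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    expected = ["wavelength_nm", "transmission"]
    if list(df.columns[:2]) != expected:
        raise FormatError(f"{path}: header must start with {','.join(expected)}")
    values = np.empty((len(df), 2), dtype=float)
    for i, row in enumerate(df.itertuples(index=False)):
        for j, col in enumerate(expected):
            cell = getattr(row, col)
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}: non-numeric {col} {cell!r} at data row {i + 1}"
                ) from exc
    wl, tr = values[:, 0], values[:, 1]
    keep = (wl >= WAVELENGTH_MIN) & (wl <= WAVELENGTH_MAX)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d rows outside 380-780 nm", path, n_dropped)
    if not keep.any():
        raise ValidationError(f"{path}: no rows within 380-780 nm")
    return TransmissionSpectrum(
        wavelengths=wl[keep], transmission=tr[keep], lens_id=lens_id, timepoint=timepoint
    )


def write_spectrum_csv(spectrum: TransmissionSpectrum, path: str | Path) -> None:
    df = pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "transmission": spectrum.transmission}
    )
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


# ---------------------------------------------------------------------------
# manifests

MANIFEST_COLUMNS = [
    "lens_id",
    "group",
    "before_image",
    "after_image",
    "before_spectrum",
    "after_spectrum",
    "excluded",
    "exclusion_reason",
]

_TRUE_TOKENS = {"1", "true", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "no", "n", ""}


def _parse_excluded(token: str, lens_id: str) -> bool:
    t = str(token).strip().lower()
    if t in ("nan",):  # pandas NA for an empty cell
        return False
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise ParseError(f"lens {lens_id!r}: cannot parse excluded flag {token!r}")


def read_manifest(path: str | Path) -> CohortManifest:
    """Read and validate a cohort manifest (CSV or TSV, sniffed by header)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValidationError(f"{path}: no records")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {', '.join(missing)}")
    if len(df) == 0:
        raise ValidationError(f"{path}: no records")
    records = tuple(
        ManifestRecord(
            lens_id=row["lens_id"],
            group=row["group"],
            before_image=row["before_image"],
            after_image=row["after_image"],
            before_spectrum=row["before_spectrum"],
            after_spectrum=row["after_spectrum"],
            excluded=_parse_excluded(row["excluded"], row["lens_id"]),
            exclusion_reason=row["exclusion_reason"],
        )
        for _, row in df.iterrows()
    )
    manifest = CohortManifest(records=records, root=str(path.parent))
    logger.info("manifest %s: per-group counts %s", path, manifest.group_counts())
    return manifest


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "lens_id": r.lens_id,
                "group": r.group,
                "before_image": r.before_image,
                "after_image": r.after_image,
                "before_spectrum": r.before_spectrum,
                "after_spectrum": r.after_spectrum,
                "excluded": int(r.excluded),
                "exclusion_reason": r.exclusion_reason,
            }
            for r in manifest.records
        ],
        columns=MANIFEST_COLUMNS,
    )
    df.to_csv(path, index=False, lineterminator="\n")
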