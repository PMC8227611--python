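"""Transmission-quotient curves.

For each lens the plate reader records transmission T(lambda) on 380-780 nm
before and after irradiation.  The per-wavelength quotient

    Q_T(lambda) = T_after(lambda) / T_before(lambda)

equals 1 where nothing changed and drops below 1 where the lens lost
transparency.  Near the UV edge T_before approaches zero and the ratio is
numerically meaningless, so wavelengths with T_before at or below a small
floor are flagged rather than reported.  Group curves are per-wavelength
mean +/- SEM over unflagged values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_formats import TransmissionSpectrum

#: Default denominator floor (transmission fraction).
DEFAULT_FLOOR = 0.005


@dataclass(frozen=True)
class QtCurve:
    """Per-lens quotient curve; flagged positions hold NaN."""

    wavelengths: np.ndarray
    quotient: np.ndarray
    flagged: np.ndarray
    lens_id: str = ""

    def __post_init__(self) -> None:
        if not (self.wavelengths.shape == self.quotient.shape == self.flagged.shape):
            raise ValidationError("curve vectors must share one length")


@dataclass(frozen=True)
class CurveSummary:
    """Group mean +/- SEM per wavelength; n_effective counts unflagged values."""

    group: str
    wavelengths: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int
    n_effective: np.ndarray
    flagged: np.ndarray


def _check_grids(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape or not np.array_equal(a, b):
        if a.shape != b.shape:
            raise ValidationError(f"wavelength grids differ in length: {a.size} vs {b.size}")
        idx = int(np.flatnonzero(a != b)[0])
        raise ValidationError(
            f"wavelength grids differ first at index {idx}: {a[idx]:g} vs {b[idx]:g} nm"
        )


def compute_qt_curve(
    before: TransmissionSpectrum,
    after: TransmissionSpectrum,
    floor: float = DEFAULT_FLOOR,
) -> QtCurve:
    """Elementwise after/before transmission quotient with denominator floor."""
    if floor < 0:
        raise ValidationError(f"floor must be >= 0, got {floor}")
    _check_grids(before.wavelengths, after.wavelengths)
    flagged = before.transmission <= floor
    quotient = np.full_like(before.transmission, np.nan)
    ok = ~flagged
    quotient[ok] = after.transmission[ok] / before.transmission[ok]
    return QtCurve(
        wavelengths=before.wavelengths.copy(),
        quotient=quotient,
        flagged=flagged,
        lens_id=before.lens_id or after.lens_id,
    )


def _summarize(wavelengths: np.ndarray, matrix: np.ndarray, group: str) -> CurveSummary:
    """Column-wise mean/SEM of a (curves x wavelengths) matrix with NaN flags."""
    valid = ~np.isnan(matrix)
    n_eff = valid.sum(axis=0)
    flagged = n_eff < 2
    mean = np.full(wavelengths.shape, np.nan)
    sem = np.full(wavelengths.shape, np.nan)
    ok = ~flagged
    with np.errstate(invalid="ignore"):
        mean[ok] = np.nanmean(matrix[:, ok], axis=0)
        sem[ok] = np.nanstd(matrix[:, ok], axis=0, ddof=1) / np.sqrt(n_eff[ok])
    return CurveSummary(
        group=group,
        wavelengths=wavelengths.copy(),
        mean=mean,
        sem=sem,
        n=matrix.shape[0],
        n_effective=n_eff,
        flagged=flagged,
    )


def summarize_qt(curves: list[QtCurve], group: str) -> CurveSummary:
    """Per-wavelength mean +/- SEM of quotient curves, ignoring flagged values."""
    if len(curves) < 2:
        raise ValidationError(f"need >= 2 curves for group {group!r}, got {len(curves)}")
    grid = curves[0].wavelengths
    for c in curves[1:]:
        _check_grids(grid, c.wavelengths)
    matrix = np.vstack([c.quotient for c in curves])
    return _summarize(grid, matrix, group)


def mean_spectrum(spectra: list[TransmissionSpectrum], group: str = "") -> CurveSummary:
    """Per-wavelength mean +/- SEM of raw transmission spectra."""
    if not spectra:
        raise ValidationError("no spectra")
    if len(spectra) < 2:
        raise ValidationError(f"need >= 2 spectra, got {len(spectra)}")
    grid = spectra[0].wavelengths
    for s in spectra[1:]:
        _check_grids(grid, s.wavelengths)
    matrix = np.vstack([s.transmission for s in spectra])
    return _summarize(grid, matrix, group)


def blank_divide(
    raw: TransmissionSpectrum, blank: TransmissionSpectrum, floor: float = DEFAULT_FLOOR
) -> TransmissionSpectrum:
    """Reference a raw export against a blank (storage-medium) spectrum.

    Normally the instrument applies the blank itself; this exists for raw
    exports only.  Blank values at or below the floor make the referenced
    transmission undefined and raise.
    """
    _check_grids(raw.wavelengths, blank.wavelengths)
    if np.any(blank.transmission <= floor):
        raise ValidationError("blank spectrum at or below floor; cannot reference")
    return TransmissionSpectrum(
        wavelengths=raw.wavelengths.copy(),
        transmission=raw.transmission / blank.transmission,
        lens_id=raw.lens_id,
        timepoint=raw.timepoint,
    )
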