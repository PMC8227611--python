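"""Dark-field opacity scoring.

For each lens the pixel intensities inside the detected circular ROI are
summed in the raw (unsmoothed) image, before and after irradiation, and the
dark-field quotient

    Q_DFI = sum(p_before) / sum(p_after)

is formed.  Since scattering structures brighten a dark-field image, the
after-sum grows with opacification and Q_DFI drops below 1; Q_DFI close to
1 means little cataractogenic change.  Group results are reported as
mean +/- SEM (standard error of the mean, Bessel-corrected).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import LenscatError, ValidationError
from .io_formats import GROUPS, CohortManifest, GreyImage, read_grey_image
from .segmentation import DEFAULT_RULE, LensMask, segment_lens

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QdfiResult:
    """Per-lens pixel sums and their quotient."""

    lens_id: str
    group: str
    sum_before: int
    sum_after: int
    quotient: float


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class ScoringParams:
    """Knobs of the scoring chain.

    sigma
        Gaussian detection bandwidth in px; ``None`` scales the default
        with the frame width (5 px at 1920).
    shared_mask
        ``None`` scores each image inside its own independently fitted
        circle; ``"before"``/``"after"`` reuse one image's mask for both;
        ``"union"`` scores inside the union of the two masks.  Intended for
        sensitivity analysis only.
    """

    sigma: float | None = None
    threshold_rule: str = DEFAULT_RULE
    shared_mask: str | None = None

    def __post_init__(self) -> None:
        if self.shared_mask not in (None, "before", "after", "union"):
            raise ValidationError(f"shared_mask must be before/after/union, got {self.shared_mask!r}")


def sum_pixels(img: GreyImage, mask: LensMask | np.ndarray) -> int:
    """Exact integer sum of intensities at true-mask positions."""
    m = mask.mask if isinstance(mask, LensMask) else np.asarray(mask, dtype=bool)
    if m.shape != img.pixels.shape:
        raise ValidationError(f"mask shape {m.shape} != image shape {img.pixels.shape}")
    if not m.any():
        raise ValidationError("empty ROI")
    return int(np.sum(img.pixels[m], dtype=np.int64))


def compute_qdfi(sum_before: float, sum_after: float) -> float:
    """Quotient of summed intensities before vs after irradiation."""
    if sum_before < 0:
        raise ValidationError(f"negative before-sum {sum_before}")
    if sum_after <= 0:
        raise ValidationError("degenerate after-image: zero pixel sum")
    return sum_before / sum_after


def aggregate_group(values: list[float] | np.ndarray, group: str) -> GroupSummary:
    """Mean and SEM (sd/sqrt(n), n-1 denominator) of per-lens quotients."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValidationError(f"SEM undefined for n<2 (group {group!r}, n={n})")
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / math.sqrt(n))
    return GroupSummary(group=group, n=n, mean=mean, sem=sem)


def score_pair(
    before: GreyImage, after: GreyImage, params: ScoringParams = ScoringParams()
) -> tuple[int, int, float]:
    """Segment and score one before/after image pair.

    Returns ``(sum_before, sum_after, quotient)``.  Each image is segmented
    independently unless ``params.shared_mask`` says otherwise; sums always
    use the raw 8-bit intensities.
    """
    mask_b = segment_lens(before, sigma=params.sigma, rule=params.threshold_rule)
    mask_a = segment_lens(after, sigma=params.sigma, rule=params.threshold_rule)
    if params.shared_mask == "before":
        mask_a = mask_b
    elif params.shared_mask == "after":
        mask_b = mask_a
    elif params.shared_mask == "union":
        union = mask_b.mask | mask_a.mask
        s_b = sum_pixels(before, union)
        s_a = sum_pixels(after, union)
        return s_b, s_a, compute_qdfi(s_b, s_a)
    for img, mask in ((before, mask_b), (after, mask_a)):
        sat = float((img.pixels[mask.mask] == 255).mean())
        if sat > 0:
            logger.info("%s: saturation fraction %.4f inside ROI", img.source_path, sat)
    s_b = sum_pixels(before, mask_b)
    s_a = sum_pixels(after, mask_a)
    return s_b, s_a, compute_qdfi(s_b, s_a)


def score_cohort(
    manifest: CohortManifest, params: ScoringParams = ScoringParams()
) -> tuple[list[QdfiResult], list[GroupSummary], dict[str, str]]:
    """Score every non-excluded lens in a cohort.

    Excluded records are skipped with a logged reason.  Per-lens failures
    (unreadable file, failed segmentation) are collected into the returned
    error map and the run continues.  Results are ordered by lens_id.
    """
    results: list[QdfiResult] = []
    errors: dict[str, str] = {}
    for rec in sorted(manifest.records, key=lambda r: r.lens_id):
        if rec.excluded:
            logger.info("lens %s excluded: %s", rec.lens_id, rec.exclusion_reason or "(no reason)")
            continue
        try:
            before = read_grey_image(manifest.resolve(rec.before_image))
            after = read_grey_image(manifest.resolve(rec.after_image))
            s_b, s_a, q = score_pair(before, after, params)
        except (LenscatError, OSError) as exc:
            errors[rec.lens_id] = str(exc)
            logger.error("lens %s failed: %s", rec.lens_id, exc)
            continue
        results.append(
            QdfiResult(lens_id=rec.lens_id, group=rec.group, sum_before=s_b, sum_after=s_a, quotient=q)
        )
    summaries: list[GroupSummary] = []
    for group in GROUPS:
        values = [r.quotient for r in results if r.group == group]
        if not values:
            continue
        if len(values) < 2:
            logger.warning("group %s has n=%d < 2; no summary", group, len(values))
            continue
        summaries.append(aggregate_group(values, group))
    return results, summaries, errors
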