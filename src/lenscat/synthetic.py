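"""Synthetic dark-field lens phantoms and transmission spectra.

A phantom is a bright scattering disc (the lens) on a near-black field,
with an analytic ground-truth mask and expected pixel sums, so the whole
detection/scoring chain can be validated end to end.  The "after" image of
a pair models two effects seen in real ex-vivo cohorts:

* a multiplicative brightening of the whole lens (``aging_factor``),
  present even without irradiation, and
* a morphology-specific opacity texture scaled by ``severity``:
  NUC (central Gaussian blob), COR (radial wedge spikes inward from the
  rim), PSC (off-center patch toward the posterior pole, +x), and YSUT
  (three arms through the center, 120 degrees apart).

Paired spectra model a sigmoidal UV cut-on with a plateau in the visible,
attenuated after irradiation either uniformly or with a blue-weighted
profile (stronger loss at short wavelengths).

All outputs are pure functions of their configuration, seed included.
The generator renders 8-bit images; the quantized noiseless field is the
ground truth the pipeline is compared against, while the continuous
closed-form quotient is available via ``expected_qdfi(..., quantize=False)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path

import numpy as np

from .errors import ParameterError, ValidationError
from .io_formats import (
    CohortManifest,
    GreyImage,
    ManifestRecord,
    TransmissionSpectrum,
    write_grey_image,
    write_manifest,
    write_spectrum_csv,
)

PHENOTYPES = ("NONE", "NUC", "COR", "PSC", "YSUT")

#: Peak texture intensity added at severity 1 (8-bit counts).
TEXTURE_AMPLITUDE = 120.0

#: Group quotient targets used by the demonstration preset; chosen to match
#: the effect sizes of the original cohort, largest change for blue light.
EFFECT_TARGETS = {"BLUE460": 0.69, "UVA370": 0.74, "UVB311": 0.78, "CONTROL": 0.82}

EFFECT_PHENOTYPES = {"BLUE460": "COR", "UVA370": "NUC", "UVB311": "PSC", "CONTROL": "NONE"}

#: Spectral attenuation presets per group: (k_blue at 400 nm, k_red at 700 nm)
#: for irradiated groups, uniform aging quotient for the control.
EFFECT_ATTENUATION = {
    "BLUE460": ("blueweighted", 0.55, 0.88),
    "UVB311": ("blueweighted", 0.72, 0.91),
    "UVA370": ("blueweighted", 0.80, 0.93),
    "CONTROL": ("uniform", 0.95),
}


@dataclass(frozen=True)
class SyntheticLensConfig:
    """Parameters of one phantom lens pair.

    Defaults mirror the acquisition geometry (1920x1080 frame) with a dim
    clear-lens scatter level of 30 counts over a background of 3 counts.
    """

    seed: int = 0
    width: int = 1920
    height: int = 1080
    disc_center: tuple[float, float] | None = None  # (x, y); None = frame center
    disc_radius: float | None = None  # None = 25% of frame height
    base_level: float = 30.0
    background_level: float = 3.0
    aging_factor: float = 1.0
    phenotype: str = "NONE"
    severity: float = 0.0
    noise_sd: float = 0.0
    vignette_strength: float = 0.0

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ParameterError(f"phenotype must be one of {PHENOTYPES}, got {self.phenotype!r}")
        if not 0.0 <= self.severity <= 1.0:
            raise ParameterError(f"severity must be in [0, 1], got {self.severity}")
        if self.aging_factor < 1.0:
            raise ParameterError(f"aging_factor must be >= 1, got {self.aging_factor}")
        if self.base_level <= self.background_level:
            raise ParameterError("base_level must exceed background_level")
        if not 0.0 <= self.vignette_strength <= 1.0:
            raise ParameterError("vignette_strength must be in [0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        cx, cy = self.center
        r = self.radius
        margin = 10.0
        if (cx - r < margin or cy - r < margin
                or cx + r > self.width - margin or cy + r > self.height - margin):
            raise ParameterError("disc must fit inside the frame with a 10 px margin")

    @property
    def center(self) -> tuple[float, float]:
        if self.disc_center is not None:
            return self.disc_center
        return (self.width / 2.0, self.height / 2.0)

    @property
    def radius(self) -> float:
        if self.disc_radius is not None:
            return float(self.disc_radius)
        return 0.25 * self.height


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth for one phantom pair: disc mask and expected sums."""

    mask: np.ndarray
    sum_before_expected: float
    sum_after_expected: float
    qdfi_expected: float


def _grids(cfg: SyntheticLensConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cx, cy = cfg.center
    rows = np.arange(cfg.height, dtype=np.float64)[:, None]
    cols = np.arange(cfg.width, dtype=np.float64)[None, :]
    dx = cols - cx
    dy = rows - cy
    return dx, dy, np.hypot(dx, dy)


@lru_cache(maxsize=16)
def _disc_mask_cached(cfg_noseed: SyntheticLensConfig) -> np.ndarray:
    _, _, dist = _grids(cfg_noseed)
    mask = dist <= cfg_noseed.radius
    mask.setflags(write=False)
    return mask


def disc_mask(cfg: SyntheticLensConfig) -> np.ndarray:
    """Ground-truth rasterization of the lens disc (pixel centers <= radius)."""
    return _disc_mask_cached(replace(cfg, seed=0))


def _unit_texture(cfg: SyntheticLensConfig) -> np.ndarray:
    """Phenotype texture at severity 1, zero outside the disc."""
    dx, dy, dist = _grids(cfg)
    r = cfg.radius
    inside = dist <= r
    tex = np.zeros((cfg.height, cfg.width), dtype=np.float64)
    if cfg.phenotype == "NONE":
        return tex
    if cfg.phenotype == "NUC":
        sigma = r / 3.0
        tex = TEXTURE_AMPLITUDE * np.exp(-(dist**2) / (2.0 * sigma**2))
    elif cfg.phenotype == "COR":
        angles = np.arctan2(dy, dx)
        n_spikes = 12
        half_width = np.deg2rad(5.0)
        spoke = np.remainder(angles, 2 * np.pi / n_spikes)
        near_spoke = np.minimum(spoke, 2 * np.pi / n_spikes - spoke) <= half_width
        radial = (dist >= 0.6 * r) & (dist <= r)
        tex = np.where(near_spoke & radial, TEXTURE_AMPLITUDE, 0.0)
    elif cfg.phenotype == "PSC":
        cx, cy = cfg.center
        d_patch = np.hypot(dx - 0.5 * r, dy)
        tex = np.where(d_patch <= 0.25 * r, TEXTURE_AMPLITUDE, 0.0)
    elif cfg.phenotype == "YSUT":
        angles = np.arctan2(dy, dx)
        arm_width = max(1.5, 0.03 * r)
        tex_mask = np.zeros_like(inside)
        for k in range(3):
            theta = np.pi / 2 + k * 2 * np.pi / 3
            # distance to the ray from the center at angle theta
            along = dx * np.cos(theta) + dy * np.sin(theta)
            across = -dx * np.sin(theta) + dy * np.cos(theta)
            tex_mask |= (along >= 0) & (along <= 0.9 * r) & (np.abs(across) <= arm_width)
        tex = np.where(tex_mask, TEXTURE_AMPLITUDE, 0.0)
    return np.where(inside, tex, 0.0)


@lru_cache(maxsize=16)
def _noiseless_field_cached(cfg_noseed: SyntheticLensConfig, timepoint: str) -> np.ndarray:
    out = _render_noiseless(cfg_noseed, timepoint)
    out.setflags(write=False)
    return out


def _noiseless_field(cfg: SyntheticLensConfig, timepoint: str) -> np.ndarray:
    """Continuous-valued image before noise and quantization.

    The field does not depend on the seed, so it is cached per
    (geometry, timepoint); callers receive a read-only view.
    """
    if timepoint not in ("before", "after"):
        raise ParameterError(f"timepoint must be before/after, got {timepoint!r}")
    return _noiseless_field_cached(replace(cfg, seed=0), timepoint)


def _render_noiseless(cfg: SyntheticLensConfig, timepoint: str) -> np.ndarray:
    _, _, dist = _grids(cfg)
    inside = dist <= cfg.radius
    img = np.full((cfg.height, cfg.width), cfg.background_level, dtype=np.float64)
    level = cfg.base_level if timepoint == "before" else cfg.base_level * cfg.aging_factor
    img[inside] = level
    if timepoint == "after" and cfg.severity > 0:
        img += cfg.severity * _unit_texture(cfg)
    if cfg.vignette_strength > 0:
        cx_f, cy_f = cfg.width / 2.0, cfg.height / 2.0
        rows = np.arange(cfg.height, dtype=np.float64)[:, None]
        cols = np.arange(cfg.width, dtype=np.float64)[None, :]
        d = np.hypot(cols - cx_f, rows - cy_f)
        img *= 1.0 - cfg.vignette_strength * (d / d.max()) ** 2
    return img


def _quantize(field_: np.ndarray) -> np.ndarray:
    return np.clip(np.floor(field_ + 0.5), 0, 255).astype(np.uint8)


@lru_cache(maxsize=16)
def _ground_truth_cached(cfg_noseed: SyntheticLensConfig) -> GroundTruth:
    mask = disc_mask(cfg_noseed)
    s_b = float(_quantize(_noiseless_field(cfg_noseed, "before"))[mask].sum(dtype=np.int64))
    s_a = float(_quantize(_noiseless_field(cfg_noseed, "after"))[mask].sum(dtype=np.int64))
    return GroundTruth(
        mask=mask, sum_before_expected=s_b, sum_after_expected=s_a, qdfi_expected=s_b / s_a
    )


def ground_truth(cfg: SyntheticLensConfig) -> GroundTruth:
    """Expected sums over the analytic disc mask of the quantized noiseless pair."""
    return _ground_truth_cached(replace(cfg, seed=0))


def simulate_lens_image(
    cfg: SyntheticLensConfig, timepoint: str
) -> tuple[GreyImage, GroundTruth]:
    """Render one 8-bit phantom image plus the pair's ground truth.

    Additive Gaussian noise (``noise_sd``) is drawn independently per
    timepoint from a stream derived from ``cfg.seed``; identical configs
    give bitwise-identical images.
    """
    field_ = _noiseless_field(cfg, timepoint)
    if timepoint == "after":
        mask = disc_mask(cfg)
        if field_[mask].mean() > 250:
            raise ValidationError("phantom saturated: mean disc value above 250")
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed), 0 if timepoint == "before" else 1])
        )
        field_ = field_ + rng.normal(0.0, cfg.noise_sd, size=field_.shape)
    img = GreyImage(pixels=_quantize(field_))
    return img, ground_truth(cfg)


def expected_qdfi(cfg: SyntheticLensConfig, quantize: bool = True) -> float:
    """Noise-free expected quotient for a config.

    With ``quantize=True`` (the default) the expectation is over the 8-bit
    rendered field, which is what the pipeline measures on a noiseless
    phantom.  With ``quantize=False`` the continuous closed form
    ``S_b / (a*S_b + dS)`` is evaluated by direct summation, where ``S_b``
    is the base disc sum, ``a`` the aging factor, and ``dS`` the texture
    mass added at the given severity.
    """
    mask = disc_mask(cfg)
    if quantize:
        gt = ground_truth(cfg)
        return gt.qdfi_expected
    s_b = float(_noiseless_field(cfg, "before")[mask].sum())
    s_a = float(_noiseless_field(cfg, "after")[mask].sum())
    return s_b / s_a


# ---------------------------------------------------------------------------
# paired spectra


@dataclass(frozen=True)
class SpectrumConfig:
    """Parameters of one paired before/after spectrum.

    The before-spectrum is a sigmoidal UV cut-on rising to ``plateau``;
    the after-spectrum is the clean curve times the attenuation profile,
    with independent measurement noise on each timepoint.
    """

    seed: int = 0
    plateau: float = 0.85
    cutoff_nm: float = 420.0
    slope: float = 15.0
    attenuation: tuple = ("uniform", 1.0)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.plateau <= 1.0:
            raise ParameterError(f"plateau must be in (0, 1], got {self.plateau}")
        if not 380.0 <= self.cutoff_nm <= 780.0:
            raise ParameterError(f"cutoff_nm must be in [380, 780], got {self.cutoff_nm}")
        if self.slope <= 0:
            raise ParameterError("slope must be > 0")
        kind = self.attenuation[0]
        factors = self.attenuation[1:]
        if kind not in ("uniform", "blueweighted") or len(factors) != (1 if kind == "uniform" else 2):
            raise ParameterError(f"bad attenuation spec {self.attenuation!r}")
        for k in factors:
            if not 0.0 < k <= 1.2:
                raise ParameterError(f"attenuation factor {k} outside (0, 1.2]")


def attenuation_profile(cfg: SpectrumConfig, wavelengths: np.ndarray) -> np.ndarray:
    """Attenuation factor per wavelength for a spectrum config."""
    kind = cfg.attenuation[0]
    if kind == "uniform":
        return np.full_like(wavelengths, float(cfg.attenuation[1]), dtype=np.float64)
    k_blue, k_red = float(cfg.attenuation[1]), float(cfg.attenuation[2])
    frac = np.clip((wavelengths - 400.0) / (700.0 - 400.0), 0.0, 1.0)
    return k_blue + frac * (k_red - k_blue)


def simulate_spectrum_pair(
    cfg: SpectrumConfig, lens_id: str = ""
) -> tuple[TransmissionSpectrum, TransmissionSpectrum]:
    """Paired spectra on the 380-780 nm grid at 1 nm steps."""
    wl = np.arange(380.0, 781.0, 1.0)
    clean = cfg.plateau / (1.0 + np.exp(-(wl - cfg.cutoff_nm) / cfg.slope))
    after_clean = clean * attenuation_profile(cfg, wl)
    if cfg.noise_sd > 0:
        rng_b = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 2]))
        rng_a = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 3]))
        before_t = clean + rng_b.normal(0.0, cfg.noise_sd, size=wl.shape)
        after_t = after_clean + rng_a.normal(0.0, cfg.noise_sd, size=wl.shape)
    else:
        before_t, after_t = clean, after_clean
    before_t = np.clip(before_t, 0.0, 1.4)
    after_t = np.clip(after_t, 0.0, 1.4)
    return (
        TransmissionSpectrum(wavelengths=wl, transmission=before_t, lens_id=lens_id, timepoint="before"),
        TransmissionSpectrum(wavelengths=wl, transmission=after_t, lens_id=lens_id, timepoint="after"),
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GroupSpec:
    """How many lenses a group gets and the templates they are drawn from."""

    n: int
    lens_cfg: SyntheticLensConfig
    spectrum_cfg: SpectrumConfig = SpectrumConfig()
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError(f"need n >= 2 per group, got {self.n}")
        if not 0 <= self.n_excluded <= self.n:
            raise ParameterError("n_excluded must be within [0, n]")


def _lens_seed(master_seed: int, group_index: int, lens_index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), group_index, lens_index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def iter_cohort(
    group_specs: dict[str, GroupSpec], master_seed: int
):
    """Yield ``(lens_id, group, cfg, spec_cfg, excluded)`` deterministically."""
    for gi, (group, spec) in enumerate(sorted(group_specs.items())):
        for li in range(spec.n):
            seed = _lens_seed(master_seed, gi, li)
            lens_id = f"{group}_{li + 1:03d}"
            cfg = replace(spec.lens_cfg, seed=seed)
            spec_cfg = replace(spec.spectrum_cfg, seed=seed)
            yield lens_id, group, cfg, spec_cfg, li < spec.n_excluded


def simulate_cohort(
    group_specs: dict[str, GroupSpec], master_seed: int, outdir: str | Path
) -> CohortManifest:
    """Write a full synthetic cohort (images, spectra, manifest, ground truth).

    Per-lens seeds derive deterministically from ``master_seed``; two runs
    with the same seed produce byte-identical manifests.
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "spectra").mkdir(parents=True, exist_ok=True)
    records = []
    truths: dict[str, dict] = {}
    for lens_id, group, cfg, spec_cfg, excluded in iter_cohort(group_specs, master_seed):
        before_img, gt = simulate_lens_image(cfg, "before")
        after_img, _ = simulate_lens_image(cfg, "after")
        b_img = f"images/{lens_id}_before.png"
        a_img = f"images/{lens_id}_after.png"
        b_sp = f"spectra/{lens_id}_before.csv"
        a_sp = f"spectra/{lens_id}_after.csv"
        write_grey_image(before_img, outdir / b_img)
        write_grey_image(after_img, outdir / a_img)
        before_sp, after_sp = simulate_spectrum_pair(spec_cfg, lens_id=lens_id)
        write_spectrum_csv(before_sp, outdir / b_sp)
        write_spectrum_csv(after_sp, outdir / a_sp)
        truths[lens_id] = {
            "qdfi_expected": gt.qdfi_expected,
            "sum_before_expected": gt.sum_before_expected,
            "sum_after_expected": gt.sum_after_expected,
            "seed": cfg.seed,
        }
        records.append(
            ManifestRecord(
                lens_id=lens_id,
                group=group,
                before_image=b_img,
                after_image=a_img,
                before_spectrum=b_sp,
                after_spectrum=a_sp,
                excluded=excluded,
                exclusion_reason="obvious damage after irradiation" if excluded else "",
            )
        )
    manifest = CohortManifest(records=tuple(records), root=str(outdir))
    write_manifest(manifest, outdir / "manifest.csv")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truths, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# calibrated preset


def calibrate_severity(cfg: SyntheticLensConfig, target_q: float) -> float:
    """Severity making the continuous expected quotient equal ``target_q``.

    Solves ``target = S_b / (a*S_b + s*M1)`` for s, where M1 is the texture
    mass at severity 1, summed directly over the noiseless texture.
    """
    if not 0 < target_q <= 1:
        raise ParameterError(f"target quotient must be in (0, 1], got {target_q}")
    mask = disc_mask(cfg)
    s_b = cfg.base_level * float(mask.sum())
    needed = s_b * (1.0 / target_q - cfg.aging_factor)
    if needed < 0:
        raise ParameterError("aging factor alone already overshoots the target quotient")
    if needed == 0:
        return 0.0
    m1 = float(_unit_texture(cfg)[mask].sum())
    if m1 <= 0:
        raise ParameterError(f"phenotype {cfg.phenotype} adds no texture mass")
    severity = needed / m1
    if severity > 1.0:
        raise ParameterError(
            f"target quotient {target_q} unreachable at severity <= 1 for {cfg.phenotype}"
        )
    return severity


def effect_size_preset(
    width: int = 480,
    height: int = 270,
    n_per_group: dict[str, int] | int = 20,
    noise_sd: float = 2.0,
    exclusions: dict[str, int] | None = None,
) -> dict[str, GroupSpec]:
    """Group specs whose expected quotients match the published effect sizes.

    Aging alone sets the control quotient (0.82); each irradiated group's
    severity is calibrated analytically so its continuous expected quotient
    hits the group target.  Calibrated to output, not mechanistic.
    """
    aging = 1.0 / EFFECT_TARGETS["CONTROL"]
    specs: dict[str, GroupSpec] = {}
    for group, target in EFFECT_TARGETS.items():
        n = n_per_group if isinstance(n_per_group, int) else n_per_group[group]
        base = SyntheticLensConfig(
            width=width,
            height=height,
            aging_factor=aging,
            phenotype=EFFECT_PHENOTYPES[group],
            noise_sd=noise_sd,
        )
        severity = 0.0 if group == "CONTROL" else calibrate_severity(base, target)
        lens_cfg = replace(base, severity=severity)
        spectrum_cfg = SpectrumConfig(attenuation=EFFECT_ATTENUATION[group], noise_sd=0.02)
        specs[group] = GroupSpec(
            n=n,
            lens_cfg=lens_cfg,
            spectrum_cfg=spectrum_cfg,
            n_excluded=0 if exclusions is None else exclusions.get(group, 0),
        )
    return specs
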