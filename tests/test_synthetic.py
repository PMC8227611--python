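import filecmp

import numpy as np
import pytest

from lenscat.errors import ParameterError, ValidationError
from lenscat.synthetic import (
    EFFECT_TARGETS,
    GroupSpec,
    SpectrumConfig,
    SyntheticLensConfig,
    attenuation_profile,
    calibrate_severity,
    disc_mask,
    expected_qdfi,
    effect_size_preset,
    simulate_cohort,
    simulate_lens_image,
    simulate_spectrum_pair,
)


class TestSimulateLensImage:
    def test_null_effect_after_identical_to_before(self, quarter_cfg):
        cfg = quarter_cfg(severity=0.0, aging_factor=1.0, noise_sd=0.0)
        before, _ = simulate_lens_image(cfg, "before")
        after, _ = simulate_lens_image(cfg, "after")
        assert np.array_equal(before.pixels, after.pixels)

    def test_analytic_disc_sum(self, quarter_cfg):
        cfg = quarter_cfg(noise_sd=0.0, phenotype="NONE")
        img, gt = simulate_lens_image(cfg, "before")
        area = int(gt.mask.sum())
        assert int(img.pixels[gt.mask].sum(dtype=np.int64)) == 30 * area
        assert gt.sum_before_expected == 30 * area

    def test_seed_reproducibility_bitwise(self, quarter_cfg):
        cfg = quarter_cfg(seed=42, noise_sd=3.0)
        a1, _ = simulate_lens_image(cfg, "after")
        a2, _ = simulate_lens_image(cfg, "after")
        assert np.array_equal(a1.pixels, a2.pixels)

    def test_different_timepoints_get_independent_noise(self, quarter_cfg):
        cfg = quarter_cfg(seed=42, aging_factor=1.0, noise_sd=3.0)
        before, _ = simulate_lens_image(cfg, "before")
        after, _ = simulate_lens_image(cfg, "after")
        assert not np.array_equal(before.pixels, after.pixels)

    def test_saturated_phantom_rejected(self, quarter_cfg):
        cfg = quarter_cfg(base_level=220.0, aging_factor=1.2, noise_sd=0.0)
        with pytest.raises(ValidationError, match="saturated"):
            simulate_lens_image(cfg, "after")

    def test_disc_must_fit_frame(self):
        with pytest.raises(ParameterError, match="margin"):
            SyntheticLensConfig(width=480, height=270, disc_radius=140.0)

    @pytest.mark.parametrize("phenotype", ["NUC", "COR", "PSC", "YSUT"])
    def test_phenotype_texture_brightens_after_image(self, quarter_cfg, phenotype):
        cfg = quarter_cfg(phenotype=phenotype, severity=0.5, aging_factor=1.0)
        before, gt = simulate_lens_image(cfg, "before")
        after, _ = simulate_lens_image(cfg, "after")
        s_b = int(before.pixels[gt.mask].sum(dtype=np.int64))
        s_a = int(after.pixels[gt.mask].sum(dtype=np.int64))
        assert s_a > s_b
        # texture fully contained in the disc
        outside = ~gt.mask
        assert np.array_equal(before.pixels[outside], after.pixels[outside])


class TestExpectedQdfi:
    def test_aging_only_is_inverse_aging(self, quarter_cfg):
        for a in (1.0, 1.2, 1.37):
            cfg = quarter_cfg(aging_factor=a)
            assert expected_qdfi(cfg, quantize=False) == pytest.approx(1.0 / a, abs=1e-12)

    def test_quantized_matches_continuous_on_integer_levels(self, quarter_cfg):
        cfg = quarter_cfg(aging_factor=1.2)  # 30 * 1.2 = 36 exactly
        assert expected_qdfi(cfg) == pytest.approx(30.0 / 36.0, abs=1e-12)

    def test_texture_mass_controls_quotient(self, quarter_cfg):
        # calibrated so the texture adds 25% of the base sum -> 1/1.25
        cfg = quarter_cfg(aging_factor=1.0, phenotype="NUC")
        sev = calibrate_severity(cfg, 0.8)
        from dataclasses import replace

        cfg = replace(cfg, severity=sev)
        assert expected_qdfi(cfg, quantize=False) == pytest.approx(0.8, abs=1e-9)

    @pytest.mark.parametrize("phenotype,severity,aging", [
        ("NONE", 0.0, 1.2),
        ("NUC", 0.3, 1.2),
        ("COR", 0.27, 1.22),
        ("PSC", 0.25, 1.22),
        ("YSUT", 0.5, 1.1),
    ])
    def test_pipeline_matches_oracle_on_noiseless_phantom(self, quarter_cfg, phenotype, severity, aging):
        from lenscat.scoring import ScoringParams, score_pair

        cfg = quarter_cfg(phenotype=phenotype, severity=severity, aging_factor=aging)
        before, _ = simulate_lens_image(cfg, "before")
        after, _ = simulate_lens_image(cfg, "after")
        _, _, q = score_pair(before, after, ScoringParams(sigma=1.25))
        assert q == pytest.approx(expected_qdfi(cfg), rel=0.005)


class TestSimulateSpectrumPair:
    def test_unit_attenuation_gives_identity(self):
        before, after = simulate_spectrum_pair(SpectrumConfig(attenuation=("uniform", 1.0)))
        assert np.array_equal(before.transmission, after.transmission)

    def test_uniform_attenuation_exact(self):
        cfg = SpectrumConfig(attenuation=("uniform", 0.95))
        before, after = simulate_spectrum_pair(cfg)
        ok = before.transmission > 1e-9
        assert np.allclose(after.transmission[ok] / before.transmission[ok], 0.95)

    def test_blueweighted_profile_interpolation(self):
        cfg = SpectrumConfig(attenuation=("blueweighted", 0.5, 0.9))
        wl = np.array([380.0, 400.0, 550.0, 700.0, 780.0])
        prof = attenuation_profile(cfg, wl)
        assert prof[0] == prof[1] == 0.5  # clamped below 400
        assert prof[2] == pytest.approx(0.7)  # midpoint
        assert prof[3] == prof[4] == 0.9  # clamped above 700

    def test_grid_is_one_nm_full_range(self):
        before, _ = simulate_spectrum_pair(SpectrumConfig())
        assert before.wavelengths[0] == 380.0
        assert before.wavelengths[-1] == 780.0
        assert len(before) == 401

    def test_bad_attenuation_rejected(self):
        with pytest.raises(ParameterError):
            SpectrumConfig(attenuation=("uniform", 1.5))
        with pytest.raises(ParameterError):
            SpectrumConfig(attenuation=("blueweighted", 0.0, 0.9))


class TestSimulateCohort:
    def test_study_sized_cohort(self, tmp_path):
        specs = effect_size_preset(
            n_per_group={"UVB311": 24, "UVA370": 22, "BLUE460": 28, "CONTROL": 80},
            exclusions={"UVB311": 2, "BLUE460": 2},
        )
        manifest = simulate_cohort(specs, master_seed=1, outdir=tmp_path / "cohort")
        assert len(manifest) == 154
        assert manifest.group_counts() == {"UVB311": 24, "UVA370": 22, "BLUE460": 28, "CONTROL": 80}
        assert manifest.effective_counts() == {"UVB311": 22, "UVA370": 22, "BLUE460": 26, "CONTROL": 80}

    def test_same_master_seed_byte_identical_manifests(self, tmp_path):
        specs = {"CONTROL": GroupSpec(n=2, lens_cfg=SyntheticLensConfig(width=480, height=270, aging_factor=1.1, noise_sd=2.0))}
        simulate_cohort(specs, master_seed=9, outdir=tmp_path / "a")
        simulate_cohort(specs, master_seed=9, outdir=tmp_path / "b")
        assert filecmp.cmp(tmp_path / "a" / "manifest.csv", tmp_path / "b" / "manifest.csv", shallow=False)
        assert filecmp.cmp(tmp_path / "a" / "ground_truth.json", tmp_path / "b" / "ground_truth.json", shallow=False)
        img = "images/CONTROL_001_after.png"
        assert (tmp_path / "a" / img).read_bytes() == (tmp_path / "b" / img).read_bytes()


class TestFig6Preset:
    def test_expected_quotients_hit_targets(self):
        specs = effect_size_preset()
        for group, target in EFFECT_TARGETS.items():
            q = expected_qdfi(specs[group].lens_cfg, quantize=False)
            assert q == pytest.approx(target, abs=1e-6), group

    def test_control_is_aging_only(self):
        specs = effect_size_preset()
        assert specs["CONTROL"].lens_cfg.severity == 0.0
        assert specs["CONTROL"].lens_cfg.aging_factor > 1.0

    def test_expected_quotients_strictly_ordered(self):
        specs = effect_size_preset()
        q = {g: expected_qdfi(s.lens_cfg, quantize=False) for g, s in specs.items()}
        assert q["BLUE460"] < q["UVA370"] < q["UVB311"] < q["CONTROL"]
        for group, spec in specs.items():
            assert 0.0 <= spec.lens_cfg.severity <= 1.0, group

    def test_unreachable_target_rejected(self, quarter_cfg):
        cfg = quarter_cfg(aging_factor=1.3, phenotype="NUC")
        with pytest.raises(ParameterError):
            calibrate_severity(cfg, 0.9)  # aging alone already below 0.9
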