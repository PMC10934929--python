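"""The synthetic transmittance generator: reproducibility, structure, nulls."""

import numpy as np
import pytest

from candlepls import (FERTILE, NONFERTILE, GeneratorConfig,
                       SyntheticFrameSpec, generate_hypercube,
                       generate_spectra, mean_spectrum, run_day, segment_eggs)


class TestConfig:
    def test_defaults_carry_study_imbalance(self):
        cfg = GeneratorConfig()
        assert cfg.n_fertile == 312 and cfg.n_nonfertile == 23
        assert cfg.n_bands == 167

    def test_fertile_amplitude_must_decay_through_day3(self):
        with pytest.raises(ValueError, match="non-increasing"):
            GeneratorConfig(fertile_amp=(0.8, 0.9, 0.7, 0.6, 0.5))

    def test_validation(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_fertile=0)
        with pytest.raises(ValueError):
            GeneratorConfig(noise_sd=-0.1)
        with pytest.raises(ValueError):
            GeneratorConfig(day=5)
        with pytest.raises(ValueError):
            GeneratorConfig(peak_band=200)

    def test_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig(seed=42, separation=0.1)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert GeneratorConfig.from_file(path) == cfg
        assert GeneratorConfig.from_file(path).config_hash() == cfg.config_hash()


class TestGenerateSpectra:
    def test_bit_reproducible_from_seed(self):
        a = generate_spectra(GeneratorConfig(seed=9))
        b = generate_spectra(GeneratorConfig(seed=9))
        assert np.array_equal(a.X, b.X)
        assert a.y.tolist() == b.y.tolist()

    def test_different_seeds_differ(self):
        a = generate_spectra(GeneratorConfig(seed=1))
        b = generate_spectra(GeneratorConfig(seed=2))
        assert not np.array_equal(a.X, b.X)

    def test_default_counts_match_day0_cohort(self):
        spectra = generate_spectra(GeneratorConfig())
        assert spectra.n == 335
        assert spectra.class_counts() == {FERTILE: 312, NONFERTILE: 23}

    def test_null_configuration_classes_indistinguishable(self):
        """At separation 0 the class-conditional mean spectra agree to within
        3 standard errors per band."""
        cfg = GeneratorConfig(separation=0.0, seed=13)
        spectra = generate_spectra(cfg)
        xf = spectra.X[spectra.y == FERTILE]
        xn = spectra.X[spectra.y == NONFERTILE]
        se = np.sqrt(xf.var(0, ddof=1) / len(xf) + xn.var(0, ddof=1) / len(xn))
        diff = np.abs(xf.mean(0) - xn.mean(0))
        ok = se > 0
        assert np.all(diff[ok] < 3 * se[ok])

    def test_peak_sits_at_configured_band(self):
        cfg = GeneratorConfig(noise_sd=0.0)
        spectra = generate_spectra(cfg)
        assert int(np.argmax(spectra.X[0])) == cfg.peak_band - 1

    def test_fertile_peak_decays_with_incubation_day(self):
        peaks = []
        for day in range(4):
            cfg = GeneratorConfig(day=day, noise_sd=0.0, n_fertile=2,
                                  n_nonfertile=2)
            spectra = generate_spectra(cfg)
            peaks.append(spectra.X[0].max())
        assert all(b <= a for a, b in zip(peaks, peaks[1:]))

    def test_noise_has_advertised_perband_scale(self):
        cfg = GeneratorConfig(separation=0.0, noise_sd=0.05, n_fertile=4000,
                              n_nonfertile=2, seed=3)
        spectra = generate_spectra(cfg)
        sd = spectra.X[spectra.y == FERTILE].std(0, ddof=1)
        interior = slice(10, 157)  # truncation at zero can bite at the edges
        assert np.allclose(sd[interior], 0.05, rtol=0.15)


class TestGenerateHypercube:
    def test_zero_noise_pixels_equal_template(self):
        cfg = GeneratorConfig(noise_sd=0.0, seed=0)
        frame = SyntheticFrameSpec()
        cube = generate_hypercube(cfg, frame)
        footprints = frame.footprints()
        for fp, label in zip(footprints, frame.egg_classes):
            tmpl = cfg.template(label)
            assert np.allclose(cube.data[fp], tmpl)

    def test_segmentation_recovers_footprints(self):
        cfg = GeneratorConfig(seed=5)
        frame = SyntheticFrameSpec()
        cube = generate_hypercube(cfg, frame)
        masks = segment_eggs(cube)
        assert len(masks) == 4
        footprints = frame.footprints()
        for m in masks:
            best = max(footprints, key=lambda f: (f & m.grid).sum())
            agreement = (best & m.grid).sum() / (best | m.grid).sum()
            assert agreement >= 0.99

    def test_contrast_peaks_at_segmentation_band(self):
        cfg = GeneratorConfig(noise_sd=0.0)
        cube = generate_hypercube(cfg, SyntheticFrameSpec())
        fg = cube.band(38)[cube.band(38) > 0.1].mean()
        bg = SyntheticFrameSpec().background_level
        contrast_38 = fg - bg
        fg1 = cube.band(1)[cube.band(38) > 0.1].mean()
        assert contrast_38 > fg1 - bg

    def test_overlapping_ellipses_rejected(self):
        frame = SyntheticFrameSpec(egg_centers=((26, 40), (26, 50), (70, 40),
                                                (70, 120)))
        with pytest.raises(ValueError, match="overlap"):
            generate_hypercube(GeneratorConfig(), frame)

    def test_offframe_ellipse_rejected(self):
        frame = SyntheticFrameSpec(egg_centers=((5, 40), (26, 120), (70, 40),
                                                (70, 120)))
        with pytest.raises(ValueError, match="fit"):
            generate_hypercube(GeneratorConfig(), frame)


def test_pipeline_difficulty_monotone_in_separation():
    """Overall accuracy of the full pipeline never gets worse as the class
    gap grows (3 seeded replicates per gap, one-misclassification slack)."""
    noise_sd = 0.02
    grid = (2, 4, 6)
    n = 60 + 8
    for seed in (101, 102, 103):
        ovas = []
        for mult in (0, 1, 2, 5, 10):
            cfg = GeneratorConfig(n_fertile=60, n_nonfertile=8,
                                  noise_sd=noise_sd,
                                  separation=mult * noise_sd, seed=seed)
            result = run_day(generate_spectra(cfg), component_grid=grid)
            best = max(s.ova for s in result.thresholds.summaries)
            ovas.append(best)
        slack = 100.0 / n  # one misclassification
        assert all(b >= a - slack for a, b in zip(ovas, ovas[1:])), \
            f"seed {seed}: OVA sequence {ovas} not non-decreasing"
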