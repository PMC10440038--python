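"""Phantom generator: shapes, determinism, class contrasts, split rule,
and the solvability/neutrality guarantees of the synthetic corpus."""

from dataclasses import replace

import numpy as np
import pytest

from thyfuse.errors import (DegenerateSplitError, EmptyRegistryError,
                            SpecValidationError)
from thyfuse.synthetic import (CaseSpec, default_registry, contour_radii,
                               generate_dataset, irt_peak_statistic,
                               pixel_statistic_scores, sample_case,
                               stratified_split, synthesize_irt_image,
                               synthesize_us_image, temperature_field,
                               us_intensity_statistic)


def specs(n_benign, n_malignant, probs, seed):
    return generate_dataset(n_benign, n_malignant, probs, seed=seed).cases


class TestUltrasoundPhantom:
    def test_shape_and_range(self, rng):
        spec = sample_case("c0", "malignant", ("US", "IRT"), rng)
        img = synthesize_us_image(spec)
        assert img.shape == (512, 512)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_seeded_determinism(self, rng):
        spec = sample_case("c0", "benign", ("US",), rng)
        assert np.array_equal(synthesize_us_image(spec), synthesize_us_image(spec))

    def test_malignant_contours_are_more_irregular(self):
        """Monte-Carlo check of the generator's morphology contrast: mean
        radial variance of the boundary contour, 100 cases per class."""
        angles = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        cases = specs(100, 100, (1.0, 0.0, 0.0), seed=21)
        var = {"benign": [], "malignant": []}
        for c in cases:
            var[c.label].append(np.var(contour_radii(c, angles)))
        assert np.mean(var["malignant"]) > np.mean(var["benign"])

    def test_geometry_outside_frame_is_rejected(self, rng):
        spec = sample_case("c0", "benign", ("US",), rng)
        bad = replace(spec, center=(5.0, 5.0))
        with pytest.raises(SpecValidationError, match="frame"):
            synthesize_us_image(bad)


class TestThermogramPhantom:
    def test_shape_is_320x240_rgb(self, rng):
        spec = sample_case("c0", "benign", ("IRT",), rng)
        img = synthesize_irt_image(spec)
        assert img.shape == (240, 320, 3)          # 320 wide, 240 high
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_zero_asymmetry_field_is_mirror_symmetric_before_noise(self, rng):
        spec = sample_case("c0", "benign", ("IRT",), rng)
        sym = replace(spec, asymmetry=0.0)
        field = temperature_field(sym, noise=False)
        np.testing.assert_allclose(field, field[:, ::-1], atol=1e-5)

    def test_malignant_hotspots_are_hotter(self):
        """Monte-Carlo check of the thermal contrast: mean peak temperature
        over 100 IRT-informative cases per class."""
        cases = specs(100, 100, (0.0, 1.0, 0.0), seed=22)
        peaks = {"benign": [], "malignant": []}
        for c in cases:
            peaks[c.label].append(irt_peak_statistic(synthesize_irt_image(c)))
        assert np.mean(peaks["malignant"]) > np.mean(peaks["benign"])


class TestRegistry:
    def test_default_registry_matches_cohort_size(self):
        reg = default_registry(seed=0)
        assert len(reg) == 2864
        assert reg.counts() == {"benign": 1536, "malignant": 1328}

    def test_generation_is_reproducible_from_seed(self):
        a = generate_dataset(20, 30, (0.2, 0.3, 0.5), seed=4)
        b = generate_dataset(20, 30, (0.2, 0.3, 0.5), seed=4)
        assert a.cases == b.cases

    def test_empty_registry_is_rejected(self):
        with pytest.raises(EmptyRegistryError):
            generate_dataset(0, 0, (0.0, 0.0, 1.0), seed=0)

    def test_invalid_probabilities_are_rejected(self):
        with pytest.raises(SpecValidationError):
            generate_dataset(5, 5, (0.5, 0.5, 0.5), seed=0)


class TestStratifiedSplit:
    @pytest.mark.parametrize("n,expected", [
        (1536, (922, 307, 307)),
        (1328, (798, 265, 265)),
        (10, (6, 2, 2)),
        (7, (5, 1, 1)),
    ])
    def test_per_class_floor_then_remainder_counts(self, n, expected):
        reg = generate_dataset(n, 5, (0.0, 0.0, 1.0), seed=1)
        split = stratified_split(reg, seed=1)
        tags = [split.partitions[c.case_id] for c in split.cases
                if c.label == "benign"]
        got = (tags.count("train"), tags.count("val"), tags.count("test"))
        assert got == expected

    def test_split_is_a_partition(self):
        reg = generate_dataset(50, 40, (0.0, 0.0, 1.0), seed=2)
        split = stratified_split(reg, seed=2)
        assert set(split.partitions) == {c.case_id for c in reg.cases}
        ids = [c.case_id for c in split.cases]
        assert len(ids) == len(set(ids))

    def test_too_small_class_raises_degenerate_split(self):
        reg = generate_dataset(10, 2, (0.0, 0.0, 1.0), seed=3)
        with pytest.raises(DegenerateSplitError):
            stratified_split(reg, seed=3)


class TestClassSignalGuarantees:
    def test_trivial_classifier_solves_both_informative_corpus(self):
        """Mean nodule intensity + peak temperature, thresholded at the
        pooled midpoint, exceeds 0.8 accuracy on 200 generated cases."""
        cases = specs(100, 100, (0.0, 0.0, 1.0), seed=31)
        us = [synthesize_us_image(c) for c in cases]
        irt = [synthesize_irt_image(c) for c in cases]
        scores = pixel_statistic_scores(us, irt)
        labels = np.array([c.label == "malignant" for c in cases])
        acc = ((scores > scores.mean()) == labels).mean()
        assert acc > 0.8

    def test_uninformative_irt_channel_is_chance_level(self):
        """On a US-only-informative corpus the IRT statistic classifies at
        0.5 +/- 0.07 over 400 cases."""
        cases = specs(200, 200, (1.0, 0.0, 0.0), seed=32)
        stat = np.array([irt_peak_statistic(synthesize_irt_image(c)) for c in cases])
        labels = np.array([c.label == "malignant" for c in cases])
        acc = ((stat > stat.mean()) == labels).mean()
        assert abs(acc - 0.5) <= 0.07
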