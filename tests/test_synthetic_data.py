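"""Generator contracts: determinism, aggregation, bleaching, fasciculation."""

import numpy as np
import pytest

from neurocult import (
    CultureSpec,
    ParameterError,
    circular_variance,
    fit_interaction_model,
    generate_factorial_dataset,
    generate_timecourse,
)


class TestCultureSpecValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_days", 0),
            ("image_shape", (32, 128)),
            ("cluster_attraction", 1.5),
            ("fasciculation_strength", -0.1),
            ("bleach_rate", 1.0),
            ("death_drop", 0.0),
            ("death_day", 99),
            ("noise_sd", -1.0),
            ("bit_depth", 8),
        ],
    )
    def test_out_of_range_fields_name_the_field(self, field, value):
        with pytest.raises(ParameterError, match=field):
            CultureSpec(**{field: value})


class TestTimecourse:
    def test_same_seed_bit_identical(self):
        spec = CultureSpec(seed=3, n_days=3)
        a, _ = generate_timecourse(spec)
        b, _ = generate_timecourse(spec)
        for ia, ib in zip(a, b):
            assert ia.pixels.dtype == ib.pixels.dtype
            assert np.array_equal(ia.pixels, ib.pixels)

    def test_returns_n_days_images(self, default_timecourse):
        spec, images, truth = default_timecourse
        assert len(images) == spec.n_days
        assert len(truth.soma_masks) == spec.n_days

    def test_no_attraction_keeps_soma_positions(self):
        _, truth = generate_timecourse(CultureSpec(seed=1, n_days=2, cluster_attraction=0.0))
        assert np.allclose(truth.soma_centroids[0], truth.soma_centroids[1])

    def test_bleach_closed_form_decay(self):
        # static geometry isolates the multiplicative bleaching factor
        spec = CultureSpec(seed=2, n_days=4, bleach_rate=0.1, noise_sd=0.0,
                           cluster_attraction=0.0, neurite_growth_rate=0.0)
        _, truth = generate_timecourse(spec)
        ratios = truth.mean_intensity[1:] / truth.mean_intensity[:-1]
        assert np.allclose(ratios, 0.9)

    def test_full_fasciculation_aligns_orientations(self):
        _, truth = generate_timecourse(CultureSpec(seed=5, n_days=2, fasciculation_strength=1.0))
        assert circular_variance(truth.orientation_fields[-1]) < 0.01

    def test_orientation_variance_decreases_with_fasciculation(self):
        variances = []
        for f in (0.0, 0.25, 0.5, 0.75, 1.0):
            _, truth = generate_timecourse(
                CultureSpec(seed=5, n_days=2, fasciculation_strength=f))
            variances.append(circular_variance(truth.orientation_fields[-1]))
        assert all(a >= b for a, b in zip(variances, variances[1:]))

    def test_orientations_lie_in_half_circle(self, default_timecourse):
        _, _, truth = default_timecourse
        ori = truth.orientation_fields[-1]
        finite = ori[np.isfinite(ori)]
        assert finite.size and (finite >= 0).all() and (finite < np.pi).all()

    def test_masks_binary_and_disjoint(self, default_timecourse):
        _, _, truth = default_timecourse
        for soma, neur in zip(truth.soma_masks, truth.neurite_masks):
            assert soma.dtype == bool and neur.dtype == bool
            assert not (soma & neur).any()

    def test_soma_count_never_increases(self):
        _, truth = generate_timecourse(CultureSpec(seed=7, n_days=6, cluster_attraction=0.35))
        counts = truth.soma_counts
        assert (np.diff(counts) <= 0).all()
        assert counts[-1] < counts[0]  # aggregation actually happened

    def test_summed_perimeter_non_increasing_under_aggregation(self):
        _, truth = generate_timecourse(CultureSpec(seed=7, n_days=6, cluster_attraction=0.35))
        perims = np.array([p.sum() for p in truth.soma_perimeters])
        # sub-pixel disc motion can wobble the rasterised perimeter slightly
        assert (np.diff(perims) <= 4).all()
        assert perims[-1] < perims[0]

    def test_death_day_drops_intensity_by_death_drop(self):
        spec = CultureSpec(seed=9, n_days=5, death_day=3, death_drop=0.3, noise_sd=0.0,
                           cluster_attraction=0.0, neurite_growth_rate=0.0, bleach_rate=0.0)
        _, truth = generate_timecourse(spec)
        ratio = truth.mean_intensity[2] / truth.mean_intensity[1]
        assert ratio == pytest.approx(0.7)

    def test_bit_depth_variants(self):
        imgs16, _ = generate_timecourse(CultureSpec(seed=1, n_days=1, bit_depth=16))
        imgs32, _ = generate_timecourse(CultureSpec(seed=1, n_days=1, bit_depth=32))
        assert imgs16[0].pixels.dtype == np.uint16
        assert imgs32[0].pixels.dtype == np.float32


class TestFactorialDataset:
    def test_no_effects_no_noise_gives_intercept_everywhere(self):
        auc, _ = generate_factorial_dataset({}, 2, noise_sd=0.0, intercept=10.0)
        assert np.allclose(auc["auc"], 10.0)
        assert len(auc) == 8 * 2

    def test_media_effect_is_exact_mean_difference(self):
        auc, design = generate_factorial_dataset({"media": 5.0}, 3, noise_sd=0.0)
        merged = auc.merge(design, on="well")
        diff = merged.loc[merged["media"] == "BPI", "auc"].mean() \
            - merged.loc[merged["media"] == "NB", "auc"].mean()
        assert diff == pytest.approx(5.0)

    def test_parameter_recovery_within_three_se(self):
        truth = {"media": 2.0, "laminin": -1.0, "density": 0.5}
        auc, design = generate_factorial_dataset(truth, 50, plate_effects=(0.0, 1.0),
                                                 noise_sd=1.0, seed=11)
        result = fit_interaction_model(auc, design)
        for factor, beta in truth.items():
            row = result.terms.set_index("term").loc[factor]
            assert abs(row["beta"] - beta) < 3 * row["se"]

    def test_nonzero_plate_effects_need_two_plates(self):
        with pytest.raises(ParameterError, match="plate"):
            generate_factorial_dataset({}, 4, plate_effects=(1.0,))

    def test_too_few_wells_rejected(self):
        with pytest.raises(ParameterError, match="n_wells_per_condition"):
            generate_factorial_dataset({}, 1)
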