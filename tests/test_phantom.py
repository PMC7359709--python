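import math

import numpy as np
import pytest

from graftct.phantom import (
    DEFAULT_INTENSITIES,
    PhantomSpec,
    generate_phantom,
    load_spec,
    save_spec,
    synthetic_accumulation_table,
    thrombus_area_profile,
    truth_summary,
)


class TestThrombusProfile:
    def test_zero_amplitude_is_constant_baseline(self):
        spec = PhantomSpec(length=5.0, thrombus_baseline=3.0, thrombus_amplitude=0.0)
        prof = thrombus_area_profile(spec)
        assert np.allclose(prof.areas, 3.0)

    def test_clean_graft_profile_is_zero(self):
        spec = PhantomSpec(length=5.0, thrombus_baseline=0.0, thrombus_amplitude=0.0)
        assert not thrombus_area_profile(spec).areas.any()

    def test_same_seed_same_profile(self):
        a = thrombus_area_profile(PhantomSpec(length=5.0, rng_seed=5))
        b = thrombus_area_profile(PhantomSpec(length=5.0, rng_seed=5))
        np.testing.assert_array_equal(a.areas, b.areas)

    def test_profile_clipped_to_capacity(self):
        spec = PhantomSpec(length=5.0, thrombus_baseline=12.0, thrombus_amplitude=8.0)
        prof = thrombus_area_profile(spec)
        assert np.all(prof.areas >= 0)
        assert np.all(prof.areas <= spec.lumen_capacity + 1e-12)

    def test_custom_profile_exceeding_capacity_rejected(self):
        n = PhantomSpec(length=5.0).n_graft_slices
        with pytest.raises(ValueError, match="capacity"):
            PhantomSpec(length=5.0, custom_profile=(100.0,) * n)


class TestGeneratePhantom:
    def test_clean_cylinder_lumen_volume_closed_form(self, clean_lumen_phantom):
        spec, _, truth = clean_lumen_phantom
        expected = spec.lumen_capacity * truth.true_length
        assert truth.true_thrombus_volume == 0.0
        assert abs(truth.true_lumen_volume - expected) / expected < 0.02
        assert not truth.labels.mask_of("thrombus").any()

    def test_4mm_by_30mm_reference_volume(self):
        spec = PhantomSpec(
            length=30.0, thrombus_baseline=0.0, thrombus_amplitude=0.0, supersample=2,
            rng_seed=3,
        )
        _, truth = generate_phantom(spec)
        # pi * 2^2 * 30 = 376.99 mm^3 at the exactly realized length
        expected = math.pi * 4.0 * truth.true_length
        assert abs(truth.true_lumen_volume - expected) / expected < 0.02

    def test_no_noise_no_supersample_gives_pure_levels(self):
        spec = PhantomSpec(length=3.0, supersample=1, noise_sigma=0.0, rng_seed=2)
        image, _ = generate_phantom(spec)
        levels = set(DEFAULT_INTENSITIES["lumen_opaque"].values())
        assert set(np.unique(image.data)).issubset(levels)

    def test_determinism_bit_identical(self):
        spec = PhantomSpec(length=4.0, noise_sigma=5.0, rng_seed=9)
        img1, truth1 = generate_phantom(spec)
        img2, truth2 = generate_phantom(spec)
        np.testing.assert_array_equal(img1.data, img2.data)
        np.testing.assert_array_equal(truth1.labels.labels, truth2.labels.labels)

    def test_geometry_stable_under_noise_level(self):
        base = dict(length=4.0, rng_seed=9)
        _, t_quiet = generate_phantom(PhantomSpec(noise_sigma=0.0, **base))
        _, t_noisy = generate_phantom(PhantomSpec(noise_sigma=10.0, **base))
        np.testing.assert_array_equal(t_quiet.labels.labels, t_noisy.labels.labels)

    def test_more_thrombus_means_less_lumen(self):
        kw = dict(length=4.0, thrombus_amplitude=0.0, rng_seed=1)
        volumes = [
            generate_phantom(PhantomSpec(thrombus_baseline=b, **kw))[1].true_lumen_volume
            for b in (0.0, 3.0, 6.0)
        ]
        assert volumes[0] > volumes[1] > volumes[2]

    def test_supersampling_refines_toward_closed_form(self):
        errors = []
        for s in (1, 4, 8):
            spec = PhantomSpec(
                length=3.0, thrombus_baseline=0.0, thrombus_amplitude=0.0,
                supersample=s, rng_seed=0,
            )
            _, truth = generate_phantom(spec)
            expected = spec.lumen_capacity * truth.true_length
            errors.append(abs(truth.true_lumen_volume - expected))
        assert errors[2] <= errors[1] <= errors[0]

    def test_per_slice_conservation_within_capacity(self, four_material_phantom):
        spec, image, truth = four_material_phantom
        z0, z1 = truth.graft_span
        total = (
            truth.true_area_profiles["lumen"].areas[z0:z1]
            + truth.true_area_profiles["thrombus"].areas[z0:z1]
        )
        assert np.all(total <= spec.lumen_capacity + image.pixel_area)
        # occupancy quantization at supersample s underestimates by O(1/s^2)
        assert np.all(total >= spec.lumen_capacity - 2 * image.pixel_area)

    def test_fully_occluded_slices_have_zero_lumen(self):
        spec0 = PhantomSpec(length=3.0)
        n = spec0.n_graft_slices
        cap = spec0.lumen_capacity
        profile = [0.5] * n
        profile[n // 2] = cap
        spec = PhantomSpec(length=3.0, custom_profile=tuple(profile))
        _, truth = generate_phantom(spec)
        z0, _ = truth.graft_span
        lumen = truth.true_area_profiles["lumen"].areas
        assert lumen[z0 + n // 2] == 0.0
        assert lumen[z0 + n // 2 - 1] > 0.0


class TestTruthSummary:
    def test_label_volumes_match_stored_truth_within_voxelization(self, lumen_phantom):
        _, _, truth = lumen_phantom
        summary = truth_summary(truth)
        for material, stored in [
            ("lumen", truth.true_lumen_volume),
            ("thrombus", truth.true_thrombus_volume),
        ]:
            assert abs(summary[material].volume - stored) / stored < 0.02

    def test_lumen_span_length_matches_spec(self, lumen_phantom):
        spec, _, truth = lumen_phantom
        summary = truth_summary(truth)
        assert abs(summary["lumen"].length - spec.realized_length) <= spec.spacing

    def test_constant_profile_truth_sd_below_one_voxel_area(self):
        spec = PhantomSpec(length=4.0, thrombus_amplitude=0.0, eccentricity=0.0, rng_seed=4)
        image, truth = generate_phantom(spec)
        summary = truth_summary(truth)
        assert summary["thrombus"].area_sd <= image.pixel_area


class TestSerializationAndEndpoints:
    def test_spec_yaml_round_trip(self, tmp_path):
        spec = PhantomSpec(length=5.0, contrast_mode="four_material", rng_seed=42)
        path = tmp_path / "spec.yaml"
        save_spec(spec, path)
        assert load_spec(path) == spec

    def test_accumulation_table_group_sizes(self):
        df = synthetic_accumulation_table(seed=0)
        counts = df["material_group"].value_counts().to_dict()
        assert counts == {"PVA": 110, "ePTFE": 26, "collagen_ePTFE": 20}
        assert len(df) == 156
        assert (df["platelets_per_mm"] > 0).all()
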