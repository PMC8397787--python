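"""Rotation / offset-center resampling: geometry, count law, no padding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oralscope.resample import (
    DEFAULT_NT,
    PatchOutOfBoundsError,
    ResamplingConfig,
    build_training_set,
    expand_case,
    extract_rotated_patch,
    max_valid_patch_side,
    random_oversample,
    rotation_angles,
    sample_offset_centers,
)
from oralscope.samples import CLASS_NAMES, DatasetManifest, ImageSample
from oralscope.synth import generate_manifest


class TestRotationAngles:
    def test_default_theta(self):
        assert rotation_angles(15) == [-15.0, 0.0, 15.0]

    def test_zero_theta_collapses(self):
        assert rotation_angles(0) == [0.0]

    @settings(max_examples=30, deadline=None)
    @given(theta=st.floats(min_value=0.01, max_value=90))
    def test_three_angles_symmetric_about_zero(self, theta):
        angles = rotation_angles(theta)
        assert len(angles) == 3
        assert angles[1] == 0.0
        assert angles[0] == -angles[2]


def brute_force_max_side(image_size, theta, offset_radius, n_angles=91):
    """Corner-tracing oracle: largest integer side with all corners in-bounds
    for every |angle| <= theta and worst-case offset of the center."""
    half_min = min(image_size) / 2.0
    angles = np.linspace(-theta, theta, n_angles)
    best = 0
    for s in range(int(2 * half_min) + 2):
        ok = True
        for a in np.deg2rad(angles):
            # rotated square corner reach along an axis
            reach = (s / 2.0) * (abs(np.cos(a)) + abs(np.sin(a)))
            if reach + offset_radius > half_min:
                ok = False
                break
        if ok:
            best = s
        else:
            break
    return best


class TestMaxValidPatchSide:
    def test_no_rotation_no_offset(self):
        assert max_valid_patch_side((512, 512), 0, 0) == 512

    def test_45_degrees_closed_form(self):
        assert max_valid_patch_side((512, 512), 45, 0) == int(512 / np.sqrt(2))

    @pytest.mark.parametrize(
        "size,theta,offset",
        [((768, 1024), 15, 20), ((512, 512), 15, 0), ((300, 400), 30, 10),
         ((200, 200), 60, 5)],
    )
    def test_matches_corner_tracing_oracle(self, size, theta, offset):
        assert max_valid_patch_side(size, theta, offset) == brute_force_max_side(
            size, theta, offset
        )


def brute_force_patch(img, center, angle, size):
    """Per-pixel inverse-map bilinear sampler, independent of the library."""
    ph, pw = size
    out = np.zeros((ph, pw) + img.shape[2:])
    a = np.deg2rad(angle)
    for i in range(ph):
        for j in range(pw):
            oi = i - (ph - 1) / 2.0
            oj = j - (pw - 1) / 2.0
            r = center[0] + np.cos(a) * oi - np.sin(a) * oj
            c = center[1] + np.sin(a) * oi + np.cos(a) * oj
            r0, c0 = int(np.floor(r)), int(np.floor(c))
            fr, fc = r - r0, c - c0
            acc = 0.0
            for dr, wr in ((0, 1 - fr), (1, fr)):
                for dc, wc in ((0, 1 - fc), (1, fc)):
                    rr = np.clip(r0 + dr, 0, img.shape[0] - 1)
                    cc = np.clip(c0 + dc, 0, img.shape[1] - 1)
                    acc = acc + wr * wc * img[rr, cc]
            out[i, j] = acc
    return out


class TestExtractRotatedPatch:
    def test_angle_zero_equals_plain_centered_crop(self):
        img = np.random.default_rng(0).uniform(0, 255, (65, 87, 3))
        center = (32.0, 43.0)
        patch = extract_rotated_patch(img, center, 0.0, (21, 21))
        np.testing.assert_allclose(patch, img[22:43, 33:54], atol=1e-9)

    def test_matches_per_pixel_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, (48, 64))
        patch = extract_rotated_patch(img, (24.0, 32.0), 15.0, (20, 22))
        expected = brute_force_patch(img, (24.0, 32.0), 15.0, (20, 22))
        np.testing.assert_allclose(patch, expected, atol=1e-4)

    def test_inverse_rotation_round_trip(self):
        # sample a large patch at +15 deg, then sample a small patch at -15
        # deg from it: equals the small patch sampled directly at 0 deg
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 255, (120, 160))
        img = np.cumsum(np.cumsum(img, 0), 1) / 1e4  # smooth field
        center = (60.0, 80.0)
        big = extract_rotated_patch(img, center, 15.0, (81, 81))
        back = extract_rotated_patch(big, (40.0, 40.0), -15.0, (31, 31))
        direct = extract_rotated_patch(img, center, 0.0, (31, 31))
        np.testing.assert_allclose(back, direct, rtol=0.02, atol=0.5)

    def test_out_of_bounds_raises_never_pads(self):
        img = np.zeros((40, 40))
        with pytest.raises(PatchOutOfBoundsError, match="no padding"):
            extract_rotated_patch(img, (20.0, 20.0), 45.0, (40, 40))

    def test_sentinel_border_never_sampled(self):
        # interior zeros, 1-px sentinel border; any geometry allowed by
        # max_valid_patch_side must yield a pure-zero patch
        rng = np.random.default_rng(3)
        for _ in range(50):
            h = int(rng.integers(40, 90))
            w = int(rng.integers(40, 90))
            img = np.zeros((h, w))
            img[0, :] = img[-1, :] = img[:, 0] = img[:, -1] = 1e6
            theta = float(rng.uniform(0, 40))
            offset = float(rng.uniform(0, 5))
            side = max_valid_patch_side((h - 2, w - 2), theta, offset)
            if side < 4:
                continue
            centers = sample_offset_centers(
                ((h - 1) / 2.0, (w - 1) / 2.0), 3, offset, int(rng.integers(1 << 30))
            )
            for c in centers:
                for a in rotation_angles(theta):
                    patch = extract_rotated_patch(img, c, a, (side, side))
                    assert patch.max() < 1.0


class TestSampleOffsetCenters:
    def test_nt_one_returns_center(self):
        assert sample_offset_centers((10.0, 20.0), 1, 5.0, 0) == [(10.0, 20.0)]

    def test_zero_radius_gives_copies(self):
        centers = sample_offset_centers((10.0, 20.0), 15, 0.0, 1)
        assert len(centers) == 15
        assert all(c == (10.0, 20.0) for c in centers)

    def test_uniform_disc_moments(self):
        centers = np.array(sample_offset_centers((0.0, 0.0), 1001, 20.0, 2))
        d = np.hypot(centers[1:, 0], centers[1:, 1])
        assert d.max() <= 20.0
        # mean distance of a uniform disc draw is 2R/3
        assert abs(d.mean() - 2 * 20.0 / 3) < 0.6

    def test_first_center_is_input_and_deterministic(self):
        a = sample_offset_centers((5.0, 5.0), 6, 3.0, 7)
        b = sample_offset_centers((5.0, 5.0), 6, 3.0, 7)
        assert a == b
        assert a[0] == (5.0, 5.0)


def _sample(label, sid="s0", size=(60, 80)):
    rng = np.random.default_rng(0)
    return ImageSample(label, "p0", sid,
                       pixels=rng.integers(0, 256, size + (3,), dtype=np.uint8))


class TestExpandCase:
    def test_cancer_yields_45_patches(self):
        ps = expand_case(_sample("cancer"), ResamplingConfig(), rng_seed=0)
        assert len(ps) == 3 * 15

    def test_normal_rotation_only(self):
        ps = expand_case(_sample("normal"), ResamplingConfig(), rng_seed=0)
        assert len(ps) == 3
        assert all(c == ps.centers[0] for c in ps.centers)

    def test_ulcer_nine_patches_all_in_bounds(self):
        s = _sample("ulcer")
        ps = expand_case(s, ResamplingConfig(), rng_seed=1)
        assert len(ps) == 9
        side = ps.patches[0].shape[0]
        h, w = s.pixels.shape[:2]
        for center, angle in zip(ps.centers, ps.angles):
            a = np.deg2rad(angle)
            reach = (side / 2.0) * (abs(np.cos(a)) + abs(np.sin(a)))
            assert center[0] - reach >= -0.5 and center[0] + reach <= h - 0.5
            assert center[1] - reach >= -0.5 and center[1] + reach <= w - 0.5

    def test_patch_determinism(self):
        a = expand_case(_sample("high_risk"), ResamplingConfig(), rng_seed=5)
        b = expand_case(_sample("high_risk"), ResamplingConfig(), rng_seed=5)
        for pa, pb in zip(a.patches, b.patches):
            np.testing.assert_array_equal(pa, pb)


class TestBuildTrainingSet:
    def test_count_law_random_manifest(self):
        m = generate_manifest([7, 5, 4, 3, 2], rng_seed=0)
        expanded = build_training_set(m, ResamplingConfig(), rng_seed=0,
                                      image_size=(192, 256))
        base = m.class_counts
        for cls in CLASS_NAMES:
            nt = 1 if cls == "normal" else DEFAULT_NT[cls]
            assert expanded.class_counts[cls] == base[cls] * 3 * nt

    def test_rotation_only_counts(self):
        m = generate_manifest([4, 3, 2, 2, 1], rng_seed=1)
        expanded = build_training_set(m, ResamplingConfig().rotation_only(),
                                      rng_seed=0, image_size=(192, 256))
        for cls in CLASS_NAMES:
            assert expanded.class_counts[cls] == m.class_counts[cls] * 3

    def test_empty_manifest(self):
        expanded = build_training_set(DatasetManifest(), ResamplingConfig(), 0)
        assert len(expanded) == 0
        assert all(v == 0 for v in expanded.class_counts.values())

    def test_count_law_invariant_over_seeds(self):
        m = generate_manifest([5, 4, 3, 2, 2], rng_seed=3)
        counts = {
            seed: build_training_set(m, ResamplingConfig(), rng_seed=seed,
                                     image_size=(96, 128)).class_counts
            for seed in range(5)
        }
        assert len({tuple(sorted(c.items())) for c in counts.values()}) == 1


class TestRandomOversample:
    def test_balances_to_majority(self):
        samples = [_sample("normal", f"n{i}") for i in range(10)]
        samples += [_sample("cancer", f"c{i}") for i in range(2)]
        out = random_oversample(DatasetManifest(samples=samples), rng_seed=0)
        assert out.class_counts["normal"] == 10
        assert out.class_counts["cancer"] == 10

    def test_already_balanced_unchanged(self):
        samples = [_sample("ulcer", f"u{i}") for i in range(3)]
        samples += [_sample("cancer", f"c{i}") for i in range(3)]
        m = DatasetManifest(samples=samples)
        out = random_oversample(m, rng_seed=0)
        assert len(out) == len(m)

    def test_duplicates_come_from_original_pool(self):
        samples = [_sample("normal", f"n{i}") for i in range(8)]
        samples += [_sample("low_risk", f"l{i}") for i in range(3)]
        out = random_oversample(DatasetManifest(samples=samples), rng_seed=1)
        originals = {s.source_id for s in samples}
        assert {s.source_id for s in out.samples} == originals
        low = [s for s in out.samples if s.label == "low_risk"]
        assert len(low) == 8
        assert {s.source_id for s in low} <= {f"l{i}" for i in range(3)}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            random_oversample(DatasetManifest(), 0)
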