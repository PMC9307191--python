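"""Green classification, darkness ordering and the weighted statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leafgreen import (
    COMMON_GREEN_CODES,
    ColorTable,
    EmptyProfileError,
    GreenProfile,
    RGBCode,
    build_profile,
    darkness_index,
    is_green,
    pool_profiles,
    weighted_stats,
)
from conftest import DARK, LIGHT, per_pixel_expansion, random_table


class TestGreenRule:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ((0, 43, 0), True),
            ((102, 128, 102), True),
            ((135, 120, 100), False),  # G < R
            ((50, 50, 50), False),  # equality is non-green
            ((0, 1, 0), True),
            ((10, 20, 20), False),  # G == B
        ],
    )
    def test_strict_inequalities(self, code, expected):
        assert is_green(code) is expected

    def test_all_common_codes_are_green(self):
        assert all(is_green(c) for c in COMMON_GREEN_CODES)


class TestDarknessIndex:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ((0, 43, 0), 0.0),
            ((102, 128, 102), 1.59375),  # 204/128
            ((51, 85, 0), 0.6),  # 51/85
        ],
    )
    def test_values(self, code, expected):
        assert darkness_index(code) == pytest.approx(expected, abs=0)

    def test_zero_green_channel_rejected(self):
        with pytest.raises(ValueError, match="G = 0"):
            darkness_index((10, 0, 10))


class TestBuildProfile:
    def test_filters_non_green_and_normalizes(self, mixed_table):
        prof = build_profile(mixed_table)
        assert prof.codes == [DARK, LIGHT]  # dark first
        np.testing.assert_allclose(prof.weights, [0.75, 0.25])
        assert abs(prof.weights.sum() - 1.0) < 1e-12

    def test_top_k_one(self, mixed_table):
        prof = build_profile(mixed_table, top_k=1)
        assert prof.codes == [DARK]
        assert prof.weights[0] == 1.0

    def test_top_k_drops_smallest_by_brute_force(self):
        rng = np.random.default_rng(5)
        greens = {}
        while len(greens) < 6:
            r, b = rng.integers(0, 120, 2)
            g = int(rng.integers(max(r, b) + 1, 256))
            greens[RGBCode(int(r), g, int(b))] = int(rng.integers(1, 1000))
        table = ColorTable("six", greens)
        prof = build_profile(table, top_k=5)
        # brute-force oracle: sort by count desc, darkness asc, rgb asc
        ranked = sorted(greens, key=lambda c: (-greens[c], darkness_index(c), c))
        assert set(prof.codes) == set(ranked[:5])
        assert abs(prof.weights.sum() - 1.0) < 1e-12

    def test_explicit_code_list(self, mixed_table):
        prof = build_profile(mixed_table, codes=[DARK])
        assert prof.codes == [DARK]

    def test_no_green_codes_diagnostic(self):
        table = ColorTable("red", {(200, 10, 10): 500, (90, 80, 70): 100})
        with pytest.raises(EmptyProfileError, match=r"\(200, 10, 10\)"):
            build_profile(table)

    def test_profile_sorted_dark_to_light(self):
        table = ColorTable("t", {c: 10 for c in COMMON_GREEN_CODES})
        prof = build_profile(table, top_k=None)
        idx = [darkness_index(c) for c in prof.codes]
        assert idx == sorted(idx)


class TestWeightedStats:
    def test_single_dark_code(self):
        prof = GreenProfile.from_counts({DARK: 7})
        s = weighted_stats(prof)
        assert (s.mean_r, s.mean_g, s.mean_b) == (0.0, 43.0, 0.0)
        assert s.mean_rg == 0.0 and s.mean_bg == 0.0

    def test_single_light_code(self):
        s = weighted_stats(GreenProfile.from_counts({LIGHT: 3}))
        assert s.mean_rg == s.mean_bg == 0.796875
        assert round(s.mean_rg, 2) == 0.80

    def test_equal_pixel_two_codes(self, equal_profile):
        s = weighted_stats(equal_profile)
        assert s.mean_r == 51.0
        assert s.mean_g == 85.5
        assert s.mean_b == 51.0
        assert s.mean_rg == s.mean_bg == 0.3984375

    def test_equals_per_pixel_oracle(self, equal_profile):
        pixels = per_pixel_expansion(equal_profile)
        s = weighted_stats(equal_profile)
        assert s.mean_r == pytest.approx(pixels[:, 0].mean(), abs=1e-12)
        assert s.mean_rg == pytest.approx((pixels[:, 0] / pixels[:, 1]).mean(), abs=1e-12)

    def test_ratio_mean_is_mean_of_ratios(self):
        # distinguishes sum(W r/g) from sum(W r)/sum(W g)
        prof = GreenProfile.from_counts({RGBCode(0, 100, 0): 1, RGBCode(90, 100, 0): 1})
        s = weighted_stats(prof)
        assert s.mean_rg == pytest.approx(0.45)
        assert s.mean_r / s.mean_g == pytest.approx(0.45)  # same here by construction
        prof2 = GreenProfile.from_counts({RGBCode(0, 200, 0): 1, RGBCode(90, 100, 0): 1})
        s2 = weighted_stats(prof2)
        assert s2.mean_rg == pytest.approx(0.45)
        assert s2.mean_r / s2.mean_g != pytest.approx(0.45)


class TestPooling:
    def test_self_pool_scale_invariant(self, equal_profile):
        pooled = pool_profiles([equal_profile, equal_profile])
        assert pooled.total_pixels == 2 * equal_profile.total_pixels
        np.testing.assert_allclose(pooled.weights, equal_profile.weights)
        assert weighted_stats(pooled) == weighted_stats(equal_profile)

    def test_disjoint_equal_pixels(self):
        a = GreenProfile.from_counts({DARK: 100})
        b = GreenProfile.from_counts({LIGHT: 100})
        pooled = pool_profiles([a, b])
        np.testing.assert_allclose(pooled.weights, [0.5, 0.5])

    def test_pool_matches_concatenation_oracle(self):
        rng = np.random.default_rng(9)
        profiles = []
        for _ in range(4):
            table = random_table(rng, max_pixels=3000)
            profiles.append(build_profile(table, top_k=None))
        pooled = pool_profiles(profiles)
        concat = np.concatenate([per_pixel_expansion(p) for p in profiles])
        s = weighted_stats(pooled)
        assert s.mean_g == pytest.approx(concat[:, 1].mean(), abs=1e-9)
        assert s.mean_bg == pytest.approx((concat[:, 2] / concat[:, 1]).mean(), abs=1e-9)


@st.composite
def green_counts(draw):
    m = draw(st.integers(1, 8))
    counts = {}
    while len(counts) < m:
        r = draw(st.integers(0, 254))
        b = draw(st.integers(0, 254))
        g = draw(st.integers(max(r, b) + 1, 255))
        counts[RGBCode(r, g, b)] = draw(st.integers(1, 10_000))
    return counts


class TestProperties:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(counts=green_counts())
    def test_weights_normalized_and_stats_bounded(self, counts):
        prof = GreenProfile.from_counts(counts)
        assert abs(prof.weights.sum() - 1.0) < 1e-12
        s = weighted_stats(prof)
        ch = prof.channels()
        assert ch[:, 0].min() - 1e-9 <= s.mean_r <= ch[:, 0].max() + 1e-9
        assert 0.0 <= s.mean_rg < 1.0 and 0.0 <= s.mean_bg < 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(counts=green_counts(), factor=st.integers(2, 1000))
    def test_scale_invariance(self, counts, factor):
        base = weighted_stats(GreenProfile.from_counts(counts))
        scaled = weighted_stats(
            GreenProfile.from_counts({c: n * factor for c, n in counts.items()})
        )
        for a, b in zip(base.as_dict().values(), scaled.as_dict().values()):
            assert a == pytest.approx(b, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(counts=green_counts(), shift=st.integers(1, 500))
    def test_dark_shift_never_raises_combined_ratio(self, counts, shift):
        """Moving pixel mass from the lightest to the darkest code cannot
        increase mean_rg + mean_bg (the weighted darkness index)."""
        prof = GreenProfile.from_counts(counts)
        if prof.m < 2 or prof.pixels[-1] <= shift:
            return
        moved = dict(counts)
        darkest, lightest = prof.codes[0], prof.codes[-1]
        moved[darkest] = moved[darkest] + shift
        moved[lightest] = moved[lightest] - shift
        if moved[lightest] < 1:
            return
        before = weighted_stats(prof)
        after = weighted_stats(GreenProfile.from_counts(moved))
        assert (after.mean_rg + after.mean_bg) <= (before.mean_rg + before.mean_bg) + 1e-9

    def test_combined_ratio_equals_weighted_darkness(self):
        rng = np.random.default_rng(2)
        prof = build_profile(random_table(rng), top_k=None)
        s = weighted_stats(prof)
        wdark = float(prof.weights @ [darkness_index(c) for c in prof.codes])
        assert s.mean_rg + s.mean_bg == pytest.approx(wdark, abs=1e-12)
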