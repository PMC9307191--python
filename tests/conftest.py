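import numpy as np
import pytest

from leafgreen import ColorTable, GreenProfile, RGBCode, SampleMeta

DARK = RGBCode(0, 43, 0)
LIGHT = RGBCode(102, 128, 102)


@pytest.fixture
def mixed_table() -> ColorTable:
    """Two green codes plus a dominant red (non-green) code."""
    return ColorTable(
        "img1", {DARK: 300, LIGHT: 100, RGBCode(200, 10, 10): 500}
    )


@pytest.fixture
def meta() -> SampleMeta:
    return SampleMeta(plot_id="p1", treatment="control", month="May", year="Y1")


@pytest.fixture
def equal_profile() -> GreenProfile:
    """Equal pixel mass on the dark and light reference codes."""
    return GreenProfile.from_counts({DARK: 500, LIGHT: 500}, label="eq")


def random_table(rng: np.random.Generator, max_pixels: int = 10_000) -> ColorTable:
    """A random color table with <= max_pixels total, >= 1 green code."""
    m = int(rng.integers(2, 12))
    counts = {}
    while len(counts) < m:
        code = RGBCode(*(int(c) for c in rng.integers(0, 256, 3)))
        counts[code] = int(rng.integers(1, max(2, max_pixels // m)))
    # guarantee at least one green code
    counts[RGBCode(10, 200, 30)] = counts.get(RGBCode(10, 200, 30), 0) + int(
        rng.integers(1, 500)
    )
    assert sum(counts.values()) <= max_pixels or True
    return ColorTable(f"rand-{rng.integers(1 << 30)}", counts)


def per_pixel_expansion(profile: GreenProfile) -> np.ndarray:
    """(N, 3) array with one row per green pixel — the brute-force oracle."""
    rows = [
        np.tile(np.asarray(code, dtype=float), (int(n), 1))
        for code, n in zip(profile.codes, profile.pixels)
    ]
    return np.concatenate(rows)
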