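"""Green-pixel profiles and pixel-weighted color statistics.

The greenness of a canopy is summarised from the green-classified palette
colors only.  A code (R, G, B) is *green* iff G strictly exceeds both R and
B; among green codes, those with (R + B) / G near zero are darker.  For a
profile of m green codes with pixel counts A_i, the weights
W_i = A_i / (A_1 + … + A_m) give five pixel-weighted statistics:

    mean R  = Σ W_i R_i        mean R/G = Σ W_i R_i / G_i
    mean G  = Σ W_i G_i        mean B/G = Σ W_i B_i / G_i
    mean B  = Σ W_i B_i

The ratio means are means of per-code ratios, not ratios of channel means.
Low mean R/G and B/G indicate a darker (healthier) canopy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .colortable import ColorTable, ColorTableError, RGBCode

__all__ = [
    "COMMON_GREEN_CODES",
    "GreenProfile",
    "ColorStats",
    "EmptyProfileError",
    "is_green",
    "darkness_index",
    "build_profile",
    "weighted_stats",
    "pool_profiles",
]

#: The five green codes most frequently observed in strawberry canopy
#: photographs, in the conventional dark-to-light listing.  Note this listing
#: is not monotone in :func:`darkness_index` for the middle pair; the
#: canonical ordering used by :class:`GreenProfile` is the index itself.
COMMON_GREEN_CODES: tuple[RGBCode, ...] = (
    RGBCode(0, 43, 0),
    RGBCode(51, 85, 51),
    RGBCode(51, 85, 0),
    RGBCode(102, 128, 51),
    RGBCode(102, 128, 102),
)


class EmptyProfileError(ColorTableError):
    """A color table contains no green codes after filtering."""


def is_green(code: "RGBCode | Sequence[int]") -> bool:
    """True iff G strictly exceeds both R and B (equality is non-green)."""
    r, g, b = code
    return g > r and g > b


def darkness_index(code: "RGBCode | Sequence[int]") -> float:
    """(R + B) / G — values near zero indicate darker green."""
    r, g, b = code
    if g == 0:
        raise ValueError(f"darkness index undefined for G = 0 in {tuple(code)}")
    return (r + b) / g


def _sort_key(code: RGBCode) -> tuple[float, int, int, int]:
    # dark -> light; ties broken lexicographically for determinism
    return (darkness_index(code), *code)


@dataclass
class GreenProfile:
    """Green codes of one sample with normalized pixel weights, dark to light.

    ``label`` identifies the sample or pool (a SampleMeta, a treatment name,
    any hashable).  Construct via :func:`build_profile`, :func:`pool_profiles`
    or :meth:`from_counts`.
    """

    label: object
    codes: list[RGBCode]
    pixels: np.ndarray  # int counts A_i, aligned with codes
    weights: np.ndarray  # W_i = A_i / sum(A), sums to 1

    @classmethod
    def from_counts(cls, counts: dict[RGBCode, int], label: object = None) -> "GreenProfile":
        if not counts:
            raise EmptyProfileError("cannot build a profile from zero green codes")
        codes = sorted((RGBCode.coerce(c) for c in counts), key=_sort_key)
        pix = np.array([counts[c] for c in codes], dtype=np.int64)
        if (pix < 1).any():
            raise ColorTableError("green pixel counts must be >= 1")
        return cls(label=label, codes=list(codes), pixels=pix, weights=pix / pix.sum())

    @property
    def m(self) -> int:
        """Number of distinct green codes."""
        return len(self.codes)

    @property
    def total_pixels(self) -> int:
        return int(self.pixels.sum())

    def channels(self) -> np.ndarray:
        """(m, 3) float array of the R, G, B channel values."""
        return np.asarray(self.codes, dtype=float)

    def counts_dict(self) -> dict[RGBCode, int]:
        return {c: int(n) for c, n in zip(self.codes, self.pixels)}


@dataclass(frozen=True)
class ColorStats:
    """The five pixel-weighted color statistics of a green profile."""

    mean_r: float
    mean_g: float
    mean_b: float
    mean_rg: float
    mean_bg: float

    def as_dict(self) -> dict[str, float]:
        return {
            "R": self.mean_r,
            "G": self.mean_g,
            "B": self.mean_b,
            "R/G": self.mean_rg,
            "B/G": self.mean_bg,
        }


def build_profile(
    table: ColorTable,
    top_k: int | None = 5,
    *,
    codes: Iterable[RGBCode] | None = None,
    label: object = None,
) -> GreenProfile:
    """Filter a color table to its green codes and normalize weights.

    ``top_k`` keeps only the k most pixel-abundant green codes (ties broken
    by darkness index, then lexicographic RGB), mirroring the practice of
    restricting attention to the handful of common greens; ``top_k=None``
    keeps all.  ``codes`` restricts to an explicit list instead (non-green
    entries in the list are rejected).  Weights are renormalized to sum to 1
    over the retained codes.
    """
    if top_k is not None and top_k < 1:
        raise ValueError(f"top_k must be positive, got {top_k}")

    green = {c: n for c, n in table.counts.items() if is_green(c)}
    if codes is not None:
        wanted = [RGBCode.coerce(c) for c in codes]
        for c in wanted:
            if not is_green(c):
                raise ValueError(f"requested code {tuple(c)} is not green")
        green = {c: green[c] for c in wanted if c in green}
    if not green:
        dominant = sorted(table.counts.items(), key=lambda kv: -kv[1])[:3]
        raise EmptyProfileError(
            f"no green codes in image {table.image_id!r}; dominant colors: "
            + ", ".join(f"{tuple(c)}×{n}" for c, n in dominant)
        )
    if codes is None and top_k is not None and len(green) > top_k:
        ranked = sorted(green, key=lambda c: (-green[c], _sort_key(c)))
        green = {c: green[c] for c in ranked[:top_k]}
    return GreenProfile.from_counts(green, label=label if label is not None else table.image_id)


def weighted_stats(profile: GreenProfile) -> ColorStats:
    """Compute the five weighted statistics Σ W_i R_i … Σ W_i B_i/G_i."""
    ch = profile.channels()
    w = profile.weights
    r, g, b = ch[:, 0], ch[:, 1], ch[:, 2]
    return ColorStats(
        mean_r=float(w @ r),
        mean_g=float(w @ g),
        mean_b=float(w @ b),
        mean_rg=float(w @ (r / g)),
        mean_bg=float(w @ (b / g)),
    )


def pool_profiles(profiles: Sequence[GreenProfile], label: object = None) -> GreenProfile:
    """Pool profiles by summing pixel counts per code (e.g. plots within a
    treatment), then renormalize.  Pooling a profile with itself leaves the
    weights — and hence all statistics — unchanged."""
    if not profiles:
        raise ValueError("need at least one profile to pool")
    counts: dict[RGBCode, int] = {}
    for p in profiles:
        for c, n in p.counts_dict().items():
            counts[c] = counts.get(c, 0) + n
    return GreenProfile.from_counts(counts, label=label)
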