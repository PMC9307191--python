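"""Color tables from palette-quantized canopy images.

A *color table* is the elementary data product of the pipeline: for one
photograph, the list of distinct palette colors ("RGB codes") together with
the number of pixels each occupies.  Field workflows typically obtain it by
converting a JPEG to a coarse-palette GIF and histogramming; here the same
step is performed with deterministic median-cut quantization (no dithering,
which would scatter counts across fabricated codes), or by nearest-neighbor
mapping onto a user-supplied fixed palette.

Tables are serialized as plain CSV with one row per (image, code), carrying
the experimental-unit metadata (plot, treatment, month, year) needed by the
downstream mixed model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

__all__ = [
    "RGBCode",
    "ColorTable",
    "SampleMeta",
    "ColorTableError",
    "FormatError",
    "quantize_image",
    "read_color_table",
    "write_color_table",
    "CSV_COLUMNS",
]

CSV_COLUMNS = [
    "image_id",
    "plot_id",
    "treatment",
    "month",
    "year",
    "r",
    "g",
    "b",
    "pixels",
]


class ColorTableError(ValueError):
    """Invalid image input or color-table construction."""


class FormatError(ColorTableError):
    """Malformed color-table CSV."""


class RGBCode(NamedTuple):
    """One 8-bit sRGB palette color."""

    r: int
    g: int
    b: int

    @classmethod
    def coerce(cls, value: "RGBCode | Sequence[int]") -> "RGBCode":
        code = cls(*(int(c) for c in value))
        for c in code:
            if not 0 <= c <= 255:
                raise ColorTableError(f"channel value {c} outside [0, 255] in {tuple(code)}")
        return code


@dataclass(frozen=True)
class SampleMeta:
    """Experimental-unit bookkeeping for one photograph."""

    plot_id: str
    treatment: str
    month: str
    year: str

    def key(self) -> tuple[str, str, str]:
        return (self.plot_id, self.month, self.year)


@dataclass
class ColorTable:
    """Distinct RGB codes and their pixel counts for a single image.

    Invariants (enforced on construction): codes are unique, every count is
    a positive integer.
    """

    image_id: str
    counts: dict[RGBCode, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[RGBCode, int] = {}
        for code, n in self.counts.items():
            code = RGBCode.coerce(code)
            n = int(n)
            if n < 1:
                raise ColorTableError(
                    f"pixel count {n} for code {tuple(code)} in image {self.image_id!r}; counts must be >= 1"
                )
            if code in clean:
                raise ColorTableError(f"duplicate code {tuple(code)} in image {self.image_id!r}")
            clean[code] = n
        self.counts = clean

    @property
    def total_pixels(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def sorted_items(self) -> list[tuple[RGBCode, int]]:
        """Entries in the canonical (r, g, b) ascending order."""
        return sorted(self.counts.items(), key=lambda kv: kv[0])


def _pixel_array(image: "Image.Image | str | Path") -> np.ndarray:
    """Decode to an (N, 3) uint8 array of sRGB pixels.

    Alpha is dropped; grayscale and palette images are promoted to RGB.
    """
    if isinstance(image, (str, Path)):
        try:
            with Image.open(image) as img:
                img = img.convert("RGB")
                arr = np.asarray(img)
        except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
            raise ColorTableError(f"cannot read image {image!r}: {exc}") from exc
    else:
        arr = np.asarray(image.convert("RGB"))
    if arr.size == 0:
        raise ColorTableError("image has no pixels")
    return arr.reshape(-1, 3)


def _histogram(pixels: np.ndarray, image_id: str) -> ColorTable:
    codes, counts = np.unique(pixels, axis=0, return_counts=True)
    return ColorTable(
        image_id,
        {RGBCode(*map(int, c)): int(n) for c, n in zip(codes, counts)},
    )


def _map_to_palette(pixels: np.ndarray, palette: Sequence[RGBCode]) -> np.ndarray:
    """Nearest palette color in Euclidean RGB; ties go to the lowest index."""
    pal = np.asarray([RGBCode.coerce(c) for c in palette], dtype=np.int64)
    uniq, inverse = np.unique(pixels, axis=0, return_inverse=True)
    d2 = ((uniq[:, None, :].astype(np.int64) - pal[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)  # argmin takes the first minimum: lowest index on ties
    return pal[nearest[inverse]].astype(np.uint8)


def quantize_image(
    image: "Image.Image | str | Path",
    palette_size: int = 256,
    *,
    image_id: str = "",
    palette: Sequence[RGBCode] | None = None,
) -> ColorTable:
    """Quantize an image to at most ``palette_size`` colors and histogram it.

    Emulates the coarse-palette (GIF-like) reduction that produces codes such
    as (0, 43, 0).  If the image already holds ``palette_size`` or fewer
    distinct colors it is returned unchanged (idempotence); otherwise Pillow's
    median-cut quantizer is applied without dithering.  Supplying ``palette``
    instead forces nearest-neighbor mapping onto that fixed code list.

    Pixel counts are conserved: the returned counts sum to the image's pixel
    count.
    """
    if palette is None and not 2 <= palette_size <= 256:
        raise ColorTableError(f"palette_size must be in [2, 256], got {palette_size}")
    pixels = _pixel_array(image)
    if not image_id and isinstance(image, (str, Path)):
        image_id = Path(image).stem

    if palette is not None:
        return _histogram(_map_to_palette(pixels, palette), image_id)

    n_distinct = len(np.unique(pixels, axis=0))
    if n_distinct <= palette_size:
        return _histogram(pixels, image_id)

    h = pixels.shape[0]
    img = Image.fromarray(pixels.reshape(h, 1, 3), mode="RGB")
    quant = img.quantize(colors=palette_size, method=Image.Quantize.MEDIANCUT, dither=Image.Dither.NONE)
    mapped = np.asarray(quant.convert("RGB")).reshape(-1, 3)
    return _histogram(mapped, image_id)


def read_color_table(path: "str | Path") -> list[tuple[ColorTable, SampleMeta]]:
    """Read color tables plus metadata from CSV; one table per image_id.

    Raises :class:`FormatError` on a missing column, a duplicate
    (image_id, r, g, b) row, a non-positive pixel count, or metadata that is
    inconsistent within an image.
    """
    try:
        df = pd.read_csv(path, dtype={c: str for c in CSV_COLUMNS[:5]})
    except FileNotFoundError as exc:
        raise ColorTableError(f"cannot read {path!r}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    if (df["pixels"] <= 0).any():
        bad = df.loc[df["pixels"] <= 0].iloc[0]
        raise FormatError(
            f"{path}: non-positive pixel count {bad['pixels']} for image {bad['image_id']!r}"
        )
    dup = df.duplicated(subset=["image_id", "r", "g", "b"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate code ({bad['r']}, {bad['g']}, {bad['b']}) in image {bad['image_id']!r}"
        )

    out: list[tuple[ColorTable, SampleMeta]] = []
    for image_id, grp in df.groupby("image_id", sort=True):
        meta_cols = grp[["plot_id", "treatment", "month", "year"]].drop_duplicates()
        if len(meta_cols) != 1:
            raise FormatError(f"{path}: inconsistent metadata for image {image_id!r}")
        meta = SampleMeta(*meta_cols.iloc[0])
        counts = {
            RGBCode(int(row.r), int(row.g), int(row.b)): int(row.pixels)
            for row in grp.itertuples()
        }
        out.append((ColorTable(str(image_id), counts), meta))
    return out


def write_color_table(
    tables: Iterable[tuple[ColorTable, SampleMeta]],
    path: "str | Path",
) -> None:
    """Write tables to CSV in deterministic order (image_id, then r,g,b)."""
    rows = []
    for table, meta in sorted(tables, key=lambda tm: tm[0].image_id):
        for code, n in table.sorted_items():
            rows.append(
                (table.image_id, meta.plot_id, meta.treatment, meta.month, meta.year, *code, n)
            )
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise ColorTableError(f"cannot write {path!r}: {exc}") from exc
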