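"""Synthetic field trials with the statistical structure the pipeline assumes.

No canopy photographs accompany the published study, so every stage of the
pipeline is exercised against generated data that mimics the trial design:
2 years × 3 soil treatments (non-treated control, steam, chloropicrin) ×
4 plots per treatment × 3 monthly photographs per plot, each photograph a
palette-coded pixel histogram over the five common green codes plus
non-green background, and a per-plot cumulative fruit yield linked linearly
to the May log dark:light ratio.

Generative model
----------------
Treatments are parameterised by a shift on the *dark-code logit* of a
shared base mixture over the green codes.  For image (plot p, month t):

    logit shift on (0,43,0)  =  delta_treatment + b_p + e_pt
    b_p  ~ N(0, plot_random_sd²)      (one draw per plot)
    e_pt ~ N(0, residual_logratio_sd²) (one draw per image)

Because renormalizing a softmax leaves log-weight differences unchanged,
the latent log dark:light ratio of an image is exactly

    log(W_dark / W_light) = base_log_ratio + delta_treatment + b_p + e_pt

i.e. the linear random-intercept model the analysis fits, up to multinomial
counting error (negligible at the default 1e5 green pixels per image).  The
defaults put the control below ratio 1 and both treatments above it
(delta = 1.0), the qualitative pattern of steam/chloropicrin darkening the
canopy.  An optional Dirichlet jitter perturbs the whole mixture for
heavier-tailed noise.  Yields follow
grams/plant = intercept + slope * (May log ratio) + N(0, sd).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from PIL import Image

from .colortable import ColorTable, RGBCode, SampleMeta
from .greenness import COMMON_GREEN_CODES
from .models import DARK_CODE, LIGHT_CODE, RatioRecord

__all__ = [
    "TrialSpec",
    "SpecError",
    "simulate_trial",
    "simulate_ratio_records",
    "render_image",
    "BASE_LOG_RATIO",
    "TREATMENT_DARK_SHIFT",
]

#: Control-group log dark:light ratio of the base mixture (ratio ≈ 0.67 < 1).
BASE_LOG_RATIO = -0.4

#: Dark-logit shift per treatment: the log-ratio treatment effect.
TREATMENT_DARK_SHIFT = {"control": 0.0, "steam": 1.0, "chloropicrin": 1.0}


class SpecError(ValueError):
    """Inconsistent synthetic-trial specification."""


def _default_mixtures() -> dict[str, dict[RGBCode, float]]:
    """Base mixture over the five green codes, dark-shifted per treatment.

    The light code holds weight 0.20; the dark code exp(base + delta) times
    that; the three intermediate codes share the remainder equally.
    """
    light_w = 0.20
    out: dict[str, dict[RGBCode, float]] = {}
    for trt, delta in TREATMENT_DARK_SHIFT.items():
        dark_w = light_w * math.exp(BASE_LOG_RATIO + delta)
        rest = 1.0 - light_w - dark_w
        if rest <= 0:
            raise SpecError("default mixture weights out of range")
        mids = {c: rest / 3.0 for c in COMMON_GREEN_CODES[1:-1]}
        out[trt] = {DARK_CODE: dark_w, **mids, LIGHT_CODE: light_w}
    return out


@dataclass
class TrialSpec:
    """Parameters of one synthetic trial.

    Mixtures are per-treatment green-code distributions (normalized on use).
    ``plot_random_sd`` and ``residual_logratio_sd`` act on the dark-code
    logit, so they are exactly the plot-level and image-level SDs of the log
    dark:light ratio.  ``within_image_noise`` is an optional Dirichlet
    concentration (larger = less jitter, None = off).  ``yield_link`` is
    (intercept g/plant, slope per log-ratio unit, residual SD).
    """

    treatments: dict[str, dict[RGBCode, float]] = field(default_factory=_default_mixtures)
    n_plots: int = 4
    months: tuple[str, ...] = ("May", "June", "July")
    years: tuple[str, ...] = ("Y1", "Y2")
    pixels_per_image: int = 100_000
    background: dict[RGBCode, float] = field(
        default_factory=lambda: {
            RGBCode(120, 90, 60): 0.6,  # soil
            RGBCode(200, 60, 60): 0.2,  # fruit
            RGBCode(220, 220, 210): 0.2,  # mulch
        }
    )
    background_fraction: float = 0.30
    plot_random_sd: float = 0.2
    residual_logratio_sd: float = 0.3
    within_image_noise: float | None = None
    dark_code: RGBCode = DARK_CODE
    light_code: RGBCode = LIGHT_CODE
    yield_intercept: float = 800.0
    yield_slope: float = 400.0
    yield_sd: float = 150.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_plots < 2:
            raise SpecError("need at least 2 plots per treatment")
        if min(self.plot_random_sd, self.residual_logratio_sd, self.yield_sd) < 0:
            raise SpecError("standard deviations must be >= 0")
        if not 0.0 <= self.background_fraction < 1.0:
            raise SpecError("background_fraction must be in [0, 1)")
        for trt, mix in self.treatments.items():
            mix = {RGBCode.coerce(c): float(w) for c, w in mix.items()}
            total = sum(mix.values())
            if total <= 0:
                raise SpecError(f"treatment {trt!r}: mixture weights must be positive")
            self.treatments[trt] = {c: w / total for c, w in mix.items()}
            if mix.get(self.dark_code, 0.0) <= 0 or mix.get(self.light_code, 0.0) <= 0:
                raise SpecError(
                    f"treatment {trt!r}: mixture must give positive weight to the "
                    f"dark {tuple(self.dark_code)} and light {tuple(self.light_code)} codes "
                    "(the yield link needs a finite log ratio)"
                )


def _image_counts(
    mixture: dict[RGBCode, float],
    shift: float,
    dark: RGBCode,
    n_green: int,
    concentration: float | None,
    rng: np.random.Generator,
) -> dict[RGBCode, int]:
    codes = list(mixture)
    logits = np.log(np.array([mixture[c] for c in codes]))
    logits[codes.index(dark)] += shift
    p = np.exp(logits - logits.max())
    p /= p.sum()
    if concentration is not None:
        p = rng.dirichlet(concentration * p)
    counts = rng.multinomial(n_green, p)
    return {c: int(n) for c, n in zip(codes, counts) if n > 0}


def simulate_trial(
    spec: TrialSpec | None = None,
    seed: "int | np.random.Generator | None" = None,
) -> tuple[list[tuple[ColorTable, SampleMeta]], "pd.DataFrame", dict]:
    """Generate a full synthetic trial.

    Returns the per-image color tables with metadata, a yield table
    (plot_id, treatment, year, grams_per_plant), and a truth record holding
    every generating parameter including the realised plot effects.
    Identical spec and seed reproduce the trial bit for bit.
    """
    import pandas as pd

    spec = spec if spec is not None else TrialSpec()
    if seed is None:
        seed = spec.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_green = int(round(spec.pixels_per_image * (1.0 - spec.background_fraction)))
    n_bg = spec.pixels_per_image - n_green
    bg_codes = list(spec.background)
    bg_p = np.array([spec.background[c] for c in bg_codes], dtype=float)
    bg_p = bg_p / bg_p.sum() if bg_codes else bg_p

    tables: list[tuple[ColorTable, SampleMeta]] = []
    yields = []
    plot_effects: dict[str, float] = {}
    may_log_ratio: dict[str, float] = {}

    for year in spec.years:
        for trt in spec.treatments:
            for k in range(1, spec.n_plots + 1):
                plot_id = f"{year}-{trt[:2].upper()}{k}"
                b_p = rng.normal(0.0, spec.plot_random_sd)
                plot_effects[plot_id] = b_p
                for month in spec.months:
                    e = rng.normal(0.0, spec.residual_logratio_sd)
                    counts = _image_counts(
                        spec.treatments[trt], b_p + e, spec.dark_code,
                        n_green, spec.within_image_noise, rng,
                    )
                    if n_bg and bg_codes:
                        for c, n in zip(bg_codes, rng.multinomial(n_bg, bg_p)):
                            if n > 0:
                                counts[c] = counts.get(c, 0) + int(n)
                    image_id = f"{plot_id}-{month}"
                    tables.append(
                        (ColorTable(image_id, counts), SampleMeta(plot_id, trt, month, year))
                    )
                    if month == spec.months[0]:
                        d = counts.get(spec.dark_code, 0)
                        l = counts.get(spec.light_code, 0)
                        may_log_ratio[plot_id] = math.log(d / l) if d > 0 and l > 0 else math.nan
                y = (
                    spec.yield_intercept
                    + spec.yield_slope * may_log_ratio[plot_id]
                    + rng.normal(0.0, spec.yield_sd)
                )
                yields.append((plot_id, trt, year, float(y)))

    yield_df = pd.DataFrame(yields, columns=["plot_id", "treatment", "year", "grams_per_plant"])
    truth = {
        "spec": {
            k: v
            for k, v in asdict(spec).items()
            if k not in ("treatments", "background")
        },
        "treatment_mixtures": {
            t: {str(tuple(c)): w for c, w in mix.items()} for t, mix in spec.treatments.items()
        },
        "treatment_log_ratio": {
            t: float(np.log(mix[spec.dark_code] / mix[spec.light_code]))
            for t, mix in spec.treatments.items()
        },
        "plot_effects": plot_effects,
        "may_log_ratio": may_log_ratio,
    }
    return tables, yield_df, truth


def simulate_ratio_records(
    effects: "dict[str, float] | None" = None,
    n_plots: int = 4,
    months: Sequence[str] = ("May", "June", "July"),
    *,
    baseline: float = BASE_LOG_RATIO,
    plot_sd: float = 0.2,
    residual_sd: float = 0.3,
    month_effects: "dict[str, float] | None" = None,
    light_pixels: int = 1_000_000,
    year: str = "Y1",
    seed: "int | np.random.Generator | None" = None,
) -> list[RatioRecord]:
    """Draw ratio records directly from the linear mixed model.

    log_ratio = baseline + effect[treatment] + month_effect + b_plot + e,
    with b_plot ~ N(0, plot_sd²), e ~ N(0, residual_sd²).  Counts are
    realised against a fixed light-pixel denominator, so the stored ratio
    matches the latent one to rounding (≤1e-6 relative at the default
    denominator).  The defaults mirror the pixel-level trial: effects
    (control 0, steam 1, chloropicrin 1), 4 plots × 3 treatments × 3 months.
    """
    if effects is None:
        effects = dict(TREATMENT_DARK_SHIFT)
    month_effects = month_effects or {}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = []
    for trt, delta in effects.items():
        for k in range(1, n_plots + 1):
            plot_id = f"{year}-{trt[:2].upper()}{k}"
            b = rng.normal(0.0, plot_sd)
            for month in months:
                lr = baseline + delta + month_effects.get(month, 0.0) + b + rng.normal(0.0, residual_sd)
                dark = max(1, round(light_pixels * math.exp(lr)))
                records.append(
                    RatioRecord(plot_id, trt, month, year, dark, light_pixels)
                )
    return records


def render_image(
    table: ColorTable,
    width: int,
    height: int,
    seed: "int | np.random.Generator | None" = None,
) -> Image.Image:
    """Render a color table as an image with pixels in seeded random order.

    Requires the table's total pixel count to equal width × height.
    Quantizing the result with a palette containing the table's codes
    recovers the table exactly.
    """
    if table.total_pixels != width * height:
        raise ValueError(
            f"table holds {table.total_pixels} pixels but image is {width}x{height}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = np.concatenate(
        [np.tile(np.asarray(code, dtype=np.uint8), (n, 1)) for code, n in table.sorted_items()]
    )
    flat = flat[rng.permutation(len(flat))]
    return Image.fromarray(flat.reshape(height, width, 3), mode="RGB")
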