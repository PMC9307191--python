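"""Dark:light ratio and treatment/yield models.

The canopy-darkness summary for one image is the ratio of the area occupied
by the designated dark green code, by default (0, 43, 0), to the area of the
light green code, by default (102, 128, 102).  A ratio above one indicates a
darker (healthier) canopy.  The log ratio is compared across treatments and
months with a linear mixed model carrying a random intercept per plot (the
experimental unit, observed repeatedly across months), and the season's
cumulative fruit yield is regressed on the May ratio by ordinary least
squares.

Small-sample inference: fixed-effect contrasts are Wald t-tests with
containment (between-plot) denominator degrees of freedom,
df = n_plots - n_treatments, appropriate for a between-unit factor in a
replicated block design.  Residual normality is checked with the
Shapiro-Wilk test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .colortable import ColorTable, RGBCode, SampleMeta
from .greenness import COMMON_GREEN_CODES

__all__ = [
    "DARK_CODE",
    "LIGHT_CODE",
    "RatioRecord",
    "ContrastTest",
    "MixedFit",
    "YieldFit",
    "ModelError",
    "dark_light_ratio",
    "fit_ratio_model",
    "fit_yield_regression",
]

DARK_CODE = COMMON_GREEN_CODES[0]  # (0, 43, 0)
LIGHT_CODE = COMMON_GREEN_CODES[-1]  # (102, 128, 102)


class ModelError(ValueError):
    """Deficient design or degenerate data for a model fit."""


@dataclass
class RatioRecord:
    """Per-image dark:light green ratio with experimental-unit labels.

    ``valid`` is False when either count is zero, in which case the ratio
    (and its log) is undefined and the record is excluded from modeling.
    """

    plot_id: str
    treatment: str
    month: str
    year: str
    dark_pixels: int
    light_pixels: int

    @property
    def valid(self) -> bool:
        return self.dark_pixels > 0 and self.light_pixels > 0

    @property
    def ratio(self) -> float:
        if self.light_pixels == 0:
            return float("nan")
        return self.dark_pixels / self.light_pixels

    @property
    def log_ratio(self) -> float:
        if not self.valid:
            return float("nan")
        return float(np.log(self.ratio))


def dark_light_ratio(
    table: ColorTable,
    meta: SampleMeta,
    dark: RGBCode = DARK_CODE,
    light: RGBCode = LIGHT_CODE,
    *,
    haldane: bool = False,
) -> RatioRecord:
    """Form the dark:light ratio record for one image.

    A missing dark or light code yields an invalid record (flagged, with a
    warning) rather than an error; ``haldane=True`` instead adds 0.5 to both
    counts so no record is lost.  The ratio depends only on the two counts,
    never on total image size.
    """
    dark = RGBCode.coerce(dark)
    light = RGBCode.coerce(light)
    d = table.counts.get(dark, 0)
    l = table.counts.get(light, 0)
    if haldane:
        # Haldane-style continuity correction; counts become half-integers
        return RatioRecord(meta.plot_id, meta.treatment, meta.month, meta.year, d + 0.5, l + 0.5)
    rec = RatioRecord(meta.plot_id, meta.treatment, meta.month, meta.year, d, l)
    if not rec.valid:
        warnings.warn(
            f"image {table.image_id!r}: dark={d}, light={l} pixels; "
            "ratio undefined, record flagged invalid",
            stacklevel=2,
        )
    return rec


@dataclass
class ContrastTest:
    """Wald t-test for one planned treatment contrast, averaged over months."""

    pair: tuple[str, str]
    estimate: float
    se: float
    statistic: float
    df: float
    pvalue: float


@dataclass
class MixedFit:
    """Random-intercept mixed-model fit of the log dark:light ratio."""

    fixed_effects: pd.Series
    random_intercept_var: float
    residual_var: float
    contrasts: dict[tuple[str, str], ContrastTest]
    normality_p: float
    formula: str
    n_obs: int
    n_plots: int
    converged: bool
    used_ols_fallback: bool = False
    result: object = field(default=None, repr=False)

    @property
    def pvalues(self) -> dict[tuple[str, str], float]:
        return {pair: t.pvalue for pair, t in self.contrasts.items()}


def _records_frame(records: list[RatioRecord]) -> pd.DataFrame:
    valid = [r for r in records if r.valid]
    n_bad = len(records) - len(valid)
    if n_bad:
        warnings.warn(f"excluding {n_bad} record(s) with undefined ratio from the model")
    return pd.DataFrame(
        {
            "plot_id": [r.plot_id for r in valid],
            "treatment": [r.treatment for r in valid],
            "month": [r.month for r in valid],
            "year": [r.year for r in valid],
            "log_ratio": [r.log_ratio for r in valid],
        }
    )


def _mean_design_row(design_info, treatment: str, months: list[str], years: list[str]) -> np.ndarray:
    """Design row for one treatment averaged over months (and years)."""
    grid = pd.DataFrame(
        [
            {"treatment": treatment, "month": m, "year": y}
            for m in months
            for y in years
        ]
    )
    mat = np.asarray(patsy.dmatrix(design_info, grid))
    return mat.mean(axis=0)


def fit_ratio_model(
    records: list[RatioRecord],
    contrasts: "list[tuple[str, str]] | None" = None,
) -> MixedFit:
    """Fit log_ratio ~ treatment * month (+ year) with a plot random intercept.

    REML estimation; month (and year, when more than one is present) enter as
    categorical.  Each planned contrast (a, b) tests the treatment difference
    a - b averaged over months, by a Wald t-test with containment df.  By
    default all pairwise treatment contrasts are tested.  Residuals (marginal,
    response minus fixed-effect fit) are checked for normality with
    Shapiro-Wilk.

    Falls back to ordinary least squares with zero random-intercept variance
    when the mixed fit is singular (e.g. noise-free data), where the two
    estimators coincide.
    """
    df = _records_frame(records)
    if df.empty:
        raise ModelError("no valid ratio records to model")

    treatments = sorted(df["treatment"].unique())
    months = sorted(df["month"].unique())
    years = sorted(df["year"].unique())
    if len(treatments) < 2:
        raise ModelError("need at least 2 treatments to compare")
    plots_per_trt = df.groupby("treatment")["plot_id"].nunique()
    deficient = plots_per_trt[plots_per_trt < 2]
    if not deficient.empty:
        raise ModelError(
            "singular design: treatment(s) "
            f"{list(deficient.index)} have fewer than 2 plots; the plot random "
            "intercept is confounded with the treatment factor"
        )

    rhs = "C(treatment)"
    if len(months) > 1:
        rhs += " * C(month)"
    if len(years) > 1:
        rhs += " + C(year)"
    formula = f"log_ratio ~ {rhs}"

    n_plots = df["plot_id"].nunique()
    fe_params = cov = None
    random_var = residual_var = np.nan
    converged = False
    used_ols = False
    result = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df["plot_id"])
            result = model.fit(reml=True)
        fe_params = result.fe_params
        cov = np.asarray(result.cov_params())[: len(fe_params), : len(fe_params)]
        random_var = float(np.asarray(result.cov_re).ravel()[0])
        residual_var = float(result.scale)
        converged = bool(result.converged)
        design_info = result.model.data.design_info
        if not (np.isfinite(fe_params).all() and np.isfinite(cov).all()):
            raise np.linalg.LinAlgError("non-finite mixed-model estimates")
    except (np.linalg.LinAlgError, ValueError):
        fe_params = None

    if fe_params is None:
        used_ols = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols(formula, df).fit()
        fe_params = ols.params
        cov = np.asarray(ols.cov_params())
        random_var = 0.0
        residual_var = float(ols.scale)
        converged = True
        result = ols
        design_info = ols.model.data.design_info

    fitted = np.asarray(patsy.dmatrix(design_info, df)) @ np.asarray(fe_params)
    resid = df["log_ratio"].to_numpy() - fitted
    if np.ptp(resid) < 1e-12 or len(resid) < 3:
        normality_p = 1.0  # constant residuals: nothing to test
    else:
        normality_p = float(scipy.stats.shapiro(resid).pvalue)

    if contrasts is None:
        contrasts = [(b, a) for a, b in itertools.combinations(treatments, 2)]
    ddf = max(n_plots - len(treatments), 1)
    tests: dict[tuple[str, str], ContrastTest] = {}
    for a, b in contrasts:
        for t in (a, b):
            if t not in treatments:
                raise ModelError(f"unknown treatment {t!r} in contrast ({a}, {b})")
        L = _mean_design_row(design_info, a, months, years) - _mean_design_row(
            design_info, b, months, years
        )
        est = float(L @ np.asarray(fe_params))
        se = float(np.sqrt(L @ cov @ L))
        if se > 0:
            tstat = est / se
            p = float(2.0 * scipy.stats.t.sf(abs(tstat), ddf))
        else:
            tstat = np.inf if est != 0 else 0.0
            p = 0.0 if est != 0 else 1.0
        tests[(a, b)] = ContrastTest(pair=(a, b), estimate=est, se=se, statistic=tstat, df=ddf, pvalue=p)

    return MixedFit(
        fixed_effects=pd.Series(np.asarray(fe_params), index=list(fe_params.index)),
        random_intercept_var=random_var,
        residual_var=residual_var,
        contrasts=tests,
        normality_p=normality_p,
        formula=formula,
        n_obs=len(df),
        n_plots=n_plots,
        converged=converged,
        used_ols_fallback=used_ols,
        result=result,
    )


@dataclass
class YieldFit:
    """OLS fit of cumulative yield (g/plant) on the May dark:light ratio."""

    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    slope_ci: tuple[float, float]
    slope_pvalue: float
    n: int
    result: object = field(default=None, repr=False)


def fit_yield_regression(
    yields: "pd.DataFrame | list[tuple[str, float]]",
    ratios: list[RatioRecord],
    *,
    month: str | None = "May",
) -> YieldFit:
    """Regress per-plot cumulative yield on the dark:light ratio of one month.

    ``yields`` is a DataFrame with columns plot_id, grams_per_plant (and
    optionally year) or a list of (plot_id, grams_per_plant) pairs; records
    are matched on plot_id (and year when available).  Requires >= 3 matched
    plots and non-constant ratios.
    """
    if not isinstance(yields, pd.DataFrame):
        yields = pd.DataFrame(yields, columns=["plot_id", "grams_per_plant"])
    if "grams_per_plant" not in yields.columns or "plot_id" not in yields.columns:
        raise ModelError("yields must carry plot_id and grams_per_plant columns")

    recs = [r for r in ratios if r.valid and (month is None or r.month == month)]
    if not recs:
        raise ModelError(f"no valid ratio records for month {month!r}")
    rdf = pd.DataFrame(
        {
            "plot_id": [r.plot_id for r in recs],
            "year": [r.year for r in recs],
            "ratio": [r.ratio for r in recs],
        }
    )
    on = ["plot_id", "year"] if "year" in yields.columns else ["plot_id"]
    merged = rdf.merge(yields.astype({"plot_id": str}), on=on)
    if len(merged) < 3:
        raise ModelError(f"need >= 3 matched plots, got {len(merged)}")
    if np.ptp(merged["ratio"].to_numpy()) < 1e-12:
        raise ModelError("ratio has zero variance; slope undefined")

    X = sm.add_constant(merged["ratio"].to_numpy())
    res = sm.OLS(merged["grams_per_plant"].to_numpy(), X).fit()
    ci = res.conf_int()[1]
    return YieldFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        slope_se=float(res.bse[1]),
        slope_ci=(float(ci[0]), float(ci[1])),
        slope_pvalue=float(res.pvalues[1]),
        n=len(merged),
        result=res,
    )
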