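"""Agreement and group-comparison statistics for the simulation study.

The simulated cohort is the ground truth; each fitting method's per-voxel
(f, D, fD) outputs are compared to it with:

* pooled ordinary least-squares regression of output against input,
* Bland-Altman bias (mean difference and 1.96-sd limits), and
* the symmetric median percent difference
  ``delta% = 200 * |input - output| / (input + output)``,

which is preferred over percent error because small and zero-valued inputs
would otherwise dominate the denominator.  A component that is truly absent
and fitted as absent (both values zero) scores delta% = 0 and is excluded
from the regressions; a present component fitted as zero scores the maximal
200%.  Group-comparison wrappers (Mann-Whitney U, one-way ANOVA, Spearman
rank) mirror the clinical analyses and are thin layers over scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signal_models import DecayCurve
from .spectral_nnls import REGIMES, SpectralConfig, spectral_fit_voxel
from .parametric_fits import (
    BiexpPriors,
    TriexpStart,
    fit_biexponential_bayesian,
    fit_triexponential_ls,
)

__all__ = [
    "AgreementReport",
    "percent_difference",
    "bland_altman",
    "linear_regress",
    "goodness_of_fit",
    "group_tests",
    "spearman",
    "fit_cohort",
    "evaluate_cohort",
    "format_reports",
]

R2_EXCLUSION_THRESHOLD = 0.70  # voxels with fit R^2 below this are excluded


@dataclass(frozen=True)
class AgreementReport:
    """Pooled agreement of one fitted quantity against its input truth."""

    quantity: str
    method: str
    slope: float
    intercept: float
    r2: float
    ba_mean_diff: float
    ba_lo: float
    ba_hi: float
    delta_pct: dict  # component -> median percent difference
    n_points: int


def percent_difference(x_in, x_out):
    """Symmetric percent difference 200*|in - out| / (in + out).

    Vectorized over arrays; both-zero pairs return 0 (an absent component
    correctly fitted as absent agrees perfectly).  Bounded by 200 for
    non-negative inputs.
    """
    x_in = np.asarray(x_in, dtype=float)
    x_out = np.asarray(x_out, dtype=float)
    denom = x_in + x_out
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 200.0 * np.abs(x_in - x_out) / denom
    d = np.where(denom == 0, 0.0, d)
    return d if d.ndim else float(d)


def bland_altman(x, y) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement: mean(y-x) +/- 1.96 sd."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need equal-length paired samples with n >= 2")
    diff = y - x
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def linear_regress(x, y) -> tuple[float, float, float]:
    """OLS slope, intercept and R^2 (squared Pearson correlation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3 for a regression")
    if np.var(x) == 0:
        raise ValueError("zero-variance regressor")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def goodness_of_fit(curve: DecayCurve, fitted: np.ndarray) -> float:
    """R^2 of a fitted curve against the measured signal; NaN if undefined."""
    y = curve.signal
    fitted = np.asarray(fitted, dtype=float)
    if fitted.size != y.size:
        raise ValueError("curve and fit must have equal length")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return np.nan
    return 1.0 - float(((y - fitted) ** 2).sum()) / ss_tot


def group_tests(values, labels) -> dict:
    """Mann-Whitney U (two groups) and/or one-way ANOVA (>= 2 groups).

    Returns a dict with ``mannwhitney`` = (z-statistic, p) when exactly two
    groups are present (normal approximation, tie-corrected) and ``anova`` =
    (F, p).  Significance convention is p < 0.05.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if any(len(g) == 0 for g in groups) or len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    out: dict = {}
    if len(groups) == 2:
        mwu = stats.mannwhitneyu(groups[0], groups[1], method="asymptotic")
        n1, n2 = len(groups[0]), len(groups[1])
        mu = n1 * n2 / 2.0
        # invert the (tie-corrected) two-sided p back to the signed z
        z = stats.norm.isf(mwu.pvalue / 2.0) * np.sign(mwu.statistic - mu)
        out["mannwhitney"] = (float(z), float(mwu.pvalue))
    f = stats.f_oneway(*groups)
    out["anova"] = (float(f.statistic), float(f.pvalue))
    return out


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (rho, p)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3 pairs")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


_FITTERS = {
    "spectral": lambda curve, **kw: spectral_fit_voxel(
        curve, kw.get("config") or SpectralConfig()),
    "biexp": lambda curve, **kw: fit_biexponential_bayesian(
        curve, kw.get("priors") or BiexpPriors()),
    "triexp": lambda curve, **kw: fit_triexponential_ls(
        curve, kw.get("starts") or TriexpStart()),
}


def fit_cohort(cohort, method: str, **kwargs) -> pd.DataFrame:
    """Fit every curve of a simulated cohort with one method.

    Returns one row per set with per-regime f, D, fD (D and fD in
    1e-3 mm^2/s), the fit R^2, peak count and flag.
    """
    if method not in _FITTERS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_FITTERS)}")
    fitter = _FITTERS[method]
    rows = []
    for set_id in range(cohort.curves.shape[0]):
        fit = fitter(cohort.curve(set_id), **kwargs)
        row = {"set_id": set_id}
        row.update(fit.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def _truth_wide(truth: pd.DataFrame) -> pd.DataFrame:
    wide = truth.pivot(index="set_id", columns="component",
                       values=["f", "D_approx", "fD_truth"])
    return wide


def evaluate_cohort(
    truth: pd.DataFrame, fits: pd.DataFrame, method: str
) -> dict[str, AgreementReport]:
    """Agreement reports for f, D and fD of one method against cohort truth.

    Regressions and Bland-Altman pool (input, output) points across the
    three components and all sets, matching a single per-method regression
    spanning all regimes; both-zero pairs are excluded from the pooled
    statistics but score delta% = 0 in the per-component medians.  D and fD
    are reported in 1e-3 mm^2/s.
    """
    if "method" in fits.columns:
        methods = fits["method"].unique()
        if len(methods) != 1 or methods[0] != method:
            raise ValueError(f"fits table holds {list(methods)}, expected [{method!r}]")
    wide = _truth_wide(truth)
    fits = fits.set_index("set_id").loc[wide.index]
    reports: dict[str, AgreementReport] = {}
    spec = {"f": ("f", 1.0), "D": ("D_approx", 1e3), "fD": ("fD_truth", 1e3)}
    for quantity, (truth_col, scale) in spec.items():
        xs, ys = [], []
        delta: dict[str, float] = {}
        for comp in REGIMES:
            x = wide[(truth_col, comp)].to_numpy() * scale
            y = fits[f"{quantity}_{comp}"].to_numpy()
            delta[comp] = float(np.median(percent_difference(x, y)))
            keep = ~((x == 0) & (y == 0))
            xs.append(x[keep])
            ys.append(y[keep])
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        slope, intercept, r2 = linear_regress(x, y)
        ba = bland_altman(x, y)
        reports[quantity] = AgreementReport(
            quantity=quantity, method=method, slope=slope, intercept=intercept,
            r2=r2, ba_mean_diff=ba[0], ba_lo=ba[1], ba_hi=ba[2],
            delta_pct=delta, n_points=int(x.size),
        )
    return reports


def format_reports(reports: dict[str, AgreementReport]) -> str:
    """Human-readable table of agreement reports (one row per quantity)."""
    lines = []
    for q, r in reports.items():
        deltas = ", ".join(f"{c}={v:.1f}%" for c, v in r.delta_pct.items())
        lines.append(
            f"{r.method:>8s} {q:>3s}: y = {r.slope:.2f} x + {r.intercept:.2f}, "
            f"R2 = {r.r2:.2f}, BA = {r.ba_mean_diff:.2f} "
            f"({r.ba_lo:.1f}, {r.ba_hi:.1f}), median delta% [{deltas}], "
            f"n = {r.n_points}"
        )
    return "\n".join(lines)
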