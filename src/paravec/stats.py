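"""Statistical surface: location tests, post hoc machinery, normality
gating, and trend fits of angles/lengths against host divergence time.

Two-sample location is tested with Welch's t (pooled-variance optional)
and the Wilcoxon rank-sum test; k groups with Kruskal-Wallis followed by
pairwise rank-sum tests under Holm adjustment and a compact-letter
display. Normality is checked with Shapiro-Wilk, implemented here as a
direct double-precision transcription of Royston's AS R94 approximation
(normal quantiles at full double precision). Trends are fit both as
ordinary least squares and as a penalized cubic B-spline smoother with
GCV-style automatic smoothness selection, so the caller can mirror the
usual "report the model explaining more variance" choice explicitly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import norm as _norm
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

# ---------------------------------------------------------------------------
# result containers


@dataclass
class TestResult:
    """A single hypothesis test: statistic, two-sided p, and direction.

    ``direction`` is the sign of mean(x) - mean(y) for two-sample tests
    (0 for one-sample and omnibus tests).
    """

    name: str
    statistic: float
    pvalue: float
    n: tuple[int, ...]
    direction: int = 0
    note: str = ""


@dataclass
class KGroupsResult:
    """Kruskal-Wallis omnibus plus pairwise rank-sum tests and letters."""

    omnibus: TestResult
    pairwise: pd.DataFrame  # group1, group2, statistic, pvalue, adjusted_p
    letters: dict[str, str]


@dataclass
class TrendFit:
    """One trend model of y against divergence time."""

    kind: str  # "linear" or "smooth"
    pvalue: float
    variance_explained: float  # R^2 (linear) or deviance explained (smooth)
    r_squared_adj: float
    grid_x: np.ndarray = field(repr=False, default=None)
    grid_y: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# two-sample and k-group tests


def _clean(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(a).all():
        raise ValidationError("values must be finite")
    return a


def compare_two_groups(x, y, method: str = "t", equal_var: bool = False) -> TestResult:
    """Unpaired two-sample test, two-sided.

    ``method="t"`` runs Welch's t-test (``equal_var=True`` for the pooled
    variant); ``method="wilcoxon"`` the Wilcoxon rank-sum test, exact for
    combined n <= 50 without ties and a normal approximation with
    continuity correction otherwise. Two identical constant groups under
    Wilcoxon are defined via midranks and give p = 1.
    """
    x, y = _clean(x), _clean(y)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least 2 observations")
    direction = int(np.sign(np.mean(x) - np.mean(y)))
    if method == "t":
        stat, p = sps.ttest_ind(x, y, equal_var=equal_var)
        name = "t" if equal_var else "welch_t"
    elif method == "wilcoxon":
        name = "wilcoxon_rank_sum"
        pooled = np.concatenate([x, y])
        if np.ptp(pooled) == 0:
            return TestResult(name, len(x) * len(y) / 2.0, 1.0, (len(x), len(y)), 0)
        ties = len(np.unique(pooled)) < len(pooled)
        mode = "exact" if (not ties and len(pooled) <= 50) else "asymptotic"
        stat, p = sps.mannwhitneyu(x, y, method=mode, use_continuity=True)
        direction = int(np.sign(np.median(x) - np.median(y)))
    else:
        raise ValidationError(f"unknown method: {method!r}")
    return TestResult(name, float(stat), float(p), (len(x), len(y)), direction)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment (never decreases any p-value)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="holm")[1]


def _compact_letters(
    groups: list[str], sig: Mapping[tuple[str, str], bool]
) -> dict[str, str]:
    """Insert-absorb compact letter display from a significance relation."""
    letters: list[set[str]] = [set(groups)]
    for g1, g2 in combinations(groups, 2):
        if not sig.get((g1, g2), False):
            continue
        for s in [s for s in letters if g1 in s and g2 in s]:
            s1, s2 = s - {g2}, s - {g1}
            letters.remove(s)
            for cand in (s1, s2):
                if not any(cand <= other for other in letters):
                    letters.append(cand)
    letters.sort(key=lambda s: sorted(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, s in enumerate(letters):
        for g in s:
            out[g] += alphabet[i % len(alphabet)]
    return out


def compare_k_groups(
    groups: Mapping[str, "np.ndarray"],
    posthoc_correction: str = "holm",
    alpha: float = 0.05,
) -> KGroupsResult:
    """Kruskal-Wallis with tie correction, plus pairwise rank-sum tests.

    Pairwise p-values are adjusted with ``posthoc_correction`` (one of
    ``holm``, ``bonferroni``, ``none``); groups sharing no display letter
    differ at level ``alpha`` after adjustment.
    """
    if posthoc_correction not in ("holm", "bonferroni", "none"):
        raise ValidationError(f"unknown correction: {posthoc_correction!r}")
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = {g: _clean(groups[g]) for g in names}
    for g, a in arrays.items():
        if len(a) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 observations")
    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:
        omnibus = TestResult("kruskal_wallis", 0.0, 1.0, tuple(len(a) for a in arrays.values()))
    else:
        h, p = sps.kruskal(*arrays.values())
        omnibus = TestResult(
            "kruskal_wallis", float(h), float(p), tuple(len(a) for a in arrays.values())
        )

    rows = []
    for g1, g2 in combinations(names, 2):
        r = compare_two_groups(arrays[g1], arrays[g2], method="wilcoxon")
        rows.append({"group1": g1, "group2": g2, "statistic": r.statistic, "pvalue": r.pvalue})
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "statistic", "pvalue"])
    if posthoc_correction == "none":
        pairwise["adjusted_p"] = pairwise["pvalue"]
    elif posthoc_correction == "bonferroni":
        pairwise["adjusted_p"] = np.minimum(pairwise["pvalue"] * len(pairwise), 1.0)
    else:
        pairwise["adjusted_p"] = holm_adjust(pairwise["pvalue"].to_numpy())

    sig = {
        (row["group1"], row["group2"]): row["adjusted_p"] < alpha
        for _, row in pairwise.iterrows()
    }
    letters = _compact_letters(names, sig)
    return KGroupsResult(omnibus=omnibus, pairwise=pairwise, letters=letters)


# ---------------------------------------------------------------------------
# Shapiro-Wilk (AS R94, Royston 1995)


def _poly(coefs, x: float) -> float:
    return float(sum(c * x**i for i, c in enumerate(coefs)))


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and upper-tail p-value for normality.

    Double-precision transcription of the AS R94 approximation: Blom
    scores m_i = Phi^{-1}((i - 3/8)/(n + 1/4)), polynomial-corrected end
    weights, and Royston's normalizing transformations of W (arcsine for
    n = 3, log-gamma form for 4 <= n <= 11, log-log form for n >= 12).
    Valid for 3 <= n <= 5000.
    """
    x = np.sort(_clean(x))
    n = len(x)
    if n < 3:
        raise ValidationError("Shapiro-Wilk requires at least 3 observations")
    if n > 5000:
        raise ValidationError("Shapiro-Wilk approximation is valid up to n = 5000")
    if np.ptp(x) == 0:
        raise ValidationError("Shapiro-Wilk is undefined for a constant sample")

    m = _norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    ssm = float(np.sum(m**2))
    rsn = 1.0 / math.sqrt(n)
    a = np.empty(n)
    if n == 3:
        a[0], a[1], a[2] = -math.sqrt(0.5), 0.0, math.sqrt(0.5)
    else:
        c1 = [0.0, 0.221157, -0.147981, -2.071190, 4.434685, -2.706056]
        c2 = [0.0, 0.042981, -0.293762, -1.752461, 5.682633, -3.582633]
        a_n = m[-1] / math.sqrt(ssm) + _poly(c1, rsn)
        if n > 5:
            a_n1 = m[-2] / math.sqrt(ssm) + _poly(c2, rsn)
            phi = (ssm - 2 * m[-1] ** 2 - 2 * m[-2] ** 2) / (
                1 - 2 * a_n**2 - 2 * a_n1**2
            )
            a[2:-2] = m[2:-2] / math.sqrt(phi)
            a[-2], a[1] = a_n1, -a_n1
        else:
            phi = (ssm - 2 * m[-1] ** 2) / (1 - 2 * a_n**2)
            a[1:-1] = m[1:-1] / math.sqrt(phi)
        a[-1], a[0] = a_n, -a_n

    xm = x - x.mean()
    W = float(np.dot(a, x) ** 2 / np.dot(xm, xm))
    W = min(W, 1.0)

    nf = float(n)
    if n == 3:
        p = 6.0 / math.pi * (math.asin(math.sqrt(W)) - math.asin(math.sqrt(0.75)))
        return W, float(min(max(p, 0.0), 1.0))
    if n <= 11:
        g = _poly([-2.273, 0.459], nf)
        mu = _poly([0.5440, -0.39978, 0.025054, -6.714e-4], nf)
        sig = math.exp(_poly([1.3822, -0.77857, 0.062767, -0.0020322], nf))
        z = (-math.log(g - math.log1p(-W)) - mu) / sig
    else:
        ln = math.log(nf)
        mu = _poly([-1.5861, -0.31082, -0.083751, 0.0038915], ln)
        sig = math.exp(_poly([-0.4803, -0.082676, 0.0030302], ln))
        z = (math.log1p(-W) - mu) / sig
    return W, float(_norm.sf(z))


def normality_check(x, max_n: int = 5000, seed: int | None = None) -> TestResult:
    """Shapiro-Wilk normality test; subsamples (seeded) above ``max_n``."""
    x = _clean(x)
    note = ""
    if len(x) > max_n:
        rng = np.random.default_rng(seed)
        x = rng.choice(x, size=max_n, replace=False)
        note = f"subsampled to {max_n} with seed {seed}"
    W, p = shapiro_wilk(x)
    return TestResult("shapiro_wilk", W, p, (len(x),), 0, note)


# ---------------------------------------------------------------------------
# trend fits


def fit_trend(
    x, y, basis_df: int = 10, n_grid: int = 100
) -> dict[str, TrendFit | None]:
    """Linear and penalized-spline trends of y against divergence time.

    Returns ``{"linear": ..., "smooth": ...}``. The linear fit is OLS with
    the slope's two-sided p and R^2. The smooth fit is a cubic B-spline
    GAM whose penalty weight is chosen by generalized cross-validation;
    it reports the joint Wald p-value of the spline coefficients and
    deviance explained. When x has fewer than 4 unique values the smooth
    fit is skipped with a warning.
    """
    import statsmodels.api as sm
    from statsmodels.gam.api import BSplines, GLMGam

    x, y = _clean(x), _clean(y)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    if len(x) < 10:
        raise ValidationError("trend fits require at least 10 observations")

    grid = np.linspace(x.min(), x.max(), n_grid)
    if np.ptp(y) == 0:
        # constant response: nothing to explain, both fits are flat
        flat = lambda kind: TrendFit(
            kind=kind, pvalue=1.0, variance_explained=0.0, r_squared_adj=0.0,
            grid_x=grid, grid_y=np.full(n_grid, float(y[0])),
        )
        return {"linear": flat("linear"), "smooth": flat("smooth")}

    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    linear = TrendFit(
        kind="linear",
        pvalue=float(ols.pvalues[1]),
        variance_explained=float(ols.rsquared),
        r_squared_adj=float(ols.rsquared_adj),
        grid_x=grid,
        grid_y=ols.params[0] + ols.params[1] * grid,
    )

    if len(np.unique(x)) < 4:
        warnings.warn("fewer than 4 unique x values; smooth fit skipped", stacklevel=2)
        return {"linear": linear, "smooth": None}

    df = min(basis_df, max(4, len(np.unique(x)) - 1))
    bs = BSplines(x, df=[df], degree=[3])
    ones = np.ones((len(y), 1))
    n = len(y)

    # generalized cross-validation over a fixed penalty grid:
    # GCV(alpha) = n * RSS / (n - edf)^2
    best = (np.inf, None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from statsmodels.tools.sm_exceptions import PerfectSeparationError

        for alpha in np.logspace(-4, 8, 25):
            try:
                cand = GLMGam(y, exog=ones, smoother=bs, alpha=alpha).fit()
            except (PerfectSeparationError, np.linalg.LinAlgError):
                continue  # residual variance ~0 at this penalty
            edf = float(np.sum(cand.edf))
            if n - edf <= 1:
                continue
            gcv = n * float(cand.deviance) / (n - edf) ** 2
            if gcv < best[0]:
                best = (gcv, cand)
    if best[1] is None:
        warnings.warn("smoothness selection failed; smooth fit skipped", stacklevel=2)
        return {"linear": linear, "smooth": None}
    res = best[1]
    null_dev = float(np.sum((y - y.mean()) ** 2))
    dev_expl = 1.0 - float(res.deviance) / null_dev if null_dev > 0 else 0.0
    k = bs.dim_basis
    R = np.zeros((k, 1 + k))
    R[:, 1:] = np.eye(k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pvalue = float(res.wald_test(R, scalar=True).pvalue)
    edf = float(np.sum(res.edf))
    denom = max(len(y) - edf, 1.0)
    adj = 1.0 - (float(res.deviance) / denom) / (null_dev / (len(y) - 1)) if null_dev > 0 else 0.0
    smooth = TrendFit(
        kind="smooth",
        pvalue=pvalue,
        variance_explained=max(dev_expl, 0.0),
        r_squared_adj=adj,
        grid_x=grid,
        grid_y=res.predict(exog=np.ones((n_grid, 1)), exog_smooth=grid),
    )
    return {"linear": linear, "smooth": smooth}
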