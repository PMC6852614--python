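"""The statistical layer relating gene prevalence to environment.

* Pearson correlations between prevalence and environmental covariates,
  with significance from the t transform of r;
* log-log ordinary least squares of prevalence on phosphate concentration
  (zero or missing values are dropped and counted, never pseudo-counted:
  pseudo-counts bias slopes);
* a z statistic for the difference of two independent regression slopes,
  z = (b1 - b2) / sqrt(se1^2 + se2^2), two-sided normal p, judged at 0.05;
* a two-predictor model (ocean region + log phosphate) with Type II
  per-predictor F tests;
* Kruskal-Wallis across regions and pairwise two-sided rank-sum
  (Mann-Whitney) tests with Benjamini-Hochberg control, from which a
  region is flagged enriched relative to all others iff every adjusted
  pairwise p is below 0.05 and its median exceeds every other region's.

One Benjamini-Hochberg family is the set of pairwise comparisons of one
gene within one depth zone; families are never pooled across genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionResult",
    "GroupComparison",
    "pearson_test",
    "loglog_fit",
    "slope_difference_z",
    "region_pi_model",
    "kruskal_wallis",
    "pairwise_wilcoxon_bh",
    "benjamini_hochberg",
]


class DegenerateInputError(ValueError):
    """Input has no variance or too few usable observations."""


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of log10(percent) on log10(Pi)."""

    slope: float
    intercept: float
    se_slope: float
    r2: float
    p_slope: float
    n: int
    zero_dropped: int


@dataclass
class GroupComparison:
    """Kruskal-Wallis verdict plus BH-adjusted pairwise rank-sum matrix."""

    H: float
    df: int
    p: float
    pairwise: pd.DataFrame  # symmetric region x region adjusted p
    pairwise_raw: pd.DataFrame
    medians: pd.Series
    enriched_flags: pd.Series  # bool per region


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def pearson_test(x, y) -> tuple[float, float, int]:
    """Pearson r with two-sided p from the t transform, n-2 df.

    Incomplete pairs are dropped; fewer than 3 complete pairs or zero
    variance raise.
    """
    x, y = _complete_pairs(x, y)
    n = len(x)
    if n < 3:
        raise DegenerateInputError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("degenerate input: zero variance")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p), n


def loglog_fit(percent, pi) -> RegressionResult:
    """OLS of log10(percent) on log10(Pi).

    Pairs with non-positive or missing percent/Pi are excluded and counted
    in ``zero_dropped``; fewer than 3 usable pairs raise.
    """
    percent = np.asarray(percent, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if percent.shape != pi.shape:
        raise ValueError("percent and pi must align")
    usable = (
        np.isfinite(percent) & np.isfinite(pi) & (percent > 0) & (pi > 0)
    )
    zero_dropped = int((~usable).sum())
    if usable.sum() < 3:
        raise DegenerateInputError(
            f"fewer than 3 usable pairs ({int(usable.sum())}); "
            f"zero_dropped={zero_dropped}"
        )
    y = np.log10(percent[usable])
    x = np.log10(pi[usable])
    if np.ptp(x) == 0:
        raise DegenerateInputError("degenerate input: constant Pi")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        se_slope=float(fit.bse[1]),
        r2=float(fit.rsquared),
        p_slope=float(fit.pvalues[1]),
        n=int(fit.nobs),
        zero_dropped=zero_dropped,
    )


def slope_difference_z(
    fit1: RegressionResult, fit2: RegressionResult
) -> tuple[float, float]:
    """z for the difference of two independent slopes; two-sided normal p."""
    for fit in (fit1, fit2):
        if not np.isfinite(fit.se_slope) or fit.se_slope <= 0:
            raise ValueError("missing or non-positive slope standard error")
    z = (fit1.slope - fit2.slope) / np.hypot(fit1.se_slope, fit2.se_slope)
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return float(z), float(p)


def region_pi_model(percent, region, pi) -> pd.DataFrame:
    """log10(percent) ~ region + log10(Pi), Type II per-predictor F tests.

    Returns a frame indexed by predictor ('region', 'log10_pi') with
    columns F, p, df. With a single region the model degenerates to the
    plain log-log fit and only the Pi row is reported (its F is the
    squared slope t).
    """
    df = pd.DataFrame(
        {"percent": np.asarray(percent, float), "region": np.asarray(region),
         "pi": np.asarray(pi, float)}
    )
    df = df[(df["percent"] > 0) & (df["pi"] > 0)].dropna()
    if len(df) < 4:
        raise DegenerateInputError("too few usable observations")
    df["log_percent"] = np.log10(df["percent"])
    df["log_pi"] = np.log10(df["pi"])

    counts = df["region"].value_counts()
    if (counts < 2).any():
        import warnings

        warnings.warn(
            f"regions with < 2 samples retained: "
            f"{sorted(counts[counts < 2].index)}",
            stacklevel=2,
        )
    if df["region"].nunique() == 1:
        fit = loglog_fit(df["percent"], df["pi"])
        t = fit.slope / fit.se_slope
        return pd.DataFrame(
            {"F": [t**2], "p": [fit.p_slope], "df": [1.0]}, index=["log10_pi"]
        )

    model = smf.ols("log_percent ~ C(region) + log_pi", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    out = pd.DataFrame(
        {
            "F": [anova.loc["C(region)", "F"], anova.loc["log_pi", "F"]],
            "p": [anova.loc["C(region)", "PR(>F)"], anova.loc["log_pi", "PR(>F)"]],
            "df": [anova.loc["C(region)", "df"], anova.loc["log_pi", "df"]],
        },
        index=["region", "log10_pi"],
    )
    return out


def _groups(values, labels) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    return {
        lab: values[labels == lab] for lab in pd.unique(labels)
    }


def kruskal_wallis(values, labels) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p on k-1 df.

    All-identical values give H = 0, p = 1.
    """
    groups = {k: v for k, v in _groups(values, labels).items() if len(v) > 0}
    if len(groups) < 2:
        raise DegenerateInputError("need >= 2 non-empty groups")
    arrays = list(groups.values())
    df = len(arrays) - 1
    if np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, df, 1.0
    H, p = scipy.stats.kruskal(*arrays)
    return float(H), df, float(p)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Step-up FDR adjustment; monotone and bounded below by the raw p."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact for small tie-free groups, normal
    approximation with tie correction otherwise (common package default)."""
    method = "exact" if (len(a) <= 8 and len(b) <= 8) else "asymptotic"
    try:
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:
        res = scipy.stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic"
        )
    return float(res.pvalue)


def pairwise_wilcoxon_bh(values, labels, alpha: float = 0.05) -> GroupComparison:
    """Pairwise two-sided rank-sum tests with Benjamini-Hochberg control.

    A region is flagged enriched relative to all other regions iff every
    adjusted pairwise p against every other region is below ``alpha`` and
    its median exceeds each other region's median. Regions with no
    observations make that pair untestable and the flag impossible.
    """
    groups = _groups(values, labels)
    names = sorted(groups)
    if len(names) < 2:
        raise DegenerateInputError("need >= 2 groups")
    H, df, p_global = kruskal_wallis(values, labels) if all(
        len(groups[n]) for n in names
    ) else (np.nan, len(names) - 1, np.nan)

    raw = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    pairs = [
        (a, b)
        for a, b in combinations(names, 2)
        if len(groups[a]) and len(groups[b])
    ]
    pvals = [_rank_sum_p(groups[a], groups[b]) for a, b in pairs]
    adj_vals = benjamini_hochberg(pvals)
    adjusted = raw.copy()
    for (a, b), pv, av in zip(pairs, pvals, adj_vals):
        raw.loc[a, b] = raw.loc[b, a] = pv
        adjusted.loc[a, b] = adjusted.loc[b, a] = av

    medians = pd.Series(
        {n: (np.median(groups[n]) if len(groups[n]) else np.nan) for n in names}
    )
    flags = {}
    for n in names:
        others = [m for m in names if m != n]
        ok = all(
            np.isfinite(adjusted.loc[n, m])
            and adjusted.loc[n, m] < alpha
            and medians[n] > medians[m]
            for m in others
        )
        flags[n] = bool(ok)
    return GroupComparison(
        H=H,
        df=df,
        p=p_global,
        pairwise=adjusted,
        pairwise_raw=raw,
        medians=medians,
        enriched_flags=pd.Series(flags),
    )
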