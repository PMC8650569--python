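"""Statistics for plate counts with detection-limit censoring.

Counts below the detection limit cannot be enumerated; instead of a
likelihood treatment they are handled by randomized imputation: each
censored record is replaced by a random value drawn uniformly on the log10
scale between ``low`` and ``high`` (defaults 1e2 and 1e4 cfu cm^-2, the
detection limit plus or minus one log).  The downstream test (two-way
ANOVA with Tukey's HSD post test on log10 counts) is repeated across
independent imputations (default 20) and the retained p-value per contrast
is the upper 95% confidence limit of the mean p across repeats, a
deliberately conservative summary.  Group comparisons in omission designs
use the two-sided Mann-Whitney/Wilcoxon rank-sum test, exact for small
samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ImputationSpec",
    "TestSummary",
    "stars_from_p",
    "impute_censored",
    "tukey_hsd_contrasts",
    "two_way_anova_tukey",
    "repeated_imputation_test",
    "mann_whitney_compare",
]


@dataclass(frozen=True)
class ImputationSpec:
    """Randomized-imputation settings for below-detection counts."""

    low: float = 1e2
    high: float = 1e4
    n_repeats: int = 20
    scale_factor: float = 10.0  # multiplier used by sensitivity checks

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError("require 0 < low < high")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    def scaled(self, factor: float) -> "ImputationSpec":
        """Shift the whole imputation range by ``factor`` (e.g. 10 or 0.1)."""
        return dc_replace(self, low=self.low * factor, high=self.high * factor)


def stars_from_p(p: float) -> str:
    """Figure-legend significance stars at the 0.05/0.01/0.001 levels."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class TestSummary:
    """One statistical contrast: label, statistic and (retained) p-value."""

    contrast: str
    statistic: float
    p_retained: float
    n_repeats_used: int = 1
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_retained <= 1.0):
            raise ValueError(f"p out of [0, 1]: {self.p_retained}")

    @property
    def significant(self) -> bool:
        return self.p_retained < self.alpha

    @property
    def stars(self) -> str:
        return stars_from_p(self.p_retained)


def impute_censored(table: pd.DataFrame, spec: ImputationSpec = ImputationSpec(),
                    rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Replace every censored count by ``10**u`` with
    ``u ~ Uniform(log10 low, log10 high)``; censoring flags are preserved
    for audit and non-censored rows are untouched."""
    rng = np.random.default_rng(rng)
    out = table.copy()
    mask = out["censored"].to_numpy(bool)
    n = int(mask.sum())
    if n:
        u = rng.uniform(np.log10(spec.low), np.log10(spec.high), size=n)
        out.loc[mask, "cfu_per_cm2"] = 10.0 ** u
    return out


def _check_design(table: pd.DataFrame, factors: tuple,
                  require_two_f1: bool = True) -> None:
    f1, f2 = factors
    if table[f2].nunique() < 2:
        raise ValueError(f"factor {f2!r} needs >= 2 levels")
    if require_two_f1 and table[f1].nunique() < 2:
        raise ValueError(f"factor {f1!r} needs >= 2 levels")
    counts = table.groupby([f1, f2], observed=True).size()
    full = pd.MultiIndex.from_product(
        [table[f1].unique(), table[f2].unique()], names=[f1, f2])
    missing = full.difference(counts.index)
    if len(missing):
        raise ValueError(f"empty design cell(s): {list(missing)}")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(
            f"cell(s) with a single replicate leave no residual df: {bad}")


def tukey_hsd_contrasts(values: np.ndarray, groups: np.ndarray) -> list:
    """All pairwise Tukey(-Kramer) HSD contrasts for one-way group data.

    The pooled within-group variance is the residual mean square of the
    saturated (cell-means) model, so applied to the interaction cells of a
    two-factor design this is the classical two-way ANOVA + Tukey post
    test.  Returns (group_a, group_b, mean_diff, p) tuples; p-values come
    from the studentized-range distribution (for two groups this reduces
    to the two-sample pooled t-test).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    k = uniq.size
    means = np.array([values[groups == g].mean() for g in uniq])
    ns = np.array([(groups == g).sum() for g in uniq])
    df = int(values.size - k)
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sse = sum(((values[groups == g] - m) ** 2).sum()
              for g, m in zip(uniq, means))
    mse = sse / df
    ii, jj = np.triu_indices(k, 1)
    diffs = means[jj] - means[ii]
    se = np.sqrt(mse / 2.0 * (1.0 / ns[ii] + 1.0 / ns[jj]))
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.abs(diffs) / se
    q = np.where(se == 0, np.where(diffs == 0, 0.0, np.inf), q)
    if k == 2:
        p = 2.0 * sps.t.sf(q / np.sqrt(2.0), df)
    else:
        p = sps.studentized_range.sf(q, k, df)
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
    return [(uniq[i], uniq[j], float(d), float(pv))
            for i, j, d, pv in zip(ii, jj, diffs, p)]


def two_way_anova_tukey(table: pd.DataFrame,
                        factors: tuple = ("species", "condition"),
                        value_col: str = "cfu_per_cm2",
                        family: str = "within",
                        alpha: float = 0.05) -> list:
    """Tukey HSD contrasts on log10 counts for a two-factor design.

    ``family`` controls the simultaneous-inference family:

    * ``"within"`` - for each level of ``factors[0]`` (typically species),
      all pairwise contrasts between levels of ``factors[1]``; the family
      is the set of levels within that slice.
    * ``"cells"`` - one Tukey run across all interaction cells
      (factor1:factor2 groups); all pairwise cell contrasts are returned
      and the family-wise error is controlled over the full cell set.

    Contrast labels are ``"level1|a vs b"`` (within) or ``"f1:f2 vs f1:f2"``
    (cells).  Raises on empty cells or single-replicate cells.
    """
    f1, f2 = factors
    # the per-slice ("within") family is well defined with one f1 level
    _check_design(table, (f1, f2), require_two_f1=(family == "cells"))
    values = np.log10(table[value_col].to_numpy(float))
    out: list[TestSummary] = []
    if family == "within":
        for lvl in pd.unique(table[f1]):
            sel = (table[f1] == lvl).to_numpy()
            for a, b, diff, p in tukey_hsd_contrasts(
                    values[sel], table.loc[sel, f2].astype(str).to_numpy()):
                out.append(TestSummary(f"{lvl}|{a} vs {b}", diff, p,
                                       alpha=alpha))
    elif family == "cells":
        groups = (table[f1].astype(str) + ":" + table[f2].astype(str)).to_numpy()
        for a, b, diff, p in tukey_hsd_contrasts(values, groups):
            out.append(TestSummary(f"{a} vs {b}", diff, p, alpha=alpha))
    else:
        raise ValueError(f"unknown family {family!r}")
    return out


def repeated_imputation_test(table: pd.DataFrame,
                             spec: ImputationSpec = ImputationSpec(),
                             test=None,
                             rng: np.random.Generator | int | None = None,
                             estimator: str = "ci_mean",
                             alpha: float = 0.05) -> list:
    """Run ``test`` across repeated random imputations of censored counts.

    ``test`` is a callable mapping a count table to a list of TestSummary
    (default: two-way species x condition Tukey).  Without censored rows a
    single run is performed.  Per contrast the retained p-value is, with
    ``estimator="ci_mean"``, ``mean(p) + t_{0.975, n-1} * sd(p)/sqrt(n)``
    truncated to [0, 1] (the upper 95% confidence limit of the mean p);
    ``estimator="percentile"`` retains the 95th percentile of the p sample
    instead.  Both are conservative: the retained p is never below the mean
    of the per-repeat p-values.
    """
    if test is None:
        test = lambda t: two_way_anova_tukey(t, alpha=alpha)  # noqa: E731
    if not bool(table["censored"].any()):
        return [dc_replace(s, n_repeats_used=1) for s in test(table)]
    rng = np.random.default_rng(rng)
    runs = []
    for _ in range(spec.n_repeats):
        runs.append(test(impute_censored(table, spec, rng)))
    labels = [s.contrast for s in runs[0]]
    out = []
    for i, label in enumerate(labels):
        ps = np.array([run[i].p_retained for run in runs])
        stat = float(np.mean([run[i].statistic for run in runs]))
        n = len(ps)
        if estimator == "ci_mean":
            if n > 1 and ps.std(ddof=1) > 0:
                half = sps.t.ppf(0.975, n - 1) * ps.std(ddof=1) / np.sqrt(n)
            else:
                half = 0.0
            p_ret = min(1.0, float(ps.mean() + half))
        elif estimator == "percentile":
            p_ret = float(np.quantile(ps, 0.95))
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        out.append(TestSummary(label, stat, p_ret, n_repeats_used=n,
                               alpha=alpha))
    return out


def mann_whitney_compare(group_a, group_b, contrast: str = "",
                         alpha: float = 0.05) -> TestSummary:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum comparison of two groups.

    The exact null distribution is used for combined n <= 12 without ties;
    otherwise the normal approximation with tie correction.  Two identical
    flat groups (every value tied) yield p = 1 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 values")
    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn("all values tied across both groups; p = 1")
        return TestSummary(contrast or "A vs B", a.size * b.size / 2.0, 1.0,
                           alpha=alpha)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestSummary(contrast or "A vs B", float(res.statistic),
                       float(min(1.0, res.pvalue)), alpha=alpha)
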