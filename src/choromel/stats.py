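"""Cohort statistics: regressions, nonparametric tests, repeatability.

The analysis plan mirrors standard SPSS practice for this kind of
cross-sectional cohort: simple (Pearson) correlations of each outcome with
age / axial length / choroidal thickness; stepwise multiple linear
regression (entry p ≤ 0.05, removal p ≥ 0.10) on standardized variables,
reporting β with 95% CI for retained predictors and final-step "if
entered" statistics for excluded ones; Wilcoxon signed-rank tests for
paired sector contrasts (exact enumeration for n ≤ 25, tie- and
continuity-corrected normal approximation otherwise); Friedman tests with
Dunn-type Bonferroni-corrected post-hoc pairwise comparisons across
sectors; and the coefficient of variation over repeated measurements.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "simple_linreg",
    "stepwise_mlr",
    "wilcoxon_signed_rank",
    "friedman_with_posthoc",
    "coefficient_of_variation",
]


@dataclass
class RegressionResult:
    """Result of a simple or stepwise multiple linear regression.

    For a simple regression only ``r`` and ``p`` are set. For a stepwise
    model, ``coef`` holds one row per predictor: standardized β, 95% CI
    and p at the final step, with ``retained`` False for predictors
    reported "if entered".
    """

    r: float | None = None
    p: float | None = None
    coef: pd.DataFrame | None = None
    retained: list[str] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)


def simple_linreg(x, y, method: str = "pearson") -> RegressionResult:
    """Correlation coefficient and two-sided p (t distribution, n−2 df)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant x or y: correlation undefined")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return RegressionResult(r=float(res.statistic), p=float(res.pvalue))


def _zscore(a: np.ndarray) -> np.ndarray:
    return (a - a.mean()) / a.std(ddof=1)


def stepwise_mlr(
    y,
    predictors: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_condition_number: float = 1e8,
) -> RegressionResult:
    """Forward-entry/backward-removal stepwise OLS on standardized variables.

    At each step the candidate with the smallest partial-F p-value enters
    if p < ``p_enter``; included predictors with p > ``p_remove`` are
    removed. The final model's standardized β and 95% CI are reported for
    retained predictors; excluded predictors are reported with the
    statistics they would have if entered into the final model.
    """
    X = pd.DataFrame(predictors).astype(float)
    y = np.asarray(y, dtype=np.float64)
    names = list(X.columns)
    n = y.size
    if n <= len(names) + 2:
        raise ValueError("need n > number of predictors + 2")
    if X.shape[1] >= 2:
        corr = X.corr().to_numpy()
        iu = np.triu_indices_from(corr, k=1)
        worst = np.argmax(np.abs(corr[iu]))
        if np.abs(corr[iu][worst]) > 0.9999 or np.linalg.cond(X.to_numpy()) > max_condition_number:
            a, b = iu[0][worst], iu[1][worst]
            raise ValueError(f"collinear predictors: {names[a]} and {names[b]}")

    yz = _zscore(y)
    Xz = X.apply(_zscore, axis=0)

    def fit(cols):
        return sm.OLS(yz, sm.add_constant(Xz[cols], has_constant="add")).fit()

    included: list[str] = []
    for _ in range(2 * len(names) + 10):  # cap guards against entry/removal cycling
        changed = False
        candidates = [c for c in names if c not in included]
        if candidates:
            pvals = {c: fit(included + [c]).pvalues[c] for c in candidates}
            best = min(pvals, key=pvals.get)
            if pvals[best] < p_enter:
                included.append(best)
                changed = True
        if included:
            res = fit(included)
            worst = max(included, key=lambda c: res.pvalues[c])
            if res.pvalues[worst] > p_remove and not (changed and worst == included[-1]):
                included.remove(worst)
                changed = True
        if not changed:
            break

    rows = []
    final = fit(included) if included else None
    for name in names:
        if name in included:
            ci = final.conf_int().loc[name]
            rows.append(
                {
                    "predictor": name,
                    "beta": float(final.params[name]),
                    "ci_low": float(ci[0]),
                    "ci_high": float(ci[1]),
                    "p": float(final.pvalues[name]),
                    "retained": True,
                }
            )
        else:
            aug = fit(included + [name])
            ci = aug.conf_int().loc[name]
            rows.append(
                {
                    "predictor": name,
                    "beta": float(aug.params[name]),
                    "ci_low": float(ci[0]),
                    "ci_high": float(ci[1]),
                    "p": float(aug.pvalues[name]),
                    "retained": False,
                }
            )
    coef = pd.DataFrame(rows).set_index("predictor")
    return RegressionResult(
        coef=coef, retained=included, removed=[c for c in names if c not in included]
    )


def wilcoxon_signed_rank(differences, mode: str = "auto") -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Zero differences are dropped. For n ≤ 25 (or ``mode='exact'``) the
    null distribution of the positive-rank sum is enumerated exactly over
    all 2ⁿ sign assignments (a dynamic program over doubled midranks, so
    ties are handled exactly); otherwise a normal approximation with tie
    and continuity corrections is used.
    """
    d = np.asarray(differences, dtype=np.float64)
    d = d[d != 0]
    n = d.size
    if n < 5:
        raise ValueError("need >= 5 nonzero differences")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if mode == "exact" or (mode == "auto" and n <= 25):
        return _wilcoxon_exact_p(ranks, w_pos)
    if mode not in ("auto", "approx", "exact"):
        raise ValueError("mode must be 'auto', 'exact' or 'approx'")
    return _wilcoxon_approx_p(d, ranks, w_pos)


def _wilcoxon_exact_p(ranks: np.ndarray, w_pos: float) -> float:
    # distribution of 2·W+ over all sign assignments; doubled midranks are integers
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    upto = 0
    for r in r2:
        # RHS is materialized before assignment, so the overlap is safe
        counts[r : upto + r + 1] = counts[r : upto + r + 1] + counts[: upto + 1]
        upto += r
    n_assign = counts.sum()
    w2 = int(np.rint(2 * w_pos))
    p_le = counts[: w2 + 1].sum() / n_assign
    p_ge = counts[w2:].sum() / n_assign
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _wilcoxon_approx_p(d: np.ndarray, ranks: np.ndarray, w_pos: float) -> float:
    n = d.size
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    # continuity correction toward the mean
    z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def friedman_with_posthoc(matrix) -> tuple[float, float, pd.DataFrame]:
    """Friedman test across conditions (columns) with Dunn–Bonferroni post hoc.

    ``matrix`` is blocks × conditions (e.g. eyes × sectors). Returns the
    tie-corrected Friedman chi-square, its p-value (χ² with k−1 df), and a
    table of pairwise Dunn z-tests on mean ranks with Bonferroni-adjusted
    p-values (multiplied by the number of pairs, clamped at 1).
    """
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        data = matrix.to_numpy(dtype=np.float64)
    else:
        data = np.asarray(matrix, dtype=np.float64)
        names = [f"c{j}" for j in range(data.shape[1])]
    n, k = data.shape
    if k < 3:
        raise ValueError("need >= 3 conditions")
    if n < 5:
        raise ValueError("need >= 5 blocks")

    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    rank_sums = ranks.sum(axis=0)
    stat_num = 12.0 * np.sum(rank_sums**2) / (n * k * (k + 1)) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0:  # every block fully tied: no evidence of any difference
        chi2, p = 0.0, 1.0
    else:
        chi2 = stat_num / correction
        chi2 = max(chi2, 0.0)
        p = float(sps.chi2.sf(chi2, df=k - 1))

    mean_ranks = rank_sums / n
    n_pairs = k * (k - 1) // 2
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        z = (mean_ranks[i] - mean_ranks[j]) / se
        raw = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "a": names[i],
                "b": names[j],
                "mean_rank_a": mean_ranks[i],
                "mean_rank_b": mean_ranks[j],
                "z": z,
                "p_raw": raw,
                "p_bonferroni": min(1.0, raw * n_pairs),
            }
        )
    return float(chi2), float(p), pd.DataFrame(rows)


def coefficient_of_variation(repeats) -> tuple[np.ndarray, tuple[float, float]]:
    """Per-eye CV (sample SD ÷ mean) and the cohort mean ± SD of the CVs.

    ``repeats`` is an (eyes × measurements) array with ≥ 2 positive
    measurements per eye.
    """
    a = np.asarray(repeats, dtype=np.float64)
    if a.ndim != 2 or a.shape[1] < 2:
        raise ValueError("repeats must be (eyes x measurements) with >= 2 measurements")
    if (a <= 0).any():
        raise ValueError("all repeated measurements must be positive")
    cv = a.std(axis=1, ddof=1) / a.mean(axis=1)
    return cv, (float(cv.mean()), float(cv.std(ddof=1)) if cv.size > 1 else 0.0)
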