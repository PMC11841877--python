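"""Nonparametric cluster-profile comparisons.

Kruskal-Wallis omnibus tests with the epsilon-squared effect size
(eps^2 = H / (n - 1)), Dunn's rank-based pairwise z tests with Bonferroni
adjustment within variable, a chi-square test of independence for the
gender x cluster table, the Stroop interference efficacy ratios, and a
noncentral-F power/sample-size utility for the one-way ANOVA omnibus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "KWResult",
    "DunnResult",
    "ChiSquareResult",
    "StatsReport",
    "kruskal_wallis",
    "epsilon_squared",
    "dunn_bonferroni",
    "chi_square_independence",
    "stroop_derived",
    "anova_sample_size",
    "report",
]


@dataclass(frozen=True)
class KWResult:
    variable: str
    H: float
    df: int
    p: float
    epsilon_squared: float
    n: int


@dataclass(frozen=True)
class DunnResult:
    pair: tuple[int, int]
    z: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class ChiSquareResult:
    table: pd.DataFrame
    statistic: float
    df: int
    p: float


@dataclass
class StatsReport:
    input_tests: pd.DataFrame  # variable, H, df, p, eps2
    outcome_tests: pd.DataFrame
    dunn: dict[str, pd.DataFrame]  # per-variable pairwise results
    gender: ChiSquareResult | None
    skipped: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = ["Cluster effect on input variables", "=" * 40]
        lines.append(self.input_tests.to_string(index=False))
        lines += ["", "Cluster effect on cognitive variables", "=" * 40]
        lines.append(self.outcome_tests.to_string(index=False))
        if self.gender is not None:
            lines += [
                "",
                f"Gender x cluster: chi2({self.gender.df}) = "
                f"{self.gender.statistic:.2f}, p = {self.gender.p:.4g}",
            ]
        if self.skipped:
            lines += ["", "Skipped (missing columns): " + ", ".join(self.skipped)]
        return "\n".join(lines)


def _group_arrays(values, labels) -> list[np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = []
    for g in np.unique(labels):
        arr = values[labels == g]
        if arr.size == 0:
            raise ValueError(f"group {g!r} is empty")
        groups.append(arr)
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    return groups


def kruskal_wallis(values, labels, variable: str = "") -> KWResult:
    """Tie-corrected Kruskal-Wallis H test across the labelled groups.

    p comes from the chi-square approximation with (k - 1) degrees of
    freedom.  With all pooled values identical H = 0 and p = 1.
    """
    groups = _group_arrays(values, labels)
    n = sum(len(g) for g in groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*groups)
    return KWResult(
        variable=variable,
        H=float(h),
        df=len(groups) - 1,
        p=float(p),
        epsilon_squared=epsilon_squared(float(h), n),
        n=n,
    )


def epsilon_squared(H: float, n: int) -> float:
    """Epsilon-squared effect size for Kruskal-Wallis: H / (n - 1)."""
    if n < 2:
        raise ValueError("epsilon-squared needs n >= 2")
    if H < 0:
        raise ValueError("H must be >= 0")
    return H / (n - 1)


def dunn_bonferroni(values, labels, alpha: float = 0.05) -> list[DunnResult]:
    """Dunn's pairwise rank tests with Bonferroni adjustment.

    z for pair (i, j) is the mean-rank difference over the pooled
    tie-corrected standard error; p values are two-sided normal tails
    multiplied by the number of pairs k(k-1)/2 and capped at 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    _group_arrays(values, labels)  # validates sizes
    n = len(values)
    ranks = sps.rankdata(values)  # mid-ranks
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    mean_ranks = {g: ranks[labels == g].mean() for g in uniq}
    sizes = {g: int((labels == g).sum()) for g in uniq}
    n_pairs = len(uniq) * (len(uniq) - 1) // 2
    results = []
    for gi, gj in combinations(uniq, 2):
        se = np.sqrt(base_var * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
        z = 0.0 if se == 0 else (mean_ranks[gi] - mean_ranks[gj]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * n_pairs)
        results.append(
            DunnResult(
                pair=(gi, gj),
                z=float(z),
                p_raw=float(p_raw),
                p_adjusted=float(p_adj),
                significant=p_adj < alpha,
            )
        )
    return results


def chi_square_independence(table: pd.DataFrame | np.ndarray) -> ChiSquareResult:
    """Pearson chi-square test of independence without continuity correction."""
    frame = pd.DataFrame(table)
    arr = frame.to_numpy(dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    chi2, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return ChiSquareResult(table=frame, statistic=float(chi2), df=int(df), p=float(p))


def stroop_derived(
    dot_time, word_time, color_time, dot_resp, word_resp, color_resp
):
    """Stroop interference efficacy ratios.

    Returns (dot_time_eff, word_time_eff, dot_resp_eff, word_resp_eff):
    color-task time over dot/word-task time and color-task responses over
    dot/word-task responses.  Zero denominators yield NaN with a warning.
    """

    def _ratio(num, den, name):
        num = np.asarray(num, dtype=float)
        den = np.asarray(den, dtype=float)
        if np.any(den == 0):
            warnings.warn(f"zero denominator in {name}; emitting NaN")
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(den == 0, np.nan, num / den)
        return out if out.shape else float(out)

    return (
        _ratio(color_time, dot_time, "dot_time_efficacy"),
        _ratio(color_time, word_time, "word_time_efficacy"),
        _ratio(color_resp, dot_resp, "dot_resp_efficacy"),
        _ratio(color_resp, word_resp, "word_resp_efficacy"),
    )


def anova_power(f: float, k: int, n: int, alpha: float) -> float:
    """Power of the one-way fixed-effects ANOVA omnibus F test.

    df1 = k - 1, df2 = n - k, noncentrality lambda = f^2 * n.
    """
    df1, df2 = k - 1, n - k
    if df2 < 1:
        return 0.0
    crit = sps.f.isf(alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, f**2 * n))


def anova_sample_size(
    f: float,
    k: int,
    alpha: float = 0.05,
    power: float = 0.80,
    balanced: bool = True,
) -> int:
    """Smallest total N reaching the target omnibus power.

    Searches N upward using the noncentral F distribution; power is
    monotone in N so the first hit is the minimum.  With ``balanced=True``
    (the G*Power convention for a one-way design) N is constrained to
    multiples of k so every group gets the same size; e.g. f = 0.25,
    k = 4 then yields the classical N = 180 rather than the unconstrained
    minimum 179.
    """
    if f <= 0:
        raise ValueError("effect size f must be > 0")
    if k < 2:
        raise ValueError("need at least 2 groups")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    step = k if balanced else 1
    start = 2 * k if balanced else k + 1
    for n in range(start, 1_000_001, step):
        if anova_power(f, k, n, alpha) >= power:
            return n
    raise RuntimeError("target power unreachable within N <= 1e6")


def report(
    cohort: pd.DataFrame,
    labels: np.ndarray,
    input_variables: list[str],
    outcome_variables: list[str],
    gender_column: str | None = "gender",
    alpha: float = 0.05,
) -> StatsReport:
    """Full nonparametric comparison of clusters on a labelled cohort.

    One Kruskal-Wallis row (H, df, p, eps^2) per input and outcome
    variable, Dunn-Bonferroni matrices per variable, and the gender x
    cluster chi-square.  Missing columns are listed and skipped.
    """
    labels = np.asarray(labels)
    skipped = [
        v
        for v in input_variables + outcome_variables
        if v not in cohort.columns
    ]
    if skipped:
        warnings.warn(f"missing variable columns skipped: {skipped}")

    def _table(variables: list[str]) -> pd.DataFrame:
        rows = []
        for var in variables:
            if var in skipped:
                continue
            res = kruskal_wallis(cohort[var].to_numpy(), labels, variable=var)
            rows.append(
                {
                    "variable": var,
                    "H": res.H,
                    "df": res.df,
                    "p": res.p,
                    "eps2": res.epsilon_squared,
                }
            )
        return pd.DataFrame(rows)

    dunn: dict[str, pd.DataFrame] = {}
    for var in input_variables + outcome_variables:
        if var in skipped:
            continue
        results = dunn_bonferroni(cohort[var].to_numpy(), labels, alpha=alpha)
        dunn[var] = pd.DataFrame(
            [
                {
                    "cluster_i": r.pair[0],
                    "cluster_j": r.pair[1],
                    "z": r.z,
                    "p_raw": r.p_raw,
                    "p_adjusted": r.p_adjusted,
                    "significant": r.significant,
                }
                for r in results
            ]
        )

    gender = None
    if gender_column is not None and gender_column in cohort.columns:
        table = pd.crosstab(labels, cohort[gender_column])
        gender = chi_square_independence(table)

    return StatsReport(
        input_tests=_table(input_variables),
        outcome_tests=_table(outcome_variables),
        dunn=dunn,
        gender=gender,
        skipped=skipped,
    )
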