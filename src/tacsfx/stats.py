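"""The condition-comparison decision chain for tACS after-effect data.

Measurements rarely satisfy normality (log band power and normalized MEP
changes are heavily skewed), so the analysis first gates on a
Kolmogorov–Smirnov normality test and then branches:

* nonparametric — Friedman's test across the three stimulation conditions
  (alpha-, beta-, sham-tACS) on baseline-normalized values, followed by
  all-pairs Steel–Dwass comparisons;
* parametric — repeated-measures ANOVA with Bonferroni-adjusted pairwise
  contrasts.

Because the mean and SD of the null normal are estimated from the data, the
KS gate uses the Lilliefors correction. Friedman uses mid-ranks with the tie
correction and offers exact enumeration of the permutation null for small
block counts; Steel–Dwass standardizes each pairwise Wilcoxon rank-sum
statistic with the tie-corrected variance and adjusts familywise through the
Studentized-range distribution, with an exact max-|z| permutation fallback
for small samples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .spectral import InputError

__all__ = [
    "TestResult",
    "PairwiseResult",
    "ks_normality",
    "naive_ks",
    "friedman_test",
    "steel_dwass",
    "rm_anova_bonferroni",
    "run_branch",
    "blocks_from_frame",
]


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float  # standardized pairwise statistic (z_pair)
    p_adjusted: float
    p_exact: float | None = None


@dataclass
class TestResult:
    test_name: str
    statistic: float
    df: float | tuple
    p_value: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------


def ks_normality(values) -> float:
    """Lilliefors-corrected KS test of normality with estimated mean/SD.

    Returns the p-value. Estimating the null's parameters from the sample
    makes the plain KS distribution wildly conservative; the Lilliefors
    null table corrects for it.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise InputError("normality test needs at least 5 values")
    if np.ptp(x) == 0:
        raise InputError("constant input — normality is undefined")
    _, pval = lilliefors(x, dist="norm", pvalmethod="table")
    return float(pval)


def naive_ks(values) -> float:
    """Uncorrected KS p-value against N(mean, sd) with plug-in estimates.

    Exposed for comparison only; anti-conservative calibration is the
    caller's problem."""
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise InputError("normality test needs at least 5 values")
    if np.ptp(x) == 0:
        raise InputError("constant input — normality is undefined")
    return float(sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue)


# ---------------------------------------------------------------------------
# Friedman
# ---------------------------------------------------------------------------


def blocks_from_frame(
    frame: pd.DataFrame,
    unit: str = "unit",
    condition: str = "condition",
    value: str = "value",
) -> tuple[np.ndarray, list[str]]:
    """Pivot long-format data into a blocks × conditions array."""
    pivot = frame.pivot_table(index=unit, columns=condition, values=value)
    if pivot.isna().any().any():
        raise InputError("missing condition cell(s) in at least one block")
    return pivot.to_numpy(dtype=float), [str(c) for c in pivot.columns]


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-squared from within-block mid-ranks."""
    b, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * float(np.sum((col_sums - b * (k + 1) / 2.0) ** 2))
    den = float(np.sum(ranks**2)) - b * k * (k + 1) ** 2 / 4.0
    if den <= 0:  # every block fully tied
        return 0.0
    return num / den


def friedman_test(
    blocks, condition_labels=None, exact: bool | None = None, exact_limit: int = 8
) -> TestResult:
    """Friedman's rank test across k related conditions in b blocks.

    ``blocks`` is a b × k array (or long DataFrame with unit/condition/value
    columns). Ties get mid-ranks and the tie-corrected statistic; df = k − 1.
    When ``exact`` (defaulting to b ≤ ``exact_limit``), the permutation null
    — all within-block rank permutations — is enumerated by dynamic
    programming over column-sum states and the exact p is reported alongside
    the asymptotic chi-squared p.
    """
    if isinstance(blocks, pd.DataFrame) and condition_labels is None:
        blocks, condition_labels = blocks_from_frame(blocks)
    x = np.asarray(blocks, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InputError("need >= 2 blocks and >= 2 conditions")
    if not np.all(np.isfinite(x)):
        raise InputError("missing condition cell(s)")
    b, k = x.shape
    ranks = sps.rankdata(x, axis=1)
    stat = _friedman_statistic(ranks)
    df = k - 1
    p_asym = float(sps.chi2.sf(stat, df)) if stat > 0 else 1.0
    result = TestResult(
        test_name="friedman",
        statistic=stat,
        df=df,
        p_value=p_asym,
        extra={"n_blocks": b, "labels": condition_labels},
    )
    if exact is None:
        exact = b <= exact_limit
    if exact:
        result.extra["p_exact"] = _friedman_exact_p(ranks, stat)
    return result


def _friedman_exact_p(ranks: np.ndarray, observed: float) -> float:
    """Exact permutation p by DP over column-sum states.

    Within each block every permutation of its (mid-)rank vector is equally
    likely under the null; the statistic depends on the permuted table only
    through the column sums, so the full (k!)^b product collapses to a
    distribution over sum vectors. Ranks are doubled to stay integral.
    """
    b, k = ranks.shape
    iranks = np.rint(ranks * 2).astype(int)
    states: dict[tuple, int] = {tuple([0] * k): 1}
    for i in range(b):
        perms = set(itertools.permutations(iranks[i]))
        new: dict[tuple, int] = {}
        for state, cnt in states.items():
            for perm in perms:
                key = tuple(s + p for s, p in zip(state, perm))
                new[key] = new.get(key, 0) + cnt
        states = new
    den = float(np.sum(ranks**2)) - b * k * (k + 1) ** 2 / 4.0
    if den <= 0:
        return 1.0
    total = sum(states.values())
    center = b * (k + 1) / 2.0
    hits = 0
    for sums, cnt in states.items():
        s = (k - 1) * sum((v / 2.0 - center) ** 2 for v in sums) / den
        if s >= observed - 1e-12:
            hits += cnt
    return hits / total


# ---------------------------------------------------------------------------
# Steel–Dwass
# ---------------------------------------------------------------------------


def _pair_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Standardized rank-sum statistic and Var[W] for one pair, tie-corrected.

    z = (W − E[W]) / sqrt(Var[W]) with W the rank sum of ``x`` in the pooled
    mid-ranked sample and Var[W] = n1 n2 / (N(N−1)) · Σ (r − r̄)².
    """
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    n = n1 + n2
    r = sps.rankdata(pooled)
    w = float(r[:n1].sum())
    e_w = n1 * (n + 1) / 2.0
    var_w = n1 * n2 / (n * (n - 1)) * float(np.sum((r - (n + 1) / 2.0) ** 2))
    if var_w <= 0:
        return 0.0, 0.0
    return (w - e_w) / math.sqrt(var_w), var_w


def _pair_z(x: np.ndarray, y: np.ndarray) -> float:
    return _pair_stats(x, y)[0]


def _srange_p(z: float, k: int, var_w: float = 0.0) -> float:
    """Familywise p for a standardized pairwise statistic via the
    Studentized-range distribution with k groups and infinite df.

    With ``var_w`` given, a continuity correction of 0.5 on the rank sum is
    applied before standardizing: the rank-sum statistic is discrete, and
    the corrected tail tracks the exact permutation distribution far better
    at small group sizes.
    """
    za = abs(z)
    if var_w > 0:
        za = max(za - 0.5 / math.sqrt(var_w), 0.0)
    q = za * math.sqrt(2.0)
    return float(sps.studentized_range.sf(q, k, np.inf))


def steel_dwass(
    groups: dict[str, np.ndarray] | list,
    exact: bool | None = None,
    exact_limit: int = 12,
) -> list[PairwiseResult]:
    """All-pairs Steel–Dwass nonparametric multiple comparisons.

    For each pair of groups the pooled data are mid-ranked and the rank-sum
    statistic standardized (``z_pair``); the familywise-adjusted p treats
    q = z·√2 as Studentized range with k groups and infinite df. When the
    total sample is small (N ≤ ``exact_limit``), the exact familywise p is
    also computed by enumerating every reassignment of the pooled values to
    the group sizes and referring each observed |z| to the permutation
    distribution of the maximum pairwise |z|.
    """
    if isinstance(groups, dict):
        labels = list(groups)
        data = [np.asarray(groups[g], dtype=float) for g in labels]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        labels = [f"g{i}" for i in range(len(data))]
    k = len(data)
    if k < 2:
        raise InputError("need at least 2 groups")
    if any(g.size < 2 for g in data):
        raise InputError("every group needs n >= 2")
    results = []
    for i, j in itertools.combinations(range(k), 2):
        z, var_w = _pair_stats(data[i], data[j])
        results.append(
            PairwiseResult(
                pair=(labels[i], labels[j]),
                statistic=z,
                p_adjusted=_srange_p(z, k, var_w),
            )
        )
    total_n = sum(g.size for g in data)
    if exact is None:
        exact = total_n <= exact_limit
    if exact:
        max_dist = _max_abs_z_distribution([g.size for g in data], data)
        for res in results:
            z_obs = abs(res.statistic)
            res.p_exact = float(np.mean(max_dist >= z_obs - 1e-12))
    return results


def _max_abs_z_distribution(sizes: list[int], data: list[np.ndarray]) -> np.ndarray:
    """Permutation distribution of max pairwise |z| over all reassignments
    of the pooled observations to groups of the given sizes.

    |z| for a pair depends only on the two index sets, so values are cached
    on the canonical (sorted) subset pair; each unordered pair recurs in many
    assignments.
    """
    pooled = np.concatenate(data)
    idx = tuple(range(pooled.size))
    out: list[tuple] = []

    def assignments(remaining: tuple, sizes_left: list[int], chosen: tuple):
        if not sizes_left:
            out.append(chosen)
            return
        for combo in itertools.combinations(remaining, sizes_left[0]):
            rest = tuple(r for r in remaining if r not in combo)
            assignments(rest, sizes_left[1:], chosen + (combo,))

    assignments(idx, list(sizes), ())
    cache: dict[tuple, float] = {}

    def abs_z(a: tuple, b: tuple) -> float:
        key = (a, b) if a < b else (b, a)
        z = cache.get(key)
        if z is None:
            z = abs(_pair_z(pooled[list(key[0])], pooled[list(key[1])]))
            cache[key] = z
        return z

    maxima = np.empty(len(out))
    for i, groups_idx in enumerate(out):
        maxima[i] = max(
            abs_z(groups_idx[a], groups_idx[b])
            for a, b in itertools.combinations(range(len(groups_idx)), 2)
        )
    return maxima


# ---------------------------------------------------------------------------
# parametric branch
# ---------------------------------------------------------------------------


def rm_anova_bonferroni(
    frame: pd.DataFrame,
    unit: str = "unit",
    condition: str = "condition",
    time: str | None = "phase",
    value: str = "value",
) -> TestResult:
    """Repeated-measures ANOVA with Bonferroni-adjusted pairwise contrasts.

    With a ``time`` column present (two phases), fits the within-subject
    condition × time design; otherwise a one-way within-subject ANOVA on
    condition. Pairwise condition contrasts are paired t-tests on the
    per-unit means, multiplied by the number of comparisons (capped at 1).
    """
    from statsmodels.stats.anova import AnovaRM

    frame = frame.copy()
    within = [condition]
    if time is not None and time in frame.columns and frame[time].nunique() > 1:
        within.append(time)
    counts = frame.groupby([unit] + within, observed=True)[value].count()
    n_cells = int(np.prod([frame[w].nunique() for w in within]))
    per_unit = counts.groupby(level=0).count()
    if counts.nunique() != 1 or (per_unit != n_cells).any():
        raise InputError("unbalanced design: unequal cell counts per unit")
    if counts.iloc[0] > 1:
        frame = frame.groupby([unit] + within, observed=True, as_index=False)[
            value
        ].mean()
    if np.ptp(frame[value].to_numpy(dtype=float)) == 0:
        # identical values in every cell: F is 0/0; report the null outcome
        conds = sorted(map(str, frame[condition].unique()))
        pairwise = [
            PairwiseResult(pair=(a, b_), statistic=0.0, p_adjusted=1.0)
            for a, b_ in itertools.combinations(conds, 2)
        ]
        return TestResult(
            test_name="rm_anova",
            statistic=0.0,
            df=(float(len(conds) - 1), float("nan")),
            p_value=1.0,
            pairwise=pairwise,
            extra={"degenerate": True},
        )
    fit = AnovaRM(
        frame, depvar=value, subject=unit, within=within
    ).fit()
    tbl = fit.anova_table
    effect = condition
    stat = float(tbl.loc[effect, "F Value"])
    df_pair = (
        float(tbl.loc[effect, "Num DF"]),
        float(tbl.loc[effect, "Den DF"]),
    )
    p = float(tbl.loc[effect, "Pr > F"])
    if not math.isfinite(stat):  # zero between- and within-variance: 0/0
        stat, p = 0.0, 1.0

    means = frame.groupby([unit, condition], observed=True)[value].mean().unstack()
    conds = list(means.columns)
    m = len(conds) * (len(conds) - 1) // 2
    pairwise = []
    for a, b_ in itertools.combinations(conds, 2):
        t_res = sps.ttest_rel(means[a], means[b_])
        t_stat, t_p = float(t_res.statistic), float(t_res.pvalue)
        if not math.isfinite(t_stat):  # identical paired values
            t_stat, t_p = 0.0, 1.0
        pairwise.append(
            PairwiseResult(
                pair=(str(a), str(b_)),
                statistic=t_stat,
                p_adjusted=min(1.0, t_p * m),
            )
        )
    return TestResult(
        test_name="rm_anova",
        statistic=stat,
        df=df_pair,
        p_value=p,
        pairwise=pairwise,
        extra={"anova_table": tbl, "effects": {e: float(tbl.loc[e, "F Value"]) for e in tbl.index}},
    )


# ---------------------------------------------------------------------------
# the branch
# ---------------------------------------------------------------------------


def run_branch(
    frame: pd.DataFrame,
    alpha: float = 0.05,
    unit: str = "unit",
    condition: str = "condition",
    value: str = "value",
    time: str | None = None,
) -> TestResult:
    """Normality-gated comparison across conditions.

    Each condition's values go through the Lilliefors KS gate; if any
    condition rejects normality at ``alpha``, the nonparametric branch runs
    (Friedman across conditions within units, then all-pairs Steel–Dwass),
    otherwise the parametric branch (repeated-measures ANOVA + Bonferroni).
    The chosen branch is recorded in ``result.extra["branch"]``.
    """
    conds = sorted(frame[condition].unique())
    ks_p = {}
    for c in conds:
        vals = frame.loc[frame[condition] == c, value].to_numpy(dtype=float)
        ks_p[str(c)] = ks_normality(vals)
    nonparametric = any(p < alpha for p in ks_p.values())
    if nonparametric:
        per_unit = (
            frame.groupby([unit, condition], observed=True)[value]
            .mean()
            .reset_index()
        )
        per_unit = per_unit.rename(
            columns={unit: "unit", condition: "condition", value: "value"}
        )
        blocks, labels = blocks_from_frame(per_unit)
        result = friedman_test(blocks, condition_labels=labels)
        groups = {
            lbl: blocks[:, j] for j, lbl in enumerate(labels)
        }
        result.pairwise = steel_dwass(groups, exact=False)
        result.extra["branch"] = "nonparametric"
    else:
        result = rm_anova_bonferroni(
            frame, unit=unit, condition=condition, time=time, value=value
        )
        result.extra["branch"] = "parametric"
    result.extra["ks_p"] = ks_p
    result.extra["alpha"] = alpha
    return result
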