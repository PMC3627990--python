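"""Inferential layer over cohort score tables.

Exact (Clopper-Pearson) binomial intervals for response rates, chi-square
proportion tests between independent groups, McNemar tests for paired rates
within bees, Spearman rank correlations with bootstrap standard errors, a
bee-level cluster bootstrap for group-mean comparison, and inter-observer
concordance.

The cluster bootstrap replaces a mixed model with bee as random effect: it
resamples bees (clusters) with replacement, yielding per-group means, 95%
percentile intervals and an overlap probability p — the fraction of one
group's resampled means falling inside the other group's interval — used as
the significance measure for group contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "RateSummary",
    "GroupComparison",
    "clopper_pearson",
    "two_proportion_test",
    "mcnemar_test",
    "spearman_bootstrap",
    "cluster_bootstrap_means",
    "concordance",
    "summarize_cohort",
]


@dataclass(frozen=True)
class RateSummary:
    """A binomial rate with its exact two-sided confidence interval."""

    k: int
    n: int
    rate: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def as_dict(self) -> dict:
        return {
            "k": self.k, "n": self.n, "rate": self.rate,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "level": self.level,
        }


@dataclass
class GroupComparison:
    """Cluster-bootstrap group means with intervals and overlap probabilities."""

    groups: dict[str, dict]  # label -> {mean, ci_low, ci_high, n, n_clusters}
    p_overlap: dict[str, float]  # "g1|g2" -> P(g1 mean inside g2 interval)
    n_boot: int
    level: float = 0.95

    def as_dict(self) -> dict:
        return {
            "groups": self.groups,
            "p_overlap": self.p_overlap,
            "n_boot": self.n_boot,
            "level": self.level,
        }


def clopper_pearson(k: int, n: int, level: float = 0.95) -> RateSummary:
    """Exact binomial confidence interval by inverting the binomial tails.

    The lower bound is 0 when k = 0 and the upper bound 1 when k = n.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    low, high = proportion_confint(k, n, alpha=1.0 - level, method="beta")
    return RateSummary(
        k=int(k), n=int(n), rate=k / n,
        ci_low=float(0.0 if k == 0 else low),
        ci_high=float(1.0 if k == n else high),
        level=level,
    )


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, correction: bool = True
) -> tuple[float, int, float]:
    """Chi-square test comparing two independent proportions (1 df).

    Yates continuity correction is applied by default, matching the usual
    two-sample proportions test.  Returns (statistic, df, p).
    """
    if min(n1, n2) < 1:
        raise ValueError("both groups need at least one observation")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts may not exceed totals")
    if np.any(table.sum(axis=0) == 0):
        raise ValueError("degenerate 2x2 table: an outcome margin is empty")
    if k1 * n2 == k2 * n1:  # identical rates: statistic 0 by convention
        return 0.0, 1, 1.0
    res = sps.chi2_contingency(table, correction=correction)
    return float(res.statistic), 1, float(res.pvalue)


def mcnemar_test(b: int, c: int, correction: bool = False) -> tuple[float, int, float]:
    """McNemar chi-square for paired rates from the discordant-pair counts.

    ``b`` and ``c`` count the two kinds of discordant pairs.  The default is
    the uncorrected statistic (b - c)^2 / (b + c); the continuity-corrected
    variant is available behind the flag.  Returns (statistic, df, p),
    two-sided.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        raise ValueError("no discordant pairs: the test is undefined")
    table = np.array([[0, b], [c, 0]])
    res = _sm_mcnemar(table, exact=False, correction=correction)
    return float(res.statistic), 1, float(res.pvalue)


def spearman_bootstrap(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rank correlation with a case-bootstrap standard error.

    Uses the average-rank (tie-corrected) formula.  A constant input vector
    makes the correlation undefined; (nan, nan) is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho = float(sps.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = x.size
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.all(xb == xb[0]) or np.all(yb == yb[0]):
            boots[i] = np.nan
        else:
            boots[i] = sps.spearmanr(xb, yb).statistic
    se = float(np.nanstd(boots, ddof=1))
    return rho, se


def cluster_bootstrap_means(
    table: pd.DataFrame,
    value_field: str,
    group_field: str,
    cluster_field: str,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> GroupComparison:
    """Group means with cluster-bootstrap intervals and overlap probabilities.

    Clusters (bees) are resampled with replacement within each group; the
    interval is the percentile interval of the resampled group means.  With
    all clusters of size one this reduces to the ordinary case bootstrap.
    ``p_overlap["g1|g2"]`` is the fraction of g1's resampled means lying
    inside g2's interval; small values indicate separated groups.
    """
    for col in (value_field, group_field, cluster_field):
        if col not in table.columns:
            raise ValueError(f"column {col!r} not in table")
    groups = sorted(table[group_field].astype(str).unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0

    boot_means: dict[str, np.ndarray] = {}
    summary: dict[str, dict] = {}
    for g in groups:
        sub = table[table[group_field].astype(str) == g]
        clusters = [
            np.asarray(v[value_field], dtype=float) for _, v in sub.groupby(cluster_field)
        ]
        if len(clusters) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 clusters")
        means = np.empty(n_boot)
        m = len(clusters)
        for i in range(n_boot):
            pick = rng.integers(0, m, size=m)
            vals = np.concatenate([clusters[j] for j in pick])
            means[i] = vals.mean()
        boot_means[g] = means
        lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
        summary[g] = {
            "mean": float(sub[value_field].mean()),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "n": int(len(sub)),
            "n_clusters": m,
        }

    p_overlap: dict[str, float] = {}
    for g1 in groups:
        for g2 in groups:
            if g1 == g2:
                continue
            lo, hi = summary[g2]["ci_low"], summary[g2]["ci_high"]
            inside = (boot_means[g1] >= lo) & (boot_means[g1] <= hi)
            p_overlap[f"{g1}|{g2}"] = float(inside.mean())
    return GroupComparison(groups=summary, p_overlap=p_overlap, n_boot=n_boot, level=level)


def concordance(calls_a: Sequence, calls_b: Sequence) -> float:
    """Percent agreement between two binary call vectors."""
    a = np.asarray(calls_a).astype(bool)
    b = np.asarray(calls_b).astype(bool)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("call vectors must be non-empty 1-D and of equal length")
    return float(100.0 * np.mean(a == b))


# ---------------------------------------------------------------------------
# cohort summary


def _trial_labels(frame: pd.DataFrame) -> pd.Series:
    """Label each test stimulus 1.CS+/2.CS+/1.CS-/2.CS- per bee."""
    order = frame.sort_values(["bee_id", "stim_index"]).groupby(["bee_id", "role"]).cumcount()
    return (order.astype(int) + 1).astype(str) + "." + frame["role"]


def summarize_cohort(
    frame: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Full inferential summary of a scored cohort (one row per stimulus).

    Produces rate summaries per stimulus class, CS+ vs CS- proportion
    tests, within-bee McNemar tests (per-trial and per-bee-pooled
    variants), the three rank correlations (velocity-escape, AI-escape,
    velocity-AI) with bootstrap SEs, and cluster-bootstrap group
    comparisons for velocity and AI by stimulus class, overall and within
    the escape subset.  Degenerate pieces (too few bees/clusters) are
    reported as null rather than failing.
    """
    frame = frame.copy()
    frame["class"] = _trial_labels(frame)

    out: dict = {"n_bees": int(frame["bee_id"].nunique()), "n_stimuli": int(len(frame))}

    rates = {}
    for cls, sub in frame.groupby("class"):
        rates[cls] = clopper_pearson(int(sub["escaped"].sum()), len(sub)).as_dict()
    out["escape_rates"] = rates

    def _counts(cls: str) -> tuple[int, int]:
        sub = frame[frame["class"] == cls]
        return int(sub["escaped"].sum()), len(sub)

    tests: dict = {}
    try:
        k1, n1 = _counts("1.CS+")
        k2, n2 = _counts("1.CS-")
        stat, df, p = two_proportion_test(k1, n1, k2, n2)
        tests["first_csplus_vs_first_csminus"] = {"chi2": stat, "df": df, "p": p}
    except ValueError as exc:
        tests["first_csplus_vs_first_csminus"] = {"error": str(exc)}

    # paired within-bee comparisons: per-trial (first trials) and pooled
    # (any escape on a role across both trials) variants
    wide = frame.pivot_table(
        index="bee_id", columns="class", values="escaped", aggfunc="first"
    )
    for label, (col_a, col_b) in {
        "mcnemar_first_trials": ("1.CS+", "1.CS-"),
        "mcnemar_second_trials": ("2.CS+", "2.CS-"),
    }.items():
        try:
            if col_a not in wide or col_b not in wide:
                raise ValueError("missing stimulus class")
            a = wide[col_a].astype(bool)
            bcol = wide[col_b].astype(bool)
            b = int((a & ~bcol).sum())
            c = int((~a & bcol).sum())
            stat, df, p = mcnemar_test(b, c)
            tests[label] = {"b": b, "c": c, "chi2": stat, "df": df, "p": p}
        except ValueError as exc:
            tests[label] = {"error": str(exc)}
    try:
        pooled = frame.groupby(["bee_id", "role"])["escaped"].any().unstack()
        a = pooled["CS+"].astype(bool)
        bcol = pooled["CS-"].astype(bool)
        b = int((a & ~bcol).sum())
        c = int((~a & bcol).sum())
        stat, df, p = mcnemar_test(b, c)
        tests["mcnemar_pooled_per_bee"] = {"b": b, "c": c, "chi2": stat, "df": df, "p": p}
    except (ValueError, KeyError) as exc:
        tests["mcnemar_pooled_per_bee"] = {"error": str(exc)}
    out["tests"] = tests

    corr = {}
    esc = frame["escaped"].astype(float).to_numpy()
    for label, (xcol, ycol) in {
        "velocity_vs_escape": ("velocity_cm_s", None),
        "ai_vs_escape": ("ai", None),
        "velocity_vs_ai": ("velocity_cm_s", "ai"),
    }.items():
        x = frame[xcol].to_numpy(dtype=float)
        y = esc if ycol is None else frame[ycol].to_numpy(dtype=float)
        try:
            rho, se = spearman_bootstrap(x, y, n_boot=min(n_boot, 1000), seed=seed)
            corr[label] = {"rho": rho, "se": se}
        except ValueError as exc:
            corr[label] = {"error": str(exc)}
    out["correlations"] = corr

    comparisons = {}
    for label, sub in {
        "all_responses": frame,
        "escape_subset": frame[frame["escaped"]],
    }.items():
        for value in ("velocity_cm_s", "ai"):
            key = f"{value}_by_class_{label}"
            try:
                comparisons[key] = cluster_bootstrap_means(
                    sub, value, "class", "bee_id", n_boot=n_boot, seed=seed
                ).as_dict()
            except ValueError as exc:
                comparisons[key] = {"degenerate": str(exc)}
    out["group_comparisons"] = comparisons

    means: dict = {}
    for role in ("CS+", "CS-"):
        sub = frame[frame["role"] == role]
        esc_sub = sub[sub["escaped"]]
        means[role] = {
            "velocity_mean": float(sub["velocity_cm_s"].mean()) if len(sub) else None,
            "ai_mean": float(sub["ai"].mean()) if len(sub) else None,
            "velocity_mean_escapes": (
                float(esc_sub["velocity_cm_s"].mean()) if len(esc_sub) else None
            ),
            "ai_mean_escapes": float(esc_sub["ai"].mean()) if len(esc_sub) else None,
            "n_escapes": int(sub["escaped"].sum()),
        }
    out["role_means"] = means
    return out
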