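"""Shared statistics core: normality gate, one-way ANOVA, Tukey(-Kramer) HSD.

These operations back both the network class-separation test and the assay
comparisons.  The ANOVA is the classical fixed-effects F test computed from
sums of squares; Tukey's honestly-significant-difference procedure uses the
studentized range distribution, in the Kramer form for unbalanced designs
(standard error from the pooled within-group mean square with
(1/n_i + 1/n_j)/2).
"""

from __future__ import annotations

import dataclasses
import logging
from functools import lru_cache
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

logger = logging.getLogger("leadnet")


class AnovaResult(NamedTuple):
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int


def _as_group_arrays(values_by_group) -> dict[str, np.ndarray]:
    out = {}
    for g, vals in values_by_group.items():
        arr = np.asarray(list(vals), dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"group {g!r} contains non-finite values")
        out[g] = arr
    return out


def one_way_anova(values_by_group) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Requires >= 2 groups, each with n >= 2.  Returns F, the upper-tail
    p-value, and both degrees of freedom.  A design with zero within- and
    between-group variance returns F = 0, p = 1 by convention.
    """
    groups = _as_group_arrays(values_by_group)
    if len(groups) < 2:
        raise ValidationError("one-way ANOVA needs >= 2 groups")
    for g, arr in groups.items():
        if arr.size < 2:
            raise ValidationError(f"group {g!r} has n < 2")
    all_vals = np.concatenate(list(groups.values()))
    n_total, k = all_vals.size, len(groups)
    df_between, df_within = k - 1, n_total - k
    if df_within < 1:
        raise ValidationError("insufficient within-group degrees of freedom")
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in groups.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in groups.values())
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        if ms_between == 0.0:
            return AnovaResult(0.0, 1.0, df_between, df_within)
        return AnovaResult(np.inf, 0.0, df_between, df_within)
    f = ms_between / ms_within
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), p, df_between, df_within)


@lru_cache(maxsize=128)
def _q_critical(alpha: float, k: int, df: int) -> float:
    return float(sps.studentized_range.ppf(1.0 - alpha, k, df))


def tukey_hsd(values_by_group, alpha: float = 0.05, pvalues: bool = True) -> pd.DataFrame:
    """All-pairs Tukey (Tukey-Kramer when unbalanced) honest significant difference.

    Parameters
    ----------
    values_by_group : mapping group -> sequence of float
    alpha : float
        Familywise error level for the ``significant`` flag.
    pvalues : bool
        When False, skip the studentized-range survival-function evaluation
        (the expensive step) and report only q statistics and significance
        decided against the cached critical value; the decisions are
        identical to ``p_adj < alpha``.

    Returns
    -------
    pandas.DataFrame
        Columns group1, group2, mean_diff, se, q, p_adj, significant.
    """
    groups = _as_group_arrays(values_by_group)
    if len(groups) < 2:
        raise ValidationError("Tukey HSD needs >= 2 groups")
    for g, arr in groups.items():
        if arr.size < 2:
            raise ValidationError(f"group {g!r} has n < 2")
    names = list(groups)
    k = len(names)
    n_total = sum(a.size for a in groups.values())
    df_within = n_total - k
    ms_within = sum(((a - a.mean()) ** 2).sum() for a in groups.values()) / df_within

    rows = []
    q_stats = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[names[i]], groups[names[j]]
            diff = a.mean() - b.mean()
            se_q = np.sqrt(ms_within / 2.0 * (1.0 / a.size + 1.0 / b.size))
            q = np.abs(diff) / se_q if se_q > 0 else (0.0 if diff == 0 else np.inf)
            rows.append({"group1": names[i], "group2": names[j],
                         "mean_diff": float(diff), "se": float(se_q),
                         "q": float(q)})
            q_stats.append(q)

    q_arr = np.asarray(q_stats)
    if pvalues:
        with np.errstate(all="ignore"):
            p_adj = sps.studentized_range.sf(np.where(np.isfinite(q_arr), q_arr, 1e3),
                                             k, df_within)
        p_adj = np.where(np.isfinite(q_arr), p_adj, 0.0)
        p_adj = np.clip(p_adj, 0.0, 1.0)
    else:
        p_adj = np.full(q_arr.size, np.nan)
    q_crit = _q_critical(float(alpha), k, df_within)
    sig = q_arr > q_crit
    df = pd.DataFrame(rows)
    df["p_adj"] = p_adj
    df["significant"] = sig
    return df


def normality_gate(values_by_group, alpha: float = 0.05) -> pd.DataFrame:
    """Per-group Shapiro-Wilk and Kolmogorov-Smirnov normality screen.

    Shapiro-Wilk is decisive: the gate passes iff every group's Shapiro p
    exceeds ``alpha``.  The KS statistic (against a normal with the group's
    estimated mean/SD, so Lilliefors-conservative p-values) is reported as
    advisory only.  Zero-variance groups fail with statistic 1 and p 0.

    Returns a DataFrame with one row per group: columns group, n,
    shapiro_stat, shapiro_p, ks_stat, ks_p, passed; the overall gate outcome
    is attached as ``df.attrs["passed"]``.
    """
    groups = _as_group_arrays(values_by_group)
    rows = []
    for g, arr in groups.items():
        if arr.size < 3:
            raise ValidationError(f"group {g!r} has n < 3; Shapiro-Wilk needs >= 3")
        if np.ptp(arr) == 0.0:
            rows.append({"group": g, "n": arr.size, "shapiro_stat": 1.0,
                         "shapiro_p": 0.0, "ks_stat": 1.0, "ks_p": 0.0,
                         "passed": False})
            continue
        sw = sps.shapiro(arr)
        ks = sps.kstest(arr, "norm", args=(arr.mean(), arr.std(ddof=1)))
        logger.debug("KS uses estimated parameters; p-values are Lilliefors-"
                     "conservative and advisory only")
        rows.append({"group": g, "n": arr.size,
                     "shapiro_stat": float(sw.statistic), "shapiro_p": float(sw.pvalue),
                     "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue),
                     "passed": bool(sw.pvalue > alpha)})
    df = pd.DataFrame(rows)
    df.attrs["passed"] = bool(df["passed"].all())
    return df


@dataclasses.dataclass
class GroupStats:
    """Descriptives plus ANOVA/Tukey for a grouped measurement."""

    summary: pd.DataFrame          # group, n, mean, sd
    anova: AnovaResult
    tukey: pd.DataFrame
    normality: pd.DataFrame | None
    normality_passed: bool | None

    def to_frame(self) -> pd.DataFrame:
        """Flat per-pair table with the ANOVA columns repeated (for CSV)."""
        df = self.tukey.copy()
        df["anova_f"] = self.anova.f_statistic
        df["anova_p"] = self.anova.p_value
        return df


def group_stats(values_by_group, alpha: float = 0.05,
                check_normality: bool = True) -> GroupStats:
    """Descriptives + normality gate + one-way ANOVA + Tukey HSD in one call.

    When the normality gate fails the ANOVA is still computed but the result
    is flagged (``normality_passed`` False) and a warning is logged, mirroring
    a screen-then-test analysis workflow.
    """
    groups = _as_group_arrays(values_by_group)
    summary = pd.DataFrame(
        [{"group": g, "n": a.size, "mean": float(a.mean()),
          "sd": float(a.std(ddof=1)) if a.size > 1 else np.nan}
         for g, a in groups.items()]
    )
    normality = passed = None
    if check_normality:
        normality = normality_gate(groups, alpha=alpha)
        passed = normality.attrs["passed"]
        if not passed:
            logger.warning("normality gate failed; ANOVA/Tukey flagged as advisory")
    anova = one_way_anova(groups)
    tukey = tukey_hsd(groups, alpha=alpha)
    return GroupStats(summary=summary, anova=anova, tukey=tukey,
                      normality=normality, normality_passed=passed)
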