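"""Behavioural and neuropsychological summary statistics.

Efficiency scores, single-pass RT outlier trimming, pooled-variance
effect sizes and group tests computable from printed summary tables
(group means, SDs and ns), and the mixed Group x Repetition ANOVA on
reading-aloud latencies.

Sign convention: group contrasts are computed as (first group - second
group); passing the clinical group first yields negative d and t when
that group performs worse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rsa_inference import FactorialResult

__all__ = [
    "GroupSummary",
    "efficiency_score",
    "trim_rt_outliers",
    "cohens_d",
    "two_sample_t",
    "repetition_anova",
]


@dataclass(frozen=True)
class GroupSummary:
    """Printed group summary: label, n, mean, SD for one measure."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("SD must be nonnegative")


def efficiency_score(accuracy: float, rt: float) -> float:
    """Composite speed-accuracy score: (accuracy / response time) * 10."""
    if rt <= 0:
        raise ValueError("response time must be positive")
    return accuracy / rt * 10.0


def trim_rt_outliers(
    rts: np.ndarray, k: float = 2.5
) -> tuple[np.ndarray, int]:
    """Single-pass per-subject RT trimming at mean +/- k * SD.

    The bounds are computed once from the full sample (no
    re-iteration).  A zero-SD sample removes nothing.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 3:
        raise ValueError("need at least 3 RTs to trim")
    mu, sd = rts.mean(), rts.std(ddof=1)
    if sd == 0 or not np.isfinite(k):
        return rts.copy(), 0
    keep = np.abs(rts - mu) <= k * sd
    return rts[keep], int((~keep).sum())


def _pooled_sd(a: GroupSummary, b: GroupSummary) -> float:
    num = (a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2
    return float(np.sqrt(num / (a.n + b.n - 2)))


def cohens_d(a: GroupSummary, b: GroupSummary) -> float:
    """Pooled-SD standardized mean difference (a - b)."""
    sp = _pooled_sd(a, b)
    if sp == 0:
        raise ValueError("zero pooled SD")
    return (a.mean - b.mean) / sp


def two_sample_t(a: GroupSummary, b: GroupSummary) -> tuple[float, int, float]:
    """Pooled-variance two-sample t test from summaries.

    Returns (t, dof, two-sided p) with dof = n_a + n_b - 2.
    """
    sp = _pooled_sd(a, b)
    if sp == 0:
        raise ValueError("zero pooled SD")
    dof = a.n + b.n - 2
    t = (a.mean - b.mean) / (sp * np.sqrt(1.0 / a.n + 1.0 / b.n))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(t), dof, float(p)


def repetition_anova(trials: pd.DataFrame) -> list[FactorialResult]:
    """Mixed ANOVA on RTs: Group (between) x Repetition (within).

    ``trials`` needs columns ``subject``, ``group``, ``repetition``,
    ``rt_ms``; repeated observations within a subject x repetition cell
    are averaged first.  Classical univariate decomposition: the Group
    effect is tested against subjects-within-groups, Repetition and the
    interaction against repetition x subjects-within-groups.  No
    sphericity correction is applied.
    """
    required = {"subject", "group", "repetition", "rt_ms"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trials table needs columns {sorted(required)}")
    agg = (
        trials.groupby(["subject", "group", "repetition"], as_index=False)[
            "rt_ms"
        ].mean()
    )
    counts = agg.pivot_table(
        index="subject", columns="repetition", values="rt_ms", aggfunc="size"
    )
    if counts.isna().any().any():
        raise ValueError("missing subject x repetition cells")
    if np.ptp(agg["rt_ms"].to_numpy()) == 0:
        raise ValueError("constant response: degenerate model")
    # the repetition x subjects-within-group error term must be positive
    subj_mean = agg.groupby("subject")["rt_ms"].transform("mean")
    cell_mean = agg.groupby(["group", "repetition"])["rt_ms"].transform("mean")
    group_mean = agg.groupby("group")["rt_ms"].transform("mean")
    ss_err = ((agg["rt_ms"] - subj_mean - cell_mean + group_mean) ** 2).sum()
    scale = max(float(agg["rt_ms"].var()), 1.0)
    if ss_err <= 1e-12 * scale:
        raise ValueError(
            "zero within-subject error variance: degenerate model"
        )
    import pingouin as pg

    aov = pg.mixed_anova(
        data=agg,
        dv="rt_ms",
        within="repetition",
        between="group",
        subject="subject",
        correction=False,
    )
    out = []
    for _, row in aov.iterrows():
        out.append(
            FactorialResult(
                term=str(row["Source"]),
                F=float(row["F"]),
                df_num=float(row["DF1"]),
                df_den=float(row["DF2"]),
                p=float(row["p_unc"]),
            )
        )
    return out
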