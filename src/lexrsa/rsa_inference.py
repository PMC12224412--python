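"""Second-order inference: partial rank correlations and group tests.

The core statistic is the partial Spearman correlation between a neural
RDM and a theoretical model RDM, controlling for confound RDMs
(lexical frequency and word length): all RDM vectors are rank
transformed (average ranks for ties), the neural and model ranks are
residualized on the confound ranks by least squares with an intercept,
and the Pearson correlation of the residuals is returned.  With no
confounds this is the plain Spearman correlation.

Group inference uses two-sided Wilcoxon signed-rank tests against a
zero median within groups, pooled-variance two-sample t (or rank-sum)
tests between groups, and Benjamini–Hochberg FDR q-values across the
model dimension.  Factorial follow-ups (ANCOVA with a fluency
covariate, gradient ANOVA with Tukey post hocs) run on the resulting
correlation tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .core import RDM, PatternMatrix
from .neural_rdm import crossval_euclidean_rdm, remove_dead_voxels

__all__ = [
    "partial_spearman",
    "signed_rank_test",
    "between_group_test",
    "fdr_bh",
    "fit_factorial",
    "tukey_posthoc",
    "RSAConfig",
    "run_rsa",
]


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v)  # average ranks for ties


def partial_spearman(
    neural: np.ndarray,
    model: np.ndarray,
    confounds: list[np.ndarray] | None = None,
) -> float:
    """Partial Spearman correlation of two RDM vectors given confounds.

    Parameters are strictly-lower-triangle RDM vectors of equal length
    (>= 4 pairs).  With an empty confound list this equals the plain
    Spearman correlation.
    """
    x = np.asarray(neural, dtype=float)
    y = np.asarray(model, dtype=float)
    confounds = confounds or []
    if x.shape != y.shape or x.ndim != 1 or x.size < 4:
        raise ValueError("need equal-length 1-D vectors with >= 4 entries")
    for c in confounds:
        if np.asarray(c).shape != x.shape:
            raise ValueError("confound vectors must match in length")
    rx, ry = _rank(x), _rank(y)
    if confounds:
        Z = np.column_stack(
            [np.ones_like(rx)] + [_rank(np.asarray(c, float)) for c in confounds]
        )
        bx, *_ = np.linalg.lstsq(Z, rx, rcond=None)
        by, *_ = np.linalg.lstsq(Z, ry, rcond=None)
        rx = rx - Z @ bx
        ry = ry - Z @ by
    else:
        rx = rx - rx.mean()
        ry = ry - ry.mean()
    sx, sy = np.sqrt((rx**2).sum()), np.sqrt((ry**2).sum())
    if sx <= 1e-12 * x.size or sy <= 1e-12 * x.size:
        raise ValueError(
            "undefined partial correlation: zero-variance residuals"
        )
    return float((rx @ ry) / (sx * sy))


def signed_rank_test(values: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value against a zero median.

    Exact zeros are dropped (Wilcoxon's original rule).  The exact null
    distribution is used for n <= 25 (when ranks are untied), the
    normal approximation with continuity correction above.
    """
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    n = v.size
    if n < 5:
        raise ValueError("need at least 5 nonzero values")
    ranks = stats.rankdata(np.abs(v))
    has_ties = np.unique(ranks).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        v,
        zero_method="wilcox",
        correction=(method == "approx"),
        alternative="two-sided",
        method=method,
    )
    return float(res.pvalue)


def between_group_test(
    a: np.ndarray, b: np.ndarray, method: str = "ttest"
) -> tuple[float, float]:
    """Two-sided between-group test: pooled-variance two-sample t
    (``"ttest"``) or Wilcoxon rank-sum (``"ranksum"``).

    Returns (statistic, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if method == "ttest":
        if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
            raise ValueError("zero pooled variance")
        res = stats.ttest_ind(a, b, equal_var=True)
        return float(res.statistic), float(res.pvalue)
    if method == "ranksum":
        res = stats.ranksums(a, b)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def fdr_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


@dataclass(frozen=True)
class FactorialResult:
    term: str
    F: float
    df_num: float
    df_den: float
    p: float


def fit_factorial(
    table: pd.DataFrame,
    response: str,
    factors: list[str],
    covariates: list[str] | None = None,
    interactions: list[tuple[str, ...]] | None = None,
) -> list[FactorialResult]:
    """Linear-model F tests (Type II sums of squares) on a long table.

    ``factors`` are treated as categorical, ``covariates`` as numeric;
    ``interactions`` name factor tuples whose products enter the model.
    Type II SS keeps the tests order-invariant in unbalanced designs.
    """
    covariates = covariates or []
    interactions = interactions or []
    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    if np.ptp(table[response].to_numpy(dtype=float)) == 0:
        raise ValueError("constant response: degenerate model")
    terms = [f"C({f})" for f in factors]
    terms += [":".join(f"C({f})" for f in ix) for ix in interactions]
    terms += list(covariates)
    formula = f"{response} ~ " + " + ".join(terms)
    fit = ols(formula, data=table).fit()
    if fit.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    # aliased (perfectly collinear) terms make Type II SS meaningless
    rank = np.linalg.matrix_rank(fit.model.exog)
    if rank < fit.model.exog.shape[1]:
        raise ValueError("aliased model terms: design matrix is singular")
    aov = anova_lm(fit, typ=2)
    out = []
    for term, row in aov.iterrows():
        if term == "Residual":
            continue
        out.append(
            FactorialResult(
                term=str(term),
                F=float(row["F"]),
                df_num=float(row["df"]),
                df_den=float(aov.loc["Residual", "df"]),
                p=float(row["PR(>F)"]),
            )
        )
    return out


def tukey_posthoc(
    values: np.ndarray, cells: np.ndarray
) -> pd.DataFrame:
    """Tukey(-Kramer) studentized-range pairwise comparisons.

    ``values`` are observations, ``cells`` their cell labels.  Uses the
    pooled within-cell variance as the error term.  With two cells the
    adjusted p equals the unadjusted pooled t-test p.
    """
    values = np.asarray(values, dtype=float)
    cells = np.asarray(cells)
    labels = list(dict.fromkeys(cells.tolist()))
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 cells")
    groups = [values[cells == lab] for lab in labels]
    ns = np.array([g.size for g in groups])
    if np.any(ns < 1):
        raise ValueError("empty cell")
    df_resid = int(values.size - k)
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    means = np.array([g.mean() for g in groups])
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    mse = sse / df_resid
    if mse <= 0:
        raise ValueError("zero residual variance")
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_resid))
            rows.append(
                {
                    "cell_a": labels[i],
                    "cell_b": labels[j],
                    "diff": diff,
                    "p_adj": min(1.0, p),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RSAConfig:
    """Knobs for the end-to-end second-order analysis."""

    alpha: float = 0.05
    fdr_family: str = "per_group_roi"  # or "pooled" across ROIs
    between_method: str = "ttest"
    partition_scheme: str = "ordered_pairs"


def subject_rhos(
    patterns: PatternMatrix,
    models: dict[str, RDM],
    confounds: list[RDM],
    scheme: str = "ordered_pairs",
) -> dict[str, float]:
    """Partial Spearman of one subject's neural RDM against each model."""
    cleaned, _ = remove_dead_voxels(patterns)
    neural = crossval_euclidean_rdm(cleaned, scheme=scheme)
    conf_vecs = [c.reorder(neural.labels).vector() for c in confounds]
    nv = neural.vector()
    return {
        name: partial_spearman(nv, m.reorder(neural.labels).vector(), conf_vecs)
        for name, m in models.items()
    }


def run_rsa(
    patterns_by_subject: dict[str, PatternMatrix],
    groups: dict[str, str],
    models: dict[str, RDM],
    confounds: list[RDM],
    cfg: RSAConfig = RSAConfig(),
    roi: str = "ROI",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject correlations and group-level inference.

    Returns ``(rsa_results, group_results)``:

    * ``rsa_results`` — one row per subject x model with the partial
      Spearman rho;
    * ``group_results`` — per group x model signed-rank p/q values
      (BH correction across the model dimension within each group by
      default, or pooled across the whole table with
      ``fdr_family="pooled"``), plus between-group rows when two
      groups are present.
    """
    rows = []
    for sid, pat in patterns_by_subject.items():
        rhos = subject_rhos(pat, models, confounds, cfg.partition_scheme)
        for model_name, rho in rhos.items():
            rows.append(
                {
                    "subject": sid,
                    "group": groups[sid],
                    "roi": roi,
                    "model": model_name,
                    "rho": rho,
                }
            )
    rsa_results = pd.DataFrame(rows)

    grows = []
    for (group, model), sub in rsa_results.groupby(["group", "model"]):
        p = signed_rank_test(sub["rho"].to_numpy())
        grows.append(
            {
                "roi": roi,
                "model": model,
                "contrast": group,
                "kind": "within",
                "statistic": float(np.median(sub["rho"])),
                "p": p,
            }
        )
    group_labels = sorted(set(groups.values()))
    if len(group_labels) == 2:
        ga, gb = group_labels
        for model, sub in rsa_results.groupby("model"):
            a = sub.loc[sub["group"] == ga, "rho"].to_numpy()
            b = sub.loc[sub["group"] == gb, "rho"].to_numpy()
            stat, p = between_group_test(a, b, cfg.between_method)
            grows.append(
                {
                    "roi": roi,
                    "model": model,
                    "contrast": f"{ga}-{gb}",
                    "kind": "between",
                    "statistic": stat,
                    "p": p,
                }
            )
    group_results = pd.DataFrame(grows)
    if cfg.fdr_family == "pooled":
        group_results["q"] = fdr_bh(group_results["p"].to_numpy())
    else:
        group_results["q"] = np.nan
        for _, idx in group_results.groupby(["roi", "contrast"]).groups.items():
            group_results.loc[idx, "q"] = fdr_bh(
                group_results.loc[idx, "p"].to_numpy()
            )
    return rsa_results, group_results
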