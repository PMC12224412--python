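"""Cross-validated Euclidean distance RDMs from multi-run patterns.

The distance between two conditions a and b is estimated as the inner
product of their pattern-difference vectors taken from *independent*
run partitions:

    d_p(a, b) = (x̄_a^T - x̄_b^T) · (x̄_a^S - x̄_b^S) / n_voxels

averaged over a partition scheme.  Because train and test noise are
independent, the estimator is unbiased: the expected self-distance is
zero and entries can undershoot zero.  Normalization by voxel count
makes values comparable across regions of different size.

Two partition schemes are provided: ``ordered_pairs`` (all ordered
pairs of distinct runs — true cross-validation, 12 partitions for 4
runs, the default) and ``all_pairs`` (including train == test, r^2
partitions, 16 for 4 runs — not fully cross-validated, provided for
comparability with analyses that report that count).
"""

from __future__ import annotations

import numpy as np

from .core import RDM, NeuralRDM, PatternMatrix

__all__ = [
    "remove_dead_voxels",
    "make_partitions",
    "crossval_euclidean_rdm",
    "naive_euclidean_rdm",
]


def remove_dead_voxels(
    patterns: PatternMatrix,
) -> tuple[PatternMatrix, int]:
    """Drop voxels with no activation (zero variance across samples).

    Returns the cleaned patterns and the number of voxels removed;
    voxel order is preserved.  Raises if nothing survives.
    """
    if patterns.n_voxels < 1:
        raise ValueError("need at least one voxel")
    var = patterns.values.var(axis=0)
    keep = var > 0
    removed = int((~keep).sum())
    if not keep.any():
        raise ValueError("all voxels are dead (zero variance)")
    if removed == 0:
        return patterns, 0
    return patterns.select_voxels(keep), removed


def make_partitions(
    runs: tuple[int, ...], scheme: str = "ordered_pairs"
) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Enumerate (train-runs, test-runs) pairs.

    ``ordered_pairs``: all ordered pairs of distinct runs, r(r-1)
    partitions.  ``all_pairs``: all ordered pairs including
    train == test, r^2 partitions.
    """
    runs = tuple(sorted(set(runs)))
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to cross-validate")
    if scheme == "ordered_pairs":
        return [((r,), (s,)) for r in runs for s in runs if r != s]
    if scheme == "all_pairs":
        return [((r,), (s,)) for r in runs for s in runs]
    raise ValueError(f"unknown partition scheme {scheme!r}")


def _partition_mean(
    run_means: dict[int, np.ndarray], part: tuple[int, ...]
) -> np.ndarray:
    return np.mean([run_means[r] for r in part], axis=0)


def crossval_euclidean_rdm(
    patterns: PatternMatrix,
    partitions: list[tuple[tuple[int, ...], tuple[int, ...]]] | None = None,
    scheme: str = "ordered_pairs",
) -> NeuralRDM:
    """Cross-validated (squared) Euclidean distance RDM.

    For each partition the cross-gram G = X_T X_S^T / V over condition
    means gives d(a, b) = G_aa + G_bb - G_ab - G_ba; entries are
    averaged over partitions and symmetrized.  The diagonal is zero by
    construction.
    """
    conditions = patterns.condition_labels
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    run_means = patterns.run_means(conditions)  # raises naming missing cond
    if partitions is None:
        partitions = make_partitions(patterns.run_labels, scheme)
    if not partitions:
        raise ValueError("empty partition scheme")
    V = patterns.n_voxels
    acc = np.zeros((len(conditions), len(conditions)))
    for train, test in partitions:
        if not train or not test:
            raise ValueError("partitions must be nonempty")
        XT = _partition_mean(run_means, train)
        XS = _partition_mean(run_means, test)
        G = XT @ XS.T / V
        g = np.diag(G)
        acc += g[:, None] + g[None, :] - G - G.T
    vals = acc / len(partitions)
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 0.0)
    return NeuralRDM(
        labels=conditions,
        values=vals,
        n_partitions=len(partitions),
        n_voxels=V,
    )


def naive_euclidean_rdm(patterns: PatternMatrix) -> RDM:
    """Squared Euclidean distance of run-averaged patterns / n_voxels.

    Positively biased under noise; serves as the noiseless-limit
    reference for the cross-validated estimator.
    """
    conditions = patterns.condition_labels
    run_means = patterns.run_means(conditions)
    mean_pat = np.mean(list(run_means.values()), axis=0)
    diff2 = (
        (mean_pat[:, None, :] - mean_pat[None, :, :]) ** 2
    ).sum(axis=2) / patterns.n_voxels
    np.fill_diagonal(diff2, 0.0)
    return RDM(labels=conditions, values=diff2)
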