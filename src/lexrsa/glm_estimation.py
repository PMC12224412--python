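"""Condition-pattern estimation from event-related time series.

A least-squares GLM with one task regressor per condition per run
(pooling repeated presentations of the same word), canonical
double-gamma HRF convolution, an intercept and discrete-cosine drift
terms realizing a high-pass filter.  Condition estimates are converted
to t-values against the implicitly modelled baseline, which is the
per-condition voxel pattern the downstream RDM stage consumes.

No autocorrelation modelling is applied: t-values here feed a
*relative* pattern-geometry analysis, not univariate inference, and
run-level serial correlation cancels largely in the cross-validated
distances (see the methods note for the stated limitation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .core import PatternMatrix

__all__ = [
    "HRFParams",
    "DesignMatrix",
    "canonical_hrf",
    "build_design",
    "fit_glm",
    "tmap",
    "estimate_patterns",
]

BASELINE = "baseline"


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF constants (seconds).

    The defaults (peak 6 s, undershoot 16 s, unit dispersions, 6:1
    peak:undershoot ratio, 32 s kernel) are the conventional choice in
    event-related fMRI software.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    length: float = 32.0

    def __post_init__(self) -> None:
        if self.peak_delay <= 0 or self.undershoot_delay <= 0:
            raise ValueError("HRF delays must be positive")
        if self.length <= self.peak_delay:
            raise ValueError("kernel length must exceed the peak delay")


def canonical_hrf(
    tr: float, params: HRFParams = HRFParams(), oversample: int = 16
) -> np.ndarray:
    """Double-gamma HRF sampled at ``tr / oversample``, peak-normalized.

    hrf(t) = Gamma(a1, d1).pdf(t) - Gamma(a2, d2).pdf(t) / ratio with
    shapes a = delay / dispersion and scales d = dispersion.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    dt = tr / oversample
    t = np.arange(0.0, params.length + dt / 2, dt)
    peak = gamma_dist.pdf(
        t, params.peak_delay / params.peak_dispersion,
        scale=params.peak_dispersion,
    )
    undershoot = gamma_dist.pdf(
        t,
        params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    hrf = peak - undershoot / params.ratio
    return hrf / hrf.max()


def _dct_drift(n_scans: int, tr: float, highpass_s: float) -> np.ndarray:
    """Discrete-cosine drift basis for periods >= ``highpass_s``.

    Number of basis functions K = floor(2 * N * TR / cutoff); the k-th
    column is cos(pi * k * (2t + 1) / (2N)), unit-normalized.
    """
    K = int(np.floor(2.0 * n_scans * tr / highpass_s))
    t = np.arange(n_scans)
    cols = [
        np.cos(np.pi * k * (2 * t + 1) / (2 * n_scans)) for k in range(1, K + 1)
    ]
    if not cols:
        return np.empty((n_scans, 0))
    X = np.column_stack(cols)
    return X / np.linalg.norm(X, axis=0)


@dataclass(frozen=True)
class DesignMatrix:
    """Scans x regressors design with named columns."""

    matrix: np.ndarray
    names: tuple[str, ...]
    tr: float
    task_names: tuple[str, ...]

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no design column named {name!r}") from None

    def task_matrix(self, conditions: tuple[str, ...]) -> np.ndarray:
        """Task columns (HRF-convolved regressors) in the given order."""
        return self.matrix[:, [self.column(c) for c in conditions]]


def build_design(
    events: pd.DataFrame,
    n_scans: int,
    tr: float,
    hrf_params: HRFParams = HRFParams(),
    highpass_s: float | None = 128.0,
    baseline_label: str = BASELINE,
    oversample: int = 16,
) -> DesignMatrix:
    """Build a single-run GLM design from an event table.

    One column per condition (rows of ``events`` sharing a
    ``trial_type``; repetitions of the same word pool into one
    regressor), each a boxcar at the event onsets/durations convolved
    with the canonical HRF and sampled at scan times, plus an intercept
    and, if ``highpass_s`` is set, discrete-cosine drift columns for
    periods >= that cutoff.  Events labelled ``baseline_label`` are left
    unmodelled (implicit baseline).
    """
    required = {"onset", "duration", "trial_type"}
    if not required.issubset(events.columns):
        raise ValueError(f"events table needs columns {sorted(required)}")
    ev = events[events["trial_type"] != baseline_label]
    if ((ev["onset"] + ev["duration"]) > n_scans * tr).any():
        raise ValueError("events extend beyond the scan window")
    conditions = tuple(dict.fromkeys(ev["trial_type"]))
    hrf = canonical_hrf(tr, hrf_params, oversample=oversample)
    dt = tr / oversample
    n_hi = n_scans * oversample
    cols = []
    for cond in conditions:
        boxcar = np.zeros(n_hi)
        sub = ev[ev["trial_type"] == cond]
        for onset, dur in zip(sub["onset"], sub["duration"]):
            a = int(round(onset / dt))
            b = max(a + 1, int(round((onset + dur) / dt)))
            boxcar[a : min(b, n_hi)] = 1.0
        conv = np.convolve(boxcar, hrf)[:n_hi]
        cols.append(conv[::oversample])
    names = list(conditions)
    X = np.column_stack(cols) if cols else np.empty((n_scans, 0))
    X = np.hstack([X, np.ones((n_scans, 1))])
    names.append("intercept")
    if highpass_s is not None:
        drift = _dct_drift(n_scans, tr, highpass_s)
        X = np.hstack([X, drift])
        names += [f"drift{k + 1}" for k in range(drift.shape[1])]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns whose removal restores full effective rank
        bad = []
        for k in range(X.shape[1]):
            keep = [c for c in range(X.shape[1]) if c != k]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(names[k])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return DesignMatrix(
        matrix=X, names=tuple(names), tr=tr, task_names=conditions
    )


@dataclass(frozen=True)
class GLMFit:
    betas: np.ndarray  # (n_regressors, n_voxels)
    residual_variance: np.ndarray  # (n_voxels,)
    dof: int
    design: DesignMatrix


def fit_glm(series: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares fit of a (scans x voxels) series."""
    Y = np.asarray(series, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError("series and design disagree on scan count")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more scans than regressors")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            "singular normal equations; using pseudo-inverse", stacklevel=2
        )
    betas, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ betas
    dof = X.shape[0] - rank
    resvar = (resid**2).sum(axis=0) / dof
    return GLMFit(betas=betas, residual_variance=resvar, dof=dof, design=design)


def tmap(fit: GLMFit, condition: str) -> np.ndarray:
    """Per-voxel t-values contrasting one condition against the
    implicit baseline (contrast selecting that single column)."""
    if fit.dof < 1:
        raise ValueError("need at least one residual degree of freedom")
    k = fit.design.column(condition)
    X = fit.design.matrix
    xtx_inv = np.linalg.pinv(X.T @ X)
    c_var = xtx_inv[k, k]
    beta = fit.betas[k]
    se = np.sqrt(fit.residual_variance * c_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
    if np.any(se == 0):
        warnings.warn(
            "zero residual variance in some voxels: infinite t-values",
            stacklevel=2,
        )
    # beta == 0 with se == 0 -> define t = 0 rather than nan
    t = np.where((se == 0) & (beta == 0), 0.0, t)
    return t


def estimate_patterns(
    series_by_run: dict[int, np.ndarray],
    events: pd.DataFrame,
    tr: float,
    conditions: tuple[str, ...],
    hrf_params: HRFParams = HRFParams(),
    highpass_s: float | None = 128.0,
) -> PatternMatrix:
    """Per-run condition t-maps from multi-run BOLD series.

    Fits one GLM per run (run-specific residual variance) and stacks
    the per-condition t-value patterns into a labelled PatternMatrix.
    """
    blocks, conds, runs = [], [], []
    for run in sorted(series_by_run):
        ev = events[events["run"] == run]
        series = np.asarray(series_by_run[run], dtype=float)
        design = build_design(
            ev, n_scans=series.shape[0], tr=tr,
            hrf_params=hrf_params, highpass_s=highpass_s,
        )
        fit = fit_glm(series, design)
        for cond in conditions:
            blocks.append(tmap(fit, cond))
            conds.append(cond)
            runs.append(run)
    return PatternMatrix(
        values=np.vstack(blocks), conditions=tuple(conds), runs=tuple(runs)
    )
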