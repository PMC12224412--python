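"""Synthetic stimulus sets, trial schedules and multi-voxel patterns.

The generator emulates the statistical structure of an event-related
word-reading experiment: a word set drawn from two semantic categories
with planted orthographic neighbours, embedding vectors with category
structure, per-run trial schedules, and per-subject multi-voxel
patterns whose pairwise geometry is a known mixture of the semantic and
orthographic model RDMs plus run-level Gaussian noise.  Two subject
groups can differ in mixture weights, which is the effect the analysis
stack is asked to recover.

Geometry is planted by classical MDS of the mixture RDM: the latent
coordinates realize the target dissimilarities by construction, and one
fixed random linear map per subject projects them into voxel space so
that cross-validated pattern distances are unbiased estimates of the
latent geometry.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RDM, EmbeddingTable, PatternMatrix, Word, WordSet
from .stimulus_models import classical_mds, orth_rdm, rdm_correlate, sem_rdm

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "make_wordset",
    "schedule_runs",
    "plant_geometry",
    "simulate_patterns",
    "simulate_bold",
    "make_dataset",
]

BASELINE = "baseline"

# trial timing components (seconds): fixation, blank, stimulus, jitter range
FIXATION_S = 0.350
GAP_S = 0.700
STIM_S = 0.700
JITTER_S = (0.550, 1.550)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic generator.

    Defaults follow the emulated study design: 33 words in two
    categories, four runs of three repetitions each, TR 1.23 s.  The
    noise level is set so that single-subject model correlations stay
    well below 1 (roughly 0.1–0.4, as in ROI-level RSA) while group
    contrasts at n = 20 per group remain detectable; the word-set
    decorrelation constraint keeps the two model RDMs essentially
    orthogonal, which is what makes null-model inference calibrated.
    """

    n_words: int = 33
    n_categories: int = 2
    n_runs: int = 4
    n_repetitions: int = 3
    n_voxels: int = 150
    latent_dim: int = 16
    emb_dim: int = 8
    w_sem: float = 0.5
    w_orth: float = 0.5
    noise_sd: float = 0.7
    n_subjects: int = 20  # per group
    group_weights: dict[str, tuple[float, float]] | None = None
    w_edge: float = 2.0
    sem_metric: str = "euclidean"
    max_model_corr: float = 0.02  # decorrelation constraint on the word set
    tr_s: float = 1.23
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_words",
            "n_categories",
            "n_runs",
            "n_repetitions",
            "n_voxels",
            "latent_dim",
            "emb_dim",
            "n_subjects",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.w_sem < 0 or self.w_orth < 0:
            raise ValueError("mixture weights must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    def resolved_group_weights(self) -> dict[str, tuple[float, float]]:
        if self.group_weights is not None:
            return dict(self.group_weights)
        return {"control": (self.w_sem, self.w_orth)}


@dataclass(frozen=True)
class SyntheticDataset:
    """A fully simulated experiment with its ground truth."""

    words: WordSet
    embeddings: EmbeddingTable
    sem_model: RDM
    orth_model: RDM
    patterns: dict[str, PatternMatrix]  # subject id -> stacked runs
    groups: dict[str, str]  # subject id -> group label
    true_weights: dict[str, tuple[float, float]]  # subject id -> (w_sem, w_orth)


def _draw_tokens(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Random letter strings, lengths ~ N(6.85, 1.7) clipped to [2, 10],
    with planted single-substitution orthographic neighbour pairs."""
    letters = string.ascii_lowercase
    tokens: list[str] = []
    seen: set[str] = set()
    while len(tokens) < cfg.n_words:
        length = int(np.clip(round(rng.normal(6.85, 1.7)), 2, 10))
        tok = "".join(rng.choice(list(letters), size=length))
        if tok not in seen:
            seen.add(tok)
            tokens.append(tok)
    # plant neighbours: replace every 4th token by a single-letter
    # substitution of the previous one (crossing category boundaries,
    # since categories alternate over the index)
    for i in range(3, cfg.n_words, 4):
        base = tokens[i - 1]
        for _ in range(50):
            pos = int(rng.integers(len(base)))
            repl = rng.choice(list(letters))
            cand = base[:pos] + repl + base[pos + 1 :]
            if cand not in seen:
                seen.discard(tokens[i])
                seen.add(cand)
                tokens[i] = cand
                break
    return tokens


def make_wordset(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> tuple[WordSet, EmbeddingTable]:
    """Draw a word set and embedding table with decorrelated models.

    Tokens are random letter strings with planted orthographic
    neighbour pairs that cross category boundaries; frequencies are
    log-normal (per-million scale); embeddings are category-centered
    Gaussian clusters so the semantic RDM carries category structure.
    Draws are rejected until the Spearman correlation between the
    orthographic and semantic model RDMs is below
    ``cfg.max_model_corr`` in magnitude, mirroring the stimulus-design
    constraint that the two models be uncorrelated.
    """
    if cfg.n_words < 4:
        raise ValueError("need at least 4 words")
    if cfg.n_categories < 1 or cfg.n_words < cfg.n_categories:
        raise ValueError("cannot split words over categories")
    cat_names = [f"cat{c + 1}" for c in range(cfg.n_categories)]
    if cfg.n_categories == 2:
        cat_names = ["art", "water"]
    for _ in range(max_tries):
        tokens = _draw_tokens(cfg, rng)
        cats = [cat_names[i % cfg.n_categories] for i in range(cfg.n_words)]
        freqs = np.exp(rng.normal(2.3, 1.2, size=cfg.n_words))
        freqs = np.clip(freqs, 1.0, 126.0)
        words = WordSet(
            tuple(
                Word(token=t, category=c, freq_pm=float(f))
                for t, c, f in zip(tokens, cats, freqs)
            )
        )
        centers = rng.normal(0.0, 1.0, size=(cfg.n_categories, cfg.emb_dim))
        centers *= 1.5 / max(np.linalg.norm(centers, axis=1).mean(), 1e-9)
        vecs = np.vstack(
            [
                centers[i % cfg.n_categories]
                + rng.normal(0.0, 1.0, size=cfg.emb_dim)
                for i in range(cfg.n_words)
            ]
        )
        emb = EmbeddingTable(tokens=tuple(tokens), vectors=vecs)
        r = rdm_correlate(
            orth_rdm(words, cfg.w_edge),
            sem_rdm(words, emb, cfg.sem_metric),
            method="spearman",
        )
        if abs(r) <= cfg.max_model_corr:
            return words, emb
    raise RuntimeError(
        f"could not draw a decorrelated word set in {max_tries} tries"
    )


def schedule_runs(
    cfg: SimulationConfig,
    words: WordSet,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-run pseudo-random trial schedule.

    Each run presents every word ``n_repetitions`` times plus
    ``n_words`` baseline (hash-mark) trials.  Trial timing is fixation
    (350 ms) + blank (700 ms) + stimulus (700 ms) + uniform jitter in
    [550, 1550] ms; the stimulus onset is recorded.

    Returns a data frame with columns ``onset``, ``duration``,
    ``trial_type``, ``run``.
    """
    rows = []
    for run in range(1, cfg.n_runs + 1):
        trial_types = list(words.tokens) * cfg.n_repetitions
        trial_types += [BASELINE] * cfg.n_words
        order = rng.permutation(len(trial_types))
        t = 0.0
        for idx in order:
            onset = t + FIXATION_S + GAP_S
            rows.append(
                {
                    "onset": round(onset, 4),
                    "duration": STIM_S,
                    "trial_type": trial_types[idx],
                    "run": run,
                }
            )
            jitter = rng.uniform(*JITTER_S)
            t = onset + STIM_S + jitter
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "run"])


def _minmax_offdiag(rdm: RDM) -> np.ndarray:
    vec = rdm.vector()
    lo, hi = vec.min(), vec.max()
    if hi - lo <= 0:
        raise ValueError("constant RDM cannot be scaled")
    out = np.zeros_like(rdm.values)
    i, j = np.tril_indices(rdm.n, k=-1)
    sv = (vec - lo) / (hi - lo)
    out[i, j] = sv
    out[j, i] = sv
    return out


def plant_geometry(
    sem: RDM,
    orth: RDM,
    w_sem: float,
    w_orth: float,
    latent_dim: int = 8,
) -> np.ndarray:
    """Latent coordinates realizing a weighted mixture geometry.

    The target RDM is ``w_sem * scale(sem) + w_orth * scale(orth)``
    with each component min-max scaled over its off-diagonal entries;
    the returned (n x latent_dim) coordinates are its classical-MDS
    embedding, so pairwise latent distances approximate the mixture by
    construction.
    """
    if sem.labels != orth.labels:
        raise ValueError("model RDMs must share labels")
    if w_sem < 0 or w_orth < 0:
        raise ValueError("weights must be nonnegative")
    if w_sem + w_orth <= 0:
        raise ValueError("at least one mixture weight must be positive")
    target = RDM(
        labels=sem.labels,
        values=w_sem * _minmax_offdiag(sem) + w_orth * _minmax_offdiag(orth),
    )
    # mixture RDMs are generally not Euclidean-embeddable; the MDS
    # truncation (clipped negative eigenvalues) is expected here
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return classical_mds(target, latent_dim)


def simulate_patterns(
    latent: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    labels: tuple[str, ...],
) -> PatternMatrix:
    """Multi-run voxel patterns for one subject.

    One fixed random linear map (latent_dim -> n_voxels, shared across
    runs) projects the latent coordinates into voxel space; each run
    adds independent Gaussian noise with SD ``cfg.noise_sd``.
    """
    latent = np.asarray(latent, dtype=float)
    if not np.all(np.isfinite(latent)):
        raise ValueError("latent coordinates must be finite")
    if cfg.n_voxels < latent.shape[1]:
        raise ValueError("n_voxels must be >= latent_dim")
    n = latent.shape[0]
    W = rng.normal(0.0, 1.0, size=(latent.shape[1], cfg.n_voxels))
    W /= np.sqrt(latent.shape[1])
    signal = latent @ W
    blocks, conds, runs = [], [], []
    for run in range(1, cfg.n_runs + 1):
        noise = rng.normal(0.0, cfg.noise_sd, size=(n, cfg.n_voxels))
        blocks.append(signal + noise)
        conds.extend(labels)
        runs.extend([run] * n)
    return PatternMatrix(
        values=np.vstack(blocks), conditions=tuple(conds), runs=tuple(runs)
    )


def simulate_bold(
    events: pd.DataFrame,
    amplitudes: np.ndarray,
    condition_labels: tuple[str, ...],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    noise_sd: float | None = None,
) -> dict[int, np.ndarray]:
    """Per-run BOLD time series from an event table and amplitude map.

    Each condition's voxel amplitude pattern (row of ``amplitudes``)
    scales an HRF-convolved regressor built from its event onsets;
    white noise is added on top.  Returns run -> (n_scans, n_voxels).
    """
    from .glm_estimation import build_design

    noise_sd = cfg.noise_sd if noise_sd is None else noise_sd
    out: dict[int, np.ndarray] = {}
    for run, ev in events.groupby("run"):
        last_offset = (ev["onset"] + ev["duration"]).max()
        n_scans = int(np.ceil((last_offset + 20.0) / cfg.tr_s))
        design = build_design(
            ev, n_scans=n_scans, tr=cfg.tr_s, highpass_s=None
        )
        X = design.task_matrix(condition_labels)
        series = X @ amplitudes
        if noise_sd > 0:
            series = series + rng.normal(0.0, noise_sd, size=series.shape)
        out[int(run)] = series
    return out


def _subject_rngs(seed: int, n: int) -> list[np.random.Generator]:
    seqs = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(s) for s in seqs]


def make_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Simulate a full experiment: word set, models and all subjects.

    Groups come from ``cfg.group_weights`` (label -> (w_sem, w_orth));
    with the default single entry one group of ``cfg.n_subjects`` is
    produced.  All randomness derives from ``cfg.seed``.
    """
    word_seq, subj_seq = np.random.SeedSequence(cfg.seed).spawn(2)
    word_rng = np.random.default_rng(word_seq)
    words, emb = make_wordset(cfg, word_rng)
    sem = sem_rdm(words, emb, cfg.sem_metric)
    orth = orth_rdm(words, cfg.w_edge)

    group_weights = cfg.resolved_group_weights()
    patterns: dict[str, PatternMatrix] = {}
    groups: dict[str, str] = {}
    true_weights: dict[str, tuple[float, float]] = {}
    n_total = cfg.n_subjects * len(group_weights)
    rngs = [np.random.default_rng(s) for s in subj_seq.spawn(n_total)]
    i = 0
    for group, (w_s, w_o) in group_weights.items():
        latent = plant_geometry(sem, orth, w_s, w_o, cfg.latent_dim)
        for k in range(cfg.n_subjects):
            sid = f"{group}{k + 1:02d}"
            patterns[sid] = simulate_patterns(
                latent, cfg, rngs[i], words.tokens
            )
            groups[sid] = group
            true_weights[sid] = (w_s, w_o)
            i += 1
    return SyntheticDataset(
        words=words,
        embeddings=emb,
        sem_model=sem,
        orth_model=orth,
        patterns=patterns,
        groups=groups,
        true_weights=true_weights,
    )
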