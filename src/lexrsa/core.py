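"""Shared containers for the word-reading RSA pipeline.

Every analysis stage exchanges a small set of labelled objects:

* :class:`Word` / :class:`WordSet` — the stimulus list with its semantic
  category and nuisance variables (lexical frequency, letter length).
* :class:`EmbeddingTable` — one real vector per word, consumed as input
  (the semantic space is *not* trained here).
* :class:`RDM` — a labelled, symmetric, zero-diagonal dissimilarity
  matrix over conditions.  Model RDMs, confound RDMs and neural RDMs are
  all instances; neural RDMs may carry negative off-diagonal entries
  because the cross-validated distance estimator is unbiased.
* :class:`PatternMatrix` — condition responses (one row per trial or per
  condition estimate) across the voxels of one region of interest.

The vectorization convention used throughout for second-order statistics
is the strictly-lower triangle in row-major order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Word",
    "WordSet",
    "EmbeddingTable",
    "RDM",
    "NeuralRDM",
    "PatternMatrix",
]


@dataclass(frozen=True)
class Word:
    """A stimulus word with its category and nuisance variables."""

    token: str
    category: str
    freq_pm: float  # lexical frequency, occurrences per million

    def __post_init__(self) -> None:
        if len(self.token) < 1:
            raise ValueError("word token must have at least one letter")
        if not np.isfinite(self.freq_pm) or self.freq_pm <= 0:
            raise ValueError(
                f"freq_pm must be positive and finite, got {self.freq_pm!r}"
            )

    @property
    def length(self) -> int:
        """Letter count of the token."""
        return len(self.token)


@dataclass(frozen=True)
class WordSet:
    """An ordered collection of unique words.

    The order is the canonical condition order shared by every RDM built
    from this set.
    """

    words: tuple[Word, ...]

    def __post_init__(self) -> None:
        tokens = [w.token for w in self.words]
        if len(set(tokens)) != len(tokens):
            dupes = sorted({t for t in tokens if tokens.count(t) > 1})
            raise ValueError(f"duplicate tokens in word set: {dupes}")

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self):
        return iter(self.words)

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(w.token for w in self.words)

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(w.category for w in self.words)

    @property
    def freqs_pm(self) -> np.ndarray:
        return np.array([w.freq_pm for w in self.words], dtype=float)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([w.length for w in self.words], dtype=float)


@dataclass(frozen=True)
class EmbeddingTable:
    """One fixed-dimension real vector per token.

    Embeddings are an *input* to the pipeline (e.g. coordinates from a
    distributional semantic model); they are never trained here.
    """

    tokens: tuple[str, ...]
    vectors: np.ndarray  # (n_tokens, k)

    def __post_init__(self) -> None:
        vec = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "vectors", vec)
        if vec.ndim != 2:
            raise ValueError("vectors must be a 2-D (n_tokens, k) array")
        if vec.shape[0] != len(self.tokens):
            raise ValueError("one vector per token required")
        if vec.shape[1] < 2:
            raise ValueError("embedding dimension must be >= 2")
        if not np.all(np.isfinite(vec)):
            raise ValueError("embedding vectors must be finite")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in embedding table")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, token: str) -> np.ndarray:
        try:
            idx = self.tokens.index(token)
        except ValueError:
            raise KeyError(f"no embedding vector for token {token!r}") from None
        return self.vectors[idx]

    def subset(self, tokens: tuple[str, ...]) -> np.ndarray:
        """Stack vectors for `tokens` in the given order."""
        return np.vstack([self.vector(t) for t in tokens])


def _lower_triangle_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    # strictly-lower triangle, row-major: (1,0), (2,0), (2,1), (3,0), ...
    return np.tril_indices(n, k=-1)


@dataclass(frozen=True)
class RDM:
    """Labelled square symmetric dissimilarity matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if vals.shape != (n, n):
            raise ValueError(
                f"values shape {vals.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("RDM entries must be finite")
        if not np.allclose(vals, vals.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(vals), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        if len(set(self.labels)) != n:
            raise ValueError("RDM labels must be unique")

    @property
    def n(self) -> int:
        return len(self.labels)

    def vector(self) -> np.ndarray:
        """Strictly-lower triangle in row-major order, length n(n-1)/2."""
        i, j = _lower_triangle_indices(self.n)
        return self.values[i, j].copy()

    @classmethod
    def from_vector(cls, labels: tuple[str, ...], vec: np.ndarray) -> "RDM":
        n = len(labels)
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (n * (n - 1) // 2,):
            raise ValueError(
                f"vector length {vec.size} incompatible with {n} labels"
            )
        out = np.zeros((n, n), dtype=float)
        i, j = _lower_triangle_indices(n)
        out[i, j] = vec
        out[j, i] = vec
        return cls(labels=tuple(labels), values=out)

    def reorder(self, labels: tuple[str, ...]) -> "RDM":
        """Return the same RDM with rows/columns in a new label order."""
        if set(labels) != set(self.labels):
            raise ValueError("reorder labels must be a permutation")
        idx = [self.labels.index(l) for l in labels]
        return type(self)(
            labels=tuple(labels), values=self.values[np.ix_(idx, idx)]
        )


@dataclass(frozen=True)
class NeuralRDM(RDM):
    """Cross-validated neural RDM.

    Off-diagonal entries may be negative (the estimator is unbiased and
    can undershoot zero); the diagonal is zero by construction.
    """

    n_partitions: int = 0
    n_voxels: int = 0


@dataclass(frozen=True)
class PatternMatrix:
    """Trial/condition response patterns across voxels with labels.

    Rows are samples (one per trial or per condition estimate); each
    sample carries a condition token and a run index.
    """

    values: np.ndarray  # (n_samples, n_voxels)
    conditions: tuple[str, ...]
    runs: tuple[int, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "runs", tuple(int(r) for r in self.runs))
        if vals.ndim != 2:
            raise ValueError("values must be 2-D (samples, voxels)")
        if vals.shape[0] != len(self.conditions) or vals.shape[0] != len(self.runs):
            raise ValueError("one condition and run label per sample required")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    @property
    def run_labels(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.runs)))

    @property
    def condition_labels(self) -> tuple[str, ...]:
        """Unique conditions in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.conditions:
            seen.setdefault(c)
        return tuple(seen)

    def run_means(
        self, conditions: tuple[str, ...] | None = None
    ) -> dict[int, np.ndarray]:
        """Per-run condition-mean patterns.

        Returns a mapping run -> (n_conditions, n_voxels) array in the
        requested condition order.  Raises if a condition is missing in
        a run.
        """
        conditions = conditions or self.condition_labels
        cond_arr = np.array(self.conditions)
        run_arr = np.array(self.runs)
        out: dict[int, np.ndarray] = {}
        for run in self.run_labels:
            rows = []
            for cond in conditions:
                mask = (run_arr == run) & (cond_arr == cond)
                if not mask.any():
                    raise ValueError(
                        f"condition {cond!r} missing in run {run}"
                    )
                rows.append(self.values[mask].mean(axis=0))
            out[run] = np.vstack(rows)
        return out

    def select_voxels(self, keep: np.ndarray) -> "PatternMatrix":
        return PatternMatrix(
            values=self.values[:, keep],
            conditions=self.conditions,
            runs=self.runs,
        )
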