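"""Theoretical dissimilarity matrices and stimulus-design checks.

Builds the model RDMs that the neural data are compared against:

* an **orthographic** RDM from a position-weighted Levenshtein edit
  distance that prices edits touching the first or last letter of either
  word higher than interior edits (shared word-initial and word-final
  letters matter disproportionately in visual word recognition);
* a **semantic** RDM from pairwise distances between word-embedding
  vectors;
* a binary **category** RDM (same / different semantic category);
* **confound** RDMs from absolute differences of a nuisance variable
  (log10 lexical frequency, letter length) and their min-max-scaled
  average.

Also provides classical (Torgerson) multidimensional scaling and a
permutation-based decorrelation check between the orthographic and
semantic models, mirroring the stimulus-selection constraint that the
two model matrices be uncorrelated.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr

from .core import RDM, EmbeddingTable, WordSet

__all__ = [
    "levenshtein",
    "weighted_levenshtein",
    "orth_rdm",
    "sem_rdm",
    "category_rdm",
    "confound_rdm",
    "combine_confounds",
    "rdm_correlate",
    "classical_mds",
    "design_check",
]


def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character insertions, deletions and
    substitutions transforming `a` into `b`."""
    return int(round(weighted_levenshtein(a, b, 1.0)))


def weighted_levenshtein(a: str, b: str, w_edge: float = 2.0) -> float:
    """Edge-weighted Levenshtein distance.

    Standard dynamic-programming edit distance, except that any edit
    operation (insertion, deletion, substitution of non-matching
    letters) that consumes the first or last character position of
    either string costs ``w_edge`` instead of 1.  Matching characters
    cost 0 wherever they sit.  With ``w_edge == 1`` this is the plain
    Levenshtein distance; for ``w_edge > 1`` words sharing initial and
    final letters come out closer than words that differ there.

    Parameters
    ----------
    a, b:
        Letter strings; may be empty.
    w_edge:
        Cost multiplier for edge-position edits, must be >= 1.
    """
    if w_edge < 1:
        raise ValueError(f"w_edge must be >= 1, got {w_edge}")
    m, n = len(a), len(b)

    def edge_a(i: int) -> bool:
        return i == 0 or i == m - 1

    def edge_b(j: int) -> bool:
        return j == 0 or j == n - 1

    def del_cost(i: int) -> float:
        return w_edge if edge_a(i) else 1.0

    def ins_cost(j: int) -> float:
        return w_edge if edge_b(j) else 1.0

    def sub_cost(i: int, j: int) -> float:
        if a[i] == b[j]:
            return 0.0
        return w_edge if (edge_a(i) or edge_b(j)) else 1.0

    # D[i][j] = cost of transforming a[:i] into b[:j]
    prev = np.zeros(n + 1)
    for j in range(1, n + 1):
        prev[j] = prev[j - 1] + ins_cost(j - 1)
    for i in range(1, m + 1):
        cur = np.empty(n + 1)
        cur[0] = prev[0] + del_cost(i - 1)
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + del_cost(i - 1),
                cur[j - 1] + ins_cost(j - 1),
                prev[j - 1] + sub_cost(i - 1, j - 1),
            )
        prev = cur
    return float(prev[n])


def orth_rdm(words: WordSet, w_edge: float = 2.0) -> RDM:
    """Orthographic model RDM: pairwise edge-weighted Levenshtein
    distances between word tokens."""
    tokens = words.tokens
    if len(tokens) < 2:
        raise ValueError("need at least 2 words for an RDM")
    n = len(tokens)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = weighted_levenshtein(tokens[i], tokens[j], w_edge)
            vals[i, j] = vals[j, i] = d
    return RDM(labels=tokens, values=vals)


def sem_rdm(
    words: WordSet, emb: EmbeddingTable, metric: str = "euclidean"
) -> RDM:
    """Semantic model RDM: pairwise distances between embedding vectors.

    ``metric`` is ``"euclidean"`` (default; embedding spaces from
    neighbor-embedding methods are conventionally read with Euclidean
    distance) or ``"cosine"``.
    """
    if metric not in ("euclidean", "cosine"):
        raise ValueError(f"unknown metric {metric!r}")
    vecs = emb.subset(words.tokens)  # raises KeyError naming missing token
    vals = squareform(pdist(vecs, metric=metric))
    np.fill_diagonal(vals, 0.0)
    return RDM(labels=words.tokens, values=vals)


def category_rdm(words: WordSet) -> RDM:
    """Binary RDM: 0 for same semantic category, 1 otherwise."""
    cats = np.array(words.categories)
    vals = (cats[:, None] != cats[None, :]).astype(float)
    return RDM(labels=words.tokens, values=vals)


def confound_rdm(
    words: WordSet,
    values: np.ndarray,
    transform: str = "identity",
) -> RDM:
    """Confound RDM: |t(v_i) - t(v_j)| for a per-word nuisance scalar.

    ``transform`` is ``"identity"`` (word length) or ``"log10"``
    (lexical frequency, which is heavily right-skewed on the
    per-million scale).
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (len(words),):
        raise ValueError("one value per word required")
    if not np.all(np.isfinite(v)):
        raise ValueError("confound values must be finite")
    if transform == "log10":
        if np.any(v <= 0):
            raise ValueError("log10 transform requires positive values")
        v = np.log10(v)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    vals = np.abs(v[:, None] - v[None, :])
    return RDM(labels=words.tokens, values=vals)


def frequency_rdm(words: WordSet) -> RDM:
    """Lexical-frequency confound RDM (log10 per-million frequency)."""
    return confound_rdm(words, words.freqs_pm, transform="log10")


def length_rdm(words: WordSet) -> RDM:
    """Word-length confound RDM (absolute letter-count difference)."""
    return confound_rdm(words, words.lengths, transform="identity")


def _minmax_scale_offdiag(rdm: RDM) -> np.ndarray:
    vec = rdm.vector()
    lo, hi = vec.min(), vec.max()
    if hi - lo <= 0:
        raise ValueError(
            "cannot min-max scale a constant (zero-range) RDM"
        )
    scaled = np.zeros_like(rdm.values)
    i, j = np.tril_indices(rdm.n, k=-1)
    sv = (vec - lo) / (hi - lo)
    scaled[i, j] = sv
    scaled[j, i] = sv
    return scaled


def combine_confounds(rdms: list[RDM]) -> RDM:
    """Average several confound RDMs after min-max scaling each to [0, 1].

    The inputs live on incommensurate scales (letters vs. log
    frequency), so each RDM is first rescaled over its off-diagonal
    entries before the entrywise average.
    """
    if not rdms:
        raise ValueError("need at least one RDM")
    labels = rdms[0].labels
    for r in rdms[1:]:
        if r.labels != labels:
            raise ValueError("RDM labels/order mismatch in combine_confounds")
    avg = np.mean([_minmax_scale_offdiag(r) for r in rdms], axis=0)
    return RDM(labels=labels, values=avg)


def rdm_correlate(a: RDM, b: RDM, method: str = "spearman") -> float:
    """Second-order correlation between two RDMs' lower-triangle vectors."""
    if a.labels != b.labels:
        raise ValueError("RDMs must share labels and order")
    if a.n < 3:
        raise ValueError("need at least 3 conditions")
    va, vb = a.vector(), b.vector()
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("undefined correlation: zero-variance RDM vector")
    if method == "spearman":
        r = spearmanr(va, vb).statistic
    elif method == "pearson":
        r = pearsonr(va, vb).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r)


def classical_mds(rdm: RDM, k: int) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared dissimilarities and returns the top-`k`
    eigendecomposition coordinates (n x k).  When the RDM is exactly
    Euclidean-embeddable in `k` dimensions the coordinates reproduce it
    up to rotation/reflection.  Negative eigenvalues (non-Euclidean
    input) are clipped to zero with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = rdm.n
    if n <= k:
        raise ValueError("need more conditions than target dimensions")
    d2 = rdm.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    # B is symmetric by construction
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:k]
    lam = eigval[order]
    if eigval.min() < -1e-8 * max(1.0, abs(eigval).max()):
        warnings.warn(
            "RDM is not Euclidean-embeddable: negative eigenvalues "
            "clipped to zero",
            stacklevel=2,
        )
    lam = np.clip(lam, 0.0, None)
    return eigvec[:, order] * np.sqrt(lam)


def design_check(
    orth: RDM,
    sem: RDM,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Check that the orthographic and semantic models are decorrelated.

    Computes the Spearman second-order correlation and a permutation
    p-value obtained by jointly permuting the condition labels of one
    RDM.  The stimulus design *passes* when the null of no association
    is **not** rejected (p > alpha).

    Returns ``{"rho": float, "p": float, "passed": bool}``.
    """
    if orth.labels != sem.labels:
        raise ValueError("RDMs must share labels")
    if orth.n < 4:
        raise ValueError("need at least 4 conditions for a permutation null")
    rng = rng or np.random.default_rng()
    rho = rdm_correlate(orth, sem, method="spearman")
    count = 0
    vals = sem.values
    vb_ref = orth.vector()
    i, j = np.tril_indices(orth.n, k=-1)
    from scipy.stats import rankdata

    ra = rankdata(vb_ref)
    for _ in range(n_permutations):
        perm = rng.permutation(orth.n)
        pv = vals[np.ix_(perm, perm)][i, j]
        rp = np.corrcoef(ra, rankdata(pv))[0, 1]
        if abs(rp) >= abs(rho) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return {"rho": rho, "p": float(p), "passed": bool(p > alpha)}
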