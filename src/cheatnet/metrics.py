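"""Structural descriptors of binary bipartite networks.

Connectance, NODF nestedness (paired overlap with decreasing fill,
averaged over row and column pairs, scaled 0-100) and Barber bipartite
modularity optimized with a label-propagation + agglomeration scheme
in the style of LPAwb+ (label propagation for weighted bipartite
networks), with seeded restarts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "StructureReport",
    "connectance",
    "nodf",
    "barber_q",
    "bipartite_modularity",
    "structure_report",
]


@dataclass
class StructureReport:
    connectance: float
    nodf: float
    modularity: float
    row_modules: np.ndarray
    col_modules: np.ndarray


def _as_binary(IM: np.ndarray) -> np.ndarray:
    IM = np.asarray(IM, dtype=float)
    if IM.size == 0:
        raise ValueError("empty matrix")
    if not np.isin(IM, (0.0, 1.0)).all():
        raise ValueError("matrix must be binary 0/1")
    return IM


def connectance(IM: np.ndarray) -> float:
    """Realized links over all possible plant x pollinator links."""
    return float(_as_binary(IM).mean())


def _nodf_pairs(X: np.ndarray) -> tuple[float, int]:
    """Sum of paired-overlap terms over row pairs of X, and pair count."""
    fills = X.sum(axis=1)
    n = X.shape[0]
    total = 0.0
    for i, j in combinations(range(n), 2):
        hi, lo = (i, j) if fills[i] >= fills[j] else (j, i)
        if fills[hi] > fills[lo] > 0:
            overlap = float((X[hi] * X[lo]).sum())
            total += 100.0 * overlap / fills[lo]
    return total, n * (n - 1) // 2


def nodf(IM: np.ndarray) -> float:
    """NODF nestedness: 0 (no paired overlap) to 100 (perfect nesting).

    For each pair of rows (and of columns) with strictly decreasing
    fill, the percentage of the sparser row's links shared with the
    denser row contributes; equal-fill pairs contribute zero.
    """
    IM = _as_binary(IM)
    if (IM.sum(axis=1) == 0).any() or (IM.sum(axis=0) == 0).any():
        raise ValueError("matrix has empty rows or columns; prune first")
    row_sum, row_pairs = _nodf_pairs(IM)
    col_sum, col_pairs = _nodf_pairs(IM.T)
    return (row_sum + col_sum) / (row_pairs + col_pairs)


def barber_q(
    B: np.ndarray, row_labels: np.ndarray, col_labels: np.ndarray
) -> float:
    """Barber bipartite modularity of a given partition.

    Q = (1/m) sum_ij (B_ij - k_i d_j / m) delta(g_i, h_j) with m the
    total edge weight, k and d the row and column degrees.
    """
    B = np.asarray(B, dtype=float)
    m = B.sum()
    if m == 0:
        raise ValueError("matrix has no links")
    k = B.sum(axis=1)
    d = B.sum(axis=0)
    Btilde = B - np.outer(k, d) / m
    same = row_labels[:, None] == col_labels[None, :]
    return float(Btilde[same].sum() / m)


def _propagate(
    Btilde: np.ndarray,
    row_labels: np.ndarray,
    col_labels: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Alternate greedy label updates until neither guild changes."""
    n_r, n_c = Btilde.shape
    changed = True
    while changed:
        changed = False
        for j in rng.permutation(n_c):
            scores: dict[int, float] = {}
            for i in range(n_r):
                scores[row_labels[i]] = scores.get(row_labels[i], 0.0) \
                    + Btilde[i, j]
            best = max(scores, key=lambda L: scores[L])
            if scores[best] > 0 and best != col_labels[j]:
                col_labels[j] = best
                changed = True
        for i in rng.permutation(n_r):
            scores = {}
            for j in range(n_c):
                scores[col_labels[j]] = scores.get(col_labels[j], 0.0) \
                    + Btilde[i, j]
            best = max(scores, key=lambda L: scores[L])
            if scores[best] > 0 and best != row_labels[i]:
                row_labels[i] = best
                changed = True


def _agglomerate(
    B: np.ndarray, row_labels: np.ndarray, col_labels: np.ndarray
) -> bool:
    """Merge the module pair that most increases Q; True if merged."""
    labels = np.unique(np.r_[row_labels, col_labels])
    best_gain, best_pair = 0.0, None
    q0 = barber_q(B, row_labels, col_labels)
    for a, b in combinations(labels, 2):
        rl = np.where(row_labels == b, a, row_labels)
        cl = np.where(col_labels == b, a, col_labels)
        gain = barber_q(B, rl, cl) - q0
        if gain > best_gain + 1e-12:
            best_gain, best_pair = gain, (a, b)
    if best_pair is None:
        return False
    a, b = best_pair
    row_labels[row_labels == b] = a
    col_labels[col_labels == b] = a
    return True


def bipartite_modularity(
    IM: np.ndarray, seed: int = 0, restarts: int = 20
) -> tuple[float, np.ndarray, np.ndarray]:
    """Best Barber Q over seeded label-propagation restarts.

    Each restart initializes every row in its own module, propagates
    labels greedily across guilds, then agglomerates modules while Q
    improves.  Deterministic for a fixed seed; Q is monotone
    non-decreasing in ``restarts`` (best-of semantics).
    """
    B = _as_binary(IM)
    n_r, n_c = B.shape
    m = B.sum()
    if m == 0:
        raise ValueError("matrix has no links")
    k = B.sum(axis=1)
    d = B.sum(axis=0)
    Btilde = B - np.outer(k, d) / m
    rng = np.random.default_rng(seed)
    best_q, best = -np.inf, None
    for it in range(restarts):
        if it == 0:
            row_labels = np.arange(n_r)
        else:
            # random coarser initializations diversify the search
            n_mod = int(rng.integers(1, n_r + 1))
            row_labels = rng.integers(0, n_mod, size=n_r)
        # columns start on their strongest row's label
        col_labels = np.array(
            [row_labels[np.argmax(Btilde[:, j])] for j in range(n_c)]
        )
        _propagate(Btilde, row_labels, col_labels, rng)
        while _agglomerate(B, row_labels, col_labels):
            _propagate(Btilde, row_labels, col_labels, rng)
        q = barber_q(B, row_labels, col_labels)
        if q > best_q:
            best_q, best = q, (row_labels.copy(), col_labels.copy())
    return best_q, best[0], best[1]


def _set_partitions(items: list[int]):
    """All set partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def exhaustive_modularity(IM: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact optimum of Barber Q for small matrices (<= ~12 species).

    Enumerates all set partitions of the rows; for each, every column
    independently takes the label maximizing its contribution (columns
    interact with the partition only through their own label, so this
    is exact).
    """
    B = _as_binary(IM)
    n_r, n_c = B.shape
    if n_r + n_c > 16:
        raise ValueError("exhaustive search limited to small matrices")
    m = B.sum()
    k = B.sum(axis=1)
    d = B.sum(axis=0)
    Btilde = B - np.outer(k, d) / m
    best_q, best = -np.inf, None
    for part in _set_partitions(list(range(n_r))):
        row_labels = np.empty(n_r, dtype=int)
        for lab, block in enumerate(part):
            row_labels[block] = lab
        col_labels = np.empty(n_c, dtype=int)
        total = 0.0
        for j in range(n_c):
            contrib = np.array(
                [Btilde[row_labels == lab, j].sum() for lab in range(len(part))]
            )
            lab = int(np.argmax(contrib))
            # a fresh singleton module contributes 0
            if contrib[lab] < 0:
                col_labels[j] = len(part) + j
            else:
                col_labels[j] = lab
                total += contrib[lab]
        q = total / m
        if q > best_q:
            best_q, best = q, (row_labels.copy(), col_labels.copy())
    return best_q, best[0], best[1]


def structure_report(IM: np.ndarray, seed: int = 0, restarts: int = 20) -> StructureReport:
    q, rl, cl = bipartite_modularity(IM, seed=seed, restarts=restarts)
    return StructureReport(
        connectance=connectance(IM),
        nodf=nodf(IM),
        modularity=q,
        row_modules=rl,
        col_modules=cl,
    )
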