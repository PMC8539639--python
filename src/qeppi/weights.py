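"""Desirability-weight selection by Shannon-entropy maximization.

The seven weights of the weighted geometric mean are chosen by exhaustive
grid search: every combination of weights from {0, 0.25, 0.5, 0.75, 1.0}
(the all-zero tuple excluded — the score normalizes by the weight sum) is
scored on the modeling set, the Shannon entropy

    H = - sum_k  score_k * log2(score_k)

is computed literally over the per-compound scores (no renormalization into
a probability distribution), and the final weight vector is the element-wise
mean of the 1000 highest-entropy combinations. Maximizing this entropy
spreads the score distribution, which keeps the index discriminative.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np

from .descriptors import PROPERTY_NAMES

#: Grid levels tested for every weight.
GRID_LEVELS: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)

#: Number of top-entropy combinations averaged into the final weights.
DEFAULT_TOP_K = 1000


@dataclass(frozen=True)
class GridSearchResult:
    """Outcome of the exhaustive weight search.

    ``final`` is the element-wise mean of the ``top_k`` highest-entropy
    weight vectors; ``top_combos`` and ``top_entropies`` record them in
    descending entropy order (ties broken by lexicographic weight order);
    ``n`` is the number of compounds scored.
    """

    final: np.ndarray
    top_combos: np.ndarray
    top_entropies: np.ndarray
    top_k: int
    n: int


def enumerate_weight_grid() -> np.ndarray:
    """All 5^7 - 1 = 78,124 weight tuples in lexicographic order.

    The all-zero tuple is excluded because the score divides by the weight
    sum.
    """
    combos = np.array(list(product(GRID_LEVELS, repeat=len(PROPERTY_NAMES))), dtype=float)
    return combos[1:]  # lexicographically first row is all-zero


def entropy(scores) -> float:
    """Shannon entropy of a score list: -sum(s * log2 s), s in (0, 1].

    The sum runs over compounds as-is; scores are not renormalized to a
    probability distribution.
    """
    s = np.asarray(scores, dtype=float)
    if np.any(s <= 0):
        raise ValueError("entropy requires strictly positive scores (apply the eps floor)")
    return float(-np.sum(s * np.log2(s)))


def _entropy_per_combo(combos: np.ndarray, log_d: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Entropy of the score distribution for each weight combo.

    Per-compound log-desirabilities are precomputed once; scores for a block
    of combos are one matrix product. Chunked so the (combos x compounds)
    score block stays small.
    """
    w_sum = combos.sum(axis=1)
    out = np.empty(len(combos))
    inv_ln2 = 1.0 / np.log(2.0)
    for start in range(0, len(combos), chunk):
        block = combos[start : start + chunk]
        log_scores = (block @ log_d.T) / w_sum[start : start + chunk, None]
        scores = np.exp(log_scores)
        out[start : start + chunk] = -np.sum(scores * log_scores, axis=1) * inv_ln2
    return out


def select_weights(
    desirabilities: np.ndarray,
    top_k: int = DEFAULT_TOP_K,
    audit_path: str | Path | None = None,
) -> GridSearchResult:
    """Exhaustive grid search for the weight vector.

    Parameters
    ----------
    desirabilities
        (n_compounds, 7) matrix of per-compound desirability values d_i in
        (0, 1], columns in canonical property order.
    top_k
        Number of highest-entropy combinations averaged into the final
        weights.
    audit_path
        Optional CSV written with every combo and its entropy, for external
        verification.

    Notes
    -----
    The result is invariant to compound order (the entropy is a sum), and
    deterministic: entropy ties at the top-k boundary are broken by the
    lexicographic order of the weight tuples.
    """
    d = np.asarray(desirabilities, dtype=float)
    if d.ndim != 2 or d.shape[1] != len(PROPERTY_NAMES):
        raise ValueError(f"expected (n, {len(PROPERTY_NAMES)}) desirability matrix, got {d.shape}")
    if np.any(d <= 0) or np.any(d > 1):
        raise ValueError("desirabilities must lie in (0, 1]")

    combos = enumerate_weight_grid()
    if top_k > len(combos):
        raise ValueError(f"top_k={top_k} exceeds grid size {len(combos)}")

    ent = _entropy_per_combo(combos, np.log(d))

    if audit_path is not None:
        with open(audit_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([f"w_{p}" for p in PROPERTY_NAMES] + ["entropy"])
            for row, h in zip(combos, ent):
                writer.writerow([*row, h])

    # combos are already lexicographic, so a stable sort on descending
    # entropy breaks ties lexicographically
    order = np.argsort(-ent, kind="stable")
    top = order[:top_k]
    return GridSearchResult(
        final=combos[top].mean(axis=0),
        top_combos=combos[top],
        top_entropies=ent[top],
        top_k=top_k,
        n=d.shape[0],
    )
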