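"""Sequence similarity: Euclidean distance between transition-probability
feature vectors, and the editing penalty cost (Levenshtein distance)
between behavior symbol sequences.

The penalty cost (PC) of converting sequence A into sequence B is the
minimal total cost of single-symbol substitutions and single-symbol
insertions/deletions, found by dynamic programming over the
(len(A)+1) x (len(B)+1) grid. At unit costs it is the classic Levenshtein
edit distance and satisfies the metric axioms. Both raw and
length-normalized (cost / max length) values are available, since
subsequences of very different lengths are compared.

Within/between feed-state distance distributions follow the study's
"0:3"-style group-pair convention: intra-state pairs are all unordered
pairs within a state (self-pairs excluded), inter-state pairs are all
cross pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Subsequence, run_length_encode
from .errors import InsufficientData, InvalidDecimation, LengthMismatch


def euclidean_distance(v_a: np.ndarray, v_b: np.ndarray) -> float:
    """sqrt(sum((a - b)^2)) between equal-length feature vectors."""
    v_a = np.asarray(v_a, dtype=float)
    v_b = np.asarray(v_b, dtype=float)
    if v_a.shape != v_b.shape:
        raise LengthMismatch(f"shapes differ: {v_a.shape} vs {v_b.shape}")
    return float(np.sqrt(np.sum((v_a - v_b) ** 2)))


@dataclass(frozen=True)
class PenaltyCostResult:
    """Minimal edit cost plus the operation counts of one optimal script."""

    cost: float
    n_substitutions: int
    n_indels: int


def penalty_cost(
    seq_a: Sequence,
    seq_b: Sequence,
    sub_cost: float = 1.0,
    indel_cost: float = 1.0,
) -> PenaltyCostResult:
    """Minimal editing penalty cost between two symbol sequences.

    Dynamic programming, exact (no banding or heuristics). Empty
    sequences are allowed: the cost is the other length times the indel
    cost. Returns the minimal cost together with substitution/indel
    counts from one optimal edit script (the script is not unique; the
    cost is).
    """
    a = list(seq_a)
    b = list(seq_b)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return PenaltyCostResult(float(max(n, m)) * indel_cost, 0, max(n, m))

    # D[i, j] = min cost to edit a[:i] into b[:j]. Rows filled with a
    # prefix-min scan so the inner insertion recurrence vectorizes.
    D = np.empty((n + 1, m + 1), dtype=float)
    D[0, :] = np.arange(m + 1) * indel_cost
    D[:, 0] = np.arange(n + 1) * indel_cost
    j_ins = np.arange(m + 1) * indel_cost
    b_arr = np.array(b, dtype=object)
    for i in range(1, n + 1):
        mismatch = (b_arr != a[i - 1]).astype(float) * sub_cost
        t = np.minimum(D[i - 1, 1:] + indel_cost, D[i - 1, :-1] + mismatch)
        t = np.concatenate(([D[i, 0]], t))
        # row[j] = min_{k<=j} t[k] + (j-k)*indel_cost
        D[i, :] = np.minimum.accumulate(t - j_ins) + j_ins

    # Traceback one optimal script to count operation types.
    n_sub = n_indel = 0
    i, j = n, m
    while i > 0 or j > 0:
        here = D[i, j]
        if i > 0 and j > 0:
            step = sub_cost if a[i - 1] != b[j - 1] else 0.0
            if np.isclose(D[i - 1, j - 1] + step, here):
                if step > 0:
                    n_sub += 1
                i -= 1
                j -= 1
                continue
        if i > 0 and np.isclose(D[i - 1, j] + indel_cost, here):
            n_indel += 1
            i -= 1
            continue
        # insertion
        n_indel += 1
        j -= 1
    return PenaltyCostResult(float(D[n, m]), n_sub, n_indel)


def encode_for_pc(
    sub: Subsequence, mode: str = "per_bout", k: int | None = None
) -> list[str]:
    """Represent a subsequence as a symbol sequence for PC comparison.

    mode='per_frame': one symbol per frame (duration-expanded).
    mode='decimate': one symbol per window of ``k`` frames, the window's
    majority label (ties broken by first occurrence within the window).
    mode='per_bout': one symbol per bout (run-length collapsed).
    """
    if mode == "per_frame":
        return list(sub.labels)
    if mode == "per_bout":
        return [b.behavior for b in run_length_encode(sub)]
    if mode == "decimate":
        if k is None or k < 1:
            raise InvalidDecimation(f"decimation window must be >= 1, got {k}")
        labels = sub.labels
        out = []
        for start in range(0, len(labels), k):
            window = labels[start : start + k]
            uniq, first_pos, counts = np.unique(
                window, return_index=True, return_counts=True
            )
            best = counts == counts.max()
            # tie -> earliest occurrence in the window
            out.append(str(uniq[best][np.argmin(first_pos[best])]))
        return out
    raise ValueError(f"unknown mode {mode!r}")


def default_decimation(subsequences: Sequence[Subsequence], max_symbols: int = 2000) -> int:
    """Smallest window k making every encoded sequence <= max_symbols."""
    longest = max(len(s) for s in subsequences)
    return max(1, int(np.ceil(longest / max_symbols)))


def _group_pair_label(a, b) -> str:
    return f"{a}:{b}"


def pairwise_distance_distributions(
    vectors_by_group: Mapping[int, Sequence[np.ndarray]],
) -> pd.DataFrame:
    """All intra- and inter-group Euclidean distances between vectors.

    Returns a long table (metric, group_pair, id_a, id_b, value). Intra
    pairs are unordered and exclude self-comparisons; inter pairs are the
    full cross product. Groups with fewer than 2 vectors cannot form
    intra pairs and raise InsufficientData.
    """
    rows = []
    groups = sorted(vectors_by_group)
    for g in groups:
        vecs = vectors_by_group[g]
        if len(vecs) < 2:
            raise InsufficientData(f"group {g} has {len(vecs)} vector(s); need >=2")
        for (i, va), (j, vb) in combinations(enumerate(vecs), 2):
            rows.append(
                ("euclidean", _group_pair_label(g, g), f"{g}.{i}", f"{g}.{j}",
                 euclidean_distance(va, vb))
            )
    for ga, gb in combinations(groups, 2):
        for (i, va), (j, vb) in product(
            enumerate(vectors_by_group[ga]), enumerate(vectors_by_group[gb])
        ):
            rows.append(
                ("euclidean", _group_pair_label(ga, gb), f"{ga}.{i}", f"{gb}.{j}",
                 euclidean_distance(va, vb))
            )
    return pd.DataFrame(rows, columns=["metric", "group_pair", "id_a", "id_b", "value"])


def pc_distributions(
    subsequences_by_group: Mapping[int, Sequence[Subsequence]],
    mode: str = "per_bout",
    k: int | None = None,
    sub_cost: float = 1.0,
    indel_cost: float = 1.0,
    normalize: bool = False,
) -> pd.DataFrame:
    """All intra- and inter-group penalty costs between subsequences.

    If ``normalize``, each cost is divided by the longer encoded length
    (metric label 'penalty_cost_normalized').
    """
    metric = "penalty_cost_normalized" if normalize else "penalty_cost"
    encoded = {
        g: [encode_for_pc(s, mode=mode, k=k) for s in subs]
        for g, subs in subsequences_by_group.items()
    }

    def value(sa: list[str], sb: list[str]) -> float:
        c = penalty_cost(sa, sb, sub_cost=sub_cost, indel_cost=indel_cost).cost
        if normalize:
            longer = max(len(sa), len(sb))
            return c / longer if longer else 0.0
        return c

    rows = []
    groups = sorted(encoded)
    for g in groups:
        seqs = encoded[g]
        if len(seqs) < 2:
            raise InsufficientData(f"group {g} has {len(seqs)} sequence(s); need >=2")
        for (i, sa), (j, sb) in combinations(enumerate(seqs), 2):
            rows.append((metric, _group_pair_label(g, g), f"{g}.{i}", f"{g}.{j}", value(sa, sb)))
    for ga, gb in combinations(groups, 2):
        for (i, sa), (j, sb) in product(enumerate(encoded[ga]), enumerate(encoded[gb])):
            rows.append((metric, _group_pair_label(ga, gb), f"{ga}.{i}", f"{gb}.{j}", value(sa, sb)))
    return pd.DataFrame(rows, columns=["metric", "group_pair", "id_a", "id_b", "value"])


def distance_summary(pairs: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/n of distance values per (metric, group_pair)."""
    g = pairs.groupby(["metric", "group_pair"], observed=True)["value"]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n="size")
    return out.reset_index()
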