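"""Transition-probability matrices, vectorization, and regime-block
densities.

For each subsequence a 12x12 matrix counts transitions between behaviors
in the fixed order SS, MS, ST, SR, SM, GM, GR, GT, GROOM, DEIM, ESC,
RESET. By default transitions are counted at bout boundaries (a behavior
*change*), so the diagonal is zero and self-dwell never inflates counts;
a per-frame mode counting every consecutive frame pair is kept for the
alternative reading. Row-normalizing the counts gives P[i, j] =
probability of exiting behavior i into behavior j; rows of behaviors never
exited stay all-zero rather than being imputed.

The 144-element row-major vectorization ("feature vector") is the object
compared across subsequences. Its cells partition into regime blocks —
hunting->hunting, hunting->nonhunting, nonhunting->hunting,
nonhunting->nonhunting — whose pooled values, summarized as bounded kernel
densities, expose how satiety redistributes transition mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Subsequence, run_length_encode
from .errors import InsufficientData, WrongLength
from .vocab import CODES, HUNTING, INDEX, N_BEHAVIORS, NONHUNTING, RESET

N_CELLS = N_BEHAVIORS * N_BEHAVIORS  # 144

BLOCK_NAMES = ("HH", "HN", "NH", "NN")


@dataclass
class TransitionMatrix:
    """Counts and row-stochastic probabilities for one subsequence."""

    counts: np.ndarray  # (12, 12) int
    sub: Subsequence | None = None

    @property
    def probs(self) -> np.ndarray:
        return normalize(self.counts)


def count_transitions(
    sub: Subsequence,
    include_reset: bool = True,
    per_frame: bool = False,
) -> np.ndarray:
    """12x12 transition count matrix for one subsequence.

    Default: one count per pair of consecutive bouts (diagonal is zero).
    With ``include_reset`` and a non-timeout termination, the final
    behavior additionally transitions into RESET. ``per_frame`` counts
    every consecutive frame pair instead (diagonal dominated by dwell).
    """
    counts = np.zeros((N_BEHAVIORS, N_BEHAVIORS), dtype=np.int64)
    if per_frame:
        labels = sub.labels
        for a, b in zip(labels[:-1], labels[1:]):
            counts[INDEX[a], INDEX[b]] += 1
        last = labels[-1]
    else:
        bouts = run_length_encode(sub)
        for a, b in zip(bouts[:-1], bouts[1:]):
            counts[INDEX[a.behavior], INDEX[b.behavior]] += 1
        last = bouts[-1].behavior
    if include_reset and sub.termination != "timeout":
        counts[INDEX[last], INDEX[RESET]] += 1
    return counts


def normalize(counts: np.ndarray) -> np.ndarray:
    """Row-normalize counts to probabilities; all-zero rows stay zero."""
    counts = np.asarray(counts, dtype=float)
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(sums > 0, counts / np.where(sums > 0, sums, 1.0), 0.0)
    return probs


def vectorize(probs: np.ndarray) -> np.ndarray:
    """Flatten a 12x12 matrix row-major into the 144-long feature vector."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (N_BEHAVIORS, N_BEHAVIORS):
        raise WrongLength(f"expected {N_BEHAVIORS}x{N_BEHAVIORS} matrix, got {probs.shape}")
    return probs.reshape(N_CELLS).copy()


def unvectorize(vec: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize` (exact round trip)."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (N_CELLS,):
        raise WrongLength(f"expected length-{N_CELLS} vector, got shape {vec.shape}")
    return vec.reshape(N_BEHAVIORS, N_BEHAVIORS).copy()


def regime_blocks(gm_as_nonhunting: bool = True) -> dict[str, np.ndarray]:
    """Index sets (into the 144-vector) of the four regime blocks.

    Hunting side: the 5 prey-directed behaviors (strikes included).
    Nonhunting side: the 5 nonhunting behaviors, plus neutral GM when
    ``gm_as_nonhunting`` (the display convention of the analysis). RESET
    row and column cells belong to no block.
    """
    hunting = [INDEX[c] for c in HUNTING]
    nonhunting = [INDEX[c] for c in NONHUNTING]
    if gm_as_nonhunting:
        nonhunting = [INDEX["GM"], *nonhunting]
    sides = {"H": hunting, "N": nonhunting}
    blocks = {}
    for name in BLOCK_NAMES:
        rows, cols = sides[name[0]], sides[name[1]]
        idx = np.array([r * N_BEHAVIORS + c for r in rows for c in cols], dtype=int)
        blocks[name] = np.sort(idx)
    return blocks


def block_values(
    vec: np.ndarray, blocks: Mapping[str, np.ndarray] | None = None
) -> dict[str, np.ndarray]:
    """Extract each regime block's cell values from a feature vector."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (N_CELLS,):
        raise WrongLength(f"expected length-{N_CELLS} vector, got shape {vec.shape}")
    if blocks is None:
        blocks = regime_blocks()
    return {name: vec[idx] for name, idx in blocks.items()}


def pooled_block_values(
    vectors: Iterable[np.ndarray], blocks: Mapping[str, np.ndarray] | None = None
) -> dict[str, np.ndarray]:
    """Pool block values across many feature vectors (one feed state)."""
    if blocks is None:
        blocks = regime_blocks()
    pools: dict[str, list[np.ndarray]] = {name: [] for name in blocks}
    for v in vectors:
        for name, vals in block_values(v, blocks).items():
            pools[name].append(vals)
    return {name: np.concatenate(v) if v else np.array([]) for name, v in pools.items()}


def block_density(
    values: Sequence[float],
    grid_size: int = 512,
    bandwidth: str | float = "silverman",
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel density of transition probabilities on the unit interval.

    Gaussian KDE (Silverman bandwidth by default) with mass reflected at
    the 0 and 1 boundaries so the trapezoid integral over [0, 1] is 1.
    Returns ``(grid, density)``. Degenerate all-equal samples fall back to
    a narrow fixed bandwidth so the density still concentrates correctly.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientData("KDE needs at least 2 values")
    grid = np.linspace(0.0, 1.0, grid_size)
    if np.ptp(values) == 0.0:
        # zero-variance sample: Silverman bandwidth collapses; use a
        # narrow Gaussian bump at the common value, reflected.
        h = 0.01
        dens = _reflected_gaussian(grid, values, h)
    else:
        kde = stats.gaussian_kde(values, bw_method=bandwidth)
        dens = kde(grid) + kde(-grid) + kde(2.0 - grid)
    area = np.trapezoid(dens, grid)
    return grid, dens / area


def _reflected_gaussian(grid: np.ndarray, values: np.ndarray, h: float) -> np.ndarray:
    def bump(x: np.ndarray) -> np.ndarray:
        z = (x[None, :] - values[:, None]) / h
        return np.exp(-0.5 * z * z).mean(axis=0) / (h * np.sqrt(2 * np.pi))

    return bump(grid) + bump(-grid) + bump(2.0 - grid)


def transitions_into(counts_list: Iterable[np.ndarray]) -> pd.Series:
    """Column sums pooled over count matrices: transitions *into* each
    behavior (one feed state's subsequences)."""
    total = np.zeros((N_BEHAVIORS, N_BEHAVIORS), dtype=np.int64)
    for c in counts_list:
        total += np.asarray(c, dtype=np.int64)
    return pd.Series(total.sum(axis=0), index=list(CODES), name="transitions_into")


def transition_table(
    subsequences: Iterable[Subsequence],
    include_reset: bool = True,
    per_frame: bool = False,
) -> pd.DataFrame:
    """Long-format transition counts/probabilities over a dataset.

    Columns: animal_id, feed_state, subsequence, from, to, count, prob.
    Zero cells are omitted to keep the table compact.
    """
    rows = []
    for sub in subsequences:
        counts = count_transitions(sub, include_reset=include_reset, per_frame=per_frame)
        probs = normalize(counts)
        for i, j in zip(*np.nonzero(counts)):
            rows.append(
                (
                    sub.animal_id,
                    sub.feed_state,
                    sub.ordinal,
                    CODES[i],
                    CODES[j],
                    int(counts[i, j]),
                    float(probs[i, j]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["animal_id", "feed_state", "subsequence", "from", "to", "count", "prob"],
    )


def feature_vectors_by_state(
    subsequences: Iterable[Subsequence],
    include_reset: bool = True,
    per_frame: bool = False,
) -> dict[int, list[np.ndarray]]:
    """Feature vector of every subsequence, grouped by feed state."""
    out: dict[int, list[np.ndarray]] = {}
    for sub in subsequences:
        counts = count_transitions(sub, include_reset=include_reset, per_frame=per_frame)
        out.setdefault(sub.feed_state, []).append(vectorize(normalize(counts)))
    return out
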