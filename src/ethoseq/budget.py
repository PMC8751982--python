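"""Time budgets: behavior probabilities, bout durations, strike tallies,
and the group comparisons used across feed states.

*Behavior probability* is a time fraction: frames spent in a behavior
divided by the subsequence's frame count, with instantaneous strike frames
excluded from the denominator — strikes carry no dwell time and are
reported as event counts instead. *Bout duration* statistics summarize how
long a behavior lasts once initiated. Strike tallies combine both views:
missed-strike events, capture-terminated subsequences, and the capture
percentage.

Group comparisons follow the study convention: one-way ANOVA across feed
states with Tukey HSD pairwise tests gated on ANOVA p < 0.05, and a
chi-square test on the capture-vs-no-capture contingency (df = states - 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Subsequence, bout_table, run_length_encode
from .errors import DegenerateSubsequence, InsufficientData
from .vocab import DURATION_BEHAVIORS, INSTANTANEOUS


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (table convention)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def behavior_probabilities(sub: Subsequence) -> pd.DataFrame:
    """Per-behavior time fractions for one subsequence.

    Returns one row per duration behavior (SM, SR, ST, GM, GR, GT, GROOM,
    DEIM, ESC) with ``probability`` = frames in behavior / non-strike
    frames. Fractions sum to 1. Strike events are counted, not timed; see
    :func:`strike_counts`.

    Raises DegenerateSubsequence if the subsequence has no non-strike
    frames.
    """
    labels = sub.labels
    keep = ~np.isin(labels, INSTANTANEOUS)
    denom = int(keep.sum())
    if denom == 0:
        raise DegenerateSubsequence(
            f"{sub.animal_id} state {sub.feed_state} subsequence {sub.ordinal}: "
            "only strike frames"
        )
    counts = pd.Series(labels[keep]).value_counts()
    rows = [
        (
            sub.animal_id,
            sub.feed_state,
            sub.ordinal,
            b,
            counts.get(b, 0) / denom,
        )
        for b in DURATION_BEHAVIORS
    ]
    return pd.DataFrame(
        rows, columns=["animal_id", "feed_state", "subsequence", "behavior", "probability"]
    )


def strike_counts(sub: Subsequence) -> dict[str, int]:
    """Number of strike events (SS, MS) in one subsequence.

    Counted as bouts so that an anomalous multi-frame strike run still
    registers as one event.
    """
    out = {c: 0 for c in INSTANTANEOUS}
    for b in run_length_encode(sub):
        if b.behavior in out:
            out[b.behavior] += 1
    return out


def probabilities_table(subsequences: Iterable[Subsequence]) -> pd.DataFrame:
    """Concatenated behavior probabilities over many subsequences."""
    frames = [behavior_probabilities(s) for s in subsequences]
    if not frames:
        return pd.DataFrame(
            columns=["animal_id", "feed_state", "subsequence", "behavior", "probability"]
        )
    return pd.concat(frames, ignore_index=True)


def bout_duration_stats(bouts: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/n of bout durations per (feed_state, behavior).

    Strike bouts are excluded (instantaneous: no meaningful duration).
    Sample SD uses the n-1 denominator; a single-bout group reports SD 0.
    Empty groups are simply absent.
    """
    dur = bouts[~bouts["behavior"].isin(INSTANTANEOUS)]
    if dur.empty:
        return pd.DataFrame(columns=["feed_state", "behavior", "mean", "sd", "n"])
    g = dur.groupby(["feed_state", "behavior"], observed=True)["duration_s"]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n="size")
    return out.reset_index()


@dataclass(frozen=True)
class StrikeTally:
    """Strike and capture bookkeeping for one feed state.

    ``capture_pct`` is the percentage of subsequences ending in prey
    capture. ``success_rate_pct`` is the alternative per-attempt view,
    captures / (captures + missed strikes); the two need not agree and
    both are reported.
    """

    feed_state: int
    missed_strikes: int
    capture_subsequences: int
    total_subsequences: int

    @property
    def capture_pct(self) -> int:
        if self.total_subsequences == 0:
            return 0
        return round_half_away(100.0 * self.capture_subsequences / self.total_subsequences)

    @property
    def success_rate_pct(self) -> int:
        attempts = self.capture_subsequences + self.missed_strikes
        if attempts == 0:
            return 0
        return round_half_away(100.0 * self.capture_subsequences / attempts)


def strike_tally(subsequences: Sequence[Subsequence], feed_state: int) -> StrikeTally:
    """Tally strikes and captures over the subsequences of one feed state."""
    subs = [s for s in subsequences if s.feed_state == feed_state]
    missed = sum(strike_counts(s)["MS"] for s in subs)
    captures = sum(1 for s in subs if s.termination == "capture")
    return StrikeTally(feed_state, missed, captures, len(subs))


def strike_tally_table(subsequences: Sequence[Subsequence]) -> pd.DataFrame:
    """Per-state tally table over all feed states present."""
    states = sorted({s.feed_state for s in subsequences})
    rows = []
    for st in states:
        t = strike_tally(subsequences, st)
        rows.append(
            (
                t.feed_state,
                t.missed_strikes,
                t.capture_subsequences,
                t.total_subsequences,
                t.capture_pct,
                t.success_rate_pct,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feed_state",
            "missed_strikes",
            "capture_subsequences",
            "total_subsequences",
            "capture_pct",
            "success_rate_pct",
        ],
    )


def group_compare(
    values: Sequence[float] | Sequence[Sequence[int]],
    groups: Sequence | None = None,
    method: str = "anova_tukey",
    alpha: float = 0.05,
) -> dict:
    """Compare a statistic across feed-state groups.

    method='anova_tukey': ``values`` are observations and ``groups`` their
    labels. Returns one-way ANOVA F and p, plus a Tukey HSD pairwise table
    when ANOVA p < alpha (the study's gating rule).

    method='chi_square': ``values`` is a contingency table (rows =
    outcomes, columns = groups), e.g. captures vs non-captures per feed
    state. Returns the chi-square statistic, df and p.
    """
    if method == "chi_square":
        table = np.asarray(values, dtype=float)
        if table.ndim != 2 or table.shape[1] < 2:
            raise InsufficientData("chi_square needs a 2-D contingency with >=2 groups")
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        return {"method": "chi_square", "statistic": float(chi2), "df": int(dof), "p": float(p)}

    if method != "anova_tukey":
        raise ValueError(f"unknown method {method!r}")
    if groups is None:
        raise ValueError("anova_tukey requires group labels")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise InsufficientData("need >=2 groups for ANOVA")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        raise InsufficientData("every group needs n >= 2 for ANOVA")
    f, p = stats.f_oneway(*samples)
    out = {"method": "anova_tukey", "F": float(f), "p": float(p), "tukey": None}
    if p < alpha:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(values, groups, alpha=alpha)
        tukey = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
        out["tukey"] = tukey
    return out


def missed_strikes_per_subsequence(subsequences: Sequence[Subsequence]) -> pd.DataFrame:
    """Missed-strike count per subsequence (for across-state comparison)."""
    rows = [
        (s.animal_id, s.feed_state, s.ordinal, strike_counts(s)["MS"])
        for s in subsequences
    ]
    return pd.DataFrame(rows, columns=["animal_id", "feed_state", "subsequence", "missed_strikes"])


def dataset_bout_table(subsequences: Iterable[Subsequence]) -> pd.DataFrame:
    """Alias for :func:`ethoseq.core.bout_table` kept near its consumers."""
    return bout_table(subsequences)
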