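"""Reported summary statistics from the original mantis hunting dataset.

The raw frame-level scorings of the original study were never deposited;
what survives are its printed summary tables. The constants here transcribe
those summaries so that derived quantities (capture percentages, regime
occupancies, dataset totals) can be recomputed, and so the synthetic
generator's defaults can be anchored to realistic magnitudes.

Keyed by feed state 0-4 (prey items consumed before the trial).
"""

from __future__ import annotations

#: Subsequence counts per feed state (totals over the 6 animals).
SUBSEQUENCE_COUNTS: dict[int, int] = {0: 58, 1: 45, 2: 35, 3: 24, 4: 26}

#: Mean probability (percent of subsequence time) of exhibiting each
#: duration behavior, per feed state.
BEHAVIOR_PROB_MEAN_PCT: dict[int, dict[str, float]] = {
    0: {"SM": 35, "SR": 20, "ST": 9, "GM": 24, "GR": 1, "GT": 4, "DEIM": 2, "GROOM": 3},
    1: {"SM": 34, "SR": 15, "ST": 8, "GM": 33, "GR": 1, "GT": 1, "DEIM": 1, "GROOM": 7},
    2: {"SM": 44, "SR": 9, "ST": 6, "GM": 34, "GR": 1, "GT": 0, "DEIM": 1, "GROOM": 6},
    3: {"SM": 33, "SR": 9, "ST": 2, "GM": 43, "GR": 3, "GT": 2, "DEIM": 0, "GROOM": 6},
    4: {"SM": 20, "SR": 4, "ST": 1, "GM": 42, "GR": 11, "GT": 9, "DEIM": 0, "GROOM": 7},
}

#: Mean (SD) bout duration in seconds of each duration behavior, per state.
BOUT_DURATION_MEAN_SD_S: dict[int, dict[str, tuple[float, float]]] = {
    0: {"SM": (3.47, 4.55), "SR": (1.21, 1.28), "ST": (1.83, 2.13), "GM": (4.99, 7.08),
        "GR": (0.39, 0.84), "GT": (0.72, 2.48), "DEIM": (0.22, 0.97), "GROOM": (1.79, 5.35)},
    1: {"SM": (3.07, 4.09), "SR": (0.84, 1.15), "ST": (1.57, 2.29), "GM": (6.07, 6.33),
        "GR": (0.45, 1.16), "GT": (0.11, 0.54), "DEIM": (0.19, 0.95), "GROOM": (3.25, 4.20)},
    2: {"SM": (3.57, 5.50), "SR": (0.46, 0.41), "ST": (1.07, 1.26), "GM": (8.53, 9.60),
        "GR": (0.32, 0.38), "GT": (0.03, 0.18), "DEIM": (0.29, 1.10), "GROOM": (3.27, 4.22)},
    3: {"SM": (3.36, 7.10), "SR": (0.38, 0.36), "ST": (0.64, 1.73), "GM": (9.91, 10.79),
        "GR": (0.87, 1.13), "GT": (0.69, 1.14), "DEIM": (0.05, 0.25), "GROOM": (5.59, 6.12)},
    4: {"SM": (3.11, 4.80), "SR": (0.41, 0.54), "ST": (0.31, 0.85), "GM": (11.49, 17.26),
        "GR": (1.15, 1.24), "GT": (1.39, 1.61), "DEIM": (0.14, 0.70), "GROOM": (7.93, 11.88)},
}

#: (capture-terminated subsequences, total subsequences) per feed state.
CAPTURES: dict[int, tuple[int, int]] = {
    0: (50, 58),
    1: (43, 45),
    2: (33, 35),
    3: (20, 24),
    4: (11, 26),
}

#: Missed-strike counts per feed state.
MISS_STRIKES: dict[int, int] = {0: 33, 1: 28, 2: 25, 3: 16, 4: 9}

#: Reported successful-strike rate (percent), per feed state.
SUCCESS_STRIKE_RATE_PCT: dict[int, int] = {0: 73, 1: 74, 2: 66, 3: 69, 4: 37}

#: Mean (SD) subsequence length in seconds, per feed state.
SUBSEQ_TIME_MEAN_SD_S: dict[int, tuple[float, float]] = {
    0: (33.80, 40.27),
    1: (39.84, 39.64),
    2: (66.60, 75.28),
    3: (98.03, 129.53),
    4: (95.33, 130.23),
}

#: Hunting behaviors whose mean probabilities sum to the reported
#: hunting-regime occupancy (64/57/59/44/25 % across states 0-4).
HUNTING_OCCUPANCY_TERMS: tuple[str, ...] = ("SM", "SR", "ST")


def hunting_occupancy_pct(feed_state: int) -> float:
    """Hunting-regime occupancy (percent) from the reported behavior means."""
    row = BEHAVIOR_PROB_MEAN_PCT[feed_state]
    return float(sum(row[b] for b in HUNTING_OCCUPANCY_TERMS))
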