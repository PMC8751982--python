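"""Semi-Markov synthetic ethogram generator.

Downstream stages need frame-level label streams with the statistical
structure the analysis assumes: feed-state-dependent transition matrices,
overdispersed dwell times, subsequences terminated by an absorbing arena
reset (usually a successful strike). This module samples such streams
from an explicit semi-Markov model: successive behaviors follow an
embedded Markov chain with zero self-transition mass, and the time spent
in each behavior is drawn from a per-behavior dwell distribution (gamma
on seconds by default, rounded to >= 1 frame), so time budgets and
transition structure are controlled independently.

Strikes are instantaneous events. When the chain selects a strike
attempt, the outcome is a successful strike with probability
``p_capture_given_strike`` — emitting SS followed by an arena reset
(capture is absorbing) — otherwise a single missed-strike frame (MS),
after which the chain continues from the MS row. An escape bout forces an
arena reset with probability ``p_escape_reset``. The trial is truncated
at ``max_duration_s`` (timeout).

Defaults across feed states 0-4 interpolate a "starved" and a "sated"
anchor: hunting->hunting transition mass and strike attempt rate fall
with satiety while general-monitoring and grooming dwell means rise,
anchored to the reported per-state bout-duration summaries of the
original dataset.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import reference
from .core import FrameSequence, Subsequence, segment_subsequences, write_ethogram
from .errors import InvalidFeedState
from .vocab import (
    CODES,
    DEFAULT_FPS,
    DURATION_BEHAVIORS,
    INDEX,
    N_BEHAVIORS,
    NONRESET,
    RESET,
    TRIAL_DURATION_S,
)

__all__ = [
    "DwellDistribution",
    "SemiMarkovParams",
    "SyntheticDataset",
    "default_params",
    "simulate_subsequence",
    "simulate_dataset",
    "save_params_yaml",
    "load_params_yaml",
]


@dataclass(frozen=True)
class DwellDistribution:
    """Dwell-time distribution of one behavior.

    family='gamma_seconds': gamma with the given mean/SD in seconds,
    rounded to whole frames (minimum 1). SD 0 degenerates to a fixed
    dwell. family='geometric_frames': geometric on frame counts with
    success probability p (support 1, 2, ...).
    """

    family: str = "gamma_seconds"
    mean_s: float = 1.0
    sd_s: float = 1.0
    p: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in ("gamma_seconds", "geometric_frames"):
            raise ValueError(f"unknown dwell family {self.family!r}")
        if self.family == "gamma_seconds":
            if self.mean_s <= 0 or self.sd_s < 0:
                raise ValueError("gamma dwell needs mean_s > 0 and sd_s >= 0")
        elif not 0 < self.p <= 1:
            raise ValueError("geometric dwell needs 0 < p <= 1")

    def sample_frames(self, rng: np.random.Generator, fps: float) -> int:
        if self.family == "geometric_frames":
            return int(rng.geometric(self.p))
        if self.sd_s == 0:
            seconds = self.mean_s
        else:
            shape = (self.mean_s / self.sd_s) ** 2
            scale = self.sd_s**2 / self.mean_s
            seconds = rng.gamma(shape, scale)
        return max(1, int(round(seconds * fps)))


@dataclass
class SemiMarkovParams:
    """Generating parameters for one feed state.

    ``transition_probs`` is a row-stochastic DataFrame over the 11
    non-reset codes with zero diagonal. The SS row is all zero by
    convention: a successful strike always transitions to RESET. Mass on
    the SS *column* is the strike-attempt hazard; the simulator resolves
    each attempt into SS (capture) or MS (miss).
    """

    feed_state: int
    initial_probs: dict[str, float]
    transition_probs: pd.DataFrame
    dwell: dict[str, DwellDistribution]
    p_capture_given_strike: float
    p_escape_reset: float = 0.25
    max_duration_s: float = TRIAL_DURATION_S
    fps: float = DEFAULT_FPS

    def validate(self, atol: float = 1e-9) -> None:
        if self.feed_state not in (0, 1, 2, 3, 4):
            raise InvalidFeedState(f"feed_state {self.feed_state} not in 0..4")
        tp = self.transition_probs
        if list(tp.index) != list(NONRESET) or list(tp.columns) != list(NONRESET):
            raise ValueError("transition_probs must be indexed by the 11 non-reset codes")
        init = sum(self.initial_probs.values())
        if abs(init - 1.0) > atol:
            raise ValueError(f"initial_probs sums to {init}, not 1")
        if any(b not in DURATION_BEHAVIORS for b in self.initial_probs):
            raise ValueError("initial_probs must range over duration behaviors")
        if not np.allclose(np.diag(tp.to_numpy()), 0.0, atol=atol):
            raise ValueError("transition diagonal must be zero")
        sums = tp.sum(axis=1)
        if abs(sums.loc["SS"]) > atol:
            raise ValueError("SS row must be zero (SS always transitions to RESET)")
        bad = [c for c in NONRESET if c != "SS" and abs(sums.loc[c] - 1.0) > atol]
        if bad:
            raise ValueError(f"transition rows do not sum to 1: {bad}")
        if not 0 <= self.p_capture_given_strike <= 1:
            raise ValueError("p_capture_given_strike must be in [0, 1]")
        for b in DURATION_BEHAVIORS:
            if b not in self.dwell:
                raise ValueError(f"missing dwell distribution for {b}")

    def observed_transition_matrix(self, include_reset: bool = True) -> np.ndarray:
        """Expected bout-level transition probabilities (12x12, canonical
        order) implied by the chain plus strike/escape resolution.

        This is the matrix a consistent estimator applied to simulated
        bout streams should recover.
        """
        T = np.zeros((N_BEHAVIORS, N_BEHAVIORS))
        tp = self.transition_probs
        pc = self.p_capture_given_strike
        for r in NONRESET:
            if r == "SS":
                continue
            row = tp.loc[r]
            i = INDEX[r]
            for c in NONRESET:
                p = float(row[c])
                if p == 0.0:
                    continue
                if c == "SS":  # strike attempt
                    T[i, INDEX["SS"]] += p * pc
                    T[i, INDEX["MS"]] += p * (1 - pc)
                else:
                    T[i, INDEX[c]] += p
            if r == "ESC":
                # escape bouts end the subsequence with prob p_escape_reset
                T[i, :] *= 1 - self.p_escape_reset
                if include_reset:
                    T[i, INDEX[RESET]] = self.p_escape_reset
        if include_reset:
            T[INDEX["SS"], INDEX[RESET]] = 1.0
        if not include_reset:
            # renormalize rows that lost mass to RESET
            sums = T.sum(axis=1, keepdims=True)
            T = np.where(sums > 0, T / np.where(sums > 0, sums, 1), 0.0)
        return T


def _interp(a: float, b: float, x: float) -> float:
    return a + (b - a) * x


def _normalized(weights: dict[str, float]) -> dict[str, float]:
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def default_params(feed_state: int) -> SemiMarkovParams:
    """Default generating parameters for one feed state.

    Parameters vary monotonically with satiety: hunting retention and
    strike-attempt hazard fall, general-monitoring attraction rises, and
    dwell means/SDs follow the reported per-state bout summaries (e.g.
    GM dwell mean 4.99 s when starved up to 11.49 s at 4-fed). Capture
    probability per strike follows the reported success-strike rates.
    """
    if feed_state not in (0, 1, 2, 3, 4):
        raise InvalidFeedState(f"feed_state {feed_state} not in 0..4")
    x = feed_state / 4.0

    strike = _interp(0.30, 0.06, x)  # strike-attempt hazard from hunting rows
    retain = _interp(0.92, 0.45, x)  # total hunting-side mass of hunting rows
    gm_to_hunt = _interp(0.60, 0.15, x)  # GM row's pull back into hunting

    hunt_targets = {"SM": 0.5, "SR": 0.3, "ST": 0.2}
    nonhunt_spread = {"GM": 0.60, "GROOM": 0.20, "GR": 0.09, "GT": 0.09,
                      "DEIM": 0.01, "ESC": 0.01}

    tp = pd.DataFrame(0.0, index=list(NONRESET), columns=list(NONRESET))

    def fill_hunting_row(r: str) -> None:
        targets = _normalized({k: v for k, v in hunt_targets.items() if k != r})
        for k, v in targets.items():
            tp.loc[r, k] = (retain - strike) * v
        tp.loc[r, "SS"] = strike
        spread = _normalized(nonhunt_spread)
        for k, v in spread.items():
            tp.loc[r, k] += (1 - retain) * v

    for r in ("ST", "SR", "SM"):
        fill_hunting_row(r)
    # after a miss the mantis repositions rather than re-striking at once
    targets = _normalized(hunt_targets)
    for k, v in targets.items():
        tp.loc["MS", k] = retain * v
    for k, v in _normalized(nonhunt_spread).items():
        tp.loc["MS", k] += (1 - retain) * v

    for k, v in _normalized(hunt_targets).items():
        tp.loc["GM", k] = gm_to_hunt * v
    for k, v in _normalized({"GR": 0.28, "GT": 0.24, "GROOM": 0.43,
                             "DEIM": 0.02, "ESC": 0.03}).items():
        tp.loc["GM", k] = (1 - gm_to_hunt) * v

    nh_to_hunt = 0.008  # nonhunting -> hunting transitions are rare (<1%)
    for r in ("GR", "GT", "GROOM", "DEIM", "ESC"):
        tp.loc[r, "SM"] = nh_to_hunt
        others = {k: v for k, v in {"GM": 0.55, "GR": 0.15, "GT": 0.12,
                                    "GROOM": 0.14, "DEIM": 0.02, "ESC": 0.02}.items()
                  if k != r}
        for k, v in _normalized(others).items():
            tp.loc[r, k] = (1 - nh_to_hunt) * v

    np.fill_diagonal(tp.values, 0.0)
    sums = tp.sum(axis=1)
    for r in NONRESET:
        if r != "SS":
            tp.loc[r] /= sums[r]
    tp.loc["SS"] = 0.0

    starved_init = {"SM": 0.45, "SR": 0.15, "ST": 0.10, "GM": 0.20, "GR": 0.02,
                    "GT": 0.02, "GROOM": 0.04, "DEIM": 0.01, "ESC": 0.01}
    sated_init = {"SM": 0.15, "SR": 0.04, "ST": 0.02, "GM": 0.50, "GR": 0.09,
                  "GT": 0.09, "GROOM": 0.09, "DEIM": 0.01, "ESC": 0.01}
    init = _normalized(
        {b: _interp(starved_init[b], sated_init[b], x) for b in DURATION_BEHAVIORS}
    )

    dwell: dict[str, DwellDistribution] = {}
    table = reference.BOUT_DURATION_MEAN_SD_S[feed_state]
    for b in DURATION_BEHAVIORS:
        if b == "ESC":
            dwell[b] = DwellDistribution("gamma_seconds", mean_s=2.0, sd_s=1.5)
        else:
            mean, sd = table[b]
            dwell[b] = DwellDistribution("gamma_seconds", mean_s=mean, sd_s=sd)

    params = SemiMarkovParams(
        feed_state=feed_state,
        initial_probs=init,
        transition_probs=tp,
        dwell=dwell,
        p_capture_given_strike=reference.SUCCESS_STRIKE_RATE_PCT[feed_state] / 100.0,
    )
    params.validate()
    return params


def _simulate_labels(
    params: SemiMarkovParams,
    rng: np.random.Generator,
    max_frames: int | None = None,
) -> tuple[list[str], str]:
    """Sample one subsequence's frame labels and its termination."""
    fps = params.fps
    if max_frames is None:
        max_frames = int(params.max_duration_s * fps)
    tp = params.transition_probs
    cols = list(tp.columns)
    rows = {r: tp.loc[r].to_numpy(dtype=float) for r in NONRESET}

    init_b = list(params.initial_probs)
    init_p = np.array([params.initial_probs[b] for b in init_b])
    current = rng.choice(init_b, p=init_p)

    labels: list[str] = []
    while True:
        if current == "SS_ATTEMPT":
            if rng.random() < params.p_capture_given_strike:
                labels.append("SS")
                return labels, "capture"
            labels.append("MS")
            current = "MS"
        else:
            n = params.dwell[current].sample_frames(rng, fps)
            labels.extend([current] * n)
            if len(labels) >= max_frames:
                return labels[:max_frames], "timeout"
            if current == "ESC" and rng.random() < params.p_escape_reset:
                return labels, "escape_reset"
        if len(labels) >= max_frames:
            return labels[:max_frames], "timeout"
        p = rows[current]
        nxt = cols[int(rng.choice(len(cols), p=p))]
        current = "SS_ATTEMPT" if nxt == "SS" else nxt


def simulate_subsequence(
    params: SemiMarkovParams, rng: np.random.Generator | int
) -> Subsequence:
    """Sample a single subsequence (wrapped in its own one-subsequence
    FrameSequence parent)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels, term = _simulate_labels(params, rng)
    if term != "timeout":
        labels = labels + [RESET]
    seq = FrameSequence(
        animal_id="sim",
        feed_state=params.feed_state,
        labels=np.array(labels, dtype=object),
        fps=params.fps,
    )
    return segment_subsequences(seq)[0]


def _child_rng(seed: int, animal: int, state: int) -> np.random.Generator:
    """Per-animal-per-state stream from one global seed (fixed counter)."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(animal, state))
    return np.random.default_rng(ss)


@dataclass
class SyntheticDataset:
    """A simulated study: n animals x 5 feed states, one video each."""

    params_by_state: dict[int, SemiMarkovParams]
    sequences: list[FrameSequence]
    provenance: dict = field(default_factory=dict)

    def subsequences(self) -> list[Subsequence]:
        out: list[Subsequence] = []
        for seq in self.sequences:
            out.extend(segment_subsequences(seq))
        return out

    def write(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for seq in self.sequences:
            p = out_dir / f"{seq.animal_id}_state{seq.feed_state}.csv"
            write_ethogram(seq, p)
            paths.append(p)
        return paths

    def checksum(self) -> str:
        h = hashlib.sha256()
        for seq in self.sequences:
            h.update(seq.animal_id.encode())
            h.update(bytes([seq.feed_state]))
            h.update(",".join(seq.labels).encode())
        return h.hexdigest()


def simulate_dataset(
    n_animals: int = 6,
    params_by_state: Mapping[int, SemiMarkovParams] | None = None,
    seed: int = 0,
    trial_duration_s: float | None = None,
) -> SyntheticDataset:
    """Simulate the full study design: one video per animal per feed state.

    Each video concatenates subsequences (separated by RESET frames)
    until the trial length is reached; the final subsequence is truncated
    at the trial boundary (timeout). Regenerating with the same seed is
    byte-identical; each (animal, state) cell has its own child stream so
    the dataset is reproducible piecewise.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    if params_by_state is None:
        params_by_state = {s: default_params(s) for s in range(5)}
    sequences: list[FrameSequence] = []
    for a in range(n_animals):
        for state in sorted(params_by_state):
            params = params_by_state[state]
            fps = params.fps
            limit = int((trial_duration_s or params.max_duration_s) * fps)
            rng = _child_rng(seed, a, state)
            labels: list[str] = []
            while len(labels) < limit:
                remaining = limit - len(labels)
                sub_labels, term = _simulate_labels(params, rng, max_frames=remaining)
                labels.extend(sub_labels)
                if term != "timeout" and len(labels) < limit:
                    labels.append(RESET)
            sequences.append(
                FrameSequence(
                    animal_id=f"animal{a + 1}",
                    feed_state=state,
                    labels=np.array(labels[:limit], dtype=object),
                    fps=fps,
                )
            )
    return SyntheticDataset(
        params_by_state=dict(params_by_state),
        sequences=sequences,
        provenance={"seed": seed, "n_animals": n_animals, "parameter_source": "default_params"},
    )


# ---------------------------------------------------------------------------
# YAML parameter files

def _params_to_dict(p: SemiMarkovParams) -> dict:
    return {
        "feed_state": p.feed_state,
        "initial_probs": {k: float(v) for k, v in p.initial_probs.items()},
        "transition_probs": {
            r: {c: float(p.transition_probs.loc[r, c])
                for c in NONRESET if p.transition_probs.loc[r, c] != 0}
            for r in NONRESET
        },
        "dwell": {
            b: {"family": d.family, "mean_s": d.mean_s, "sd_s": d.sd_s, "p": d.p}
            for b, d in p.dwell.items()
        },
        "p_capture_given_strike": p.p_capture_given_strike,
        "p_escape_reset": p.p_escape_reset,
        "max_duration_s": p.max_duration_s,
        "fps": p.fps,
    }


def _params_from_dict(d: dict) -> SemiMarkovParams:
    tp = pd.DataFrame(0.0, index=list(NONRESET), columns=list(NONRESET))
    for r, row in d["transition_probs"].items():
        for c, v in row.items():
            tp.loc[r, c] = float(v)
    params = SemiMarkovParams(
        feed_state=int(d["feed_state"]),
        initial_probs={k: float(v) for k, v in d["initial_probs"].items()},
        transition_probs=tp,
        dwell={b: DwellDistribution(**spec) for b, spec in d["dwell"].items()},
        p_capture_given_strike=float(d["p_capture_given_strike"]),
        p_escape_reset=float(d.get("p_escape_reset", 0.25)),
        max_duration_s=float(d.get("max_duration_s", TRIAL_DURATION_S)),
        fps=float(d.get("fps", DEFAULT_FPS)),
    )
    params.validate()
    return params


def save_params_yaml(params_by_state: Mapping[int, SemiMarkovParams], path: str | Path) -> None:
    data = {int(s): _params_to_dict(p) for s, p in params_by_state.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_params_yaml(path: str | Path) -> dict[int, SemiMarkovParams]:
    data = yaml.safe_load(Path(path).read_text())
    return {int(s): _params_from_dict(d) for s, d in data.items()}
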