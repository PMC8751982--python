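"""Pipeline orchestration: simulate -> budget -> transitions -> distances.

`run_pipeline` drives the full analysis from a config mapping, writing
tidy CSVs, a summary JSON, qualitative figures (per-video behavior
rasters, regime heat map, distance box plots) and a run manifest. The
figures are descriptive outputs, not analysis surfaces.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .budget import bout_duration_stats, probabilities_table, strike_tally_table
from .core import (
    FrameSequence,
    Subsequence,
    bout_table,
    read_ethogram,
    segment_subsequences,
    write_bout_table,
    write_ethogram,
)
from .distance import (
    default_decimation,
    distance_summary,
    pairwise_distance_distributions,
    pc_distributions,
)
from .simulate import default_params, simulate_dataset
from .transitions import feature_vectors_by_state, transition_table
from .vocab import CODES, DEFAULT_FPS, HUNTING, INDEX, RESET

log = logging.getLogger("ethoseq")

DEFAULT_CONFIG: dict[str, Any] = {
    "fps": DEFAULT_FPS,
    "seed": 0,
    "n_animals": 6,
    "trial_duration_s": None,  # None -> full 7-minute trials
    "include_reset": True,
    "per_frame": False,
    "pc_mode": "decimate",
    "pc_max_symbols": 2000,
    "pc_sub_cost": 1.0,
    "pc_indel_cost": 1.0,
    "pc_normalize": True,
    "figures": True,
}


@dataclass
class RunManifest:
    """Record of one pipeline run, written alongside the outputs."""

    config: dict[str, Any]
    version: str = __version__
    seed: int | None = None
    input_checksums: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    timings_s: dict[str, float] = field(default_factory=dict)
    error: str | None = None

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_input_dir(in_dir: Path, fps: float) -> list[FrameSequence]:
    paths = sorted(in_dir.glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no ethogram CSVs found in {in_dir}")
    return [read_ethogram(p, fps=fps) for p in paths]


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> RunManifest:
    """Execute all stages. Either ``config['input_dir']`` points at
    ethogram CSVs, or a synthetic dataset is simulated from the defaults
    with ``config['seed']``/``config['n_animals']``."""
    cfg = {**DEFAULT_CONFIG, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=cfg.get("seed"))
    try:
        _run_stages(cfg, out, manifest)
    except Exception as exc:  # manifest is written even on failure
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    return manifest


def _run_stages(cfg: dict[str, Any], out: Path, manifest: RunManifest) -> None:
    fps = float(cfg["fps"])

    t0 = time.perf_counter()
    if cfg.get("input_dir"):
        in_dir = Path(cfg["input_dir"])
        if not in_dir.is_dir():
            raise FileNotFoundError(f"input_dir does not exist: {in_dir}")
        sequences = load_input_dir(in_dir, fps)
        manifest.input_checksums = {p.name: _checksum(p) for p in sorted(in_dir.glob("*.csv"))}
    else:
        dataset = simulate_dataset(
            n_animals=int(cfg["n_animals"]),
            seed=int(cfg["seed"]),
            trial_duration_s=cfg.get("trial_duration_s"),
        )
        sim_dir = out / "ethograms"
        paths = dataset.write(sim_dir)
        manifest.outputs += [str(p) for p in paths]
        sequences = dataset.sequences
    manifest.timings_s["load"] = time.perf_counter() - t0
    log.info("stage load: %d videos", len(sequences))

    subsequences: list[Subsequence] = []
    for seq in sequences:
        subsequences.extend(segment_subsequences(seq))
    log.info("segmented %d subsequences", len(subsequences))

    t0 = time.perf_counter()
    probs = probabilities_table(subsequences)
    probs.to_csv(out / "probabilities.csv", index=False)
    bouts = bout_table(subsequences)
    write_bout_table(bouts, out / "bouts.csv")
    bout_duration_stats(bouts).to_csv(out / "bout_stats.csv", index=False)
    strike_tally_table(subsequences).to_csv(out / "strike_tally.csv", index=False)
    manifest.timings_s["budget"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    trans = transition_table(
        subsequences, include_reset=cfg["include_reset"], per_frame=cfg["per_frame"]
    )
    trans.to_csv(out / "transitions.csv", index=False)
    vectors = feature_vectors_by_state(
        subsequences, include_reset=cfg["include_reset"], per_frame=cfg["per_frame"]
    )
    manifest.timings_s["transitions"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    eu = pairwise_distance_distributions(vectors)
    by_state: dict[int, list[Subsequence]] = {}
    for s in subsequences:
        by_state.setdefault(s.feed_state, []).append(s)
    k = default_decimation(subsequences, int(cfg["pc_max_symbols"])) \
        if cfg["pc_mode"] == "decimate" else None
    pc = pc_distributions(
        by_state,
        mode=cfg["pc_mode"],
        k=k,
        sub_cost=float(cfg["pc_sub_cost"]),
        indel_cost=float(cfg["pc_indel_cost"]),
        normalize=bool(cfg["pc_normalize"]),
    )
    pairs = pd.concat([eu, pc], ignore_index=True)
    pairs.to_csv(out / "distances.csv", index=False)
    distance_summary(pairs).to_csv(out / "distance_summary.csv", index=False)
    manifest.timings_s["distances"] = time.perf_counter() - t0

    summary = {
        "n_videos": len(sequences),
        "n_subsequences": len(subsequences),
        "n_bouts": int(len(bouts)),
        "n_distance_pairs": int(len(pairs)),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    if cfg.get("figures"):
        t0 = time.perf_counter()
        n_figs = _write_figures(sequences, vectors, pairs, out / "figures")
        manifest.timings_s["figures"] = time.perf_counter() - t0
        log.info("wrote %d figures", n_figs)

    manifest.outputs += [
        str(out / f)
        for f in (
            "probabilities.csv", "bouts.csv", "bout_stats.csv", "strike_tally.csv",
            "transitions.csv", "distances.csv", "distance_summary.csv", "summary.json",
        )
    ]


def _write_figures(sequences, vectors_by_state, pairs: pd.DataFrame, fig_dir: Path) -> int:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir.mkdir(parents=True, exist_ok=True)
    n = 0

    # per-video behavior raster (behavior index vs frame number)
    order = list(CODES)
    for seq in sequences:
        fig, ax = plt.subplots(figsize=(8, 3))
        y = [INDEX[c] for c in seq.labels]
        colors = ["tab:red" if c in HUNTING else "0.5" if c == "GM"
                  else "k" if c == RESET else "tab:blue" for c in seq.labels]
        ax.scatter(range(len(y)), y, s=1, c=colors, marker="|")
        ax.set_yticks(range(len(order)), order)
        ax.set_xlabel("frame")
        ax.set_title(f"{seq.animal_id} feed state {seq.feed_state}")
        fig.tight_layout()
        fig.savefig(fig_dir / f"raster_{seq.animal_id}_state{seq.feed_state}.png", dpi=72)
        plt.close(fig)
        n += 1

    # feature-vector heat map: subsequence columns grouped by feed state
    cols = []
    for state in sorted(vectors_by_state):
        cols.extend(vectors_by_state[state])
    if cols:
        fig, ax = plt.subplots(figsize=(8, 6))
        ax.imshow(np.column_stack(cols), aspect="auto", cmap="viridis", vmin=0, vmax=1)
        ax.set_xlabel("subsequence (grouped by feed state)")
        ax.set_ylabel("transition cell (row-major)")
        fig.tight_layout()
        fig.savefig(fig_dir / "feature_vector_heatmap.png", dpi=90)
        plt.close(fig)
        n += 1

    # distance box plots per metric
    for metric, df in pairs.groupby("metric"):
        groups = sorted(df["group_pair"].unique())
        data = [df.loc[df["group_pair"] == g, "value"] for g in groups]
        fig, ax = plt.subplots(figsize=(max(6, len(groups) * 0.5), 4))
        ax.boxplot(data, tick_labels=groups)
        ax.plot(range(1, len(groups) + 1), [d.mean() for d in data], "k-")
        ax.set_ylabel(metric)
        ax.tick_params(axis="x", rotation=90)
        fig.tight_layout()
        fig.savefig(fig_dir / f"boxplot_{metric}.png", dpi=90)
        plt.close(fig)
        n += 1
    return n


def make_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the small worked-example fixtures used in tests and docs.

    * the 12-vs-17 symbol pair whose minimal penalty cost is 17;
    * a 4-frame capture subsequence (SM, SR, SS, RESET);
    * a multi-subsequence video in the style of the example animal's
      starved trial (several capture-terminated subsequences plus a
      trailing timeout run).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    pc_path = out / "pc_pair.json"
    pc_path.write_text(
        json.dumps({"seq_a": "555444455555", "seq_b": "88886666666666666",
                    "expected_cost": 17})
    )
    paths["pc_pair"] = pc_path

    cap = FrameSequence("fixture", 0, np.array(["SM", "SR", "SS", RESET], dtype=object))
    p = out / "capture_subsequence.csv"
    write_ethogram(cap, p)
    paths["capture_subsequence"] = p

    labels: list[str] = []
    rng = np.random.default_rng(20211208)
    for _ in range(6):
        for _ in range(int(rng.integers(3, 6))):
            b = str(rng.choice(["SM", "SR", "ST", "GM"]))
            labels.extend([b] * int(rng.integers(2, 30)))
        labels += ["SS", RESET]
    labels += ["GM"] * 40  # trailing timeout run
    video = FrameSequence("animal6_style", 0, np.array(labels, dtype=object))
    p = out / "multi_subsequence_video.csv"
    write_ethogram(video, p)
    paths["multi_subsequence_video"] = p
    return paths
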