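"""Experimental design generation for the saccade block paradigm.

A run is a sequence of short saccade mini-blocks (condition = amplitude
class x hemifield) separated by jittered fixation periods.  Block order is
balanced so that every condition follows every other condition a near-equal
number of times, which decorrelates overlapping hemodynamic responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "SIZES",
    "HEMIFIELDS",
    "DesignParams",
    "Block",
    "RunDesign",
    "ExperimentDesign",
    "make_block_sequence",
    "make_target_sequence",
    "make_run_timing",
    "make_experiment_design",
    "write_events_tsv",
    "read_events_tsv",
]

SIZES = ("small", "large", "mixed")
HEMIFIELDS = ("left", "right")
CONDITIONS: tuple[str, ...] = tuple(f"{s}_{h}" for s in SIZES for h in HEMIFIELDS)

#: placeholder eccentricity (deg) of the peripheral target for each size class
ECCENTRICITY_DEG = {"small": 5.0, "medium": 10.0, "large": 30.0}

#: nominal saccade-amplitude class labels used downstream by QC
NOMINAL_AMPLITUDE_DEG = {"small": 4.0, "medium": 10.0, "large": 30.0}


@dataclass(frozen=True)
class DesignParams:
    """Parameters of one run of the block paradigm."""

    conditions: tuple[str, ...] = CONDITIONS
    repeats_per_condition: int = 6
    block_duration_s: float = 4.0
    saccades_per_block: int = 6
    fixation_jitter_s: tuple[float, float] = (6.0, 8.0)
    lead_trail_fixation_s: float = 8.0
    target_eccentricities_deg: tuple[float, ...] = (5.0, 10.0, 30.0)
    runs_per_subject: int = 5
    tr_s: float = 2.0
    target_jitter_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats_per_condition < 1:
            raise ValueError("repeats_per_condition must be >= 1")
        if self.block_duration_s <= 0:
            raise ValueError("block_duration_s must be positive")
        lo, hi = self.fixation_jitter_s
        if lo > hi:
            raise ValueError("fixation jitter interval must satisfy low <= high")
        if self.saccades_per_block < 1:
            raise ValueError("saccades_per_block must be >= 1")

    @property
    def blocks_per_run(self) -> int:
        return len(self.conditions) * self.repeats_per_condition


@dataclass(frozen=True)
class Block:
    """One mini-block: ordinal position, condition, timing and target schedule."""

    index: int
    condition: str
    onset_s: float
    duration_s: float
    target_times_s: tuple[float, ...]  # offsets within the block
    target_positions_deg: tuple[float, ...]  # signed eccentricities

    @property
    def size_class(self) -> str:
        return self.condition.split("_")[0]

    @property
    def hemifield(self) -> str:
        return self.condition.split("_")[1]

    def nominal_amplitudes(self) -> tuple[float, ...]:
        """Unsigned amplitude expected for each scheduled saccade."""
        prev = 0.0
        amps = []
        for pos in self.target_positions_deg:
            amps.append(abs(pos - prev))
            prev = pos
        return tuple(amps)


@dataclass(frozen=True)
class RunDesign:
    run_id: int
    blocks: tuple[Block, ...]
    duration_s: float
    n_volumes: int
    tr_s: float


@dataclass(frozen=True)
class ExperimentDesign:
    subject_id: str
    runs: tuple[RunDesign, ...]
    params: DesignParams


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def make_block_sequence(params: DesignParams, seed: int) -> list[str]:
    """Return a balanced ordering of condition labels for one run.

    Every condition appears exactly ``repeats_per_condition`` times and the
    counts of ordered cross-condition transitions differ pairwise by at most
    one.  The ordering is an Eulerian path on a near-uniform transition
    multigraph, randomised by ``seed``.
    """
    conds = list(params.conditions)
    c = len(conds)
    r = params.repeats_per_condition
    if r < 1:
        raise ValueError("repeats_per_condition must be >= 1")
    rng = np.random.default_rng(seed)
    if c == 1:
        return conds * r

    n_edges = c * r - 1
    q, _ = divmod(n_edges, c * (c - 1))
    d = r - q * (c - 1)  # extra out-degree needed per node; 1 <= d <= c-1

    # Edge multiset: every ordered pair q times, plus cyclic shifts k=1..d,
    # minus one edge of the d-shift (fixes Eulerian-path start/end degrees).
    counts = np.full((c, c), q, dtype=int)
    np.fill_diagonal(counts, 0)
    for k in range(1, d + 1):
        for i in range(c):
            counts[i, (i + k) % c] += 1
    end = int(rng.integers(c))
    start = (end + d) % c
    counts[end, start] -= 1

    # Hierholzer with seed-shuffled adjacency.
    adj: list[list[int]] = []
    for i in range(c):
        nbrs = [j for j in range(c) for _ in range(counts[i, j])]
        rng.shuffle(nbrs)
        adj.append(nbrs)
    stack = [start]
    path: list[int] = []
    while stack:
        v = stack[-1]
        if adj[v]:
            stack.append(adj[v].pop())
        else:
            path.append(stack.pop())
    path.reverse()
    assert len(path) == c * r, "Eulerian path construction failed"

    relabel = rng.permutation(c)
    return [conds[relabel[v]] for v in path]


def make_target_sequence(
    condition: str, params: DesignParams, seed: int
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Target onset times (within-block) and signed positions for one block.

    Odd saccades go out to a peripheral box, even saccades return to centre,
    so the schedule alternates peripheral / 0.  The target rate is exactly
    ``saccades_per_block / block_duration`` (1.5 Hz by default); individual
    intervals are jittered uniformly by ``target_jitter_frac`` around the
    mean and renormalised.
    """
    size, hemi = condition.split("_")
    if size not in SIZES or hemi not in HEMIFIELDS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    n = params.saccades_per_block
    sign = -1.0 if hemi == "left" else 1.0

    n_out = (n + 1) // 2
    if size == "mixed":
        eccs = [ECCENTRICITY_DEG[s] for s in ("small", "medium", "large")]
        out = [eccs[i % 3] for i in range(n_out)]
        rng.shuffle(out)
    else:
        out = [ECCENTRICITY_DEG[size]] * n_out
    positions = []
    for i in range(n):
        positions.append(sign * out[i // 2] if i % 2 == 0 else 0.0)

    mean = params.block_duration_s / n
    j = params.target_jitter_frac
    intervals = rng.uniform(mean * (1 - j), mean * (1 + j), size=n)
    intervals *= params.block_duration_s / intervals.sum()
    times = np.concatenate([[0.0], np.cumsum(intervals[:-1])])
    return tuple(times), tuple(positions)


def make_run_timing(
    sequence: Sequence[str], params: DesignParams, seed: int, run_id: int = 0
) -> RunDesign:
    """Lay out a block sequence in time: lead fixation, jittered gaps, targets."""
    if len(sequence) == 0:
        raise ValueError("block sequence must be nonempty")
    ss = _as_seedseq(seed)
    gap_rng = np.random.default_rng(ss.spawn(1)[0])
    target_seeds = ss.spawn(len(sequence) + 1)[1:]

    blocks = []
    onset = params.lead_trail_fixation_s
    lo, hi = params.fixation_jitter_s
    for i, cond in enumerate(sequence):
        times, positions = make_target_sequence(cond, params, target_seeds[i])
        blocks.append(
            Block(
                index=i,
                condition=cond,
                onset_s=onset,
                duration_s=params.block_duration_s,
                target_times_s=times,
                target_positions_deg=positions,
            )
        )
        onset += params.block_duration_s
        if i < len(sequence) - 1:
            onset += float(gap_rng.uniform(lo, hi))
    duration = blocks[-1].onset_s + params.block_duration_s + params.lead_trail_fixation_s
    n_volumes = int(ceil(duration / params.tr_s))
    return RunDesign(
        run_id=run_id,
        blocks=tuple(blocks),
        duration_s=duration,
        n_volumes=n_volumes,
        tr_s=params.tr_s,
    )


def make_experiment_design(
    params: DesignParams,
    subject_id: str = "sub-01",
    seed: int | None = None,
    n_runs: int | None = None,
) -> ExperimentDesign:
    """Generate all runs for one subject, deterministically from the seed."""
    if seed is None:
        seed = params.seed
    n_runs = n_runs if n_runs is not None else params.runs_per_subject
    ss = _as_seedseq(seed)
    run_seeds = ss.spawn(2 * n_runs)
    runs = []
    for r in range(n_runs):
        seq = make_block_sequence(params, run_seeds[2 * r])
        runs.append(make_run_timing(seq, params, run_seeds[2 * r + 1], run_id=r))
    return ExperimentDesign(subject_id=subject_id, runs=tuple(runs), params=params)


def transition_counts(sequence: Sequence[str]) -> dict[tuple[str, str], int]:
    """Ordered cross-condition transition tallies (a -> b, a != b)."""
    counts: dict[tuple[str, str], int] = {}
    labels = sorted(set(sequence))
    for a in labels:
        for b in labels:
            if a != b:
                counts[(a, b)] = 0
    for a, b in zip(sequence[:-1], sequence[1:]):
        if a != b:
            counts[(a, b)] += 1
    return counts


# ---------------------------------------------------------------------------
# events I/O (tab-separated, BIDS-events dialect; one row per target onset)

EVENTS_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "hemifield",
    "target_deg",
    "block_index",
    "block_onset",
    "block_duration",
]


def events_frame(run: RunDesign) -> pd.DataFrame:
    rows = []
    for block in run.blocks:
        times = block.target_times_s
        for k, (t, pos) in enumerate(zip(times, block.target_positions_deg)):
            nxt = times[k + 1] if k + 1 < len(times) else block.duration_s
            rows.append(
                {
                    "onset": round(block.onset_s + t, 6),
                    "duration": round(nxt - t, 6),
                    "trial_type": block.condition,
                    "hemifield": block.hemifield,
                    "target_deg": pos,
                    "block_index": block.index,
                    "block_onset": round(block.onset_s, 6),
                    "block_duration": block.duration_s,
                }
            )
    return pd.DataFrame(rows, columns=EVENTS_COLUMNS)


def write_events_tsv(run: RunDesign, path: str | Path) -> None:
    events_frame(run).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> RunDesign:
    """Rebuild a RunDesign (timing + target schedule) from an events table."""
    df = pd.read_csv(path, sep="\t")
    blocks = []
    for idx, grp in df.groupby("block_index", sort=True):
        onset = float(grp["block_onset"].iloc[0])
        duration = float(grp["block_duration"].iloc[0])
        times = tuple(float(t) - onset for t in grp["onset"])
        positions = tuple(float(p) for p in grp["target_deg"])
        blocks.append(
            Block(
                index=int(idx),
                condition=str(grp["trial_type"].iloc[0]),
                onset_s=onset,
                duration_s=duration,
                target_times_s=times,
                target_positions_deg=positions,
            )
        )
    blocks.sort(key=lambda b: b.index)
    tr = 2.0
    duration_s = blocks[-1].onset_s + blocks[-1].duration_s + 8.0
    return RunDesign(
        run_id=0,
        blocks=tuple(blocks),
        duration_s=duration_s,
        n_volumes=int(ceil(duration_s / tr)),
        tr_s=tr,
    )
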