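"""Saccade detection, amplitude classification and block-level QC.

Saccades are detected as horizontal deviations larger than 2 degrees from
the current fixation position; the fixation estimate is the median of a
short (100 ms) post-saccadic window.  Detected event sequences are checked
block-by-block against the stimulus schedule (amplitude class and
direction), and subjects / runs / blocks failing the exclusion rules are
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import Block, RunDesign
from .oculo import EyeTrace

__all__ = [
    "SaccadeClassRules",
    "SaccadeEvent",
    "BlockQcResult",
    "classify_amplitude",
    "detect_saccades",
    "validate_block",
    "qc_run",
    "apply_exclusions",
]

QC_COLUMNS = ["subject", "run", "block", "valid", "reason"]


@dataclass(frozen=True)
class SaccadeClassRules:
    """Detection threshold and amplitude class boundaries (degrees).

    small is the closed interval [2, 6]; medium the open interval (6, 15);
    large is strictly greater than 20.  Amplitudes in [15, 20] fall in the
    stated gap and are labelled ``unclassified``.
    """

    detect_threshold_deg: float = 2.0
    small_range_deg: tuple[float, float] = (2.0, 6.0)
    medium_range_deg: tuple[float, float] = (6.0, 15.0)
    large_min_deg: float = 20.0
    boundary_policy: str = "unclassified"
    fixation_window_s: float = 0.1
    stability_ptp_deg: float = 1.0
    missing_fraction_max: float = 0.2
    block_slack_s: float = 0.8

    def __post_init__(self) -> None:
        if self.small_range_deg[1] > self.medium_range_deg[0]:
            raise ValueError("small and medium ranges overlap")
        if self.medium_range_deg[1] > self.large_min_deg:
            raise ValueError("medium and large ranges overlap")
        if self.detect_threshold_deg > self.small_range_deg[0]:
            raise ValueError("detect threshold must not exceed small lower bound")


@dataclass(frozen=True)
class SaccadeEvent:
    onset_s: float
    amplitude_deg: float
    direction: str  # "left" | "right"
    label: str  # "small" | "medium" | "large" | "unclassified"
    peak_velocity_deg_s: float = float("nan")
    endpoint_deg: float = float("nan")


@dataclass(frozen=True)
class BlockQcResult:
    block_index: int
    events: tuple[SaccadeEvent, ...]
    valid: bool
    reason: str  # ok | count_mismatch | class_mismatch | direction_mismatch | missing_data

    def __post_init__(self) -> None:
        assert self.valid == (self.reason == "ok")


def classify_amplitude(amplitude_deg: float, rules: SaccadeClassRules) -> str:
    """Map an unsigned amplitude to its class label."""
    if amplitude_deg <= rules.detect_threshold_deg:
        raise ValueError(
            f"amplitude {amplitude_deg} not above detection threshold "
            f"{rules.detect_threshold_deg}"
        )
    lo_s, hi_s = rules.small_range_deg
    lo_m, hi_m = rules.medium_range_deg
    if lo_s <= amplitude_deg <= hi_s:
        return "small"
    if lo_m < amplitude_deg < hi_m:
        return "medium"
    if amplitude_deg > rules.large_min_deg:
        return "large"
    return "unclassified"


def detect_saccades(trace: EyeTrace, rules: SaccadeClassRules) -> list[SaccadeEvent]:
    """Scan a trace for gaze departures > threshold from the running fixation.

    Stateful forward scan: when gaze leaves the current fixation estimate by
    more than the detection threshold, advance until a 100 ms window is
    stable again; the new fixation is that window's median and the event
    amplitude is the fixation-to-fixation displacement.  NaN gaps reset the
    fixation estimate.  An all-missing trace yields an empty list.
    """
    x = np.asarray(trace.gaze_x_deg, dtype=float)
    t = np.asarray(trace.time_s, dtype=float)
    n = x.size
    if n == 0 or np.all(np.isnan(x)):
        return []
    hz = trace.sampling_hz
    w = max(2, int(round(rules.fixation_window_s * hz)))
    thresh = rules.detect_threshold_deg

    # trailing-window medians, precomputed (NaN where the window is incomplete)
    roll_med = pd.Series(x).rolling(w, min_periods=w).median().to_numpy()

    events: list[SaccadeEvent] = []

    def stable(i: int) -> bool:
        win = x[i : i + w]
        return win.size == w and not np.any(np.isnan(win)) and np.ptp(win) < rules.stability_ptp_deg

    def next_fixation(i: int) -> tuple[float, int]:
        """First stable window at or after i -> (median, index past window)."""
        j = i
        while j + w <= n:
            if stable(j):
                return float(np.median(x[j : j + w])), j + w
            j += 1
        # tail never stabilises: use whatever finite samples remain
        tail = x[i:]
        tail = tail[~np.isnan(tail)]
        med = float(np.median(tail)) if tail.size else np.nan
        return med, n

    fix, i = next_fixation(0)
    while i < n:
        if np.isnan(x[i]):
            j = i
            while j < n and np.isnan(x[j]):
                j += 1
            fix, i = next_fixation(j)
            continue
        if np.isnan(fix):
            fix, i = next_fixation(i)
            continue
        if abs(x[i] - fix) > thresh:
            onset_idx = i
            new_fix, j = next_fixation(i)
            if np.isnan(new_fix):
                break
            amp = abs(new_fix - fix)
            if amp > thresh:
                seg = x[max(onset_idx - 1, 0) : j]
                vel = np.abs(np.diff(seg)) * hz
                vel = vel[~np.isnan(vel)]
                events.append(
                    SaccadeEvent(
                        onset_s=float(t[onset_idx]),
                        amplitude_deg=amp,
                        direction="right" if new_fix > fix else "left",
                        label=classify_amplitude(amp, rules),
                        peak_velocity_deg_s=float(vel.max()) if vel.size else np.nan,
                        endpoint_deg=new_fix,
                    )
                )
            fix = new_fix
            i = j
        else:
            # track sub-threshold drift: running median over the last window
            med = roll_med[i]
            if not np.isnan(med) and abs(med - fix) <= thresh:
                fix = med
            i += 1
    return events


def _expected_schedule(block: Block, rules: SaccadeClassRules) -> list[tuple[str, str]]:
    """(class, direction) expected for each scheduled saccade of the block."""
    out = []
    prev = 0.0
    for pos in block.target_positions_deg:
        amp = abs(pos - prev)
        out.append((classify_amplitude(amp, rules), "right" if pos > prev else "left"))
        prev = pos
    return out


def validate_block(
    events: list[SaccadeEvent],
    block: Block,
    rules: SaccadeClassRules,
    missing: bool = False,
) -> BlockQcResult:
    """Check a block's detected events against its stimulus schedule."""
    ev = tuple(sorted(events, key=lambda e: e.onset_s))
    if missing:
        return BlockQcResult(block.index, ev, False, "missing_data")
    expected = _expected_schedule(block, rules)
    if len(ev) != len(expected):
        return BlockQcResult(block.index, ev, False, "count_mismatch")
    for e, (cls, _) in zip(ev, expected):
        if e.label != cls:
            return BlockQcResult(block.index, ev, False, "class_mismatch")
    for e, (_, direction) in zip(ev, expected):
        if e.direction != direction:
            return BlockQcResult(block.index, ev, False, "direction_mismatch")
    return BlockQcResult(block.index, ev, True, "ok")


def qc_run(
    trace: EyeTrace,
    run: RunDesign,
    rules: SaccadeClassRules | None = None,
) -> list[BlockQcResult]:
    """Detect saccades on a full-run trace and validate every block."""
    rules = rules or SaccadeClassRules()
    events = detect_saccades(trace, rules)
    t = np.asarray(trace.time_s)
    x = np.asarray(trace.gaze_x_deg, dtype=float)
    results = []
    for block in run.blocks:
        lo = block.onset_s
        hi = block.onset_s + block.duration_s + rules.block_slack_s
        win = (t >= lo) & (t < hi)
        frac_missing = float(np.mean(np.isnan(x[win]))) if win.any() else 1.0
        blk_events = [e for e in events if lo <= e.onset_s < hi]
        results.append(
            validate_block(
                blk_events, block, rules, missing=frac_missing > rules.missing_fraction_max
            )
        )
    return results


def qc_table(
    results: dict[tuple[str, int], list[BlockQcResult]],
) -> pd.DataFrame:
    """Flatten per-(subject, run) QC results into a tidy table."""
    rows = [
        {"subject": subj, "run": run, "block": r.block_index, "valid": r.valid, "reason": r.reason}
        for (subj, run), res in results.items()
        for r in res
    ]
    return pd.DataFrame(rows, columns=QC_COLUMNS)


def apply_exclusions(qc: pd.DataFrame, threshold: float = 0.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the block / run / subject exclusion rules to a QC table.

    Drops invalid blocks, then any run with more than ``threshold`` of its
    blocks invalid, then any subject with more than ``threshold`` of all
    their blocks invalid.  Returns (retained table, exclusion report).
    """
    qc = qc.copy()
    report_rows = []

    bad_subjects = []
    for subj, grp in qc.groupby("subject"):
        frac = 1.0 - grp["valid"].mean()
        if frac > threshold:
            bad_subjects.append(subj)
            report_rows.append(
                {
                    "level": "subject",
                    "subject": subj,
                    "run": "",
                    "block": "",
                    "reason": f"{frac:.0%} of blocks invalid",
                }
            )
    kept = qc[~qc["subject"].isin(bad_subjects)]

    bad_runs = []
    for (subj, run), grp in kept.groupby(["subject", "run"]):
        frac = 1.0 - grp["valid"].mean()
        if frac > threshold:
            bad_runs.append((subj, run))
            report_rows.append(
                {
                    "level": "run",
                    "subject": subj,
                    "run": run,
                    "block": "",
                    "reason": f"{frac:.0%} of blocks invalid",
                }
            )
    if bad_runs:
        mask = kept.apply(lambda r: (r["subject"], r["run"]) in bad_runs, axis=1)
        kept = kept[~mask]

    for _, row in kept[~kept["valid"]].iterrows():
        report_rows.append(
            {
                "level": "block",
                "subject": row["subject"],
                "run": row["run"],
                "block": row["block"],
                "reason": row["reason"],
            }
        )
    kept = kept[kept["valid"]].reset_index(drop=True)
    report = pd.DataFrame(report_rows, columns=["level", "subject", "run", "block", "reason"])
    return kept, report


def write_qc_tsv(qc: pd.DataFrame, path: str | Path) -> None:
    qc.to_csv(path, sep="\t", index=False)
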