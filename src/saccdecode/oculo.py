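"""Simulation of 60 Hz horizontal eye-position traces for a run design.

Saccade kinematics follow the main-sequence law (saturating amplitude /
peak-velocity relation); the position profile of each saccade is a raised
cosine whose duration is set so the profile's peak velocity matches the law.
Endpoint scatter grows linearly with amplitude, which reproduces the
behavioural signature that large saccades are both faster and more variable
than small ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import RunDesign

__all__ = [
    "OculoParams",
    "BadBehavior",
    "EyeTrace",
    "peak_velocity",
    "simulate_trace",
    "write_trace_tsv",
    "read_trace_tsv",
]


@dataclass(frozen=True)
class OculoParams:
    """Kinematic and noise parameters of the simulated oculomotor plant.

    ``endpoint_sd_slope`` is the landing-point SD expressed as a fraction of
    saccade amplitude.  The default (0.02) keeps clean traces inside the QC
    amplitude classes with very high probability while preserving the
    amplitude-dependent variability effect.
    """

    sampling_hz: float = 60.0
    latency_mean_s: float = 0.18
    latency_sd_s: float = 0.03
    latency_min_s: float = 0.08
    vmax_deg_s: float = 500.0
    a0_deg: float = 14.0
    endpoint_sd_slope: float = 0.02
    noise_sd_deg: float = 0.15
    blink_rate_hz: float = 0.0
    blink_duration_s: float = 0.2
    refixation_threshold_deg: float = 0.3
    corrective_threshold_deg: float = 0.5
    endpoint_max_sigmas: float = 2.0  # truncation of the landing-error draw
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if self.vmax_deg_s <= 0 or self.a0_deg <= 0:
            raise ValueError("main-sequence parameters must be positive")
        for name in ("latency_sd_s", "endpoint_sd_slope", "noise_sd_deg", "blink_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class BadBehavior:
    """Per-block rates of injected task violations, for exercising QC.

    ``drop_rate``: block keeps only its first saccade (participant gives up);
    ``blink_rate``: the whole block window is missing data (eyes closed);
    ``wrong_hemifield_rate``: all targets of the block are mirrored.
    """

    drop_rate: float = 0.0
    blink_rate: float = 0.0
    wrong_hemifield_rate: float = 0.0

    def any(self) -> bool:
        return (self.drop_rate + self.blink_rate + self.wrong_hemifield_rate) > 0


@dataclass
class EyeTrace:
    time_s: np.ndarray
    gaze_x_deg: np.ndarray  # NaN marks missing samples (blinks / eyes closed)
    run_id: int = 0
    subject_id: str = "sub-01"

    @property
    def sampling_hz(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])


def peak_velocity(amplitude_deg: float, params: OculoParams) -> float:
    """Main-sequence peak velocity: V = vmax * (1 - exp(-A / a0))."""
    if amplitude_deg < 0:
        raise ValueError("amplitude must be >= 0")
    return params.vmax_deg_s * (1.0 - np.exp(-amplitude_deg / params.a0_deg))


def _landing(target: float, amplitude: float, params: OculoParams, rng) -> float:
    """Target plus truncated Gaussian endpoint error (SD grows with amplitude)."""
    sd = params.endpoint_sd_slope * amplitude
    if sd == 0:
        return target
    err = rng.normal(0.0, sd)
    lim = params.endpoint_max_sigmas * sd
    return target + float(np.clip(err, -lim, lim))


def _saccade_events(
    run: RunDesign,
    params: OculoParams,
    rng: np.random.Generator,
    bad: BadBehavior,
):
    """Plan the list of saccades (onset, duration, start, end) and bad blocks."""
    dt = 1.0 / params.sampling_hz
    events = []
    blink_blocks = []
    bad_blocks: dict[int, str] = {}
    pos = 0.0
    prev_end = 0.0
    for block in run.blocks:
        positions = list(block.target_positions_deg)
        mode = None
        if bad.any():
            u = rng.uniform()
            if u < bad.drop_rate:
                mode = "drop"
            elif u < bad.drop_rate + bad.blink_rate:
                mode = "blink"
            elif u < bad.drop_rate + bad.blink_rate + bad.wrong_hemifield_rate:
                mode = "wrong"
        if mode == "wrong":
            positions = [-p for p in positions]
        if mode is not None:
            bad_blocks[block.index] = mode
        if mode == "blink":
            blink_blocks.append((block.onset_s - 0.1, block.onset_s + block.duration_s + 0.5))
            continue
        for k, (t_rel, target) in enumerate(zip(block.target_times_s, positions)):
            if mode == "drop" and k >= 1:
                break
            latency = max(
                params.latency_min_s,
                rng.normal(params.latency_mean_s, params.latency_sd_s),
            )
            onset = max(block.onset_s + t_rel + latency, prev_end + dt)
            amp_planned = abs(target - pos)
            if amp_planned < 1e-9:
                continue
            landing = _landing(target, amp_planned, params, rng)
            amp = abs(landing - pos)
            vp = peak_velocity(amp, params)
            dur = amp * np.pi / (2.0 * vp) if vp > 0 else dt
            events.append((onset, dur, pos, landing))
            pos = landing
            prev_end = onset + dur
            # inaccurate primaries are followed by a small corrective saccade
            if (
                params.corrective_threshold_deg > 0
                and abs(landing - target) > params.corrective_threshold_deg
            ):
                c_onset = prev_end + rng.uniform(0.12, 0.2)
                c_amp = abs(landing - target)
                c_landing = _landing(target, c_amp, params, rng)
                c_vp = peak_velocity(c_amp, params)
                c_dur = c_amp * np.pi / (2.0 * c_vp) if c_vp > 0 else dt
                events.append((c_onset, c_dur, pos, c_landing))
                pos = c_landing
                prev_end = c_onset + c_dur
        # between blocks the central box stays lit: correct residual offset
        if (
            params.refixation_threshold_deg > 0
            and abs(pos) > params.refixation_threshold_deg
        ):
            onset = max(
                block.onset_s + block.duration_s + rng.uniform(1.0, 2.0), prev_end + dt
            )
            amp = abs(pos)
            landing = _landing(0.0, amp, params, rng)
            vp = peak_velocity(amp, params)
            dur = amp * np.pi / (2.0 * vp) if vp > 0 else dt
            events.append((onset, dur, pos, landing))
            pos = landing
            prev_end = onset + dur
    return events, blink_blocks, bad_blocks


def simulate_trace(
    run: RunDesign,
    params: OculoParams,
    seed: int,
    bad: BadBehavior | None = None,
    run_id: int | None = None,
    subject_id: str = "sub-01",
) -> EyeTrace:
    """Simulate the horizontal gaze trace executing ``run``'s target schedule.

    Returns a uniformly sampled trace of length round(duration * rate).  The
    result also carries ``trace.bad_blocks`` (dict block index -> injected
    violation) when a :class:`BadBehavior` spec is supplied.
    """
    rng = np.random.default_rng(seed)
    bad = bad or BadBehavior()
    n = int(round(run.duration_s * params.sampling_hz))
    t = np.arange(n) / params.sampling_hz
    x = np.zeros(n)

    events, blink_windows, bad_blocks = _saccade_events(run, params, rng, bad)
    pos = 0.0
    cursor = 0
    for onset, dur, x0, x1 in events:
        i0 = int(np.searchsorted(t, onset))
        i1 = int(np.searchsorted(t, onset + dur))
        x[cursor:i0] = pos
        if i1 > i0:
            phase = (t[i0:i1] - onset) / dur
            x[i0:i1] = x0 + (x1 - x0) * 0.5 * (1.0 - np.cos(np.pi * phase))
        pos = x1
        cursor = i1
    x[cursor:] = pos

    if params.noise_sd_deg > 0:
        x = x + rng.normal(0.0, params.noise_sd_deg, size=n)

    if params.blink_rate_hz > 0:
        n_blinks = rng.poisson(params.blink_rate_hz * run.duration_s)
        for start in rng.uniform(0.0, run.duration_s, size=n_blinks):
            blink_windows.append((start, start + params.blink_duration_s))
    for lo, hi in blink_windows:
        x[(t >= lo) & (t < hi)] = np.nan

    trace = EyeTrace(
        time_s=t,
        gaze_x_deg=x,
        run_id=run.run_id if run_id is None else run_id,
        subject_id=subject_id,
    )
    trace.bad_blocks = bad_blocks
    return trace


def write_trace_tsv(trace: EyeTrace, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": trace.time_s, "gaze_x_deg": trace.gaze_x_deg})
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_trace_tsv(path: str | Path, run_id: int = 0, subject_id: str = "sub-01") -> EyeTrace:
    df = pd.read_csv(path, sep="\t")
    return EyeTrace(
        time_s=df["time_s"].to_numpy(float),
        gaze_x_deg=df["gaze_x_deg"].to_numpy(float),
        run_id=run_id,
        subject_id=subject_id,
    )
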