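"""BOLD time-series simulation with known multivoxel ground truth.

Each ROI can be declared informative: blocks of a given amplitude class then
evoke, on top of a common all-saccades response, a class-specific spatial
pattern over a subset of that ROI's voxels.  Mixed blocks combine the class
patterns according to a configurable rule.  Noise is AR(1) plus a run
baseline and linear drift.  Everything is deterministic given the seed and
the injected parameters are returned so downstream recovery can be checked
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.signal import lfilter

from .atlas import GridSpec, RoiMask, ROI_LABELS
from .design import ExperimentDesign, RunDesign

__all__ = [
    "HrfParams",
    "RoiEffect",
    "EffectSpec",
    "NoiseParams",
    "BoldRun",
    "GroundTruth",
    "hrf",
    "block_regressors",
    "simulate_subject",
]

SIZE_CLASSES = ("small", "medium", "large")


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma hemodynamic response, scaled to unit peak."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    peak_undershoot_ratio: float = 6.0
    length_s: float = 32.0
    dt_s: float = 0.1


def hrf(params: HrfParams | None = None) -> np.ndarray:
    """Sampled double-gamma kernel: difference of two gamma densities, peak 1."""
    p = params or HrfParams()
    t = np.arange(0.0, p.length_s, p.dt_s)
    peak = stats.gamma.pdf(t, p.peak_delay_s / p.peak_dispersion_s, scale=p.peak_dispersion_s)
    under = stats.gamma.pdf(
        t, p.undershoot_delay_s / p.undershoot_dispersion_s, scale=p.undershoot_dispersion_s
    )
    kernel = peak - under / p.peak_undershoot_ratio
    return kernel / kernel.max()


def block_regressors(
    run: RunDesign,
    n_volumes: int | None = None,
    hrf_params: HrfParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """HRF-convolved boxcar (and its temporal derivative) per block.

    Convolution is done on the fine HRF grid then sampled at volume onsets.
    Returns arrays of shape (n_volumes, n_blocks).
    """
    p = hrf_params or HrfParams()
    n_vol = n_volumes if n_volumes is not None else run.n_volumes
    kernel = hrf(p)
    dt = p.dt_s
    n_fine = int(np.ceil(n_vol * run.tr_s / dt)) + kernel.size
    vol_idx = np.round(np.arange(n_vol) * run.tr_s / dt).astype(int)

    main = np.zeros((n_vol, len(run.blocks)))
    deriv = np.zeros_like(main)
    for b, block in enumerate(run.blocks):
        box = np.zeros(n_fine)
        i0 = int(round(block.onset_s / dt))
        i1 = int(round((block.onset_s + block.duration_s) / dt))
        box[i0:i1] = 1.0
        conv = np.convolve(box, kernel)[:n_fine] * dt
        main[:, b] = conv[vol_idx]
        deriv[:, b] = np.gradient(conv, dt)[vol_idx]
    return main, deriv


@dataclass(frozen=True)
class RoiEffect:
    """Signal injected into one ROI."""

    informative: bool = False
    pattern_effect: float = 0.0  # amplitude of the class-specific pattern
    common_effect: float = 1.0  # all-saccades activation amplitude
    informative_fraction: float = 0.5  # share of voxels carrying the pattern
    adaptation_gain: float = 0.0  # attenuation of same-size (non-mixed) blocks

    def __post_init__(self) -> None:
        if self.pattern_effect < 0 or self.common_effect < 0:
            raise ValueError("effect amplitudes must be >= 0")
        if not 0.0 <= self.informative_fraction <= 1.0:
            raise ValueError("informative_fraction must be in [0, 1]")


@dataclass(frozen=True)
class EffectSpec:
    rois: dict[str, RoiEffect] = field(default_factory=dict)
    mixed_rule: str = "mean"  # mixed blocks evoke the mean of the class patterns
    subject_gain_sd: float = 0.0  # between-subject SD of a multiplicative gain

    def effect_for(self, label: str) -> RoiEffect:
        return self.rois.get(label, RoiEffect())

    @classmethod
    def null(cls) -> "EffectSpec":
        """No condition information anywhere (pattern_effect = 0)."""
        return cls(rois={label: RoiEffect(common_effect=1.0) for label in ROI_LABELS})

    @classmethod
    def paper_like(
        cls,
        parietal_effect: float = 0.4,
        fef_effect: float = 0.25,
        subject_gain_sd: float = 0.25,
    ) -> "EffectSpec":
        """Parietal and FEF carry amplitude information; SEF and Prec do not."""
        rois = {}
        for label in ROI_LABELS:
            if "Par" in label:
                rois[label] = RoiEffect(informative=True, pattern_effect=parietal_effect)
            elif "FEF" in label:
                rois[label] = RoiEffect(informative=True, pattern_effect=fef_effect)
            else:
                rois[label] = RoiEffect()
        return cls(rois=rois, subject_gain_sd=subject_gain_sd)


@dataclass(frozen=True)
class NoiseParams:
    sd: float = 1.0
    ar1_rho: float = 0.3
    baseline: float = 100.0
    baseline_run_sd: float = 1.0  # run-to-run baseline jitter
    drift_sd: float = 0.5  # per-voxel total drift amplitude over a run

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")


@dataclass
class BoldRun:
    """Voxel x volume data restricted to the atlas voxels (plus background)."""

    data: np.ndarray  # (n_voxels, n_volumes)
    voxel_indices: np.ndarray  # linear grid indices, canonical order
    grid: GridSpec
    run_id: int
    subject_id: str
    tr_s: float

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class GroundTruth:
    """Everything needed to reconstruct the noiseless signal exactly."""

    voxel_indices: np.ndarray
    patterns: dict[str, dict[str, np.ndarray]]  # roi -> class -> full-length vector
    informative_voxels: dict[str, np.ndarray]  # roi -> indices into voxel vector
    subject_gain: float
    amplitudes: list[np.ndarray]  # per run: (n_blocks, n_voxels)
    effects: EffectSpec

    def noiseless_run(self, run: RunDesign, hrf_params: HrfParams | None = None) -> np.ndarray:
        main, _ = block_regressors(run, hrf_params=hrf_params)
        return (main @ self.amplitudes[run.run_id]).T


def _class_weights(condition: str, mixed_rule: str) -> dict[str, float]:
    size = condition.split("_")[0]
    if size in ("small", "large"):
        return {size: 1.0}
    if size == "mixed":
        if mixed_rule == "mean":
            return {c: 1.0 / 3.0 for c in SIZE_CLASSES}
        if mixed_rule == "sum":
            return {c: 1.0 for c in SIZE_CLASSES}
        raise ValueError(f"unknown mixed_rule {mixed_rule!r}")
    raise ValueError(f"unknown condition {condition!r}")


def simulate_subject(
    design: ExperimentDesign,
    masks: dict[str, RoiMask],
    effects: EffectSpec | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
    hrf_params: HrfParams | None = None,
    n_background_voxels: int = 0,
) -> tuple[list[BoldRun], GroundTruth]:
    """Simulate all runs of one subject on the atlas voxels.

    Per ROI and amplitude class, a unit-norm pattern vector is drawn once per
    subject over the informative fraction of voxels.  Each block contributes
    ``gain * (common + pattern_effect * pattern[class])`` times its
    HRF-convolved boxcar; noise and slow nuisance terms are added on top.
    """
    effects = effects or EffectSpec.null()
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)

    labels = [label for label in ROI_LABELS if label in masks]
    grid = masks[labels[0]].grid
    roi_index = np.concatenate([masks[label].indices for label in labels])
    if n_background_voxels > 0:
        free = np.setdiff1d(np.arange(grid.n_voxels), roi_index)
        bg = rng.choice(free, size=min(n_background_voxels, free.size), replace=False)
        voxel_indices = np.concatenate([roi_index, np.sort(bg)])
    else:
        voxel_indices = roi_index
    n_vox = voxel_indices.size

    # slices of the voxel vector covered by each ROI
    offsets = {}
    pos = 0
    for label in labels:
        size = masks[label].size
        offsets[label] = slice(pos, pos + size)
        pos += size

    gain = 1.0
    if effects.subject_gain_sd > 0:
        gain = max(0.0, 1.0 + rng.normal(0.0, effects.subject_gain_sd))

    patterns: dict[str, dict[str, np.ndarray]] = {}
    informative: dict[str, np.ndarray] = {}
    for label in labels:
        eff = effects.effect_for(label)
        size = masks[label].size
        n_inf = max(1, int(round(eff.informative_fraction * size))) if eff.informative else 0
        idx = np.sort(rng.choice(size, size=n_inf, replace=False)) if n_inf else np.array([], int)
        informative[label] = idx
        patterns[label] = {}
        for cls in SIZE_CLASSES:
            vec = np.zeros(size)
            if eff.informative and n_inf:
                raw = rng.normal(size=n_inf)
                vec[idx] = raw / np.linalg.norm(raw)
            patterns[label][cls] = vec

    runs_out: list[BoldRun] = []
    amplitudes: list[np.ndarray] = []
    for run in design.runs:
        amp = np.zeros((len(run.blocks), n_vox))
        for b, block in enumerate(run.blocks):
            weights = _class_weights(block.condition, effects.mixed_rule)
            for label in labels:
                eff = effects.effect_for(label)
                vec = np.full(masks[label].size, eff.common_effect)
                for cls, w in weights.items():
                    vec = vec + eff.pattern_effect * w * patterns[label][cls]
                if eff.adaptation_gain > 0 and block.size_class != "mixed":
                    vec = vec * (1.0 - eff.adaptation_gain)
                amp[b, offsets[label]] = gain * vec
        amplitudes.append(amp)

        main, _ = block_regressors(run, hrf_params=hrf_params)
        signal = (main @ amp).T  # (n_vox, n_vol)

        n_vol = run.n_volumes
        data = signal.copy()
        if noise.sd > 0:
            white = rng.normal(0.0, noise.sd * np.sqrt(1 - noise.ar1_rho**2), (n_vox, n_vol))
            data += lfilter([1.0], [1.0, -noise.ar1_rho], white, axis=1)
        base = noise.baseline + (
            rng.normal(0.0, noise.baseline_run_sd) if noise.baseline_run_sd > 0 else 0.0
        )
        data += base
        if noise.drift_sd > 0:
            slope = rng.normal(0.0, noise.drift_sd, size=n_vox)
            data += slope[:, None] * np.linspace(-0.5, 0.5, n_vol)[None, :]
        runs_out.append(
            BoldRun(
                data=data,
                voxel_indices=voxel_indices,
                grid=grid,
                run_id=run.run_id,
                subject_id=design.subject_id,
                tr_s=run.tr_s,
            )
        )

    truth = GroundTruth(
        voxel_indices=voxel_indices,
        patterns=patterns,
        informative_voxels=informative,
        subject_gain=gain,
        amplitudes=amplitudes,
        effects=effects,
    )
    return runs_out, truth
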