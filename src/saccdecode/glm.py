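"""First-level modelling: high-pass filtering, design matrices, OLS, contrasts.

Per-block mode fits one regressor per mini-block (beta-series for decoding);
per-condition mode fits one regressor per block type (univariate branch).
Estimation is ordinary least squares; the same high-pass filter is applied
to data and design so exact signals are recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import linalg, ndimage

from .atlas import GridSpec
from .bold import BoldRun, HrfParams, block_regressors
from .design import RunDesign

__all__ = [
    "GlmConfig",
    "DesignMatrix",
    "GlmFit",
    "CONDITION_ORDER",
    "CONTRAST_LARGE_MINUS_SMALL",
    "CONTRAST_ADAPTATION",
    "gaussian_highpass",
    "build_design_matrix",
    "fit_glm",
    "fit_run",
    "compute_contrast",
    "smooth_volume",
]

CONDITION_ORDER = (
    "large_left",
    "large_right",
    "small_left",
    "small_right",
    "mixed_left",
    "mixed_right",
)

#: large - small, collapsed over hemifields
CONTRAST_LARGE_MINUS_SMALL = {
    "large_left": 0.5,
    "large_right": 0.5,
    "small_left": -0.5,
    "small_right": -0.5,
    "mixed_left": 0.0,
    "mixed_right": 0.0,
}

#: mixed - same-size (small and large grouped together)
CONTRAST_ADAPTATION = {
    "large_left": -0.25,
    "large_right": -0.25,
    "small_left": -0.25,
    "small_right": -0.25,
    "mixed_left": 0.5,
    "mixed_right": 0.5,
}

FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass(frozen=True)
class GlmConfig:
    highpass_sigma_s: float = 50.0
    include_temporal_derivatives: bool = True
    n_motion_regressors: int = 6
    mode: str = "per_block"  # or "per_condition"
    smoothing_fwhm_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.highpass_sigma_s <= 0:
            raise ValueError("highpass_sigma_s must be positive")
        if self.mode not in ("per_block", "per_condition"):
            raise ValueError(f"unknown GLM mode {self.mode!r}")


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_volumes, n_regressors)
    labels: list[str]
    main_labels: list[str]  # labels of the block / condition regressors

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.labels)


@dataclass
class GlmFit:
    betas: np.ndarray  # (n_regressors, n_voxels); zero rows for dropped columns
    labels: list[str]
    residual_variance: np.ndarray  # (n_voxels,)
    dof: int

    def beta(self, label: str) -> np.ndarray:
        return self.betas[self.labels.index(label)]


@lru_cache(maxsize=8)
def _highpass_fit_matrix(n: int, sigma_s: float, tr: float) -> np.ndarray:
    """Rows evaluate, at each time point, a local Gaussian-weighted line fit."""
    t = np.arange(n) * tr
    H = np.empty((n, n))
    for k in range(n):
        dt = t - t[k]
        w = np.exp(-0.5 * (dt / sigma_s) ** 2)
        s0 = w.sum()
        s1 = (w * dt).sum()
        s2 = (w * dt * dt).sum()
        H[k] = (s2 * w - s1 * w * dt) / (s0 * s2 - s1 * s1)
    return H


def gaussian_highpass(series: np.ndarray, sigma_s: float, tr: float) -> np.ndarray:
    """Remove slow trends with a Gaussian-weighted running-line fit.

    At every time point a straight line is fitted with Gaussian weights (SD =
    sigma) centred there and its local value subtracted; the series mean is
    added back.  Accepts 1-D (time,) or 2-D (time, voxels) input.
    """
    y = np.asarray(series, dtype=float)
    if y.shape[0] < 3:
        raise ValueError("series must have length >= 3")
    H = _highpass_fit_matrix(y.shape[0], float(sigma_s), float(tr))
    return y - H @ y + y.mean(axis=0, keepdims=(y.ndim > 1))


def build_design_matrix(
    run: RunDesign,
    config: GlmConfig | None = None,
    n_volumes: int | None = None,
    hrf_params: HrfParams | None = None,
    motion: np.ndarray | None = None,
) -> DesignMatrix:
    """HRF-convolved design matrix for one run.

    per_block: one column per block (+ derivative each) + motion + intercept.
    per_condition: one column per block type (+ derivative each) + motion +
    intercept, block types ordered as ``CONDITION_ORDER``.
    Motion defaults to zero-filled columns (no motion simulated); real
    6-column tables can be passed instead.
    """
    config = config or GlmConfig()
    n_vol = n_volumes if n_volumes is not None else run.n_volumes

    onsets = [b.onset_s for b in run.blocks]
    offsets = [b.onset_s + b.duration_s for b in run.blocks]
    order = np.argsort(onsets)
    for a, b in zip(order[:-1], order[1:]):
        if onsets[b] < offsets[a] - 1e-9:
            raise ValueError(f"blocks {a} and {b} overlap in time")

    main, deriv = block_regressors(run, n_volumes=n_vol, hrf_params=hrf_params)

    if config.mode == "per_block":
        cols = [main[:, b] for b in range(main.shape[1])]
        dcols = [deriv[:, b] for b in range(deriv.shape[1])]
        main_labels = [f"block_{b:02d}" for b in range(main.shape[1])]
    else:
        conds = [c for c in CONDITION_ORDER if any(b.condition == c for b in run.blocks)]
        cols, dcols, main_labels = [], [], []
        for cond in conds:
            sel = [b for b, blk in enumerate(run.blocks) if blk.condition == cond]
            cols.append(main[:, sel].sum(axis=1))
            dcols.append(deriv[:, sel].sum(axis=1))
            main_labels.append(cond)

    columns = list(cols)
    labels = list(main_labels)
    if config.include_temporal_derivatives:
        columns += dcols
        labels += [f"{lbl}_deriv" for lbl in main_labels]
    if config.n_motion_regressors > 0:
        if motion is None:
            motion = np.zeros((n_vol, config.n_motion_regressors))
        if motion.shape != (n_vol, config.n_motion_regressors):
            raise ValueError("motion regressor table has the wrong shape")
        columns += [motion[:, j] for j in range(motion.shape[1])]
        labels += [f"motion_{j + 1}" for j in range(motion.shape[1])]
    columns.append(np.ones(n_vol))
    labels.append("intercept")
    return DesignMatrix(np.column_stack(columns), labels, main_labels)


def fit_glm(data: np.ndarray, design: DesignMatrix) -> GlmFit:
    """Voxel-wise ordinary least squares.

    ``data`` is (n_volumes, n_voxels).  All-zero columns (e.g. placeholder
    motion regressors) are inert and get beta 0; any other rank deficiency
    raises with the offending column labels.
    """
    Y = np.asarray(data, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError(f"data has {Y.shape[0]} volumes but design has {X.shape[0]} rows")

    norms = np.linalg.norm(X, axis=0)
    active = norms > 0
    Xa = X[:, active]
    rank = np.linalg.matrix_rank(Xa)
    if rank < Xa.shape[1]:
        _, R, piv = linalg.qr(Xa, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = piv[diag < diag.max() * 1e-10]
        active_labels = [lbl for lbl, a in zip(design.labels, active) if a]
        names = [active_labels[j] for j in sorted(bad)]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {names}")

    beta_a, _, _, _ = np.linalg.lstsq(Xa, Y, rcond=None)
    betas = np.zeros((X.shape[1], Y.shape[1]))
    betas[active] = beta_a
    resid = Y - Xa @ beta_a
    dof = Y.shape[0] - Xa.shape[1]
    resvar = (resid**2).sum(axis=0) / max(dof, 1)
    return GlmFit(betas=betas, labels=list(design.labels), residual_variance=resvar, dof=dof)


def fit_run(
    bold: BoldRun,
    run: RunDesign,
    config: GlmConfig | None = None,
    hrf_params: HrfParams | None = None,
    motion: np.ndarray | None = None,
) -> GlmFit:
    """High-pass filter data and design identically, then fit OLS."""
    config = config or GlmConfig()
    design = build_design_matrix(
        run, config, n_volumes=bold.n_volumes, hrf_params=hrf_params, motion=motion
    )
    Y = gaussian_highpass(bold.data.T, config.highpass_sigma_s, bold.tr_s)
    Xf = design.matrix.copy()
    nonzero = np.linalg.norm(Xf, axis=0) > 0
    Xf[:, nonzero] = gaussian_highpass(
        Xf[:, nonzero], config.highpass_sigma_s, bold.tr_s
    )
    return fit_glm(Y, DesignMatrix(Xf, design.labels, design.main_labels))


def compute_contrast(
    betas: dict[str, np.ndarray], weights: dict[str, float]
) -> np.ndarray:
    """Per-voxel weighted sum of condition betas."""
    missing = set(weights) - set(betas)
    if missing:
        raise ValueError(f"weights refer to conditions without betas: {sorted(missing)}")
    conds = sorted(weights)
    out = np.zeros_like(np.asarray(betas[conds[0]], dtype=float))
    for cond in conds:
        out = out + weights[cond] * np.asarray(betas[cond], dtype=float)
    return out


def smooth_volume(volume: np.ndarray, fwhm_mm: float, grid: GridSpec) -> np.ndarray:
    """Separable 3-D Gaussian smoothing; ``fwhm_mm = 0`` is the identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return np.asarray(volume, dtype=float).copy()
    sigma_vox = [fwhm_mm / FWHM_TO_SD / vs for vs in grid.voxel_size_mm]
    return ndimage.gaussian_filter(
        np.asarray(volume, dtype=float), sigma=sigma_vox, mode="reflect", truncate=6.0
    )
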