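"""Group-level statistics: t-tests against chance, sign-flip max-statistic
permutation across ROIs (family-wise error control), paired behavioural
tests and within-ROI voxelwise permutation contrasts.

Sign flips are shared across ROIs (or voxels) within a subject, which
preserves the dependence structure required for valid max-statistic
family-wise correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import RoiMask

__all__ = [
    "InferenceConfig",
    "TResult",
    "PermutationResult",
    "VoxelContrastResult",
    "one_sample_t",
    "paired_t",
    "signflip_maxt",
    "group_voxel_contrast",
]


@dataclass(frozen=True)
class InferenceConfig:
    alpha: float = 0.05
    n_permutations: int = 10000
    chance_pct: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass(frozen=True)
class TResult:
    t: float
    df: int
    degenerate: bool = False  # zero-variance input (t is +/-inf or 0 by convention)


def one_sample_t(values: np.ndarray, mu0: float = 0.0) -> TResult:
    """Student's one-sample t: t = mean(x - mu0) / (sd / sqrt(n)), df = n - 1."""
    x = np.asarray(values, dtype=float) - mu0
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values")
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        t = 0.0 if mean == 0 else float(np.sign(mean)) * np.inf
        return TResult(t=t, df=n - 1, degenerate=True)
    return TResult(t=float(mean / (sd / np.sqrt(n))), df=n - 1)


def paired_t(values_a: np.ndarray, values_b: np.ndarray) -> TResult:
    """Paired t-test: one-sample t on the per-subject differences vs 0."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0)


def _t_rows(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Vectorised one-sample t for sign-flipped data.

    ``diffs``: (n_subjects, n_vars); ``signs``: (n_perm, n_subjects).
    Squares are flip-invariant, so only the mean changes per permutation.
    """
    n = diffs.shape[0]
    ssq = (diffs**2).sum(axis=0)  # (n_vars,)
    means = signs @ diffs / n  # (n_perm, n_vars)
    var = (ssq[None, :] - n * means**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    t[np.isnan(t)] = 0.0  # all-zero rows
    return t


def _all_sign_patterns(n: int, chunk: int = 1 << 14):
    """Yield chunks of all 2^n sign vectors as (+/-1) arrays."""
    total = 1 << n
    bits = np.arange(n)
    for start in range(0, total, chunk):
        codes = np.arange(start, min(start + chunk, total), dtype=np.int64)
        yield 1.0 - 2.0 * ((codes[:, None] >> bits[None, :]) & 1)


@dataclass
class PermutationResult:
    labels: list[str]
    t_obs: np.ndarray
    p_fwe: np.ndarray  # family-wise (max-t corrected)
    p_uncorrected: np.ndarray  # single-variable sign-flip p
    maxt_null: np.ndarray
    critical_t: float
    alpha: float
    method: str
    df: int

    @property
    def significant(self) -> np.ndarray:
        return self.p_fwe <= self.alpha

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi": self.labels,
                "t_obs": self.t_obs,
                "p_fwe": self.p_fwe,
                "p_uncorrected": self.p_uncorrected,
                "critical_t": self.critical_t,
                "significant": self.significant,
            }
        )


def signflip_maxt(
    accuracies: np.ndarray | pd.DataFrame,
    config: InferenceConfig | None = None,
    labels: list[str] | None = None,
    method: str = "auto",
) -> PermutationResult:
    """Sign-flip max-t permutation test of accuracy > chance across ROIs.

    Per permutation one sign per subject is drawn (shared across ROIs), the
    one-sample t against chance is recomputed per ROI, and the max over ROIs
    recorded.  ``method`` is ``monte_carlo``, ``exhaustive`` (all 2^n
    patterns, n <= 20) or ``auto`` (exhaustive whenever 2^n <= n_permutations).

    p-value conventions: exhaustive p = #{t_max >= t_obs} / 2^n (the identity
    flip is part of the enumeration); Monte-Carlo p = (1 + count) / (n + 1).
    """
    config = config or InferenceConfig()
    if isinstance(accuracies, pd.DataFrame):
        labels = labels or [str(c) for c in accuracies.columns]
        acc = accuracies.to_numpy(dtype=float)
    else:
        acc = np.asarray(accuracies, dtype=float)
        if acc.ndim == 1:
            acc = acc[:, None]
        labels = labels or [f"var_{j}" for j in range(acc.shape[1])]
    n_subj, n_var = acc.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")

    diffs = acc - config.chance_pct
    t_obs = _t_rows(diffs, np.ones((1, n_subj)))[0]

    if method == "auto":
        method = "exhaustive" if (n_subj <= 20 and 2**n_subj <= config.n_permutations) else "monte_carlo"
    if method == "exhaustive" and n_subj > 20:
        raise ValueError("exhaustive enumeration supported only for n <= 20 subjects")

    eps = 1e-12
    count_max = np.zeros(n_var)
    count_unc = np.zeros(n_var)
    maxt_parts = []
    if method == "exhaustive":
        total = 2**n_subj
        for signs in _all_sign_patterns(n_subj):
            t = _t_rows(diffs, signs)
            tmax = t.max(axis=1)
            maxt_parts.append(tmax)
            count_max += (tmax[:, None] >= t_obs[None, :] - eps).sum(axis=0)
            count_unc += (t >= t_obs[None, :] - eps).sum(axis=0)
        p_fwe = count_max / total
        p_unc = count_unc / total
    elif method == "monte_carlo":
        rng = np.random.default_rng(config.seed)
        signs = rng.choice([-1.0, 1.0], size=(config.n_permutations, n_subj))
        t = _t_rows(diffs, signs)
        tmax = t.max(axis=1)
        maxt_parts.append(tmax)
        count_max = (tmax[:, None] >= t_obs[None, :] - eps).sum(axis=0)
        count_unc = (t >= t_obs[None, :] - eps).sum(axis=0)
        p_fwe = (1.0 + count_max) / (config.n_permutations + 1.0)
        p_unc = (1.0 + count_unc) / (config.n_permutations + 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")

    maxt = np.concatenate(maxt_parts)
    critical_t = float(np.quantile(maxt, 1.0 - config.alpha, method="higher"))
    return PermutationResult(
        labels=list(labels),
        t_obs=t_obs,
        p_fwe=np.asarray(p_fwe, dtype=float),
        p_uncorrected=np.asarray(p_unc, dtype=float),
        maxt_null=maxt,
        critical_t=critical_t,
        alpha=config.alpha,
        method=method,
        df=n_subj - 1,
    )


@dataclass
class VoxelContrastResult:
    roi: str
    t: np.ndarray  # per in-ROI voxel
    p_fwe: np.ndarray
    survivors: np.ndarray  # boolean, per in-ROI voxel
    clusters: list[np.ndarray]  # linear grid indices, largest first
    alpha: float
    tail: str


def group_voxel_contrast(
    maps: np.ndarray,
    mask: RoiMask,
    config: InferenceConfig | None = None,
    tail: str = "greater",
) -> VoxelContrastResult:
    """Voxelwise one-sample t across subjects with within-ROI max-t correction.

    ``maps`` is (n_subjects, n_roi_voxels), aligned with the mask's canonical
    voxel order.  Sign flips are shared across voxels within a subject;
    ``tail`` is ``greater`` (contrast > 0) or ``two-sided``.
    """
    config = config or InferenceConfig()
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[1] != mask.size:
        raise ValueError("maps must be (n_subjects, n_roi_voxels) on the mask's grid")
    n_subj = maps.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")

    stat = (lambda t: t) if tail == "greater" else np.abs
    if tail not in ("greater", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")

    t_obs = stat(_t_rows(maps, np.ones((1, n_subj)))[0])
    rng = np.random.default_rng(config.seed)
    signs = rng.choice([-1.0, 1.0], size=(config.n_permutations, n_subj))
    # chunk to bound memory on large ROIs
    maxt = np.empty(config.n_permutations)
    chunk = max(1, int(2e7) // max(mask.size, 1))
    for start in range(0, config.n_permutations, chunk):
        t = stat(_t_rows(maps, signs[start : start + chunk]))
        maxt[start : start + t.shape[0]] = t.max(axis=1)
    eps = 1e-12
    count = (maxt[:, None] >= t_obs[None, :] - eps).sum(axis=0)
    p_fwe = (1.0 + count) / (config.n_permutations + 1.0)
    survivors = p_fwe <= config.alpha

    surv_vol = np.zeros(mask.grid.shape, dtype=bool)
    surv_vol.reshape(-1)[mask.indices[survivors]] = True
    labelled, n_clusters = ndimage.label(surv_vol)
    clusters = [
        np.flatnonzero(labelled.reshape(-1) == i) for i in range(1, n_clusters + 1)
    ]
    clusters.sort(key=len, reverse=True)
    return VoxelContrastResult(
        roi=mask.label,
        t=t_obs,
        p_fwe=p_fwe,
        survivors=survivors,
        clusters=clusters,
        alpha=config.alpha,
        tail=tail,
    )
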