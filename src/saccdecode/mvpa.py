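"""ROI decoding: mean-centering, linear SVM, leave-one-run-out CV,
univariate feature selection and accuracy-vs-size curves.

Only small and large blocks enter the classifier (hemifields collapsed),
one sample per block beta.  All steps that could leak test information
(centering statistics shared across runs, feature ranking) are computed per
run or on training runs only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .design import RunDesign
from .glm import GlmFit

__all__ = [
    "SampleSet",
    "MvpaConfig",
    "LinearSvmModel",
    "sample_set_from_betas",
    "mean_center",
    "train_linear_svm",
    "select_topk",
    "loro_accuracy",
    "feature_counts",
    "accuracy_vs_size",
]

DECODED_CLASSES = ("small", "large")


@dataclass
class SampleSet:
    """Block-beta samples for one subject and ROI."""

    X: np.ndarray  # (n_samples, n_voxels)
    y: np.ndarray  # label per sample, "small" | "large"
    runs: np.ndarray  # run id per sample
    subject_id: str = "sub-01"
    roi: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.runs = np.asarray(self.runs)
        if not set(np.unique(self.y)) <= set(DECODED_CLASSES):
            raise ValueError("sample labels must be 'small' or 'large'")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class MvpaConfig:
    svm_c: float = 1.0
    centering: str = "both"  # per_sample_spatial | per_voxel_run | both
    feature_min: int = 200
    feature_step: int = 100
    feature_cap: int = 900
    seed: int = 0

    def __post_init__(self) -> None:
        if self.svm_c <= 0:
            raise ValueError("svm_c must be > 0")
        if self.centering not in ("per_sample_spatial", "per_voxel_run", "both"):
            raise ValueError(f"unknown centering mode {self.centering!r}")


def sample_set_from_betas(
    fits: dict[int, GlmFit],
    designs: dict[int, RunDesign],
    voxel_slice: slice | np.ndarray,
    retained_blocks: dict[int, set[int]] | None = None,
    subject_id: str = "sub-01",
    roi: str = "",
) -> SampleSet:
    """Assemble the decoding samples from per-block GLM fits.

    Keeps only small and large blocks (hemifields collapsed into the size
    label); ``retained_blocks`` optionally restricts to QC-valid blocks.
    """
    rows, labels, run_ids = [], [], []
    for run_id in sorted(fits):
        fit = fits[run_id]
        run = designs[run_id]
        for block in run.blocks:
            size = block.size_class
            if size not in DECODED_CLASSES:
                continue
            if retained_blocks is not None and block.index not in retained_blocks.get(
                run_id, set()
            ):
                continue
            beta = fit.beta(f"block_{block.index:02d}")
            rows.append(np.asarray(beta)[voxel_slice])
            labels.append(size)
            run_ids.append(run_id)
    if not rows:
        raise ValueError("no small/large samples available")
    return SampleSet(
        X=np.vstack(rows), y=np.array(labels), runs=np.array(run_ids),
        subject_id=subject_id, roi=roi,
    )


def mean_center(samples: SampleSet, mode: str = "both") -> SampleSet:
    """Remove sample and/or voxel means, independently within each run.

    per_sample_spatial: subtract each sample's mean over voxels.
    per_voxel_run: subtract each voxel's mean over that run's samples.
    both: spatial first, then per-voxel within run.
    """
    if samples.n_samples == 0:
        raise ValueError("empty sample set")
    X = samples.X.copy()
    if mode in ("per_sample_spatial", "both"):
        X = X - X.mean(axis=1, keepdims=True)
    if mode in ("per_voxel_run", "both"):
        for run_id in np.unique(samples.runs):
            sel = samples.runs == run_id
            X[sel] = X[sel] - X[sel].mean(axis=0, keepdims=True)
    if mode not in ("per_sample_spatial", "per_voxel_run", "both"):
        raise ValueError(f"unknown centering mode {mode!r}")
    return replace(samples, X=X)


@dataclass
class LinearSvmModel:
    w: np.ndarray
    b: float
    positive_label: str
    negative_label: str

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_function(X)
        return np.where(d > 0, self.positive_label, self.negative_label)


def train_linear_svm(
    X: np.ndarray, y: np.ndarray, c: float = 1.0, positive_label: str | None = None
) -> LinearSvmModel:
    """Soft-margin linear SVM (hinge loss, deterministic solver, tol 1e-6).

    The positive class is "large" when present, else the lexicographically
    last label.  Raises on single-class input.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if positive_label is None:
        positive_label = "large" if "large" in classes else classes[-1]
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not among {classes}")
    negative_label = next(cls for cls in classes if cls != positive_label)
    y_num = np.where(y == positive_label, 1, -1)

    clf = SVC(kernel="linear", C=c, tol=1e-6, shrinking=False)
    clf.fit(X, y_num)
    w = clf.coef_.ravel().copy()
    b = float(clf.intercept_[0])
    # libsvm orders classes by first appearance of the numeric label
    if clf.classes_[1] != 1:
        w, b = -w, -b
    return LinearSvmModel(w=w, b=b, positive_label=positive_label, negative_label=negative_label)


def select_topk(localizer_by_run: np.ndarray, k: int) -> np.ndarray:
    """Top-k voxels by mean localizer value across (training) runs.

    Ties are broken by canonical voxel order; the returned indices are
    sorted ascending.
    """
    loc = np.atleast_2d(np.asarray(localizer_by_run, dtype=float))
    scores = loc.mean(axis=0)
    if k > scores.size:
        raise ValueError(f"k={k} exceeds ROI size {scores.size}")
    if k < 1:
        raise ValueError("k must be >= 1")
    order = np.lexsort((np.arange(scores.size), -scores))
    return np.sort(order[:k])


def loro_accuracy(
    samples: SampleSet,
    config: MvpaConfig | None = None,
    localizer: dict[int, np.ndarray] | None = None,
    n_features: int | None = None,
) -> float:
    """Leave-one-run-out cross-validated accuracy, in percent.

    Per fold: centering is applied within each run independently, feature
    selection (when requested) uses the training runs' localizer maps only,
    the SVM is trained on all-but-one run and scored on the held-out run.
    """
    config = config or MvpaConfig()
    run_ids = np.unique(samples.runs)
    if run_ids.size < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    if n_features is not None and localizer is None:
        raise ValueError("feature selection requires localizer maps")

    centered = mean_center(samples, config.centering)
    fold_acc = []
    for test_run in run_ids:
        test = centered.runs == test_run
        train = ~test
        if n_features is not None:
            loc = np.vstack([localizer[r] for r in run_ids if r != test_run])
            voxels = select_topk(loc, n_features)
        else:
            voxels = slice(None)
        model = train_linear_svm(
            centered.X[train][:, voxels], centered.y[train], c=config.svm_c
        )
        pred = model.predict(centered.X[test][:, voxels])
        fold_acc.append(float(np.mean(pred == centered.y[test])))
    return 100.0 * float(np.mean(fold_acc))


def feature_counts(roi_size: int, config: MvpaConfig | None = None) -> list[int]:
    """Voxel-count grid for the accuracy-vs-size curve.

    200, 300, ... up to min(cap, ROI size); the full ROI size is appended
    when the ROI is smaller than the cap.  ROIs smaller than the minimum
    yield just their own size.
    """
    config = config or MvpaConfig()
    top = min(config.feature_cap, roi_size)
    counts = list(range(config.feature_min, top + 1, config.feature_step))
    if roi_size <= config.feature_cap and (not counts or counts[-1] != roi_size):
        counts.append(roi_size)
    return counts


def accuracy_vs_size(
    samples: SampleSet,
    localizer: dict[int, np.ndarray],
    config: MvpaConfig | None = None,
) -> pd.DataFrame:
    """LORO accuracy at every feature count; returns (n_features, accuracy_pct)."""
    config = config or MvpaConfig()
    rows = []
    for k in feature_counts(samples.n_features, config):
        n_feat = None if k >= samples.n_features else k
        acc = loro_accuracy(samples, config, localizer=localizer, n_features=n_feat)
        rows.append({"n_features": k, "accuracy_pct": acc})
    return pd.DataFrame(rows)
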