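"""PCA overview of feature matrices with median-ratio log preprocessing.

The overview projection: replace missing cells by the detection-limit
estimate, express every abundance as a ratio to the feature's median across
all samples, log10-transform, mean-center per feature, and run PCA without
variance scaling.  Ratios absorb any global rescaling of the raw matrix, so
the projection depends only on relative abundance patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .feature_matrix import DetectionLimits, FeatureMatrix, impute_detection_limit


@dataclass
class PCAResult:
    """Sample scores and explained-variance fractions of the overview PCA."""

    scores: pd.DataFrame  # samples × components
    explained_variance_fraction: np.ndarray
    preprocessing: str = "impute->median_ratio->log10->center"

    def __post_init__(self) -> None:
        ev = np.asarray(self.explained_variance_fraction, dtype=float)
        if (ev < -1e-12).any() or (np.diff(ev) > 1e-12).any() or ev.sum() > 1 + 1e-9:
            raise ValueError("explained variances must be nonincreasing, nonnegative, sum <= 1")
        self.explained_variance_fraction = ev

    @property
    def explained_percent(self) -> np.ndarray:
        return self.explained_variance_fraction * 100.0

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        out = self.scores.copy()
        out.index.name = "sample_id"
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write("# explained_percent=" +
                     ",".join(repr(v) for v in self.explained_percent) + "\n")
            out.to_csv(fh, sep="\t")


def pca_overview(
    matrix: FeatureMatrix,
    limits: DetectionLimits | None = None,
    n_components: int | None = 2,
) -> PCAResult:
    """PCA of the median-ratio log-transformed matrix, without scaling.

    ``limits`` are used to substitute missing cells first (required when the
    matrix still carries missing values).  The per-feature median is taken
    across *all* samples.  A zero median is a hard error — the ratio would
    be undefined.
    """
    if matrix.n_samples < 2 or matrix.n_features < 2:
        raise ValueError("pca_overview needs >= 2 samples and >= 2 features")
    work = matrix
    if not work.is_imputed:
        if limits is None:
            raise ValueError("matrix has missing cells; detection limits required")
        work = impute_detection_limit(work, limits)
    elif limits is not None:
        work = impute_detection_limit(work, limits)

    V = work.values.to_numpy()
    med = np.median(V, axis=1, keepdims=True)
    zero = np.flatnonzero(med.ravel() == 0)
    if zero.size:
        raise ValueError(
            f"zero median for features {[matrix.feature_ids[i] for i in zero[:5]]}; "
            "cannot form abundance ratios"
        )
    R = np.log10(V / med)
    R = R - R.mean(axis=1, keepdims=True)

    X = R.T  # samples × features
    max_rank = min(X.shape[0] - 1 if X.shape[0] > 1 else 1, X.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=cols),
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
    )


def plot_scores(result: PCAResult, labels: pd.Series, path: str | Path) -> None:
    """Scatter of the first two components colored by class (optional extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for cls in labels.unique():
        sel = labels.index[labels == cls]
        ax.scatter(result.scores.loc[sel, "PC1"], result.scores.loc[sel, "PC2"],
                   label=str(cls), s=25)
    ev = result.explained_percent
    ax.set_xlabel(f"PC1 ({ev[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({ev[1]:.1f}%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
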