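"""Sample-level QC: PCA on log-transformed normalized counts and
robust outlier flagging against sex-age group centroids.

The transform is log2(normalized count + 1) with per-gene centering (the
variance-stabilized transforms of heavier toolchains are deliberately not
reproduced).  Outlier flagging uses the distance of each sample from its
(sex, age) group centroid in the first two principal components, against a
median + k*MAD rule over all such distances — robust at three replicates
per group.  Flagging and removal are separate explicit steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data_model import ExpressionMatrix, SampleDesign
from .de import normalize
from .errors import EstimationError


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components (PC1, PC2, ...)
    variance_fraction: np.ndarray  # per component, non-increasing
    transform: str = "log2(normalized + 1), gene-centered"
    outlier_flags: pd.DataFrame | None = None  # sample, distance, threshold, flagged

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


def pca_samples(
    matrix: ExpressionMatrix,
    factors: pd.Series,
    n_components: int = 2,
    top_n_variable: int | None = None,
) -> PCAResult:
    """PCA of samples on log2(normalized + 1) gene vectors.

    Component signs are fixed by making each component's largest-magnitude
    gene loading positive, so results are deterministic.  ``top_n_variable``
    optionally restricts to the most variable genes.
    """
    if matrix.n_samples < 2:
        raise EstimationError("PCA needs at least 2 samples")
    log_expr = np.log2(normalize(matrix, factors) + 1.0)
    X = log_expr.to_numpy().T  # samples x genes; sklearn centers each gene
    if top_n_variable is not None and top_n_variable < X.shape[1]:
        order = np.argsort(X.var(axis=0))[::-1][:top_n_variable]
        X = X[:, order]
    max_rank = min(matrix.n_samples - 1, X.shape[1])
    if n_components > max_rank:
        warnings.warn(
            f"n_components clipped from {n_components} to {max_rank}", stacklevel=2
        )
        n_components = max_rank
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    # sign convention: largest-|loading| positive per component
    for k in range(scores.shape[1]):
        loading = pca.components_[k]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, k] *= -1.0
    total_var = X.var(axis=0, ddof=1).sum()
    # scale-aware zero guard: numerically constant data has no variance to explain
    if total_var <= 1e-12 * max(1.0, float(np.mean(np.square(X)))):
        frac = np.zeros(scores.shape[1])
    else:
        frac = pca.explained_variance_ / total_var
    score_df = pd.DataFrame(
        scores,
        index=pd.Index(matrix.sample_ids, name="sample"),
        columns=[f"PC{k + 1}" for k in range(scores.shape[1])],
    )
    return PCAResult(score_df, frac)


def flag_outliers(
    result: PCAResult, design: SampleDesign, k: float = 5.0
) -> pd.DataFrame:
    """Flag samples far from their sex-age group centroid in PC1/PC2.

    A sample is flagged when its Euclidean centroid distance exceeds
    median + k * MAD of all centroid distances.  Groups of size 1 are
    skipped with a warning (no centroid to speak of).  The frame is also
    stored on ``result.outlier_flags``.
    """
    if result.scores.shape[1] < 2:
        raise EstimationError("outlier flagging needs >= 2 components")
    pcs = result.scores[["PC1", "PC2"]]
    rows = []
    for (sex, age), samples in design.groups().items():
        samples = [s for s in samples if s in pcs.index]
        if len(samples) < 2:
            warnings.warn(
                f"group ({sex}, {age}) has < 2 samples; outlier flagging skipped",
                stacklevel=2,
            )
            continue
        sub = pcs.loc[samples].to_numpy()
        centroid = sub.mean(axis=0)
        dist = np.linalg.norm(sub - centroid, axis=1)
        for s, d in zip(samples, dist):
            rows.append({"sample": s, "group": f"{sex}{age}", "distance": d})
    flags = pd.DataFrame(rows)
    if flags.empty:
        flags["flagged"] = []
        flags["threshold"] = []
        result.outlier_flags = flags
        return flags
    med = flags["distance"].median()
    mad = (flags["distance"] - med).abs().median()
    threshold = med + k * mad
    flags["threshold"] = threshold
    flags["flagged"] = flags["distance"] > threshold
    result.outlier_flags = flags
    return flags


def remove_samples(
    matrix: ExpressionMatrix, design: SampleDesign, sample_ids
) -> tuple[ExpressionMatrix, SampleDesign]:
    """Drop the given samples from both the matrix and the design."""
    drop = set(sample_ids)
    keep = [s for s in matrix.sample_ids if s not in drop]
    return matrix.subset_samples(keep), design.subset(keep)
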