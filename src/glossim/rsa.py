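"""Representational similarity analysis.

Pairwise dissimilarity between the latent representations of stimuli is the
correlation distance (1 minus Pearson's r across feature dimensions).  Block
averages by condition (gloss level, light field) quantify clustering; the
same-versus-different-condition contrast, computed per model training
instance, is tested with a paired t-test across instances.  Prediction
vectors of different models over a common stimulus set are compared by
Euclidean distance after unit-range normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DissimilarityMatrix", "StatResult", "correlation_distance_matrix",
    "block_average", "same_vs_different_contrast", "prediction_distance_matrix",
    "embed_for_visualization",
]


@dataclass
class DissimilarityMatrix:
    values: np.ndarray
    labels: list = field(default_factory=list)
    metric: str = "correlation_distance"
    excluded_pairs: list = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        finite = v[np.isfinite(v)]
        if not np.allclose(v, v.T, atol=1e-10, equal_nan=True):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if self.metric == "correlation_distance" and finite.size and (
                finite.min() < -1e-10 or finite.max() > 2 + 1e-10):
            raise ValueError("correlation distances must lie in [0, 2]")
        self.values = v


@dataclass
class StatResult:
    statistic_name: str
    value: float
    df: float
    p_value: float
    effect_size: float  # Cohen's d or eta^2
    ci: tuple = (np.nan, np.nan)
    flags: list = field(default_factory=list)


def correlation_distance_matrix(features: np.ndarray, labels=None,
                                standardize_dims: bool = False) -> DissimilarityMatrix:
    """Entry (i, j) = 1 - Pearson r between feature rows i and j.

    With ``standardize_dims`` each feature dimension is z-scored across items
    first.  Latent dimensions can differ in scale by orders of magnitude, in
    which case the raw row-correlation is driven entirely by the
    largest-variance dimensions; standardizing makes the dissimilarity
    reflect the code's full geometry.  The default remains the plain
    correlation distance of the rows as given.

    Zero-variance rows yield undefined correlations; those pairs are recorded
    in `excluded_pairs` and set to NaN.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 items and 2 dimensions")
    if standardize_dims:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    sd = X.std(axis=1)
    degenerate = np.where(sd == 0)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    excluded = []
    for i in degenerate:
        d[i, :] = np.nan
        d[:, i] = np.nan
        d[i, i] = 0.0
        excluded.extend((int(i), int(j)) for j in range(X.shape[0]) if j != i)
    return DissimilarityMatrix(values=d, labels=list(labels) if labels is not None else [],
                               metric="correlation_distance", excluded_pairs=excluded)


def block_average(matrix: DissimilarityMatrix, condition_labels) -> tuple:
    """Condition x condition matrix of mean dissimilarities, excluding the
    self diagonal entries of the full matrix.

    Returns (block matrix, ordered condition list).  A singleton condition
    with no off-diagonal pairs raises.
    """
    labels = np.asarray(condition_labels)
    v = matrix.values
    if len(labels) != v.shape[0]:
        raise ValueError("every item must be labeled")
    conds = list(dict.fromkeys(labels.tolist()))  # first-appearance order
    k = len(conds)
    out = np.zeros((k, k))
    for a, ca in enumerate(conds):
        for b, cb in enumerate(conds):
            ia = np.where(labels == ca)[0]
            ib = np.where(labels == cb)[0]
            block = v[np.ix_(ia, ib)]
            if a == b:
                mask = ~np.eye(len(ia), dtype=bool)
                vals = block[mask]
            else:
                vals = block.ravel()
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise ValueError(f"condition pair ({ca}, {cb}) has no off-diagonal pairs")
            out[a, b] = vals.mean()
    return out, conds


def _contrast_for_instance(matrix: DissimilarityMatrix, labels) -> float:
    """mean(different-condition) - mean(same-condition), diagonal excluded."""
    labels = np.asarray(labels)
    v = matrix.values
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(len(labels), dtype=bool)
    finite = np.isfinite(v)
    same_vals = v[same & off & finite]
    diff_vals = v[~same & finite]
    return float(diff_vals.mean() - same_vals.mean())


def same_vs_different_contrast(matrices, labels, n_boot: int = 10_000,
                               boot_seed: int = 0):
    """Per-instance same-vs-different contrasts and a paired t-test across
    model training instances (df = instances - 1), with Cohen's d and a
    percentile bootstrap CI on the mean contrast."""
    contrasts = np.array([_contrast_for_instance(m, labels) for m in matrices])
    if len(contrasts) < 2:
        return contrasts, StatResult("t", np.nan, np.nan, np.nan, np.nan,
                                     flags=["fewer than 2 instances: no test"])
    mean = contrasts.mean()
    sd = contrasts.std(ddof=1)
    flags = []
    if sd == 0:
        t_val, p = np.inf, 0.0
        flags.append("zero variance across instances: t undefined/infinite")
        d = np.inf
    else:
        t_val, p = stats.ttest_1samp(contrasts, 0.0)
        d = mean / sd
    rng = np.random.default_rng(np.random.SeedSequence([int(boot_seed), 13]))
    boots = np.array([
        rng.choice(contrasts, size=len(contrasts), replace=True).mean()
        for _ in range(n_boot)
    ])
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return contrasts, StatResult("t", float(t_val), len(contrasts) - 1, float(p),
                                 float(d), ci=ci, flags=flags)


def prediction_distance_matrix(prediction_vectors: dict) -> DissimilarityMatrix:
    """Euclidean distances between models' prediction vectors over a common
    stimulus set; vectors must already be normalized to [0, 1] per model."""
    names = list(prediction_vectors)
    vecs = [np.asarray(prediction_vectors[n], dtype=np.float64) for n in names]
    lengths = {len(v) for v in vecs}
    if len(lengths) != 1:
        raise ValueError("prediction vectors must have equal length")
    k = len(names)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = float(np.linalg.norm(vecs[i] - vecs[j]))
    return DissimilarityMatrix(values=out, labels=names, metric="euclidean")


def embed_for_visualization(features: np.ndarray, dims: int = 2, seed: int = 0,
                            method: str = "tsne") -> np.ndarray:
    """2-D layout for figures only (never used for statistics)."""
    from .baselines import pixel_embedding

    return pixel_embedding(np.asarray(features), method=method, dims=dims,
                           seed=seed).features
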