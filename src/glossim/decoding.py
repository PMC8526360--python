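"""Linear readouts from feature spaces.

A linear maximum-margin classifier fitted on high/low gloss labels defines
the *gloss axis*; the signed distance of a representation from its hyperplane
is the model's continuous gloss prediction (positive = glossier, magnitude =
strength of evidence).  The same machinery provides six-way light-field
classification, relief regression, per-dimension decoding, and traversal of
the gloss axis in a generative model's latent space.

Features are z-scored per dimension on the training split before fitting;
decision values are reported divided by the weight norm so they are distances
in (standardized) feature-space units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVC, LinearSVC

__all__ = [
    "GlossAxis", "DecodingReport", "train_test_split_indices",
    "fit_gloss_classifier", "predict_gloss", "decode_lightfield",
    "regress_relief", "per_dimension_decoding", "gloss_axis_traversal",
]

_SVM_C = 1.0


@dataclass
class GlossAxis:
    weights: np.ndarray  # in standardized feature space
    bias: float
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not np.any(self.weights):
            raise ValueError("gloss axis weights must not all be zero")

    @property
    def unit_normal(self) -> np.ndarray:
        return self.weights / np.linalg.norm(self.weights)


@dataclass
class DecodingReport:
    task: str
    score: float  # accuracy or R^2
    per_dimension: dict = field(default_factory=dict)
    split_sizes: tuple = (0, 0)
    seed: int = 0
    extras: dict = field(default_factory=dict)


def train_test_split_indices(n: int, split_seed: int, train_frac: float = 0.75):
    rng = np.random.default_rng(np.random.SeedSequence([int(split_seed), 7]))
    order = rng.permutation(n)
    n_train = int(round(n * train_frac))
    return order[:n_train], order[n_train:]


def _standardize(train: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def fit_gloss_classifier(features: np.ndarray, labels, split_seed: int = 0,
                         train_idx=None, test_idx=None):
    """Soft-margin linear SVM on a 75/25 split; returns (GlossAxis, report).

    `labels` may be strings ('low'/'high') or binary ints; the positive side
    of the hyperplane is the high-gloss class.
    """
    X = np.asarray(features, dtype=np.float64)
    y = _binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need both gloss classes")
    if X.shape[0] != len(y):
        raise ValueError("features/labels length mismatch")
    if train_idx is None:
        train_idx, test_idx = train_test_split_indices(len(y), split_seed)
    mu, sd = _standardize(X[train_idx])
    Xz = (X - mu) / sd
    svm = SVC(kernel="linear", C=_SVM_C)
    svm.fit(Xz[train_idx], y[train_idx])
    acc = float(np.mean(svm.predict(Xz[test_idx]) == y[test_idx])) if len(test_idx) else np.nan
    axis = GlossAxis(weights=svm.coef_.ravel(), bias=float(svm.intercept_[0]),
                     scaler_mean=mu, scaler_std=sd,
                     provenance={"split_seed": split_seed, "C": _SVM_C})
    report = DecodingReport(task="gloss2way", score=acc,
                            split_sizes=(len(train_idx), len(test_idx)), seed=split_seed)
    return axis, report


def _binary_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        return (labels.astype(str) == "high").astype(int)
    return labels.astype(int)


def predict_gloss(axis: GlossAxis, features: np.ndarray) -> np.ndarray:
    """Signed distance from the gloss hyperplane (continuous gloss prediction).

    Accepts a single feature vector or a batch; linear (affine) in the input.
    """
    X = np.asarray(features, dtype=np.float64)
    single = X.ndim == 1
    if single:
        X = X[None]
    if X.shape[1] != len(axis.weights):
        raise ValueError("feature dimensionality does not match the axis")
    Xz = (X - axis.scaler_mean) / axis.scaler_std
    d = (Xz @ axis.weights + axis.bias) / np.linalg.norm(axis.weights)
    return float(d[0]) if single else d


def decode_lightfield(features: np.ndarray, lightfield_ids, split_seed: int = 0,
                      train_idx=None, test_idx=None) -> DecodingReport:
    """Multiclass (one-vs-rest) linear classification of the light field."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(lightfield_ids).astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two light fields")
    if train_idx is None:
        train_idx, test_idx = train_test_split_indices(len(y), split_seed)
    mu, sd = _standardize(X[train_idx])
    Xz = (X - mu) / sd
    clf = LinearSVC(C=_SVM_C, multi_class="ovr", dual="auto", max_iter=5000)
    clf.fit(Xz[train_idx], y[train_idx])
    acc = float(np.mean(clf.predict(Xz[test_idx]) == y[test_idx]))
    return DecodingReport(task="lightfield", score=acc,
                          split_sizes=(len(train_idx), len(test_idx)), seed=split_seed,
                          extras={"chance": 1.0 / len(classes), "n_classes": len(classes)})


def regress_relief(features: np.ndarray, relief, split_seed: int = 0,
                   train_idx=None, test_idx=None) -> DecodingReport:
    """OLS regression of relief depth on features; held-out R^2 (may be
    negative; reported as computed)."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(relief, dtype=np.float64)
    if train_idx is None:
        train_idx, test_idx = train_test_split_indices(len(y), split_seed)
    if np.linalg.matrix_rank(X[train_idx] - X[train_idx].mean(0)) == 0:
        raise ValueError("degenerate design matrix")
    reg = LinearRegression()
    reg.fit(X[train_idx], y[train_idx])
    pred = reg.predict(X[test_idx])
    ss_res = np.sum((y[test_idx] - pred) ** 2)
    ss_tot = np.sum((y[test_idx] - y[test_idx].mean()) ** 2)
    r2 = float(1.0 - ss_res / ss_tot)
    return DecodingReport(task="relief_regression", score=r2,
                          split_sizes=(len(train_idx), len(test_idx)), seed=split_seed)


def per_dimension_decoding(features: np.ndarray, targets, task: str = "gloss2way",
                           split_seed: int = 0) -> DecodingReport:
    """Repeat a decode with each single feature dimension; report all scores
    and the best dimension."""
    X = np.asarray(features, dtype=np.float64)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 dimensions")
    train_idx, test_idx = train_test_split_indices(X.shape[0], split_seed)
    scores = {}
    for d in range(X.shape[1]):
        col = X[:, [d]]
        if task == "gloss2way":
            _, rep = fit_gloss_classifier(col, targets, split_seed,
                                          train_idx=train_idx, test_idx=test_idx)
        elif task == "lightfield":
            rep = decode_lightfield(col, targets, split_seed,
                                    train_idx=train_idx, test_idx=test_idx)
        elif task == "relief_regression":
            rep = regress_relief(col, targets, split_seed,
                                 train_idx=train_idx, test_idx=test_idx)
        else:
            raise ValueError(f"unknown task {task!r}")
        scores[d] = rep.score
    best = max(scores, key=scores.get)
    return DecodingReport(task=f"{task}/per_dimension", score=scores[best],
                          per_dimension=scores,
                          split_sizes=(len(train_idx), len(test_idx)), seed=split_seed,
                          extras={"best_dimension": best})


def gloss_axis_traversal(axis: GlossAxis, seed_latent: np.ndarray, n_steps: int = 5,
                         step: float = 0.07, direction: str = "glossy"):
    """Latent points stepping along the unit gloss-axis normal.

    Returns an (n_steps, latent_dim) array starting at the seed latent; the
    decision values of successive points form an arithmetic sequence with
    common difference +-`step` (standardized units).  Pass the points to
    :func:`glossim.pixelvae.generate` with a fixed sampling seed to produce
    the gloss-modulated image sequence.
    """
    if direction not in ("glossy", "matte"):
        raise ValueError("direction must be 'glossy' or 'matte'")
    z0 = np.asarray(seed_latent, dtype=np.float64)
    if z0.shape[-1] != len(axis.weights):
        raise ValueError("latent dimensionality does not match the axis")
    sign = 1.0 if direction == "glossy" else -1.0
    # displacement of `step` standardized units along the unit normal,
    # expressed in raw feature coordinates
    disp = axis.unit_normal * axis.scaler_std
    pts = np.stack([z0 + sign * k * step * disp for k in range(n_steps)])
    return pts
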