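"""Comparison models: a supervised residual-network gloss classifier (and a
continuous-output regressor variant), a simple convolutional autoencoder,
pixel-histogram skewness, a simplified multiscale texture-statistic set, and
raw-pixel embeddings (MDS / tSNE / LLE).

Each model exposes its representation as a :class:`FeatureSpace` so the same
linear-readout and representational analyses run over every model.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .nn import (Tensor, Dense, Conv2d, Module, Adam, clip_global_norm,
                 avg_pool2d, global_avg_pool, upsample_nearest, logsumexp)
from .world import grey601

__all__ = [
    "FeatureSpace", "SupervisedConfig", "SupervisedNet",
    "train_supervised_classifier", "train_supervised_regressor",
    "AutoencoderConfig", "train_autoencoder",
    "histogram_skewness", "skewness_threshold_accuracy",
    "texture_statistics", "pixel_embedding",
]


@dataclass
class FeatureSpace:
    name: str
    features: np.ndarray  # (n_images, dims)
    provenance: dict = field(default_factory=dict)

    @property
    def dims(self) -> int:
        return self.features.shape[1]

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if not np.isfinite(self.features).all():
            raise ValueError("FeatureSpace entries must be finite")


# ---------------------------------------------------------------------------
# supervised residual network
# ---------------------------------------------------------------------------

@dataclass
class SupervisedConfig:
    image_size: int = 128
    maps: int = 56
    blocks: int = 3
    layers_per_block: int = 3
    penultimate: int = 10
    learning_rate: float = 0.001
    lr_decay: float = 0.99995  # per epoch
    batch_size: int = 32
    epochs: int = 21
    grad_clip: float = 5.0
    scale_preset: str = "full"

    @classmethod
    def desk(cls, image_size: int = 32, epochs: int = 21, **kw) -> "SupervisedConfig":
        # keeps the full 21-epoch schedule (cheap at this scale); widths and
        # layers-per-block are the shrunk quantities
        return cls(image_size=image_size, maps=16, blocks=3, layers_per_block=2,
                   epochs=epochs, scale_preset="desk", **kw)


class SupervisedNet(Module):
    """Residual conv net with a 10-unit penultimate layer used as its
    feature space; the output head is a 2-way softmax (classifier) or a
    scalar (regressor)."""

    def __init__(self, config: SupervisedConfig, n_out: int = 2, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 33]))
        m = config.maps
        self.stem = Conv2d(rng, 3, m, 3)
        self.blocks = []
        self.downs = []
        for b in range(config.blocks):
            self.blocks.append([Conv2d(rng, m, m, 3)
                                for _ in range(config.layers_per_block)])
            if b < config.blocks - 1:
                self.downs.append(Conv2d(rng, m, m, 3, stride=2))
        self.fc_latent = Dense(rng, m, config.penultimate)
        self.fc_out = Dense(rng, config.penultimate, n_out)
        self.trained = False
        self.seed = int(seed)

    def parameters(self):
        params = super().parameters()
        for block in self.blocks:
            for conv in block:
                params.extend(conv.parameters())
        return params

    def _latent(self, x: Tensor) -> Tensor:
        h = self.stem(x).relu()
        for b, block in enumerate(self.blocks):
            u = h
            for conv in block:
                u = conv(u.relu())
            h = h + u  # residual skip within each block
            if b < len(self.downs):
                h = self.downs[b](h.relu())
        h = global_avg_pool(h.relu())
        return self.fc_latent(h)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc_out(self._latent(x).relu())

    def features(self, images: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Penultimate 10-unit activations (the model's 'latent code')."""
        out = []
        x = images.astype(np.float32) * 2.0 - 1.0
        for s in range(0, len(x), batch_size):
            out.append(self._latent(Tensor(x[s : s + batch_size])).data.copy())
        return np.concatenate(out)

    def predict(self, images: np.ndarray, batch_size: int = 128) -> np.ndarray:
        out = []
        x = images.astype(np.float32) * 2.0 - 1.0
        for s in range(0, len(x), batch_size):
            out.append(self(Tensor(x[s : s + batch_size])).data.copy())
        return np.concatenate(out)


def _softmax_xent(logits: Tensor, labels: np.ndarray) -> Tensor:
    n = logits.shape[0]
    lse = logsumexp(logits, axis=1)
    picked = logits[np.arange(n), labels]
    return (lse - picked).mean()


def _train_net(net: SupervisedNet, images, targets, loss_fn, seed):
    cfg = net.config
    params = net.parameters()
    opt = Adam(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 55]))
    x = images
    history = []
    for epoch in range(cfg.epochs):
        t0 = time.time()
        order = rng.permutation(len(x))
        tot, nb = 0.0, 0
        for s in range(0, len(x) - cfg.batch_size + 1, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            logits = net(Tensor(x[idx].astype(np.float32) * 2.0 - 1.0))
            loss = loss_fn(logits, targets[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite loss")
            opt.zero_grad()
            loss.backward()
            clip_global_norm(params, cfg.grad_clip)
            opt.step()
            tot += float(loss.data)
            nb += 1
        opt.decay_lr(cfg.lr_decay)
        history.append({"epoch": epoch, "loss": tot / max(nb, 1),
                        "wall_clock": time.time() - t0})
    net.trained = True
    return history


def train_supervised_classifier(images: np.ndarray, labels: np.ndarray,
                                config: SupervisedConfig, seed: int = 0,
                                test_images=None, test_labels=None):
    """Softmax cross-entropy training on high/low gloss labels.

    Returns (net, report dict with training history, FeatureSpace of the
    training images and, when a test set is given, held-out accuracy).
    """
    labels = np.asarray(labels)
    if labels.dtype.kind not in "iub":
        raise ValueError("labels must be integer class indices (0 = low, 1 = high)")
    net = SupervisedNet(config, n_out=2, seed=seed)
    history = _train_net(net, images, labels, _softmax_xent, seed)
    report = {"history": history, "seed": seed}
    if test_images is not None:
        preds = net.predict(test_images).argmax(axis=1)
        report["test_accuracy"] = float(np.mean(preds == np.asarray(test_labels)))
    fs = FeatureSpace("supervised_latent", net.features(images),
                      provenance={"seed": seed, "preset": config.scale_preset})
    return net, report, fs


def train_supervised_regressor(images: np.ndarray, targets: np.ndarray,
                               config: SupervisedConfig, seed: int = 0,
                               test_images=None, test_targets=None):
    """Same backbone with a scalar output and squared-error loss; targets are
    standardized internally and predictions returned on the original scale."""
    targets = np.asarray(targets, dtype=np.float64)
    mu, sd = targets.mean(), targets.std()
    z = ((targets - mu) / (sd if sd > 0 else 1.0)).astype(np.float32)

    def sq_loss(out: Tensor, t: np.ndarray) -> Tensor:
        d = out.reshape(out.shape[0]) - Tensor(t)
        return (d * d).mean()

    net = SupervisedNet(config, n_out=1, seed=seed)
    history = _train_net(net, images, z, sq_loss, seed)
    net._target_scale = (mu, sd)
    report = {"history": history, "seed": seed}
    if test_images is not None:
        pred = net.predict(test_images).ravel() * sd + mu
        resid = np.asarray(test_targets) - pred
        tot = np.asarray(test_targets) - np.mean(test_targets)
        report["test_r2"] = float(1.0 - np.sum(resid**2) / np.sum(tot**2))
        report["predictions"] = pred
    return net, report


# ---------------------------------------------------------------------------
# simple autoencoder
# ---------------------------------------------------------------------------

@dataclass
class AutoencoderConfig:
    image_size: int = 128
    widths: tuple = (64, 32, 16, 16)
    bottleneck: int = 4096
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 1000
    grad_clip: float = 5.0
    scale_preset: str = "full"

    @classmethod
    def desk(cls, image_size: int = 32, epochs: int = 5, **kw) -> "AutoencoderConfig":
        return cls(image_size=image_size, widths=(16, 16, 8, 8), bottleneck=256,
                   epochs=epochs, scale_preset="desk", **kw)


class Autoencoder(Module):
    def __init__(self, config: AutoencoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 44]))
        widths = config.widths
        self.enc = []
        cin = 3
        for w in widths:
            self.enc.append(Conv2d(rng, cin, w, 3))
            cin = w
        spatial = config.image_size // (2 ** len(widths))
        self.flat = spatial * spatial * widths[-1]
        self.spatial = spatial
        self.fc_in = Dense(rng, self.flat, config.bottleneck)
        self.fc_out = Dense(rng, config.bottleneck, self.flat)
        self.dec = []
        rev = list(widths[::-1][1:]) + [3]
        cin = widths[-1]
        for w in rev:
            self.dec.append(Conv2d(rng, cin, w, 3))
            cin = w
        self.trained = False

    def bottleneck_features(self, images: np.ndarray, batch_size: int = 128) -> np.ndarray:
        out = []
        for s in range(0, len(images), batch_size):
            x = Tensor(images[s : s + batch_size].astype(np.float32))
            out.append(self._encode(x).data.copy())
        return np.concatenate(out)

    def _encode(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.enc:
            h = avg_pool2d(conv(h).relu())
        h = h.reshape(h.shape[0], self.flat)
        return self.fc_in(h)

    def __call__(self, x: Tensor) -> Tensor:
        h = self._encode(x).relu()
        h = self.fc_out(h).relu()
        h = h.reshape(h.shape[0], self.spatial, self.spatial, -1)
        for i, conv in enumerate(self.dec):
            h = conv(upsample_nearest(h))
            if i < len(self.dec) - 1:
                h = h.relu()
        return h.sigmoid()


def train_autoencoder(images: np.ndarray, config: AutoencoderConfig, seed: int = 0):
    """Mean-absolute-error reconstruction training; the fully connected
    bottleneck activations are exposed as the model's FeatureSpace."""
    model = Autoencoder(config, seed=seed)
    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 66]))
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(images))
        tot, nb = 0.0, 0
        for s in range(0, len(images) - config.batch_size + 1, config.batch_size):
            x = images[order[s : s + config.batch_size]].astype(np.float32)
            recon = model(Tensor(x))
            diff = recon - Tensor(x)
            loss = (diff * diff + 1e-12) ** 0.5  # |x|, smoothed at 0
            loss = loss.mean()
            opt.zero_grad()
            loss.backward()
            clip_global_norm(params, config.grad_clip)
            opt.step()
            tot += float(loss.data)
            nb += 1
        history.append({"epoch": epoch, "mae": tot / max(nb, 1)})
    model.trained = True
    fs = FeatureSpace("autoencoder_bottleneck", model.bottleneck_features(images),
                      provenance={"seed": seed, "preset": config.scale_preset})
    return model, history, fs


# ---------------------------------------------------------------------------
# histogram skewness
# ---------------------------------------------------------------------------

def histogram_skewness(image: np.ndarray) -> float:
    """Third standardized moment of the greyscale pixel distribution (0 for a
    constant image)."""
    g = grey601(image).ravel()
    m = g.mean()
    v = np.mean((g - m) ** 2)
    if v < 1e-18:
        return 0.0
    return float(np.mean((g - m) ** 3) / v**1.5)


def skewness_threshold_accuracy(train_values, train_labels, test_values, test_labels) -> float:
    """Accuracy of the optimal skewness threshold (fit on train, score on test).

    The threshold maximizing training accuracy is searched over midpoints of
    consecutive sorted values (both polarities); when several thresholds tie,
    the midpoint of the best-accuracy interval is used.
    """
    tv = np.asarray(train_values, dtype=float)
    tl = np.asarray(train_labels)
    if len(np.unique(tl)) < 2:
        raise ValueError("training set must contain both classes")
    uniq = np.unique(tv)
    cands = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    best_acc, best_thr, best_dir = -1.0, 0.0, 1
    for direction in (1, -1):
        accs = np.array([np.mean(((tv > c) == (tl == 1)) if direction == 1
                                 else ((tv <= c) == (tl == 1))) for c in cands])
        top = accs.max()
        if top > best_acc:
            # midpoint of the FIRST contiguous best-accuracy interval (ties
            # may occur in several disjoint threshold ranges)
            idx = np.flatnonzero(accs == top)
            run_end = idx[0]
            while run_end + 1 in idx:
                run_end += 1
            best_acc = top
            best_thr = (cands[idx[0]] + cands[run_end]) / 2.0
            best_dir = direction
    sv = np.asarray(test_values, dtype=float)
    sl = np.asarray(test_labels)
    pred = (sv > best_thr) if best_dir == 1 else (sv <= best_thr)
    return float(np.mean(pred == (sl == 1)))


# ---------------------------------------------------------------------------
# simplified multiscale texture statistics
# ---------------------------------------------------------------------------

def _log_gabor_bank(size: int, scales: int, orientations: int):
    """Complex log-Gabor filters in the frequency domain (one per
    scale x orientation), plus the frequency grid."""
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.sqrt(fx**2 + fy**2)
    theta = np.arctan2(fy, fx)
    f[0, 0] = 1.0  # avoid log(0); DC handled by radial term -> 0
    bank = []
    sigma_r = 0.80  # narrow enough that octave-spaced bands barely overlap
    for s in range(scales):
        f0 = 0.25 / (2**s)
        radial = np.exp(-(np.log(f / f0) ** 2) / (2 * np.log(sigma_r) ** 2))
        radial[0, 0] = 0.0
        for o in range(orientations):
            ang0 = o * np.pi / orientations
            d = np.angle(np.exp(1j * (theta - ang0)))
            angular = np.exp(-(d**2) / (2 * (np.pi / orientations / 1.2) ** 2))
            bank.append(((s, o), radial * angular))
    return bank


_AUTOCORR_N = 7


def texture_statistics(image: np.ndarray, scales: int = 3, orientations: int = 4) -> np.ndarray:
    """Simplified multiscale oriented texture description of a greyscale image.

    Feature ordering (documented, fixed): [image mean, image variance] then,
    per band in (scale, orientation) raster order, the four marginal moments
    of the band's real response (mean, variance, skew, kurtosis); then per
    band the central 7x7 normalized autocorrelation of the real response
    (row-major); then cross-scale magnitude correlations between adjacent
    scales at matched orientation, in (scale-pair, orientation) order.
    """
    g = grey601(image) if image.ndim == 3 else np.asarray(image, dtype=float)
    size = g.shape[0]
    if size < 4 * _AUTOCORR_N:
        raise ValueError("image smaller than filter support")
    # mirror extension: band responses measure image structure, not the
    # discontinuity at the periodic FFT seam
    bank = _log_gabor_bank(2 * size, scales, orientations)
    G = np.fft.fft2(np.pad(g, ((0, size), (0, size)), mode="symmetric"))
    responses = {key: np.fft.ifft2(G * filt)[:size, :size] for key, filt in bank}

    feats = [g.mean(), g.var()]
    # marginal moments of real responses
    for s in range(scales):
        for o in range(orientations):
            r = responses[(s, o)].real.ravel()
            m, v = r.mean(), r.var()
            if v < 1e-18:
                feats += [m, 0.0, 0.0, 0.0]
            else:
                zc = r - m
                feats += [m, v, float(np.mean(zc**3) / v**1.5),
                          float(np.mean(zc**4) / v**2)]
    # central 7x7 normalized autocorrelation per band
    half = _AUTOCORR_N // 2
    for s in range(scales):
        for o in range(orientations):
            r = responses[(s, o)].real
            v = r.var()
            if v < 1e-18:
                feats += [0.0] * _AUTOCORR_N**2
                continue
            spec = np.abs(np.fft.fft2(r - r.mean())) ** 2
            ac = np.fft.ifft2(spec).real / (r.size * v)
            ac = np.fft.fftshift(ac)
            c = size // 2
            feats += list(ac[c - half : c + half + 1, c - half : c + half + 1].ravel())
    # cross-scale magnitude correlations (adjacent scales, same orientation)
    for s in range(scales - 1):
        for o in range(orientations):
            a = np.abs(responses[(s, o)]).ravel()
            b = np.abs(responses[(s + 1, o)]).ravel()
            if a.std() < 1e-12 or b.std() < 1e-12:
                feats.append(0.0)
            else:
                feats.append(float(np.corrcoef(a, b)[0, 1]))
    return np.asarray(feats, dtype=np.float64)


# ---------------------------------------------------------------------------
# raw-pixel embeddings
# ---------------------------------------------------------------------------

def _classical_mds(X: np.ndarray, dims: int) -> np.ndarray:
    """Classical (Torgerson) scaling of the Euclidean distance matrix."""
    D2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    n = len(X)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    # deterministic sign convention
    for d in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, d]))
        if coords[i, d] < 0:
            coords[:, d] *= -1
    return coords


def pixel_embedding(images: np.ndarray, method: str, dims: int = 10,
                    seed: int = 0) -> FeatureSpace:
    """Low-dimensional embedding of raw pixel vectors.

    `images` may be (n, h, w, c) or already-flat (n, p).  MDS is classical
    scaling (a linear projection that preserves pairwise distances exactly
    when the data are at most `dims`-dimensional); tSNE and LLE delegate to
    scikit-learn at default parameters.  Probe images must be embedded
    jointly with the training images — there is no out-of-sample projection.
    """
    X = np.asarray(images, dtype=np.float64)
    if X.ndim > 2:
        X = X.reshape(len(X), -1)
    if len(X) < dims + 2:
        raise ValueError("need at least dims + 2 images")
    if method == "mds":
        coords = _classical_mds(X, dims)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        n = len(X)
        perplexity = min(30.0, max(2.0, (n - 1) / 3.0 - 1.0))
        coords = TSNE(n_components=dims, method="exact" if dims > 3 else "barnes_hut",
                      random_state=seed, init="pca", perplexity=perplexity).fit_transform(X)
    elif method == "lle":
        from sklearn.manifold import LocallyLinearEmbedding

        n_neighbors = min(5, len(X) - 1)
        coords = LocallyLinearEmbedding(n_components=dims, n_neighbors=n_neighbors,
                                        random_state=seed).fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return FeatureSpace(f"pixel_{method}", coords,
                        provenance={"method": method, "dims": dims, "seed": seed})
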