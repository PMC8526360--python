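"""PixelVAE-style unsupervised generative model.

Two jointly trained streams: a convolutional *conditioning* encoder that
compresses an image into a small diagonal-Gaussian latent code (default 10
dimensions), and an autoregressive *pixel* stream of masked convolutions that
models each 8-bit pixel value with a discretized mixture of logistic
distributions, conditioned on previously generated pixels (raster order) and
on the latent code.  The training objective is the usual variational bound:
teacher-forced reconstruction negative log-likelihood plus the closed-form
KL divergence of the posterior from a standard-normal prior.  No weight
regularization is applied, which encourages the model to store whole-image
structure in its latent code.

The latent code means are the representation used by every downstream
readout analysis.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import (Tensor, Dense, Conv2d, MaskedConv2d, Module, Adam,
                 clip_global_norm, concatenate, logsumexp, where)

__all__ = [
    "PixelVAEConfig", "PixelVAE", "TrainingLog",
    "discretized_logistic_likelihood", "elbo_loss", "train_unsupervised",
    "encode", "generate", "save_model", "load_model",
]


@dataclass
class PixelVAEConfig:
    image_size: int = 128
    latent_dim: int = 10
    cond_widths: tuple = (64, 128, 256)
    cond_strides: tuple = (2, 2, 2)
    cond_fc: int = 512
    ar_blocks: int = 6
    ar_layers_per_block: int = 3
    ar_maps: int = 64
    mixture_components: int = 12
    learning_rate: float = 0.001
    lr_decay: float = 0.999995  # multiplicative, per epoch
    batch_size: int = 5
    epochs: int = 200
    grad_clip: float = 5.0
    scale_preset: str = "full"

    def __post_init__(self):
        if self.latent_dim < 1 or self.mixture_components < 1:
            raise ValueError("latent_dim and mixture_components must be >= 1")
        if not (0 < self.lr_decay <= 1):
            raise ValueError("lr_decay must be in (0, 1]")

    @classmethod
    def desk(cls, image_size: int = 32, epochs: int = 20, **kw) -> "PixelVAEConfig":
        """CPU-trainable preset preserving every architectural mechanism.

        The encoder keeps full resolution in its first layer (highlights are
        1-3 px at this scale) and the autoregressive stream is kept narrow so
        reconstruction leans on the latent code.
        """
        return cls(image_size=image_size, latent_dim=10, cond_widths=(32, 64, 128),
                   cond_strides=(1, 2, 2), cond_fc=128, ar_blocks=3,
                   ar_layers_per_block=2, ar_maps=8, mixture_components=12,
                   batch_size=5, epochs=epochs, scale_preset="desk", **kw)


@dataclass
class TrainingLog:
    epochs: list = field(default_factory=list)  # dict rows

    def append(self, **row):
        self.epochs.append(row)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.epochs)


# ---------------------------------------------------------------------------
# discretized logistic mixture likelihood
# ---------------------------------------------------------------------------

_LOGSCALE_MIN = -7.0


def discretized_logistic_likelihood(weights, locations, log_scales, value: int) -> float:
    """Probability of 8-bit bin [value-1/2, value+1/2] under a logistic mixture.

    Parameters are in 0-255 units (`log_scales` is the log of the logistic
    scale in those units).  The edge bins at 0 and 255 absorb the open tails,
    so the probabilities over the 256 values sum to one.
    """
    if not 0 <= value <= 255:
        raise ValueError("value must be an 8-bit intensity")
    w = np.asarray(weights, dtype=float)
    mu = np.asarray(locations, dtype=float)
    s = np.exp(np.asarray(log_scales, dtype=float))
    if not (np.isfinite(w).all() and np.isfinite(mu).all() and np.isfinite(s).all()):
        raise ValueError("non-finite mixture parameters")
    w = w / w.sum()

    def cdf(x):
        return 1.0 / (1.0 + np.exp(-(x - mu) / s))

    upper = cdf(value + 0.5) if value < 255 else np.ones_like(mu)
    lower = cdf(value - 0.5) if value > 0 else np.zeros_like(mu)
    return float(np.sum(w * (upper - lower)))


def _dlm_log_prob(params: dict, x: np.ndarray) -> Tensor:
    """Teacher-forced log-likelihood map (B, H, W) of images under the mixture.

    `x` is the target image scaled to [-1, 1] on the 255-level grid.  Means of
    the green/blue channels are shifted by learned linear coefficients times
    the true values of the preceding channels.
    """
    logits, means, log_scales, coeffs = (params["logits"], params["means"],
                                         params["log_scales"], params["coeffs"])
    b, h, w, k = logits.shape
    xr = x[..., 0:1]  # numpy constants (teacher forcing)
    xg = x[..., 1:2]
    m_r = means[:, :, :, 0, :]
    m_g = means[:, :, :, 1, :] + coeffs[:, :, :, 0, :] * Tensor(xr)
    m_b = (means[:, :, :, 2, :] + coeffs[:, :, :, 1, :] * Tensor(xr)
           + coeffs[:, :, :, 2, :] * Tensor(xg))
    # single fused pass over all three channels: (B,H,W,3,K)
    m = concatenate([t.reshape(b, h, w, 1, k) for t in (m_r, m_g, m_b)], axis=3)
    xv = x[..., None]  # (B,H,W,3,1) broadcasts against K
    ls = log_scales.clip_min(_LOGSCALE_MIN)
    inv_s = (-ls).exp()
    centered = Tensor(xv) - m
    plus_in = inv_s * (centered + 1.0 / 255.0)
    min_in = inv_s * (centered - 1.0 / 255.0)
    cdf_delta = plus_in.sigmoid() - min_in.sigmoid()
    log_cdf_plus = plus_in.log_sigmoid()  # lower edge bin
    log_one_minus_cdf_min = -(min_in.softplus())  # upper edge bin
    mid_in = inv_s * centered
    log_pdf_mid = mid_in - ls - 2.0 * mid_in.softplus()
    # interior: log of the bin mass, falling back to the density times the
    # bin width when the mass underflows
    interior = where(cdf_delta.data > 1e-5,
                     cdf_delta.clip_min(1e-12).log(),
                     log_pdf_mid - np.float32(np.log(127.5)))
    lp = where(xv < -0.999, log_cdf_plus,
               where(xv > 0.999, log_one_minus_cdf_min, interior))
    joint = lp.sum(axis=3)  # (B,H,W,K)
    log_mix = logits - logsumexp(logits, axis=-1).reshape(b, h, w, 1)
    return logsumexp(joint + log_mix, axis=-1)  # (B,H,W)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class _Encoder(Module):
    def __init__(self, rng, cfg: PixelVAEConfig):
        widths = cfg.cond_widths
        strides = cfg.cond_strides
        self.convs = []
        cin = 3
        for wd, st in zip(widths, strides):
            self.convs.append(Conv2d(rng, cin, wd, 3, stride=st))
            cin = wd
        spatial = cfg.image_size // int(np.prod(strides))
        self.flat_dim = spatial * spatial * widths[-1]
        self.fc = Dense(rng, self.flat_dim, cfg.cond_fc)
        self.head = Dense(rng, cfg.cond_fc, 2 * cfg.latent_dim)
        self.latent_dim = cfg.latent_dim

    def __call__(self, x: Tensor):
        h = x
        for conv in self.convs:
            h = conv(h).relu()
        h = h.reshape(h.shape[0], self.flat_dim)
        h = self.fc(h).relu()
        out = self.head(h)
        mean = out[:, : self.latent_dim]
        log_var = out[:, self.latent_dim :]
        return mean, log_var


class _ResBlock(Module):
    def __init__(self, rng, cfg: PixelVAEConfig):
        self.latent_proj = Dense(rng, cfg.latent_dim, cfg.ar_maps)
        self.layers = [MaskedConv2d(rng, cfg.ar_maps, cfg.ar_maps, 3, include_center=True)
                       for _ in range(cfg.ar_layers_per_block)]

    def __call__(self, h: Tensor, z: Tensor) -> Tensor:
        b = z.shape[0]
        bias = self.latent_proj(z).reshape(b, 1, 1, -1)
        inp = h + bias  # latent enters as a spatially broadcast bias
        u = inp
        for conv in self.layers:
            u = conv(u.relu())
        return inp + u


class _ARDecoder(Module):
    def __init__(self, rng, cfg: PixelVAEConfig):
        self.first = MaskedConv2d(rng, 3, cfg.ar_maps, 7, include_center=False)
        self.blocks = [_ResBlock(rng, cfg) for _ in range(cfg.ar_blocks)]
        self.head1 = Conv2d(rng, cfg.ar_maps, cfg.ar_maps, 1)
        self.head2 = Conv2d(rng, cfg.ar_maps, 10 * cfg.mixture_components, 1)
        # long-range skips pair outer blocks (first->last, second->second-last)
        n = cfg.ar_blocks
        self.skips = {n - 1: 0, n - 2: 1} if n >= 4 else ({n - 1: 0} if n >= 2 else {})
        self.k = cfg.mixture_components

    def __call__(self, x: Tensor, z: Tensor) -> dict:
        h = self.first(x)
        outs = []
        for i, block in enumerate(self.blocks):
            if i in self.skips:
                h = h + outs[self.skips[i]]
            h = block(h, z)
            outs.append(h)
        h = self.head1(h.relu()).relu()
        out = self.head2(h)
        b, hh, ww, _ = out.shape
        k = self.k
        logits = out[:, :, :, :k]
        rest = out[:, :, :, k:].reshape(b, hh, ww, 3, 3, k)
        return {
            "logits": logits,
            "means": rest[:, :, :, :, 0, :],
            "log_scales": rest[:, :, :, :, 1, :],
            "coeffs": rest[:, :, :, :, 2, :].tanh(),
        }


class PixelVAE(Module):
    def __init__(self, config: PixelVAEConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
        self.encoder = _Encoder(rng, config)
        self.decoder = _ARDecoder(rng, config)
        self.trained = False
        self.seed = int(seed)


def _to_signed(images: np.ndarray) -> np.ndarray:
    """[0,1] float images -> 255-level grid scaled to [-1, 1]."""
    return (np.round(np.clip(images, 0, 1) * 255.0) / 127.5 - 1.0).astype(np.float32)


def kl_standard_normal(mean: Tensor, log_var: Tensor) -> Tensor:
    """Closed-form KL( N(mean, diag exp(log_var)) || N(0, I) ), summed over
    dimensions, averaged over the batch."""
    t = log_var.exp() + mean * mean - 1.0 - log_var
    return 0.5 * t.sum(axis=1).mean()


def elbo_loss(model: PixelVAE, images: np.ndarray, rng: np.random.Generator | None = None,
              sample_posterior: bool = True):
    """(reconstruction NLL, KL) per image, as autodiff Tensors.

    Teacher forcing: the pixel stream is fed the true image.  With
    `sample_posterior` the latent is a reparameterized draw; otherwise the
    posterior mean is used (deterministic evaluation).
    """
    x = _to_signed(images)
    if x.shape[1] != model.config.image_size:
        raise ValueError("image size does not match model configuration")
    xt = Tensor(x)
    mean, log_var = model.encoder(xt)
    if sample_posterior:
        rng = rng or np.random.default_rng(0)
        eps = rng.standard_normal(mean.shape).astype(np.float32)
        z = mean + (log_var * 0.5).exp() * Tensor(eps)
    else:
        z = mean
    params = model.decoder(xt, z)
    log_prob = _dlm_log_prob(params, x)  # (B,H,W)
    recon_nll = -(log_prob.sum(axis=1).sum(axis=1).mean())
    kl = kl_standard_normal(mean, log_var)
    return recon_nll, kl


def train_unsupervised(images: np.ndarray, config: PixelVAEConfig, seed: int = 0,
                       val_images: np.ndarray | None = None,
                       verbose: bool = False):
    """Train a PixelVAE on [0,1] float images; returns (model, TrainingLog)."""
    if len(images) == 0:
        raise ValueError("empty training set")
    model = PixelVAE(config, seed=seed)
    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    log = TrainingLog()
    n = len(images)
    bs = config.batch_size
    npx = config.image_size**2 * 3
    for epoch in range(config.epochs):
        t0 = time.time()
        order = rng.permutation(n)
        tot_recon = tot_kl = 0.0
        nb = 0
        for start in range(0, n - bs + 1, bs):
            batch = images[order[start : start + bs]]
            recon, kl = elbo_loss(model, batch, rng=rng)
            loss = recon + kl
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {nb}: "
                    f"recon={recon.data}, kl={kl.data}")
            opt.zero_grad()
            loss.backward()
            clip_global_norm(params, config.grad_clip)
            opt.step()
            tot_recon += float(recon.data)
            tot_kl += float(kl.data)
            nb += 1
        opt.decay_lr(config.lr_decay)
        val_nll = np.nan
        if val_images is not None and len(val_images):
            val_nll = evaluate_nll(model, val_images)
        log.append(epoch=epoch, recon_nll_per_px=tot_recon / max(nb, 1) / npx,
                   kl=tot_kl / max(nb, 1), val_nll_per_px=val_nll,
                   wall_clock=time.time() - t0, seed=seed)
        if verbose:
            row = log.epochs[-1]
            print(f"epoch {epoch}: recon/px {row['recon_nll_per_px']:.4f} "
                  f"kl {row['kl']:.2f} val/px {row['val_nll_per_px']:.4f} "
                  f"({row['wall_clock']:.1f}s)", flush=True)
    model.trained = True
    return model, log


def evaluate_nll(model: PixelVAE, images: np.ndarray, batch_size: int = 32) -> float:
    """Mean (recon NLL + KL) per subpixel, posterior mean, no sampling."""
    npx = model.config.image_size**2 * 3
    total = 0.0
    n = 0
    for start in range(0, len(images), batch_size):
        batch = images[start : start + batch_size]
        recon, kl = elbo_loss(model, batch, sample_posterior=False)
        total += float((recon.data + kl.data)) * len(batch)
        n += len(batch)
    return total / n / npx


def encode(model: PixelVAE, images: np.ndarray, batch_size: int = 64):
    """Posterior parameters for a batch of [0,1] images.

    Returns (means, log_vars) arrays of shape (n, latent_dim).  Downstream
    decoding uses the means (deterministic features).
    """
    means, lvs = [], []
    x = _to_signed(images if images.ndim == 4 else images[None])
    for start in range(0, len(x), batch_size):
        m, lv = model.encoder(Tensor(x[start : start + batch_size]))
        means.append(m.data.copy())
        lvs.append(lv.data.copy())
    means = np.concatenate(means)
    lvs = np.concatenate(lvs)
    if images.ndim == 3:
        return means[0], lvs[0]
    return means, lvs


def _sample_channel(mu: float, log_s: float, u: float) -> float:
    return mu + np.exp(max(log_s, _LOGSCALE_MIN)) * (np.log(u) - np.log1p(-u))


def generate(model: PixelVAE, latent: np.ndarray, rng: np.random.Generator | None = None,
             temperature: float = 1.0) -> np.ndarray:
    """Sample an image pixel by pixel in raster order, conditioned on `latent`.

    With ``temperature == 0`` the most probable mixture component's location
    is taken deterministically at every step.  Returns a [0,1] float image.
    """
    cfg = model.config
    s = cfg.image_size
    z = Tensor(np.asarray(latent, dtype=np.float32).reshape(1, cfg.latent_dim))
    canvas = np.zeros((1, s, s, 3), dtype=np.float32)
    rng = rng or np.random.default_rng(0)
    for i in range(s):
        for j in range(s):
            params = model.decoder(Tensor(canvas), z)
            logits = params["logits"].data[0, i, j]
            means = params["means"].data[0, i, j]       # (3, K)
            log_scales = params["log_scales"].data[0, i, j]
            coeffs = params["coeffs"].data[0, i, j]
            if temperature <= 0:
                k = int(np.argmax(logits))
                draw = lambda mu, ls: mu
            else:
                p = np.exp(logits - logits.max())
                p /= p.sum()
                k = int(rng.choice(len(p), p=p))
                draw = lambda mu, ls: _sample_channel(
                    mu, ls, float(np.clip(rng.random(), 1e-5, 1 - 1e-5)))
            xr = float(np.clip(draw(means[0, k], log_scales[0, k]), -1, 1))
            xg = float(np.clip(draw(means[1, k] + coeffs[0, k] * xr,
                                    log_scales[1, k]), -1, 1))
            xb = float(np.clip(draw(means[2, k] + coeffs[1, k] * xr
                                    + coeffs[2, k] * xg, log_scales[2, k]), -1, 1))
            canvas[0, i, j] = (xr, xg, xb)
    img = (canvas[0] + 1.0) / 2.0
    return np.clip(np.round(img * 255.0) / 255.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: PixelVAE, path: str | Path):
    path = Path(path)
    state = model.state_dict()
    np.savez_compressed(path, *state,
                        config=json.dumps(asdict(model.config)),
                        seed=model.seed, trained=model.trained)


def load_model(path: str | Path) -> PixelVAE:
    with np.load(Path(path), allow_pickle=False) as data:
        cfg = PixelVAEConfig(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in json.loads(str(data["config"])).items()})
        model = PixelVAE(cfg, seed=int(data["seed"]))
        arrays = [data[f"arr_{i}"] for i in range(len(model.parameters()))]
        model.load_state_dict(arrays)
        model.trained = bool(data["trained"])
    return model
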