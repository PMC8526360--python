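"""Highlight image cues and specular-component manipulations.

Three cues of the specular highlights are measured from separately stored
image components:

* **coverage** — fraction of pixels brighter in the composite than in the
  diffuse component alone;
* **sharpness** — cross-scale phase agreement of a 3-scale, 4-orientation
  complex log-Gabor decomposition, weighted by fine-scale energy and averaged
  over the highlight region (a local-phase-coherence score: intensity-scaling
  invariant, reduced by blur);
* **contrast** — summed root-mean-square contrast over eight octave-spaced
  bandpass-filtered versions of the specular component.

Four manipulations weaken (or, for translation, merely displace) the
specular component before recombination with the diffuse component:
rightward translation in five-pixel steps, morphological erosion (2x2
kernel), Gaussian blur of growing kernel width, and multiplicative reduction
of the highlight-pixel standard deviation with the mean preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .world import grey601

__all__ = [
    "CueProfile", "measure_coverage", "measure_sharpness", "measure_contrast",
    "measure_cues", "manipulate_specular", "recombine", "cue_decoding",
    "cue_response_curves", "HIGHLIGHT_THRESHOLD",
]

#: Highlight mask threshold on the BT.601 greyscale of the specular
#: component, on the 0-255 convention.
HIGHLIGHT_THRESHOLD = 4.0 / 255.0


@dataclass
class CueProfile:
    coverage: float
    sharpness: float
    contrast: float
    image_id: str = ""

    def __post_init__(self):
        if not (0 <= self.coverage <= 1):
            raise ValueError("coverage must lie in [0, 1]")
        if not np.isfinite([self.coverage, self.sharpness, self.contrast]).all():
            raise ValueError("cue values must be finite")


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def measure_coverage(composite: np.ndarray, diffuse: np.ndarray,
                     tol: float = 0.5 / 255.0) -> float:
    """Fraction of pixels with higher greyscale intensity in the composite
    than in the diffuse component image.

    The default tolerance is half an 8-bit quantization level, matching the
    0-255 image convention: a specular contribution below one grey level does
    not count as a visible highlight.
    """
    if composite.shape != diffuse.shape:
        raise ValueError("shape mismatch")
    return float(np.mean(grey601(composite) > grey601(diffuse) + tol))


def _mirror_fft(g: np.ndarray) -> np.ndarray:
    """FFT of the 2N x 2N symmetric (mirror) extension of an N x N image.

    The extension is continuous across the periodic seams, so high-frequency
    filter responses measure image structure rather than wrap-around edges.
    Responses are computed at 2N and cropped back to the original window.
    """
    return np.fft.fft2(np.pad(g, ((0, g.shape[0]), (0, g.shape[1])),
                              mode="symmetric"))


def _phase_bank(size: int, scales: int = 3, orientations: int = 4):
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.sqrt(fx**2 + fy**2)
    theta = np.arctan2(fy, fx)
    f[0, 0] = 1.0
    bank = []
    for o in range(orientations):
        ang0 = o * np.pi / orientations
        d = np.angle(np.exp(1j * (theta - ang0)))
        angular = np.exp(-(d**2) / (2 * (np.pi / orientations / 1.2) ** 2))
        per_scale = []
        for s in range(scales):
            f0 = 0.25 / (2**s)
            radial = np.exp(-(np.log(f / f0) ** 2) / (2 * np.log(0.65) ** 2))
            radial[0, 0] = 0.0
            per_scale.append(radial * angular)
        bank.append(per_scale)
    return bank


_BANK_CACHE: dict = {}


def measure_sharpness(specular: np.ndarray) -> float:
    """Local phase coherence of the specular component.

    For each orientation, complex responses r1 (fine) .. r3 (coarse) of a
    log-Gabor pyramid are combined as |r1 + r2 + r3| (large only where the
    scales agree in phase) weighted against the total band energy
    (|r1|+|r2|+|r3|), with the numerator carrying the fine-scale response so
    blurring — which removes fine-scale energy but leaves phases untouched —
    lowers the score.  Averaged over the highlight region; a constant image
    scores 0; intensity scaling leaves the score unchanged.
    """
    g = grey601(specular) if specular.ndim == 3 else np.asarray(specular, dtype=float)
    size = g.shape[0]
    if np.ptp(g) < 1e-12:
        return 0.0
    if 2 * size not in _BANK_CACHE:
        _BANK_CACHE[2 * size] = _phase_bank(2 * size)
    bank = _BANK_CACHE[2 * size]
    mask = g > max(HIGHLIGHT_THRESHOLD, 0.05 * g.max())
    if not mask.any():
        mask = np.ones_like(g, dtype=bool)
    G = _mirror_fft(g)
    num = np.zeros_like(g)
    den = np.zeros_like(g)
    for per_scale in bank:
        rs = [np.fft.ifft2(G * filt)[:size, :size] for filt in per_scale]
        aligned = np.abs(sum(rs))
        energy = sum(np.abs(r) for r in rs)
        fine_frac = np.abs(rs[0])
        num += aligned * fine_frac
        den += energy * (energy / 3.0)
    score = np.sum(num[mask]) / (np.sum(den[mask]) + 1e-12)
    return float(score)


def _contrast_bank(size: int, n_bands: int = 8):
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.sqrt(fx**2 + fy**2)
    f[0, 0] = 1e-9
    bands = []
    for b in range(n_bands):
        f0 = 0.5 / (2**b)  # octave-spaced centre frequencies from Nyquist down
        filt = np.exp(-(np.log2(f / f0) ** 2) / (2 * 0.4**2))
        filt[0, 0] = 0.0
        bands.append(filt)
    return bands


_CONTRAST_CACHE: dict = {}


def measure_contrast(specular: np.ndarray) -> float:
    """Sum of RMS contrast over eight octave-spaced bandpass versions of the
    (greyscale) specular component.  Homogeneous of degree 1 in intensity;
    zero for a constant image (bandpass removes DC)."""
    g = grey601(specular) if specular.ndim == 3 else np.asarray(specular, dtype=float)
    size = g.shape[0]
    if 2 * size not in _CONTRAST_CACHE:
        _CONTRAST_CACHE[2 * size] = _contrast_bank(2 * size)
    G = _mirror_fft(g)
    total = 0.0
    for filt in _CONTRAST_CACHE[2 * size]:
        band = np.fft.ifft2(G * filt).real[:size, :size]
        total += float(np.sqrt(np.mean(band**2)))
    return total


def measure_cues(composite: np.ndarray, diffuse: np.ndarray,
                 specular: np.ndarray, image_id: str = "") -> CueProfile:
    return CueProfile(coverage=measure_coverage(composite, diffuse),
                      sharpness=measure_sharpness(specular),
                      contrast=measure_contrast(specular),
                      image_id=image_id)


# ---------------------------------------------------------------------------
# manipulations
# ---------------------------------------------------------------------------

_KINDS = ("translate", "erode", "blur", "contrast")


def _gauss_kernel(width: int) -> np.ndarray:
    if width <= 1:
        return np.ones((1,))
    x = np.arange(width) - (width - 1) / 2.0
    k = np.exp(-(x**2) / (2 * (width / 3.0) ** 2))
    return k / k.sum()


def manipulate_specular(specular: np.ndarray, kind: str, step: int,
                        margin: int = 0, shift_px: int = 5) -> np.ndarray:
    """Apply one weakening/displacement manipulation at the given step (1-10).

    For ``translate`` the input must carry an oversized render margin (the
    image is shifted rightward by ``shift_px * step`` pixels and the central
    window re-cropped), so `margin >= shift_px * 10`.  ``erode`` applies
    `step` iterations of greyscale morphological erosion with a 2x2 kernel
    per channel; ``blur`` convolves with a Gaussian kernel of width
    ``1 + step`` (growing 2x2 .. 11x11); ``contrast`` multiplies the
    highlight-pixel standard deviation by ``1 - 0.09 * step`` (1.0 down to
    0.1) with the per-channel highlight mean preserved.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown manipulation kind {kind!r}")
    if not 0 <= step <= 10:
        raise ValueError("step must lie in 0..10")
    spec = np.asarray(specular, dtype=np.float64)
    if step == 0:
        if kind == "translate":
            return spec[margin:-margin or None, margin:-margin or None]
        return spec.copy()
    if kind == "translate":
        total = shift_px * step
        if margin < shift_px * 10:
            raise ValueError("translate needs an oversized render margin")
        out = np.roll(spec, total, axis=1)
        return out[margin:-margin or None, margin:-margin or None]
    if kind == "erode":
        out = spec.copy()
        footprint = np.ones((2, 2), dtype=bool)
        for _ in range(step):
            for c in range(out.shape[-1] if out.ndim == 3 else 1):
                channel = out[..., c] if out.ndim == 3 else out
                eroded = ndimage.grey_erosion(channel, footprint=footprint)
                if out.ndim == 3:
                    out[..., c] = eroded
                else:
                    out = eroded
        return out
    if kind == "blur":
        k = _gauss_kernel(1 + step)
        out = ndimage.convolve1d(spec, k, axis=0, mode="nearest")
        return ndimage.convolve1d(out, k, axis=1, mode="nearest")
    # contrast
    factor = 1.0 - 0.09 * step
    mask = grey601(spec) > HIGHLIGHT_THRESHOLD if spec.ndim == 3 else spec > HIGHLIGHT_THRESHOLD
    out = spec.copy()
    if not mask.any():
        return out
    if out.ndim == 3:
        for c in range(3):
            vals = out[..., c][mask]
            mu = vals.mean()
            out[..., c][mask] = mu + factor * (vals - mu)
    else:
        vals = out[mask]
        mu = vals.mean()
        out[mask] = mu + factor * (vals - mu)
    return out


def recombine(diffuse: np.ndarray, specular: np.ndarray) -> np.ndarray:
    """Clipped sum of the diffuse and (possibly manipulated) specular
    components — the renderer's composite convention."""
    if diffuse.shape != specular.shape:
        raise ValueError("shape mismatch")
    return np.clip(diffuse + specular, 0.0, 1.0)


# ---------------------------------------------------------------------------
# cue-based analyses
# ---------------------------------------------------------------------------

def cue_decoding(features: np.ndarray, cue_profiles, split_seed: int = 0) -> dict:
    """Held-out R^2 of linear regressions from latent features to each cue,
    plus the mean over the three cues."""
    from .decoding import regress_relief, train_test_split_indices

    cov = np.array([c.coverage for c in cue_profiles])
    sha = np.array([c.sharpness for c in cue_profiles])
    con = np.array([c.contrast for c in cue_profiles])
    train_idx, test_idx = train_test_split_indices(len(cov), split_seed)
    out = {}
    for name, y in (("coverage", cov), ("sharpness", sha), ("contrast", con)):
        rep = regress_relief(features, y, split_seed, train_idx=train_idx,
                             test_idx=test_idx)
        out[name] = rep.score
    out["mean"] = float(np.mean([out["coverage"], out["sharpness"], out["contrast"]]))
    return out


def cue_response_curves(predict_fn, sequences, kinds=("contrast", "blur", "erode", "translate"),
                        steps=range(0, 11), shift_px: int = 5) -> dict:
    """Predicted gloss at each manipulation step relative to the original.

    `sequences` is a list of (diffuse, specular, margin) triples where the
    components carry an oversized margin; `predict_fn` maps a composite
    [0,1] image to a scalar gloss prediction.  Returns per-kind arrays of
    shape (n_sequences, n_steps) of relative predicted gloss (step 0 is 0 by
    construction) plus mean/sd summaries.
    """
    steps = list(steps)
    out = {}
    for kind in kinds:
        rows = []
        for diffuse, specular, margin in sequences:
            m = margin
            dif_c = diffuse[m:-m or None, m:-m or None]
            vals = []
            for k in steps:
                if kind == "translate":
                    spec_k = manipulate_specular(specular, kind, k, margin=m,
                                                 shift_px=shift_px)
                else:
                    spec_full = manipulate_specular(specular, kind, k)
                    spec_k = spec_full[m:-m or None, m:-m or None]
                vals.append(float(predict_fn(recombine(dif_c, spec_k))))
            vals = np.asarray(vals)
            rows.append(vals - vals[0])
        arr = np.stack(rows)
        out[kind] = {"relative": arr, "mean": arr.mean(axis=0), "sd": arr.std(axis=0)}
    return out
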