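"""Procedural simulated world of glossy and matte bumpy surfaces.

The world is a 40x40-unit sheet with irregularly placed smooth bumps, viewed
top-down and lit by one of six fixed multi-directional light fields (or by a
single directional lamp at a stated elevation).  Surface material is a
Lambertian diffuse component (per-channel albedo) plus a Blinn-style specular
lobe parameterized by a magnitude (strength) and a concentration (lobe
tightness).  Diffuse and specular components are rendered and stored
separately; the displayed image is their clipped sum.

Four sampling regimes are provided:

* ``bimodal`` — half the scenes low gloss (magnitude U[0.1,0.3], concentration
  U[0.2,0.4]), half high gloss (U[0.3,0.5], U[0.75,0.95]);
* ``continuous`` — magnitude and concentration independently U[0.1,0.8];
* ``rating_probe`` — magnitude U[0.2,1.0] with concentration equal to it;
* ``higher_variation`` — ten bump-kernel families x 50 seeded light fields
  with camera-height jitter, for the wider-visual-diet condition.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WorldConfig", "SceneParams", "LightField", "RenderedScene",
    "sample_scene", "build_heightfield", "render_scene", "generate_dataset",
    "render_dataset", "render_relief_sequence", "render_pair_set",
    "RELIEF_SCHEDULE_GEOMETRIC", "RELIEF_SCHEDULE_PRINTED",
    "lamp_lightfield", "grey601",
]

#: Default 7-step relief schedule: geometric progression 0.10 -> 3.0.
RELIEF_SCHEDULE_GEOMETRIC = tuple(float(x) for x in np.geomspace(0.10, 3.0, 7).round(4))
#: The alternative as-printed schedule (non-monotonic at step 6).
RELIEF_SCHEDULE_PRINTED = (0.10, 0.18, 0.31, 0.55, 0.97, 0.70, 3.0)

_BT601 = np.array([0.299, 0.587, 0.114])


def grey601(img: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luma of an (H, W, 3) image."""
    return img @ _BT601


# ---------------------------------------------------------------------------
# configuration & scene state
# ---------------------------------------------------------------------------

_REGIMES = ("bimodal", "continuous", "rating_probe", "higher_variation")


@dataclass(frozen=True)
class WorldConfig:
    image_size: int = 64
    sheet_extent: float = 40.0
    #: scene units visible across the image: the camera hovers close above the
    #: sheet, so each rendering shows a sub-window of it (bumps appear large)
    view_extent: float = 14.0
    n_lightfields: int = 6
    relief_range: tuple = (0.1, 2.5)
    albedo_range: tuple = (0.3, 0.7)
    gloss_regime: str = "bimodal"
    bimodal_low: tuple = ((0.1, 0.3), (0.2, 0.4))
    bimodal_high: tuple = ((0.3, 0.5), (0.75, 0.95))
    continuous_range: tuple = (0.1, 0.8)
    rating_probe_range: tuple = (0.2, 1.0)
    camera_jitter: float = 4.0  # max |translation| in scene units; rotation up to same value in degrees
    master_seed: int = 0
    lighting_seed: int = 1234  # fixes the six light fields

    def __post_init__(self):
        if self.gloss_regime not in _REGIMES:
            raise ValueError(f"unknown gloss regime {self.gloss_regime!r}")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.n_lightfields < 2:
            raise ValueError("need at least 2 light fields")
        for name in ("relief_range", "albedo_range", "continuous_range", "rating_probe_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must satisfy min <= max")
        for rng_pair in (*self.bimodal_low, *self.bimodal_high):
            lo, hi = rng_pair
            if not (0 <= lo <= hi):
                raise ValueError("gloss ranges must be ordered and non-negative")
        lo, hi = self.albedo_range
        if not (0 <= lo and hi <= 1):
            raise ValueError("albedo must be a reflectance fraction in [0,1]")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


@dataclass(frozen=True)
class SceneParams:
    lightfield_id: int
    relief_depth: float
    albedo: tuple  # 3 reflectance fractions
    spec_magnitude: float
    spec_concentration: float
    gloss_label: str  # low / high / unlabeled
    bump_seed: int
    camera_offset: tuple = (0.0, 0.0, 0.0)  # dx, dy (scene units), rotation (deg)
    camera_scale: float = 1.0
    lighting_angle: float | None = None  # lamp elevation in degrees; None = light field
    bump_family: int = 0

    def replace(self, **kw) -> "SceneParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class LightField:
    lights: tuple  # of (direction unit 3-vec, intensity, color 3-vec)
    ambient: float


@dataclass
class RenderedScene:
    diffuse: np.ndarray
    specular: np.ndarray  # pre-clipping specular component
    composite: np.ndarray
    params: SceneParams

    def __post_init__(self):
        if not (np.isfinite(self.diffuse).all() and np.isfinite(self.specular).all()):
            raise ValueError("non-finite image values")


# ---------------------------------------------------------------------------
# light fields
# ---------------------------------------------------------------------------

def _build_lightfield(lightfield_id: int, lighting_seed: int) -> LightField:
    """Deterministic multi-directional light set for one environment id.

    Each id gets 8-16 directional lights clustered around a distinct dominant
    azimuth, a colour-temperature tint, and an ambient term; total intensity
    is normalized so a flat white Lambertian sheet has mean composite
    intensity in [0.3, 0.8].
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(lighting_seed), int(lightfield_id)]))
    # dense enough that a tight specular lobe always reflects *something*,
    # approximating the angular richness of a natural environment
    n_lights = int(rng.integers(32, 49))
    dominant_az = lightfield_id * (2 * np.pi / 6) + rng.uniform(-0.3, 0.3)
    az = dominant_az + rng.normal(0, 1.4, n_lights)
    # a third of the sources sit near the zenith (sky / ceiling), so even a
    # nearly flat glossy sheet reflects something toward the top-down viewer
    n_zenith = n_lights // 3
    # environments also differ systematically in how low their dominant
    # sources sit (sunset-like vs overhead-lit), like distinct natural scenes
    elev_lo = 10.0 + 6.0 * (lightfield_id % 3)
    elev = np.deg2rad(np.concatenate([
        rng.uniform(elev_lo, elev_lo + 40.0, n_lights - n_zenith),
        rng.uniform(60, 88, n_zenith),
    ]))
    dirs = np.stack([np.cos(elev) * np.cos(az), np.cos(elev) * np.sin(az), np.sin(elev)], axis=1)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    # heavy-tailed intensities: a few dominant sources plus many dim ones,
    # like sun/sky or window/interior environments
    raw_int = rng.lognormal(0.0, 1.0, n_lights)
    # strongly identity-linked colour temperature and overall level, so the
    # six environments are as distinct as natural light probes
    temp = (lightfield_id % 6 - 2.5) / 2.5 + rng.uniform(-0.15, 0.15)
    color = np.clip(np.array([1.0 + 0.22 * temp, 1.0, 1.0 - 0.22 * temp]), 0.0, None)
    ambient = rng.uniform(0.05, 0.15)
    # normalize so a flat white Lambertian sheet renders at the target mean
    target = 0.42 + 0.04 * (lightfield_id % 6) + rng.uniform(0.0, 0.03)
    flat = float(np.sum(raw_int * dirs[:, 2]) * color.mean()) + ambient
    scale = (target - ambient) / max(flat - ambient, 1e-9)
    lights = tuple(
        (tuple(dirs[i]), float(raw_int[i] * scale), tuple(color)) for i in range(n_lights)
    )
    return LightField(lights=lights, ambient=float(ambient))


def lamp_lightfield(angle_deg: float) -> LightField:
    """Single directional lamp at the given elevation angle (e.g. 30 or 90)."""
    e = np.deg2rad(angle_deg)
    d = (float(np.cos(e)), 0.0, float(np.sin(e)))
    return LightField(lights=((d, 0.55, (1.0, 1.0, 1.0)),), ambient=0.08)


_LF_CACHE: dict = {}


def get_lightfield(params: SceneParams, config: WorldConfig) -> LightField:
    if params.lighting_angle is not None:
        return lamp_lightfield(params.lighting_angle)
    key = (config.lighting_seed, params.lightfield_id)
    if key not in _LF_CACHE:
        _LF_CACHE[key] = _build_lightfield(params.lightfield_id, config.lighting_seed)
    return _LF_CACHE[key]


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_scene(config: WorldConfig, rng: np.random.Generator) -> SceneParams:
    """Draw one scene's world state under the configured regime."""
    regime = config.gloss_regime
    relief = float(rng.uniform(*config.relief_range))
    albedo = tuple(float(a) for a in rng.uniform(*config.albedo_range, size=3))
    family = 0
    cam_scale = 1.0
    if regime == "bimodal":
        if rng.random() < 0.5:
            (mlo, mhi), (clo, chi) = config.bimodal_low
            label = "low"
        else:
            (mlo, mhi), (clo, chi) = config.bimodal_high
            label = "high"
        mag = float(rng.uniform(mlo, mhi))
        conc = float(rng.uniform(clo, chi))
    elif regime == "continuous":
        mag = float(rng.uniform(*config.continuous_range))
        conc = float(rng.uniform(*config.continuous_range))
        label = "unlabeled"
    elif regime == "rating_probe":
        mag = float(rng.uniform(*config.rating_probe_range))
        conc = mag
        label = "unlabeled"
    elif regime == "higher_variation":
        mag = float(rng.uniform(*config.continuous_range))
        conc = float(rng.uniform(*config.continuous_range))
        label = "unlabeled"
        family = int(rng.integers(0, 10))
        cam_scale = float(rng.uniform(0.8, 1.2))
    else:  # pragma: no cover - guarded in WorldConfig
        raise ValueError(f"unknown gloss regime {regime!r}")
    lf_id = int(rng.integers(0, 50 if regime == "higher_variation" else config.n_lightfields))
    j = config.camera_jitter
    offset = (float(rng.uniform(-j, j)), float(rng.uniform(-j, j)), float(rng.uniform(-j, j)))
    return SceneParams(
        lightfield_id=lf_id, relief_depth=relief, albedo=albedo,
        spec_magnitude=mag, spec_concentration=conc, gloss_label=label,
        bump_seed=int(rng.integers(0, 2**31 - 1)), camera_offset=offset,
        camera_scale=cam_scale, bump_family=family,
    )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _bump_layout(bump_seed: int, family: int, extent: float):
    """Random radial-kernel layout on the sheet, fixed by (bump_seed, family)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(bump_seed), int(family)]))
    n_bumps = int(rng.integers(40, 70))
    margin = 0.15 * extent
    centers = rng.uniform(-extent / 2 - margin, extent / 2 + margin, size=(n_bumps, 2))
    # family 0 is the default bump world; other families vary kernel widths,
    # allow indentations, and stretch kernels into ridges
    if family == 0:
        widths = rng.uniform(1.5, 4.0, size=n_bumps)
        amps = rng.uniform(0.3, 1.0, size=n_bumps)
        aniso = np.ones(n_bumps)
        theta = np.zeros(n_bumps)
    else:
        frng = np.random.default_rng(np.random.SeedSequence([9917, int(family)]))
        wlo = float(frng.uniform(0.8, 2.5))
        whi = wlo + float(frng.uniform(1.0, 4.0))
        p_neg = float(frng.uniform(0.0, 0.5))
        max_aniso = float(frng.uniform(1.0, 3.0))
        widths = rng.uniform(wlo, whi, size=n_bumps)
        signs = np.where(rng.random(n_bumps) < p_neg, -1.0, 1.0)
        amps = rng.uniform(0.3, 1.0, size=n_bumps) * signs
        aniso = rng.uniform(1.0, max_aniso, size=n_bumps)
        theta = rng.uniform(0, np.pi, size=n_bumps)
    return centers, widths, amps, aniso, theta


def _eval_height(x: np.ndarray, y: np.ndarray, layout) -> np.ndarray:
    centers, widths, amps, aniso, theta = layout
    h = np.zeros_like(x)
    ct, st = np.cos(theta), np.sin(theta)
    for k in range(len(widths)):
        dx = x - centers[k, 0]
        dy = y - centers[k, 1]
        u = ct[k] * dx + st[k] * dy
        v = -st[k] * dx + ct[k] * dy
        r2 = (u / (widths[k] * aniso[k])) ** 2 + (v / widths[k]) ** 2
        h += amps[k] * np.exp(-0.5 * r2)
    return h


def _pixel_grid(params: SceneParams, config: WorldConfig, size: int, margin_px: int = 0):
    """Scene-unit coordinates of each pixel centre under the camera pose."""
    n = size + 2 * margin_px
    half = config.view_extent / 2 * (n / size) * params.camera_scale
    coords = (np.arange(n) + 0.5) / n * 2 * half - half
    xg, yg = np.meshgrid(coords, coords)  # x rightward, y downward
    dx, dy, rot = params.camera_offset
    a = np.deg2rad(rot)
    xr = np.cos(a) * xg - np.sin(a) * yg + dx
    yr = np.sin(a) * xg + np.cos(a) * yg + dy
    return xr, yr


def build_heightfield(params: SceneParams, size: int, config: WorldConfig | None = None,
                      margin_px: int = 0) -> np.ndarray:
    """Elevation grid whose range (max - min) equals ``relief_depth`` exactly.

    Deterministic given (bump_seed, bump_family, size, relief_depth, camera
    pose).  A zero relief yields a constant grid; depth only rescales the
    fixed bump layout.
    """
    if size < 16:
        raise ValueError("size must be >= 16")
    cfg = config or WorldConfig(image_size=size)
    layout = _bump_layout(params.bump_seed, params.bump_family, cfg.sheet_extent)
    x, y = _pixel_grid(params, cfg, size, margin_px)
    h = _eval_height(x, y, layout)
    if np.isnan(h).any():
        raise ValueError("NaN elevation")
    h_min, h_max = h.min(), h.max()
    if h_max - h_min < 1e-12 or params.relief_depth == 0:
        return np.zeros_like(h)
    return (h - h_min) / (h_max - h_min) * params.relief_depth


# ---------------------------------------------------------------------------
# shading
# ---------------------------------------------------------------------------

# Blinn lobe shininess: concentration 0.2 -> ~5 (broad), 0.95 -> ~200 (tight)
_SHINE_B = float(np.log(200.0 / 5.0) / 0.75)
_SHINE_A = float(np.log(5.0) - 0.2 * _SHINE_B)


def shininess(concentration: float) -> float:
    return float(np.exp(_SHINE_A + _SHINE_B * concentration))


def render_scene(params: SceneParams, config: WorldConfig, size: int | None = None,
                 margin_px: int = 0) -> RenderedScene:
    """Render diffuse + specular components from the heightfield normals.

    Normals come from central finite differences of the elevation grid; the
    viewer is top-down, so the Blinn half-vector is h = normalize(l + z).
    """
    size = size or config.image_size
    h = build_heightfield(params, size, config, margin_px=margin_px)
    spacing = config.view_extent / size * params.camera_scale
    gy, gx = np.gradient(h, spacing)
    norm = np.sqrt(gx**2 + gy**2 + 1.0)
    nx, ny, nz = -gx / norm, -gy / norm, 1.0 / norm

    lf = get_lightfield(params, config)
    albedo = np.asarray(params.albedo)
    shin = shininess(params.spec_concentration)
    diffuse = np.zeros(h.shape + (3,))
    specular = np.zeros_like(diffuse)
    view = np.array([0.0, 0.0, 1.0])
    for (ld, intensity, color) in lf.lights:
        ld = np.asarray(ld)
        ndotl = np.clip(nx * ld[0] + ny * ld[1] + nz * ld[2], 0.0, None)
        half = ld + view
        half = half / np.linalg.norm(half)
        ndoth = np.clip(nx * half[0] + ny * half[1] + nz * half[2], 0.0, None)
        col = np.asarray(color)
        diffuse += intensity * ndotl[..., None] * col
        # energy-normalized Blinn lobe: tighter lobes get brighter peaks
        specular += intensity * ((shin + 2.0) / 4.0) * (ndoth**shin)[..., None] * col
    diffuse = albedo * diffuse + lf.ambient * albedo
    specular = params.spec_magnitude * specular
    composite = np.clip(diffuse + specular, 0.0, 1.0)
    return RenderedScene(diffuse=diffuse, specular=specular,
                         composite=composite, params=params)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

_MANIFEST_COLS = [
    "index", "split", "lightfield_id", "lighting_angle", "relief_depth",
    "albedo_r", "albedo_g", "albedo_b", "spec_magnitude", "spec_concentration",
    "gloss_label", "bump_seed", "cam_dx", "cam_dy", "cam_rot", "camera_scale",
    "bump_family", "path",
]


def _params_row(i: int, split: str, p: SceneParams, path: str = "") -> dict:
    return {
        "index": i, "split": split, "lightfield_id": p.lightfield_id,
        "lighting_angle": "" if p.lighting_angle is None else p.lighting_angle,
        "relief_depth": p.relief_depth, "albedo_r": p.albedo[0],
        "albedo_g": p.albedo[1], "albedo_b": p.albedo[2],
        "spec_magnitude": p.spec_magnitude, "spec_concentration": p.spec_concentration,
        "gloss_label": p.gloss_label, "bump_seed": p.bump_seed,
        "cam_dx": p.camera_offset[0], "cam_dy": p.camera_offset[1],
        "cam_rot": p.camera_offset[2], "camera_scale": p.camera_scale,
        "bump_family": p.bump_family, "path": path,
    }


def split_of(i: int, n: int) -> str:
    """Deterministic 90/5/5 split by position (first train, then val, test)."""
    if i < int(n * 0.9):
        return "train"
    if i < int(n * 0.95):
        return "val"
    return "test"


def render_dataset(config: WorldConfig, n: int, seed: int | None = None):
    """Sample and render `n` scenes in memory.

    Returns (images float array (n, s, s, 3) in [0,1], manifest DataFrame).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seed = config.master_seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    s = config.image_size
    images = np.empty((n, s, s, 3), dtype=np.float32)
    rows = []
    for i in range(n):
        p = sample_scene(config, rng)
        images[i] = render_scene(p, config).composite
        rows.append(_params_row(i, split_of(i, n), p))
    manifest = pd.DataFrame(rows, columns=_MANIFEST_COLS)
    return images, manifest


def generate_dataset(config: WorldConfig, n: int, seed: int | None = None,
                     out_dir: str | Path | None = None):
    """Render a dataset and (optionally) write PNGs + manifest CSV + config JSON.

    Images are stored as 8-bit RGB PNG with linear (no gamma) encoding;
    quantization to 8 bits happens only at file write.
    """
    images, manifest = render_dataset(config, n, seed)
    if out_dir is not None:
        import imageio.v3 as iio

        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        paths = []
        for i in range(n):
            rel = f"images/{i:06d}.png"
            iio.imwrite(out_dir / rel, (images[i] * 255).round().astype(np.uint8))
            paths.append(rel)
        manifest = manifest.assign(path=paths)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        sidecar = {"config": json.loads(config.to_json()),
                   "seed": int(config.master_seed if seed is None else seed),
                   "n": n, "encoding": "linear RGB, 8-bit quantized at write"}
        (out_dir / "manifest.json").write_text(json.dumps(sidecar, indent=2))
    return images, manifest


def manifest_csv_bytes(manifest: pd.DataFrame) -> bytes:
    buf = io.StringIO()
    manifest.to_csv(buf, index=False)
    return buf.getvalue().encode()


# ---------------------------------------------------------------------------
# experiment stimulus sets
# ---------------------------------------------------------------------------

def render_relief_sequence(params: SceneParams, config: WorldConfig,
                           reliefs=RELIEF_SCHEDULE_GEOMETRIC,
                           size: int | None = None) -> list:
    """Render the same scene at each relief depth (material, lighting, camera
    and bump layout held fixed)."""
    if any(r <= 0 for r in reliefs):
        raise ValueError("reliefs must be positive")
    return [render_scene(params.replace(relief_depth=float(r)), config, size=size)
            for r in reliefs]


_PAIR_GROUPS = {
    1: "same-lightfield/different-relief",
    2: "same-lamp/different-relief",
    3: "same-relief/different-lightfield",
    4: "same-relief/different-lamp-angle",
}
_PAIR_RELIEFS = (0.40, 1.5)
_LAMP_ANGLES = (30.0, 90.0)


def render_pair_set(config: WorldConfig, group: int, n_candidates: int, seed: int) -> list:
    """Candidate scene-parameter pairs for the constancy-degree comparisons.

    Each pair shares material and camera; the differing factor depends on the
    group: (1) relief differs under a shared natural light field, (2) relief
    differs under a shared lamp, (3) light field differs at shared relief,
    (4) lamp angle (30 vs 90 degrees) differs at shared relief.
    """
    if group not in _PAIR_GROUPS:
        raise ValueError(f"unknown pair group {group}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(group)]))
    pairs = []
    for _ in range(n_candidates):
        base = sample_scene(config, rng)
        if group == 1:
            a = base.replace(relief_depth=_PAIR_RELIEFS[0])
            b = base.replace(relief_depth=_PAIR_RELIEFS[1])
        elif group == 2:
            angle = float(rng.choice(_LAMP_ANGLES))
            a = base.replace(relief_depth=_PAIR_RELIEFS[0], lighting_angle=angle)
            b = base.replace(relief_depth=_PAIR_RELIEFS[1], lighting_angle=angle)
        elif group == 3:
            ids = rng.choice(config.n_lightfields, size=2, replace=False)
            a = base.replace(lightfield_id=int(ids[0]))
            b = base.replace(lightfield_id=int(ids[1]))
        else:
            a = base.replace(lighting_angle=_LAMP_ANGLES[0])
            b = base.replace(lighting_angle=_LAMP_ANGLES[1])
        pairs.append((a, b))
    return pairs
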