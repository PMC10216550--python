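"""Synthetic bright-field scene generator.

Emulates label-free microscopy frames of adherent cell cultures for
end-to-end testing of the restoration/classification pipeline: a bright
background carrying a media-dependent texture field, cell-like dark blobs
whose expected count encodes the density class, a multiplicative vignette
(radial brightness falloff), additive stripe / dust / lens-flare artifacts,
and Poisson + Gaussian noise.  Every scene is deterministic given its
config (including the seed), and the generator exposes its ground truth —
the exact vignette field, blob placement log and background mask — so
restoration quality can be scored against a known answer.

Composition order: ``clip(vignette * (background + texture + blobs)
+ artifacts + noise)``.

Classes:

* density: low / medium / high expected blob counts (Poisson draws);
* media: A / B / C differ by the spatial-correlation length of the
  background texture (filtered white noise), standing in for
  media-dependent morphology differences.

Per-scene nuisance variation (vignette strength jitter and center offset,
random artifact parameters) mimics field-to-field variability of a real
screening system, so illumination acts as a confound rather than a fixed
offset that a classifier could simply absorb.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

__all__ = ["SceneConfig", "LabeledImage", "generate_scene", "generate_dataset", "write_dataset"]

DENSITY_CLASSES = ("low", "medium", "high")
MEDIA_CLASSES = ("A", "B", "C")
ARTIFACTS = ("stripe", "dust", "flare")

#: media class -> spatial-correlation length (px) of the texture field
DEFAULT_TEXTURE_GRAIN = {"A": 1.5, "B": 3.0, "C": 6.0}
#: density class -> expected blob count per frame
DEFAULT_BLOB_MEANS = {"low": 15.0, "medium": 40.0, "high": 80.0}


@dataclass(frozen=True)
class SceneConfig:
    """Full recipe for one scene; identical configs give identical pixels."""

    height: int = 192
    width: int = 256
    bit_depth: int = 16
    density_class: str = "medium"
    media_class: str = "A"
    blob_count_means: dict = field(default_factory=lambda: dict(DEFAULT_BLOB_MEANS))
    blob_radius_range: tuple[float, float] = (4.0, 10.0)
    blob_amplitude: float = 0.12  # fraction of dynamic range (darkening)
    background_level: float = 0.60  # fraction of dynamic range
    texture_grain: dict = field(default_factory=lambda: dict(DEFAULT_TEXTURE_GRAIN))
    texture_contrast: float = 0.04  # fraction of dynamic range (sd)
    vignette_strength: float = 0.5
    vignette_profile: str = "radial_gaussian"
    vignette_jitter: float = 0.2  # relative strength jitter + center offset
    artifact_set: tuple[str, ...] = ARTIFACTS
    stripe_amplitude: float = 0.015
    dust_mean_count: float = 8.0
    flare_amplitude: float = 0.08
    noise_gaussian_sd: float = 0.01  # fraction of dynamic range
    noise_poisson_scale: float = 0.05  # expected counts per intensity unit
    seed: int = 0

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValueError(f"non-positive dimensions {self.height}x{self.width}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.density_class not in DENSITY_CLASSES:
            raise ValueError(f"unknown density_class {self.density_class!r}")
        if self.media_class not in MEDIA_CLASSES:
            raise ValueError(f"unknown media_class {self.media_class!r}")
        unknown = set(self.artifact_set) - set(ARTIFACTS)
        if unknown:
            raise ValueError(f"unknown artifact name(s) {sorted(unknown)}; allowed: {ARTIFACTS}")
        if not (0.0 <= self.vignette_strength < 1.0):
            raise ValueError(f"vignette_strength must be in [0, 1), got {self.vignette_strength}")
        if self.vignette_profile not in ("radial_gaussian", "radial_poly4"):
            raise ValueError(f"unknown vignette_profile {self.vignette_profile!r}")
        means = [self.blob_count_means[c] for c in DENSITY_CLASSES]
        if not (means[0] < means[1] < means[2]):
            raise ValueError("blob_count_means must be strictly increasing low < medium < high")

    @property
    def max_value(self) -> float:
        return float(2**self.bit_depth - 1)


@dataclass
class LabeledImage:
    """A generated scene plus its labels and generator ground truth."""

    image: np.ndarray
    density_label: str
    media_label: str
    ground_truth: SceneConfig
    vignette_field: np.ndarray
    blob_centers: np.ndarray  # (n, 2) row/col placement log
    background_mask: np.ndarray  # True where no blob was rendered


def _vignette_field(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative field: 1 at center, ~(1 - strength) at the corners."""
    if cfg.vignette_strength == 0.0:
        return np.ones((cfg.height, cfg.width))
    strength = cfg.vignette_strength
    cy, cx = (cfg.height - 1) / 2.0, (cfg.width - 1) / 2.0
    if cfg.vignette_jitter > 0:
        strength = strength * float(rng.uniform(1 - cfg.vignette_jitter, 1 + cfg.vignette_jitter))
        strength = min(strength, 0.95)
        cy += float(rng.uniform(-0.08, 0.08)) * cfg.height
        cx += float(rng.uniform(-0.08, 0.08)) * cfg.width
    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    corners = [(0, 0), (0, cfg.width - 1), (cfg.height - 1, 0), (cfg.height - 1, cfg.width - 1)]
    r2_corner = max((y - cy) ** 2 + (x - cx) ** 2 for y, x in corners)
    if cfg.vignette_profile == "radial_gaussian":
        sigma2 = r2_corner / (2.0 * np.log(1.0 / (1.0 - strength)))
        return 1.0 - strength * (1.0 - np.exp(-r2 / (2.0 * sigma2))) / (
            1.0 - np.exp(-r2_corner / (2.0 * sigma2))
        )
    rho2 = r2 / r2_corner  # radial_poly4
    return 1.0 - strength * (0.5 * rho2 + 0.5 * rho2**2)


def _texture_field(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Stationary Gaussian random field with media-dependent correlation length."""
    from scipy.ndimage import gaussian_filter

    grain = float(cfg.texture_grain[cfg.media_class])
    white = rng.standard_normal((cfg.height, cfg.width))
    smooth = gaussian_filter(white, sigma=grain, mode="wrap")
    sd = smooth.std() or 1.0
    return smooth / sd * (cfg.texture_contrast * cfg.max_value)


def _render_blobs(cfg: SceneConfig, rng: np.random.Generator):
    """Anisotropic Gaussian darkening bumps; returns (field, centers, mask)."""
    count = int(rng.poisson(cfg.blob_count_means[cfg.density_class]))
    fieldimg = np.zeros((cfg.height, cfg.width))
    mask = np.ones((cfg.height, cfg.width), dtype=bool)
    centers = np.empty((count, 2))
    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
    r_lo, r_hi = cfg.blob_radius_range
    for k in range(count):
        cy = rng.uniform(0, cfg.height - 1)
        cx = rng.uniform(0, cfg.width - 1)
        centers[k] = (cy, cx)
        ry = rng.uniform(r_lo, r_hi)
        rx = ry * rng.uniform(0.5, 1.0)  # anisotropy
        phi = rng.uniform(0, np.pi)
        amp = cfg.blob_amplitude * cfg.max_value * rng.uniform(0.7, 1.3)
        c, s = np.cos(phi), np.sin(phi)
        dy, dx = yy - cy, xx - cx
        u_ax = c * dx + s * dy
        v_ax = -s * dx + c * dy
        g = np.exp(-0.5 * ((u_ax / rx) ** 2 + (v_ax / ry) ** 2))
        fieldimg -= amp * g
        mask &= g < 0.05
    return fieldimg, centers, mask


def _artifacts(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    art = np.zeros((cfg.height, cfg.width))
    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
    rngmax = cfg.max_value
    if "stripe" in cfg.artifact_set:
        period = rng.uniform(20, 60)
        alpha = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        art += cfg.stripe_amplitude * rngmax * np.sin(
            2 * np.pi * (xx * np.cos(alpha) + yy * np.sin(alpha)) / period + phase
        )
    if "dust" in cfg.artifact_set:
        for _ in range(int(rng.poisson(cfg.dust_mean_count))):
            cy = rng.uniform(0, cfg.height - 1)
            cx = rng.uniform(0, cfg.width - 1)
            r = rng.uniform(2, 5)
            disc = ((yy - cy) ** 2 + (xx - cx) ** 2) <= r**2
            art[disc] -= 0.10 * rngmax
    if "flare" in cfg.artifact_set:
        cy = rng.uniform(0.1, 0.9) * cfg.height
        cx = rng.uniform(0.1, 0.9) * cfg.width
        sigma = 0.25 * min(cfg.height, cfg.width) * rng.uniform(0.8, 1.5)
        art += cfg.flare_amplitude * rngmax * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
        )
    return art


def generate_scene(config: SceneConfig) -> LabeledImage:
    """Render one scene deterministically from its config."""
    rng = np.random.default_rng(config.seed)
    vignette = _vignette_field(config, rng)
    texture = _texture_field(config, rng)
    blobs, centers, mask = _render_blobs(config, rng)
    art = _artifacts(config, rng)

    scene = config.background_level * config.max_value + texture + blobs
    img = vignette * scene + art

    if config.noise_poisson_scale > 0:
        kappa = config.noise_poisson_scale
        img = rng.poisson(np.clip(img, 0, None) * kappa) / kappa
    if config.noise_gaussian_sd > 0:
        img += rng.normal(0.0, config.noise_gaussian_sd * config.max_value, img.shape)

    img = np.clip(img, 0.0, config.max_value)
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    return LabeledImage(
        image=np.rint(img).astype(dtype),
        density_label=config.density_class,
        media_label=config.media_class,
        ground_truth=config,
        vignette_field=vignette,
        blob_centers=centers,
        background_mask=mask,
    )


def generate_dataset(
    n_per_class: int, base_config: SceneConfig = SceneConfig(), seed: int = 0
) -> list[LabeledImage]:
    """Balanced 3x3 factorial dataset: 9 * n_per_class scenes.

    Per-image seeds are derived deterministically from the master seed, so
    the same call reproduces the same dataset bit for bit.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(9 * n_per_class) % (2**31)
    images = []
    k = 0
    for rep in range(n_per_class):
        for density in DENSITY_CLASSES:
            for media in MEDIA_CLASSES:
                cfg = replace(
                    base_config,
                    density_class=density,
                    media_class=media,
                    seed=int(child_seeds[k]),
                )
                images.append(generate_scene(cfg))
                k += 1
    return images


def write_dataset(images: list[LabeledImage], out_dir: str | Path) -> Path:
    """Write TIFF (16-bit) or PNG (8-bit) frames plus a CSV manifest."""
    import pandas as pd
    import tifffile
    from skimage.io import imsave

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for i, li in enumerate(images):
        if li.ground_truth.bit_depth == 16:
            name = f"scene_{i:04d}.tif"
            tifffile.imwrite(out / name, li.image)
        else:
            name = f"scene_{i:04d}.png"
            imsave(out / name, li.image, check_contrast=False)
        records.append(
            {
                "filename": name,
                "density_label": li.density_label,
                "media_label": li.media_label,
                "seed": li.ground_truth.seed,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest
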