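"""Gray-level co-occurrence matrices and Haralick texture features.

A GLCM is the joint distribution of gray-level pairs at a fixed pixel
displacement (distance d, orientation theta).  Six Haralick statistics are
computed per matrix: angular second moment (ASM), contrast (CON),
correlation (COR), dissimilarity (DIS), energy (ENR = sqrt(ASM)) and
homogeneity (HOM).  The default grid is d in 1..5 and theta in
{0, 45, 90} degrees, giving 90 features per image.

Conventions fixed here (they matter for reproducibility):

* displacement for theta=0 is (0, +d) (rightwards), theta=90 is (-d, 0)
  (upwards), theta=45 is (-d, +d) (up-right diagonal), with rows increasing
  downward;
* matrices are symmetrized (transpose added) and normalized to
  probabilities, so the marginal means/deviations coincide;
* images are quantized to ``levels`` gray levels by linear min-max binning
  over the per-image range (a constant image maps to level 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GlcmSpec",
    "Glcm",
    "FEATURE_NAMES",
    "quantize",
    "compute_glcm",
    "haralick_features",
    "extract_features",
    "feature_columns",
]

FEATURE_NAMES = ("ASM", "CON", "COR", "DIS", "ENR", "HOM")

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0)}


@dataclass(frozen=True)
class GlcmSpec:
    """Distance/orientation grid and quantization settings."""

    distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    angles: tuple[int, ...] = (0, 45, 90)
    levels: int = 256
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if any(d < 1 for d in self.distances):
            raise ValueError("distances must be positive integers")
        unknown = set(self.angles) - set(_OFFSETS)
        if unknown:
            raise ValueError(f"unsupported angles {sorted(unknown)}; allowed: 0, 45, 90")


@dataclass
class Glcm:
    """One co-occurrence matrix with its marginal moments."""

    p: np.ndarray
    distance: int
    angle: int
    symmetric: bool
    normalized: bool

    @property
    def marginal_mean(self) -> tuple[float, float]:
        g = self.p.shape[0]
        i = np.arange(g, dtype=np.float64)
        mu_i = float((self.p.sum(axis=1) * i).sum())
        mu_j = float((self.p.sum(axis=0) * i).sum())
        return mu_i, mu_j

    @property
    def marginal_std(self) -> tuple[float, float]:
        g = self.p.shape[0]
        i = np.arange(g, dtype=np.float64)
        mu_i, mu_j = self.marginal_mean
        var_i = float((self.p.sum(axis=1) * (i - mu_i) ** 2).sum())
        var_j = float((self.p.sum(axis=0) * (i - mu_j) ** 2).sum())
        return np.sqrt(max(var_i, 0.0)), np.sqrt(max(var_j, 0.0))


def quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Linear min-max binning of ``img`` into ``levels`` integer gray levels."""
    img = np.asarray(img, dtype=np.float64)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros(img.shape, dtype=np.intp)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(np.intp)
    return np.minimum(q, levels - 1)


def compute_glcm(
    img: np.ndarray, d: int, theta: int, spec: GlcmSpec = GlcmSpec()
) -> Glcm:
    """Co-occurrence matrix of ``img`` at displacement (distance d, angle theta).

    ``img`` may be float (it is quantized to ``spec.levels``) or an integer
    array already in ``[0, spec.levels)``.
    """
    if theta not in _OFFSETS:
        raise ValueError(f"unsupported angle {theta}; allowed: 0, 45, 90")
    if d < 1:
        raise ValueError(f"distance must be >= 1, got {d}")
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() < spec.levels:
        q = img.astype(np.intp)
    else:
        q = quantize(img, spec.levels)

    dr, dc = (o * d for o in _OFFSETS[theta])
    m, n = q.shape
    r0, r1 = max(0, -dr), min(m, m - dr)
    c0, c1 = max(0, -dc), min(n, n - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(
            f"distance {d} at angle {theta} exceeds image extent {m}x{n}: no pixel pairs"
        )
    ref = q[r0:r1, c0:c1].ravel()
    nbr = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()

    g = spec.levels
    counts = np.bincount(ref * g + nbr, minlength=g * g).reshape(g, g).astype(np.float64)
    if spec.symmetric:
        counts = counts + counts.T
    if spec.normalized:
        counts = counts / counts.sum()
    return Glcm(p=counts, distance=d, angle=theta,
                symmetric=spec.symmetric, normalized=spec.normalized)


from functools import lru_cache


@lru_cache(maxsize=8)
def _grids(n: int):
    i = np.arange(n, dtype=np.float64)
    diff = i[:, None] - i[None, :]
    return i, diff**2, np.abs(diff), 1.0 / (1.0 + diff**2)


def haralick_features(g: Glcm) -> dict[str, float]:
    """The six Haralick statistics of a normalized GLCM.

    COR is defined as 1 when either marginal deviation vanishes (a
    single-level image is perfectly linearly dependent on itself).
    """
    if not g.normalized or abs(g.p.sum() - 1.0) > 1e-9:
        raise ValueError("haralick_features requires a normalized GLCM")
    p = g.p
    n = p.shape[0]
    i, diff2, absdiff, homw = _grids(n)

    asm = float((p * p).sum())
    con = float((p * diff2).sum())
    dis = float((p * absdiff).sum())
    hom = float((p * homw).sum())
    enr = float(np.sqrt(asm))
    p_i = p.sum(axis=1)
    p_j = p.sum(axis=0)
    mu_i = float(p_i @ i)
    mu_j = float(p_j @ i)
    var_i = float(p_i @ (i - mu_i) ** 2)
    var_j = float(p_j @ (i - mu_j) ** 2)
    sd = np.sqrt(max(var_i, 0.0) * max(var_j, 0.0))
    if sd == 0.0:
        cor = 1.0
    else:
        cor = float(((p @ (i - mu_j)) @ (i - mu_i)) / sd)
    return {"ASM": asm, "CON": con, "COR": cor, "DIS": dis, "ENR": enr, "HOM": hom}


def feature_columns(spec: GlcmSpec = GlcmSpec()) -> list[str]:
    """Systematic column names ``{FEAT}_d{d}_a{theta}`` for the feature grid."""
    return [
        f"{feat}_d{d}_a{a}"
        for feat in FEATURE_NAMES
        for d in spec.distances
        for a in spec.angles
    ]


def image_features(img: np.ndarray, spec: GlcmSpec = GlcmSpec()) -> dict[str, float]:
    """All Haralick features of one (already transformed) image."""
    q = quantize(img, spec.levels)
    out: dict[str, float] = {}
    for d in spec.distances:
        for a in spec.angles:
            g = compute_glcm(q, d, a, spec)
            feats = haralick_features(g)
            for name, val in feats.items():
                out[f"{name}_d{d}_a{a}"] = val
    return out


VARIANTS = ("u", "dftmod_u", "dftmod_lowrank", "dftmod_sparse", "dftmod_p", "dftmod_ppsw")


def _variant_transform(img: np.ndarray, variant: str, wavelet_spec, rpca_downscale):
    """Apply the per-variant image transform chain ahead of quantization.

    DFT-modulus images are quadrant-centered and log1p-scaled, matching the
    display convention used when inspecting spectra.
    """
    from .ppsd import dft_modulus, ppsd_decompose

    if variant == "u":
        return np.asarray(img, dtype=np.float64)
    if variant == "dftmod_u":
        return dft_modulus(img).values
    if variant == "dftmod_p":
        return dft_modulus(ppsd_decompose(img).periodic).values
    if variant == "dftmod_ppsw":
        from .restore import WaveletSpec, ppsw_restore

        spec = wavelet_spec if wavelet_spec is not None else WaveletSpec()
        return dft_modulus(ppsw_restore(img, spec)).values
    if variant in ("dftmod_lowrank", "dftmod_sparse"):
        from .rpca import rpca_decompose

        res = rpca_decompose(img, downscale=rpca_downscale)
        part = res.low_rank if variant == "dftmod_lowrank" else res.sparse
        return dft_modulus(part).values
    raise ValueError(f"unknown source variant {variant!r}; allowed: {VARIANTS}")


def extract_features(
    images,
    density_labels=None,
    media_labels=None,
    variant: str = "u",
    spec: GlcmSpec = GlcmSpec(),
    wavelet_spec=None,
    rpca_downscale: int = 1,
) -> pd.DataFrame:
    """Per-image GLCM feature table for one source variant.

    Returns a DataFrame with one row per image (input order preserved),
    the 6 x |distances| x |angles| feature columns, optional
    ``density_label`` / ``media_label`` columns, and ``source_variant``.
    """
    images = list(images)
    if not images:
        raise ValueError("empty image list")
    rows = []
    for img in images:
        transformed = _variant_transform(img, variant, wavelet_spec, rpca_downscale)
        rows.append(image_features(transformed, spec))
    table = pd.DataFrame(rows, columns=feature_columns(spec))
    if density_labels is not None:
        table["density_label"] = list(density_labels)
    if media_labels is not None:
        table["media_label"] = list(media_labels)
    table["source_variant"] = variant
    return table
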