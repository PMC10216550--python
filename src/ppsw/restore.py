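"""Periodic Plus Smooth Wavelet (PPSW) illumination correction.

Restoration proceeds in three steps: (1) split the image into periodic and
smooth components (:mod:`ppsw.ppsd`); (2) run a separable multi-level
discrete wavelet analysis on each component; (3) fuse the slowly-varying
content into an illumination estimate ``b`` and subtract it while restoring
the global mean.  The fusion rule keeps the smooth component reconstructed
from its coarsest approximation only (details zeroed) plus the deviation of
the periodic component's coarsest approximation from the image mean:

    b = recon(approx_L(s)) + (recon(approx_L(p)) - mean(u))
    corrected = u - b + mean(b)

Vignetting is low-frequency, so ``s`` carries the border-induced trend and
the coarse approximation of ``p`` the interior shading; subtracting both
flattens the background without touching cell-scale detail, and the mean
shift keeps overall brightness unchanged.  The default analysis wavelet is
``bior1.1`` at level 5 with symmetric (half-sample) boundary extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .ppsd import ppsd_decompose

__all__ = [
    "WaveletSpec",
    "WaveletPyramid",
    "wavelet_decompose",
    "wavelet_reconstruct",
    "ppsw_restore",
    "illumination_estimate",
    "wavelet_sweep",
]


@dataclass(frozen=True)
class WaveletSpec:
    """Mother-wavelet family, decomposition depth and boundary rule."""

    family_name: str = "bior1.1"
    level: int = 5
    boundary_mode: str = "symmetric"

    def wavelet(self) -> pywt.Wavelet:
        return pywt.Wavelet(self.family_name)

    def validate_for(self, shape: tuple[int, int]) -> None:
        if self.level < 1:
            raise ValueError(f"level must be >= 1, got {self.level}")
        max_level = pywt.dwtn_max_level(shape, self.wavelet())
        if self.level > max_level:
            raise ValueError(
                f"level {self.level} too deep for image {shape[0]}x{shape[1]} with "
                f"{self.family_name}: max admissible level is {max_level}"
            )


@dataclass
class WaveletPyramid:
    """Level-ordered coefficients of a 2-D multi-level wavelet analysis.

    ``approx`` is the coarsest (level L) approximation; ``details`` lists the
    (horizontal, vertical, diagonal) triples from level L down to level 1.
    Carries everything needed to invert exactly.
    """

    approx: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    spec: WaveletSpec
    source_dims: tuple[int, int]

    def coeffs(self) -> list:
        return [self.approx] + [tuple(d) for d in self.details]


def wavelet_decompose(u: np.ndarray, spec: WaveletSpec = WaveletSpec()) -> WaveletPyramid:
    """Separable 2-D multi-level wavelet analysis of ``u``."""
    u = np.asarray(u, dtype=np.float64)
    if u.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={u.ndim}")
    spec.validate_for(u.shape)
    coeffs = pywt.wavedec2(u, spec.wavelet(), mode=spec.boundary_mode, level=spec.level)
    return WaveletPyramid(
        approx=coeffs[0],
        details=[tuple(c) for c in coeffs[1:]],
        spec=spec,
        source_dims=u.shape,
    )


def wavelet_reconstruct(pyr: WaveletPyramid) -> np.ndarray:
    """Inverse transform; output cropped to the source dimensions."""
    rec = pywt.waverec2(pyr.coeffs(), pyr.spec.wavelet(), mode=pyr.spec.boundary_mode)
    m, n = pyr.source_dims
    return rec[:m, :n]


def _approx_only(pyr: WaveletPyramid) -> np.ndarray:
    """Reconstruction from the coarsest approximation with all details zeroed."""
    zeroed = WaveletPyramid(
        approx=pyr.approx,
        details=[tuple(np.zeros_like(g) for g in d) for d in pyr.details],
        spec=pyr.spec,
        source_dims=pyr.source_dims,
    )
    return wavelet_reconstruct(zeroed)


def illumination_estimate(u: np.ndarray, spec: WaveletSpec = WaveletSpec()) -> np.ndarray:
    """The fused low-frequency illumination field ``b`` (see module docstring).

    Isolated behind one function so alternative fusion rules can be swapped.
    """
    u = np.asarray(u, dtype=np.float64)
    p, s, _ = ppsd_decompose(u)
    s_trend = _approx_only(wavelet_decompose(s, spec))
    p_trend = _approx_only(wavelet_decompose(p, spec))
    return s_trend + (p_trend - float(u.mean()))


def ppsw_restore(
    u: np.ndarray,
    spec: WaveletSpec = WaveletSpec(),
    bit_depth: int = 16,
    keep_float: bool = True,
) -> np.ndarray:
    """Illumination-corrected image ``u - b + mean(b)``.

    Mean brightness is preserved to round-off.  With ``keep_float``
    (default) the float intermediate is returned untouched; otherwise the
    output is clipped to ``[0, 2**bit_depth - 1]`` and rounded to the
    integer grid (which can shift the mean when the correction drives
    pixels out of range).
    """
    u = np.asarray(u, dtype=np.float64)
    b = illumination_estimate(u, spec)
    corrected = u - b + float(b.mean())
    if not keep_float:
        corrected = np.rint(np.clip(corrected, 0.0, float(2**bit_depth - 1)))
    return corrected


def wavelet_sweep(
    images,
    labels,
    candidates: list[WaveletSpec],
    target: str = "density",
    seed: int = 0,
    n_estimators: int = 200,
    levels: int = 256,
):
    """Rank candidate wavelets by downstream classification accuracy.

    For each candidate: restore every image, take the DFT modulus, extract
    the GLCM feature grid, train a default random forest on a stratified
    70:30 split, and record held-out accuracy.  Returns a DataFrame sorted
    by accuracy (descending), ties broken alphabetically by family name.
    """
    import pandas as pd

    from .ml import SplitSpec, split, train_evaluate
    from .texture import GlcmSpec, extract_features

    if not candidates:
        raise ValueError("candidate wavelet list is empty")
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("wavelet sweep needs at least two classes")

    rows = []
    for cand in candidates:
        table = extract_features(
            images,
            density_labels=labels if target == "density" else None,
            media_labels=labels if target == "media" else None,
            variant="dftmod_ppsw",
            spec=GlcmSpec(levels=levels),
            wavelet_spec=cand,
        )
        train, test = split(table, SplitSpec(seed=seed))
        res = train_evaluate(
            train, test, model_name="random_forest", target=target, seed=seed,
            n_estimators=n_estimators,
        )
        rows.append(
            {
                "family_name": cand.family_name,
                "level": cand.level,
                "accuracy": res.accuracy,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["accuracy", "family_name"], ascending=[False, True]
    ).reset_index(drop=True)
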