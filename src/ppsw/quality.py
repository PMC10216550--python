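"""Image-quality metrics: PSNR and background-flatness diagnostics.

PSNR is ``10 * log10(MAX^2 / MSE)`` in decibels, with MAX taken from the
bit depth (65535 for 16-bit) rather than the observed maximum, following
the standard definition.  Identical images get the ``inf`` sentinel.
Background flatness is summarized by the coefficient of variation over a
mask, which on synthetic scenes can be the generator's own background
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf, log10

import numpy as np

__all__ = ["QualityReport", "psnr", "quality_summary", "flatness_cv"]


@dataclass
class QualityReport:
    psnr_db: float
    mse: float
    max_value: float
    flatness_cv: float | None = None


def psnr(reference: np.ndarray, test: np.ndarray, max_value: float = 65535.0) -> float:
    """Peak signal-to-noise ratio of ``test`` against ``reference``, in dB."""
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError(f"dimension mismatch: {reference.shape} vs {test.shape}")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return inf
    return 10.0 * log10(max_value**2 / mse)


def quality_report(reference, test, max_value=65535.0, background_mask=None) -> QualityReport:
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    mse = float(np.mean((reference - test) ** 2))
    cv = flatness_cv(test, background_mask) if background_mask is not None else None
    return QualityReport(psnr_db=psnr(reference, test, max_value), mse=mse,
                         max_value=max_value, flatness_cv=cv)


def flatness_cv(img: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Coefficient of variation (sd/mean) of the background pixels."""
    img = np.asarray(img, dtype=np.float64)
    vals = img[np.asarray(mask, dtype=bool)] if mask is not None else img.ravel()
    mean = float(vals.mean())
    if mean == 0.0:
        raise ValueError("background mean is zero; CV undefined")
    return float(vals.std()) / mean


def quality_summary(pairs, max_value: float = 65535.0) -> dict:
    """Median and interquartile range of PSNR over (reference, test) pairs.

    Infinite values (bit-identical pairs) are excluded from the quantiles
    and reported as a count.  Quantiles use linear interpolation.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("quality_summary needs at least one image pair")
    values = np.array([psnr(r, t, max_value) for r, t in pairs])
    finite = values[np.isfinite(values)]
    n_inf = int(np.sum(~np.isfinite(values)))
    if finite.size == 0:
        raise ValueError("all PSNR values are infinite; summary degenerate")
    q25, q50, q75 = np.percentile(finite, [25, 50, 75])
    return {
        "median_db": float(q50),
        "q25_db": float(q25),
        "q75_db": float(q75),
        "n": int(values.size),
        "n_infinite": n_inf,
    }
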