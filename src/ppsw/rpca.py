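"""Robust PCA baseline: low-rank + sparse matrix decomposition.

Solves the principal component pursuit problem

    min ||L||_* + lambda * ||S||_1   subject to   L + S = M

with the inexact augmented Lagrange multiplier (IALM) scheme: alternating
singular-value thresholding on L and soft thresholding on S, with a
geometrically increasing penalty mu.  Applied per-image (the M x N image
is the matrix); an optional integer downscale path trades fidelity for
speed on large frames, with nearest-neighbor upsampling of the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RpcaResult", "rpca_decompose"]


@dataclass
class RpcaResult:
    low_rank: np.ndarray
    sparse: np.ndarray
    lam: float
    iterations: int
    residual: float
    converged: bool
    objective_trace: list[float] = field(default_factory=list)
    residual_trace: list[float] = field(default_factory=list)


def _soft_threshold(x: np.ndarray, tau: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)


def _svd_threshold(x: np.ndarray, tau: float) -> np.ndarray:
    u, sv, vt = np.linalg.svd(x, full_matrices=False)
    sv = np.maximum(sv - tau, 0.0)
    return (u * sv) @ vt


def rpca_decompose(
    m: np.ndarray,
    lam: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 1000,
    mu_factor: float = 1.5,
    downscale: int = 1,
) -> RpcaResult:
    """Decompose matrix/image ``m`` into low-rank L plus sparse S.

    Parameters
    ----------
    m
        Finite 2-D array.
    lam
        Sparsity weight; default ``1/sqrt(max(M, N))``.
    tol
        Convergence threshold on the relative Frobenius feasibility
        residual ``||M - L - S||_F / ||M||_F``.
    downscale
        Integer stride; >1 decomposes a strided subimage and upsamples the
        result by nearest neighbor (cheap approximation for large frames).
    """
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got ndim={m.ndim}")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix contains non-finite values")
    if downscale > 1:
        small = rpca_decompose(m[::downscale, ::downscale], lam, tol, max_iter, mu_factor)
        up_l = np.repeat(np.repeat(small.low_rank, downscale, 0), downscale, 1)
        up_s = np.repeat(np.repeat(small.sparse, downscale, 0), downscale, 1)
        up_l = up_l[: m.shape[0], : m.shape[1]]
        up_s = up_s[: m.shape[0], : m.shape[1]]
        res = float(np.linalg.norm(m - up_l - up_s) / (np.linalg.norm(m) or 1.0))
        return RpcaResult(up_l, up_s, small.lam, small.iterations, res,
                          small.converged, small.objective_trace, small.residual_trace)

    norm_m = float(np.linalg.norm(m))
    if norm_m == 0.0:
        return RpcaResult(np.zeros_like(m), np.zeros_like(m),
                          lam or 1.0 / np.sqrt(max(m.shape)), 0, 0.0, True, [0.0], [0.0])
    if lam is None:
        lam = 1.0 / np.sqrt(max(m.shape))

    # standard IALM initialization (Lin et al. conventions)
    sv2 = np.linalg.norm(m, 2)
    mu = 1.25 / sv2
    y = m / max(sv2, np.abs(m).max() / lam)
    s = np.zeros_like(m)
    trace: list[float] = []
    res_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        l = _svd_threshold(m - s + y / mu, 1.0 / mu)
        s = _soft_threshold(m - l + y / mu, lam / mu)
        residual_mat = m - l - s
        y = y + mu * residual_mat
        mu *= mu_factor
        obj = float(np.linalg.svd(l, compute_uv=False).sum() + lam * np.abs(s).sum())
        trace.append(obj)
        res = float(np.linalg.norm(residual_mat) / norm_m)
        res_trace.append(res)
        if res < tol:
            converged = True
            break
    return RpcaResult(low_rank=l, sparse=s, lam=lam, iterations=it,
                      residual=res, converged=converged, objective_trace=trace,
                      residual_trace=res_trace)
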