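"""Kymograph pre-processing: Gaussian smoothing, Laplacian response, cost images.

The pipeline turns a raw kymograph into two nonnegative energy landscapes,
``K_B`` (bright ridges) and ``K_D`` (dark valleys), whose low-cost vertical
paths correspond to pronounced features.  The Laplacian-of-Gaussian response
is positive in dark bands and negative in bright bands; pixels that do not
belong to the relevant polarity are set to the barrier value 1.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .model import CostImage, Kymograph, KymographError, LaplacianResponse, Polarity, PreprocessParams


def smooth(kymo: Kymograph, sigma_h: float = 10.0, sigma_v: float = 3.0) -> Kymograph:
    """Anisotropic Gaussian smoothing.

    ``sigma_h`` acts along columns (channel position), ``sigma_v`` along rows
    (time).  Boundaries are handled by reflection so no spurious edge ridges
    are introduced.
    """
    if sigma_h <= 0 or sigma_v <= 0:
        raise ValueError("smoothing sigmas must be strictly positive")
    out = ndimage.gaussian_filter(kymo.intensity, sigma=(sigma_v, sigma_h), mode="reflect")
    return kymo.with_intensity(out)


def laplacian_response(smoothed: Kymograph, sigma_log: float = 10.0) -> LaplacianResponse:
    """Laplacian-of-Gaussian response, rescaled to [-1, 1].

    Positive values mark dark bands (intensity minima), negative values bright
    bands; positive entries are divided by the maximum positive value and
    negative entries by the magnitude of the minimum, so any nonempty set
    attains exactly +1 / -1.
    """
    if sigma_log <= 0:
        raise ValueError("sigma_log must be strictly positive")
    # Discrete Laplacian of the Gaussian-filtered image: positive at local
    # minima (dark bands), negative at maxima (bright bands) — the required
    # sign convention — and exactly zero on constants (the [1, -2, 1] stencil
    # sums to zero, unlike the truncated analytic LoG kernel).
    blurred = ndimage.gaussian_filter(smoothed.intensity, sigma=sigma_log, mode="reflect")
    out = ndimage.laplace(blurred, mode="reflect").astype(float)
    tol = 1e-12 * max(1.0, float(np.abs(smoothed.intensity).max()))
    out[np.abs(out) < tol] = 0.0
    pos = out > 0
    neg = out < 0
    if pos.any():
        out[pos] /= out[pos].max()
    if neg.any():
        out[neg] /= -out[neg].min()
    return LaplacianResponse(out)


def cost_images(K: LaplacianResponse) -> tuple[CostImage, CostImage]:
    """Split the Laplacian response into bright and dark cost images.

    ``K_B = 1 + K`` where ``K < 0`` (bright bands approach cost 0), barrier 1
    elsewhere; ``K_D = 1 - K`` where ``K > 0``, barrier 1 elsewhere.  Both lie
    in [0, 1] with the smallest values at the most pronounced features.
    """
    v = K.values
    kb = np.where(v < 0, 1.0 + v, 1.0)
    kd = np.where(v > 0, 1.0 - v, 1.0)
    return CostImage(kb, Polarity.BRIGHT), CostImage(kd, Polarity.DARK)


def cost_images_ranked(values: np.ndarray) -> tuple[CostImage, CostImage]:
    """Contrast-equalised bright/dark cost images from a Laplacian response.

    For each polarity, the cost of an on-polarity pixel is one minus the
    empirical CDF rank of its response strength among all on-polarity pixels
    of the given array; off-polarity pixels are barriers at 1.  Ranking makes
    every coherent ridge uniformly deep regardless of its absolute contrast,
    so a minimum-cost path gains nothing by hopping from a weak feature to a
    strong one across a barrier — with amplitude-graded costs such hops win
    whenever the movie is long, because the crossing penalty is fixed while
    the depth gain grows with the number of frames.  Ranks are invariant
    under any monotone rescaling of the response, which also makes the
    global-versus-local rescaling question moot.
    """
    values = np.asarray(values, dtype=float)
    out = []
    for sign, pol in ((-1.0, Polarity.BRIGHT), (1.0, Polarity.DARK)):
        strength = np.where(sign * values > 0, sign * values, 0.0)
        on = strength > 0
        cost = np.ones_like(values)
        if on.any():
            flat = strength[on]
            order = np.sort(flat)
            cost[on] = 1.0 - np.searchsorted(order, flat, side="right") / flat.size
        out.append(CostImage(cost, pol))
    return out[0], out[1]


def preprocess(kymo: Kymograph, params: PreprocessParams | None = None) -> tuple[CostImage, CostImage]:
    """Full pre-processing chain: smooth, LoG response, bright/dark cost images."""
    params = params or PreprocessParams()
    sm = smooth(kymo, params.sigma_h, params.sigma_v)
    K = laplacian_response(sm, params.sigma_log)
    return cost_images(K)
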