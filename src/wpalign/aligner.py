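"""Feature straightening and full recursive kymograph alignment.

A detected feature is straightened by moving it, in every frame, to its
time-averaged column ``c* = round(<F(y)>)`` — its position at thermodynamic
equilibrium — while the pixels on either side are stretched or compressed
linearly and resampled with a cubic spline.  The kymograph is then split at
the aligned column, a margin of ``w`` columns on each side of the split is
excluded from further search (the margin and the feature are written through
to the output unchanged), and the procedure recurses on the left and right
remainders until regions become narrower than a typical feature (2w) or no
distinct feature is found.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .model import AlignmentResult, AlignParams, CostImage, Feature, Kymograph, KymographError, Polarity
from .feature_detect import Rejection, select_feature
from .preprocess import cost_images_ranked, laplacian_response, smooth


def _row_coordinate_map(n: int, f: int, c_star: int) -> np.ndarray:
    """Input coordinate sampled at each output column for one row.

    Piecewise-linear map fixing both region ends: output 0 -> input 0,
    output c* -> input F(y), output n-1 -> input n-1.  When c* sits on a
    region edge the empty side passes through unchanged and the other side is
    a single linear stretch; the map is monotone non-decreasing in every
    case, so composed warps remain invertible.
    """
    u = np.arange(n, dtype=float)
    if 0 < c_star < n - 1:
        return np.interp(u, [0.0, float(c_star), float(n - 1)], [0.0, float(f), float(n - 1)])
    if c_star == 0:
        return np.interp(u, [0.0, float(n - 1)], [float(f), float(n - 1)])
    return np.interp(u, [0.0, float(n - 1)], [0.0, float(f)])


def _warp_rows(intensity: np.ndarray, feature: Feature, c_star: int) -> tuple[np.ndarray, np.ndarray]:
    """Resample every row at its piecewise-linear coordinate map.

    Returns the warped intensities and the per-row coordinate maps (input
    coordinate per output column), for composition into a global warp.
    """
    m, n = intensity.shape
    out = np.empty_like(intensity, dtype=float)
    coords_all = np.empty((m, n), dtype=float)
    x = np.arange(n, dtype=float)
    for y in range(m):
        f = int(feature.path[y])
        coords = _row_coordinate_map(n, f, c_star)
        coords_all[y] = coords
        if np.array_equal(coords, x):
            out[y] = intensity[y]
        elif n >= 4:
            spline = CubicSpline(x, intensity[y], bc_type="natural")
            out[y] = spline(np.clip(coords, 0.0, n - 1.0))
        else:
            out[y] = np.interp(np.clip(coords, 0.0, n - 1.0), x, intensity[y])
    return out, coords_all


def align_single_feature(region: Kymograph, feature: Feature) -> Kymograph:
    """Straighten one feature so it sits at its mean column in every row."""
    m, n = region.intensity.shape
    if feature.path.size != m:
        raise KymographError(
            f"feature defined for {feature.path.size} rows but region has {m}")
    if feature.path.min() < 0 or feature.path.max() > n - 1:
        raise KymographError("feature path leaves the region")
    warped, _ = _warp_rows(region.intensity, feature, feature.mean_position)
    return region.with_intensity(warped)


def _align_pass(kymo: Kymograph, params: AlignParams) -> AlignmentResult:
    """One full recursive detect-and-straighten sweep over the kymograph.

    The output kymograph has exactly the input's dimensions: the ``w``-column
    margins dropped at each split are excluded from further feature search
    only, not from the image.  The smoothing and Laplacian filters run once,
    on the whole kymograph; the response image is then warped alongside the
    intensities at every feature alignment, and each recursion region builds
    its bright/dark cost images by contrast-equalised ranking of its slice of
    that co-warped response (see :func:`~wpalign.preprocess.cost_images_ranked`).
    After a feature is straightened, its own response basin — which at the
    detection scale spans roughly ``sqrt(sigma_h^2 + sigma_log^2)`` columns on
    each side, much more than the ``w``-column margin — is cleared in its
    polarity so the same ridge cannot be re-detected from its flanks.  Region
    bookkeeping is kept on an explicit stack (left region before right) so
    arbitrarily wide kymographs do not hit the interpreter recursion limit.
    """
    w = params.feature_half_width
    m, n = kymo.intensity.shape

    out = kymo.intensity.astype(float).copy()
    row_maps = np.tile(np.arange(n, dtype=float), (m, 1))
    features: list[Feature] = []
    rejected: list[tuple[int, int]] = []

    if m < 2:
        return AlignmentResult(kymo.with_intensity(out), features, rejected, row_maps)

    pp = params.preprocess
    K = laplacian_response(smooth(kymo, pp.sigma_h, pp.sigma_v), pp.sigma_log).values.copy()
    suppress_r = int(np.ceil(np.hypot(pp.sigma_h, pp.sigma_log)))

    stack: list[tuple[int, int]] = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        width = hi - lo
        if width < 2 * w:
            continue
        kb, kd = cost_images_ranked(K[:, lo:hi])
        det = select_feature(kb, kd, params.graph)
        if isinstance(det, Rejection):
            rejected.append((lo, hi))
            continue
        c_local = det.mean_position
        warped, coords = _warp_rows(out[:, lo:hi], det, c_local)
        out[:, lo:hi] = warped
        local_x = np.arange(width, dtype=float)
        for y in range(m):
            # the response travels with the pixels it describes; the composed
            # warp is tracked the same way
            K[y, lo:hi] = np.interp(coords[y], local_x, K[y, lo:hi])
            row_maps[y, lo:hi] = np.interp(coords[y], local_x, row_maps[y, lo:hi])
        features.append(det.shifted(lo))
        c_global = lo + c_local
        slo, shi = max(0, c_global - suppress_r), min(n, c_global + suppress_r + 1)
        block = K[:, slo:shi]
        if det.polarity == Polarity.BRIGHT:
            np.clip(block, 0.0, None, out=block)
        else:
            np.clip(block, None, 0.0, out=block)
        # LIFO stack: push right first so the left region is processed first.
        stack.append((c_global + 1 + w, hi))
        stack.append((lo, c_global - w))

    result = AlignmentResult(kymo.with_intensity(out), features, rejected, row_maps)
    result.features = result.sorted_features()
    return result


def align_kymograph(kymo: Kymograph, params: AlignParams | None = None,
                    max_passes: int = 4, tol: float = 0.02) -> AlignmentResult:
    """Recursively detect and straighten every distinct feature.

    The recursive sweep (:func:`_align_pass`) is iterated until it converges:
    a straightened feature sharpens the image, which lets the next sweep
    detect and correct residual misalignment the first could not see.  A
    sweep is accepted only if it lowers the mean column variance by more
    than ``tol`` (relative); the first rejected sweep ends the iteration and
    is discarded, so alignment never degrades the image and aligning an
    already-aligned kymograph is a no-op.  ``features`` and
    ``rejected_regions`` describe the last executed sweep; ``row_maps`` is
    the composition of all accepted sweeps.
    """
    params = params or AlignParams()
    m, n = kymo.intensity.shape
    x = np.arange(n, dtype=float)

    best = _align_pass(kymo, params)
    var_in = float(kymo.intensity.var(axis=0).mean())
    var_best = float(best.aligned.intensity.var(axis=0).mean())
    if var_best >= var_in * (1.0 - tol):
        # the sweep did not help; report its findings but keep the input
        return AlignmentResult(kymo, best.features, best.rejected_regions,
                               np.tile(x, (m, 1)))
    for _ in range(max_passes - 1):
        cand = _align_pass(best.aligned, params)
        var_cand = float(cand.aligned.intensity.var(axis=0).mean())
        if var_cand >= var_best * (1.0 - tol):
            break
        composed = np.stack([np.interp(cand.row_maps[y], x, best.row_maps[y])
                             for y in range(m)])
        best = AlignmentResult(cand.aligned, cand.features, cand.rejected_regions, composed)
        var_best = var_cand
    return best
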