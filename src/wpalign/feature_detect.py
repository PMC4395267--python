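"""Constrained shortest-path feature detection.

The admissible-path graph over an m x n cost image has one node per pixel plus
two peripheral nodes (a source above the first row and a sink below the last).
Pixel (y, j) connects to pixels (y+1, j') with |j' - j| <= k; every edge is
weighted by the cost of the pixel it points to, and sink edges carry constant
weight 1.  The graph is acyclic by construction, so the minimum-cost complete
path can be found by a row-by-row dynamic program without ever materialising
the graph — this is what keeps the algorithm linear in the kymograph width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import minimum_filter1d

from .model import (
    AlignParams,
    CostImage,
    Feature,
    GraphParams,
    KMode,
    KSelection,
    Kymograph,
    KymographError,
    Polarity,
    SourceEdgeScheme,
)
from .preprocess import preprocess


@dataclass(frozen=True)
class PathProblem:
    """A constrained path search over one cost image.

    The implicit graph has ``m * n + 2`` nodes (one per pixel plus the two
    peripheral source/sink nodes) and is acyclic because edges only run from
    each row to the next.
    """

    cost: CostImage
    k: int = 2
    source_edge_scheme: SourceEdgeScheme = SourceEdgeScheme.DESTINATION_INTENSITY

    @property
    def n_nodes(self) -> int:
        m, n = self.cost.values.shape
        return m * n + 2

    def solve(self) -> Feature:
        return shortest_feature_path(self.cost, self.k, self.source_edge_scheme)


def shortest_feature_path(cost: CostImage, k: int,
                          scheme: SourceEdgeScheme = SourceEdgeScheme.DESTINATION_INTENSITY) -> Feature:
    """Minimum-cost complete path through a cost image with step bound ``k``.

    Returns a :class:`Feature` whose reported cost is the sum of traversed
    cost-image entries over all rows (the constant sink edge is excluded).
    Ties are broken toward the smallest column index.
    """
    values = cost.values
    m, n = values.shape
    if m <= 0 or n <= 0:
        raise KymographError("empty region: cannot search for a feature")
    if k < 0:
        raise ValueError("k must be >= 0")

    # Forward pass: dp[y, j] = min cost of a source -> (y, j) path under the
    # chosen source-edge scheme.
    dp = np.empty_like(values)
    if scheme == SourceEdgeScheme.DESTINATION_INTENSITY:
        dp[0] = values[0]
    else:  # unit source edges: constant, so row 0 intensities do not compete
        dp[0] = 1.0
    size = 2 * k + 1
    for y in range(1, m):
        if k == 0:
            dp[y] = dp[y - 1] + values[y]
        else:
            dp[y] = minimum_filter1d(dp[y - 1], size=size, mode="nearest") + values[y]

    # Backtrack, breaking ties toward the smallest column.
    path = np.empty(m, dtype=int)
    path[-1] = int(np.argmin(dp[-1]))
    for y in range(m - 1, 0, -1):
        lo = max(0, path[y] - k)
        hi = min(n, path[y] + k + 1)
        path[y - 1] = lo + int(np.argmin(dp[y - 1, lo:hi]))

    total = float(values[np.arange(m), path].sum())
    return Feature(path, cost.polarity, total)


class Rejection:
    """Marker returned when no path is distinct enough to count as a feature.

    Carries the best candidate, its normalised per-row cost and the reason
    (``"cost"`` or ``"wander"``) for logging.
    """

    def __init__(self, best: Feature, normalized_cost: float, theta: float,
                 reason: str = "cost"):
        self.best = best
        self.normalized_cost = normalized_cost
        self.theta = theta
        self.reason = reason

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Rejection(reason={self.reason!r}, "
                f"normalized_cost={self.normalized_cost:.4f}, "
                f"theta={self.theta}, polarity={self.best.polarity.value})")


def select_feature(kb: CostImage, kd: CostImage, graph: GraphParams) -> Feature | Rejection:
    """Pick the better of the bright and dark shortest paths, apply distinctness.

    The lower-cost path wins; exact ties go to dark.  The winner counts as a
    distinct feature iff its per-row (height-normalised) cost is below
    ``theta`` and its total column excursion stays within the diffusive bound
    ``graph.max_wander(m)`` — a path that drifts much farther than diffusion
    allows is riding a featureless gap, not a band.
    """
    bright = shortest_feature_path(kb, graph.k, graph.source_edge_scheme)
    dark = shortest_feature_path(kd, graph.k, graph.source_edge_scheme)
    best = dark if dark.cost <= bright.cost else bright
    m = kb.values.shape[0]
    normalized = best.cost / m
    if normalized >= graph.theta:
        return Rejection(best, normalized, graph.theta, reason="cost")
    if float(best.path.max() - best.path.min()) > graph.max_wander(m):
        return Rejection(best, normalized, graph.theta, reason="wander")
    return best


def detect_best_feature(region: Kymograph, params: AlignParams) -> Feature | Rejection:
    """Detect the most pronounced bright or dark feature in a single region.

    Runs the full pre-processing chain on the region (affine bright/dark
    cost images) and selects the better of the bright and dark shortest
    paths.  This is the standalone single-region entry point; the recursive
    aligner instead filters the whole kymograph once, carries the response
    through its warps, and prices regions by contrast ranking — see
    :func:`wpalign.aligner.align_kymograph`.
    """
    kb, kd = preprocess(region, params.preprocess)
    return select_feature(kb, kd, params.graph)


def choose_k(sel: KSelection) -> int:
    """Continuity bound for a molecule of length ``L``.

    Linear mode is the reference-scaling rule k = k_ref * L_ref / L; sqrt mode
    replaces the ratio with its square root, the scaling the center-of-mass
    diffusion argument strictly implies.  Either way at least 1 is returned so
    features can always move.
    """
    ratio = sel.L_ref / sel.L
    if sel.mode == KMode.SQRT:
        ratio = math.sqrt(ratio)
    from .model import round_half_away

    return max(1, round_half_away(sel.k_ref * ratio))
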