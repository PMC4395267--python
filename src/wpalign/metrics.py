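"""Barcode quality metrics: time trace, column variances, information score.

The time trace is the column-wise time average of an (ideally aligned)
kymograph — the 1D consensus barcode used for downstream comparison.
Residual misalignment and camera noise show up as the column-wise variance
sigma^2(x); its flat average <sigma^2(x)> summarises kymograph noise in one
number.

The information score condenses a trace into the total self-information of
its peak/valley contrasts: with noise s2 = sigma^2 and regularisation chi,

    IS = sum_k [ 1/2 * ln(2*pi*ln(s2 + chi)) + ln(|dI_k|)^2 / (2*ln(s2 + chi)) ]

where the |dI_k| are robust intensity differences between neighbouring peaks
and valleys of the trace.  Sharper extrema and lower noise give higher
scores.  The squared-log reading treats each contrast as a Gaussian variate
in log intensity, so each term is a negative log density (self-information in
nats by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .model import Kymograph


@dataclass(frozen=True)
class TimeTrace:
    """Column statistics of a kymograph over time."""

    mean_intensity: np.ndarray
    column_variance: np.ndarray
    mean_variance: float


@dataclass(frozen=True)
class InfoScoreInputs:
    """Inputs to the information score.

    ``delta_I``: positive peak-to-valley intensity differences; ``sigma2``:
    kymograph noise, taken as the mean column variance of the aligned
    kymograph; ``chi >= 1`` keeps ln(sigma2 + chi) nonnegative so the score
    stays real at any noise level.
    """

    delta_I: tuple[float, ...]
    sigma2: float
    chi: float = 1.0

    def __post_init__(self) -> None:
        if self.chi < 1:
            raise ValueError("chi must be >= 1")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if any(d <= 0 for d in self.delta_I):
            raise ValueError("all |delta I| must be strictly positive")
        object.__setattr__(self, "delta_I", tuple(float(d) for d in self.delta_I))


def time_trace(kymo: Kymograph) -> TimeTrace:
    """Mean intensity, column variance and mean variance of a kymograph.

    Variances use the population (1/m) convention.
    """
    arr = kymo.intensity
    mean = arr.mean(axis=0)
    var = arr.var(axis=0)  # ddof=0: population variance
    return TimeTrace(mean, var, float(var.mean()))


def extrema_differences(trace: TimeTrace, smoothing_sigma: float = 2.0,
                        min_prominence: float | None = None,
                        sigma2: float | None = None, chi: float = 1.0) -> list[float]:
    """Robust intensity differences between neighbouring peaks and valleys.

    The mean-intensity profile is smoothed with a 1D Gaussian (disabled when
    ``smoothing_sigma`` is 0), interior extrema are kept when their prominence
    clears ``min_prominence`` (default: half the noise scale,
    0.5*sqrt(sigma2 + chi)), and trace endpoints are appended when they extend
    the alternation by at least the same margin.  Runs of same-type extrema
    are collapsed to the most extreme one so the surviving sequence
    alternates; the |dI_k| are absolute differences of consecutive values.
    Returns an empty list when fewer than two extrema survive.
    """
    profile = np.asarray(trace.mean_intensity, dtype=float)
    if profile.size < 3:
        return []
    if min_prominence is None:
        s2 = trace.mean_variance if sigma2 is None else sigma2
        min_prominence = 0.5 * math.sqrt(s2 + chi)
    if smoothing_sigma > 0:
        profile = gaussian_filter1d(profile, smoothing_sigma, mode="reflect")

    peaks, _ = find_peaks(profile, prominence=min_prominence)
    valleys, _ = find_peaks(-profile, prominence=min_prominence)
    extrema = sorted([(int(i), +1) for i in peaks] + [(int(i), -1) for i in valleys])
    if not extrema:
        return []

    # Endpoints join the sequence typed opposite to the nearest interior
    # extremum, provided they clear the prominence floor against it.
    first_i, first_t = extrema[0]
    if abs(profile[0] - profile[first_i]) >= min_prominence:
        extrema.insert(0, (0, -first_t))
    last_i, last_t = extrema[-1]
    if abs(profile[-1] - profile[last_i]) >= min_prominence:
        extrema.append((profile.size - 1, -last_t))

    # Collapse same-type runs, keeping the most extreme value of each run.
    collapsed: list[tuple[int, int]] = []
    for idx, typ in extrema:
        if collapsed and collapsed[-1][1] == typ:
            prev_idx = collapsed[-1][0]
            better = profile[idx] > profile[prev_idx] if typ > 0 else profile[idx] < profile[prev_idx]
            if better:
                collapsed[-1] = (idx, typ)
        else:
            collapsed.append((idx, typ))

    if len(collapsed) < 2:
        return []
    vals = profile[[i for i, _ in collapsed]]
    return [float(abs(b - a)) for a, b in zip(vals[:-1], vals[1:])]


def information_score(inputs: InfoScoreInputs, base: float = math.e) -> float:
    """Self-information score of a set of peak/valley contrasts.

    Returns 0 for an empty contrast list, and +inf when the noise term
    ln(sigma2 + chi) vanishes (noise-free trace with chi = 1).  ``base``
    selects the logarithm of the reported score (nats by default); the
    internal Gaussian structure always uses natural logs.
    """
    if not inputs.delta_I:
        return 0.0
    denom = math.log(inputs.sigma2 + inputs.chi)
    if denom == 0.0:
        return math.inf
    total = 0.0
    for d in inputs.delta_I:
        total += 0.5 * math.log(2.0 * math.pi * denom) + math.log(d) ** 2 / (2.0 * denom)
    if base != math.e:
        total /= math.log(base)
    return total


def score_kymograph(kymo: Kymograph, smoothing_sigma: float = 2.0,
                    min_prominence: float | None = None, chi: float = 1.0) -> dict:
    """Convenience wrapper: trace, extrema and information score in one call."""
    trace = time_trace(kymo)
    deltas = extrema_differences(trace, smoothing_sigma=smoothing_sigma,
                                 min_prominence=min_prominence, chi=chi)
    score = information_score(InfoScoreInputs(tuple(deltas), trace.mean_variance, chi))
    return {
        "mean_variance": trace.mean_variance,
        "n_extrema_differences": len(deltas),
        "delta_I": deltas,
        "information_score": score,
    }
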