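"""Runtime-scaling measurement for the full alignment pipeline.

The alignment cost is dominated by the shortest-path search, whose implicit
graph grows bilinearly in frames and width; at fixed frame count the wall
time should therefore grow linearly with kymograph width.  This module
builds wide synthetic kymographs by concatenating standard-width simulated
barcodes and fits a power law ``a * n^b`` to the measured wall times.
"""

from __future__ import annotations

import time

import numpy as np

from .aligner import align_kymograph
from .model import AlignParams, Kymograph
from .synthetic import BarcodeSpec, DynamicsSpec, generate_barcode, generate_kymograph

_TILE = 170  # standard simulated barcode width, px


def concatenated_kymograph(width: int, m: int = 200, seed: int = 0) -> Kymograph:
    """Kymograph of the given width built from concatenated barcode tiles."""
    segments, offset, i = [], 0, 0
    while offset < width:
        barcode, _ = generate_barcode(
            BarcodeSpec(n=_TILE, n_features=1, end_margin_px=0, seed=seed + i))
        segments.append(barcode)
        offset += _TILE
        i += 1
    profile = np.concatenate(segments)[:width]
    kymo, _ = generate_kymograph(profile, DynamicsSpec(m=m, seed=seed + 7919))
    return kymo


def time_scaling_exponent(widths: list[int] | None = None, m: int = 200, seed: int = 0,
                          params: AlignParams | None = None,
                          repeats: int = 2) -> tuple[float, list[float]]:
    """Fit ``a * n^b`` to alignment wall time over kymograph widths.

    Each width is timed ``repeats`` times and the fastest run is kept, which
    suppresses transient machine-load spikes.  Returns the exponent ``b``
    (least squares in log-log space) and the per-width times in seconds.
    """
    widths = widths or [200, 500, 1000, 2000, 5000, 10000]
    times = []
    for w in widths:
        kymo = concatenated_kymograph(w, m=m, seed=seed)
        best = np.inf
        for _ in range(max(1, repeats)):
            t0 = time.perf_counter()
            align_kymograph(kymo, params)
            best = min(best, time.perf_counter() - t0)
        times.append(best)
    b = float(np.polyfit(np.log(widths), np.log(times), 1)[0])
    return b, times
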