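"""Core data types for kymographs, features and alignment results, plus file I/O.

A kymograph is an ``m x n`` grayscale intensity matrix in which row ``y`` is a
time frame and column ``x`` is a position along the nanochannel.  All
coordinates in this package are 0-based (row 0 = first frame, column 0 =
leftmost pixel); intensities are in arbitrary camera units.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np


class Polarity(str, Enum):
    """Whether a feature is a bright ridge or a dark valley."""

    BRIGHT = "bright"
    DARK = "dark"


class KymographError(ValueError):
    """Raised for malformed kymograph inputs or contract violations."""


def round_half_away(x: float) -> int:
    """Round half away from zero (platform-independent, unlike ``round``)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class Kymograph:
    """An m x n intensity matrix: rows are time frames, columns are positions.

    Parameters
    ----------
    intensity : ndarray, shape (m, n)
        Nonnegative finite intensities, arbitrary camera units.
    pixel_size : float
        Physical pixel size along the channel, in micrometres per pixel.
    frame_interval : float or None
        Time between frames in seconds, if known.
    """

    intensity: np.ndarray
    pixel_size: float = 0.16
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise KymographError(f"kymograph must be a 2D matrix, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise KymographError("kymograph intensities must all be finite")
        object.__setattr__(self, "intensity", arr)

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]

    @property
    def width(self) -> int:
        return self.intensity.shape[1]

    @property
    def length_um(self) -> float:
        """Extension of the imaged molecule in micrometres (width * pixel size)."""
        return self.width * self.pixel_size

    def with_intensity(self, intensity: np.ndarray) -> "Kymograph":
        return dataclasses.replace(self, intensity=intensity)


@dataclass(frozen=True)
class PreprocessParams:
    """Gaussian smoothing and Laplacian-of-Gaussian filter widths, in pixels."""

    sigma_h: float = 10.0
    sigma_v: float = 3.0
    sigma_log: float = 10.0

    def __post_init__(self) -> None:
        for name in ("sigma_h", "sigma_v", "sigma_log"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class LaplacianResponse:
    """Rescaled Laplacian-of-Gaussian response K.

    Positive in dark bands, negative in bright bands.  Positive entries are
    scaled so their maximum is exactly 1; negative entries so their minimum is
    exactly -1 (when either set is nonempty).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise KymographError("Laplacian response must be 2D")
        if arr.size and (arr.min() < -1.0 - 1e-12 or arr.max() > 1.0 + 1e-12):
            raise KymographError("Laplacian response entries must lie in [-1, 1]")
        object.__setattr__(self, "values", arr)


@dataclass(frozen=True)
class CostImage:
    """Nonnegative energy landscape in [0, 1]; barriers sit at the maximum, 1."""

    values: np.ndarray
    polarity: Polarity

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise KymographError("cost image must be 2D")
        if arr.size and (arr.min() < 0 or arr.max() > 1.0 + 1e-12):
            raise KymographError("cost image entries must lie in [0, 1]")
        object.__setattr__(self, "values", arr)


class SourceEdgeScheme(str, Enum):
    """Weighting of the edges leaving the top peripheral (source) node."""

    DESTINATION_INTENSITY = "destination_intensity"
    UNIT = "unit"


@dataclass(frozen=True)
class GraphParams:
    """Parameters of the admissible-path graph over a cost image.

    ``k`` is the maximum horizontal step (pixels) a feature may take between
    adjacent frames; ``theta`` is the per-row normalised cost below which a
    detected path is accepted as a distinct feature.  ``max_wander_factor``
    scales a second distinctness test: a genuine feature diffuses, so its
    total excursion over ``m`` frames is bounded by about ``k * sqrt(m)``
    (the whole-movie counterpart of the per-frame bound ``k``); a path whose
    column range exceeds ``max_wander_factor * k * sqrt(m)`` is a drifting
    gap artefact, not a feature, and is rejected.  Set the factor to ``inf``
    to disable the test.
    """

    k: int = 2
    source_edge_scheme: SourceEdgeScheme = SourceEdgeScheme.DESTINATION_INTENSITY
    theta: float = 0.3
    max_wander_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if not (0 < self.theta <= 1):
            raise ValueError("theta must lie in (0, 1]")
        if self.max_wander_factor <= 0:
            raise ValueError("max_wander_factor must be positive")

    def max_wander(self, m: int) -> float:
        """Largest column excursion a distinct feature may show in m frames."""
        return self.max_wander_factor * self.k * math.sqrt(m)


class KMode(str, Enum):
    LINEAR = "linear"
    SQRT = "sqrt"


@dataclass(frozen=True)
class KSelection:
    """Continuity bound selection from molecule length.

    The reference values come from 24 um molecules imaged with k = 2; for a
    molecule of length ``L`` the linear rule is k = k_ref * L_ref / L.  The
    diffusion argument behind it (displacement per frame shrinking with
    molecule length) strictly gives a square-root dependence, offered as the
    alternative ``sqrt`` mode.
    """

    L: float
    k_ref: int = 2
    L_ref: float = 24.0
    mode: KMode = KMode.LINEAR

    def __post_init__(self) -> None:
        if self.L <= 0 or self.L_ref <= 0:
            raise ValueError("molecule lengths must be strictly positive")
        if self.k_ref <= 0:
            raise ValueError("k_ref must be strictly positive")


@dataclass(frozen=True)
class Feature:
    """A complete, continuity-constrained column trajectory through all rows.

    ``path[y]`` is the feature's column in frame ``y``; ``cost`` is the sum of
    traversed cost-image entries (the constant unit sink edge is excluded).
    """

    path: np.ndarray
    polarity: Polarity
    cost: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.path, dtype=int)
        if arr.ndim != 1 or arr.size < 1:
            raise KymographError("feature path must be a nonempty 1D integer array")
        object.__setattr__(self, "path", arr)

    @property
    def mean_position(self) -> int:
        return round_half_away(float(np.mean(self.path)))

    def check_continuity(self, k: int) -> None:
        if self.path.size > 1 and int(np.max(np.abs(np.diff(self.path)))) > k:
            raise KymographError(f"feature violates continuity constraint k={k}")

    def shifted(self, offset: int) -> "Feature":
        return Feature(self.path + offset, self.polarity, self.cost)


@dataclass(frozen=True)
class AlignParams:
    """Parameters for the recursive alignment.

    ``feature_half_width`` (w) is half the width of a typical feature in
    pixels; recursion drops w columns on each side of every aligned feature
    and stops on regions narrower than 2w.
    """

    feature_half_width: int = 5
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    graph: GraphParams = field(default_factory=GraphParams)

    def __post_init__(self) -> None:
        if self.feature_half_width < 1:
            raise ValueError("feature_half_width must be >= 1")


@dataclass
class AlignmentResult:
    """Output of the full recursive alignment.

    ``features`` hold global column coordinates, ordered by region from left
    to right; ``rejected_regions`` are [start, stop) column intervals where the
    best path failed the distinctness threshold.  ``row_maps`` stores, for each
    row, the input coordinate sampled at every output column (the composed
    warp), useful for diagnostics against simulated ground truth.
    """

    aligned: Kymograph
    features: list[Feature]
    rejected_regions: list[tuple[int, int]]
    row_maps: np.ndarray | None = None

    def sorted_features(self) -> list[Feature]:
        return sorted(self.features, key=lambda f: f.mean_position)

    def to_json_dict(self, params: AlignParams | None = None) -> dict:
        out = {
            "n_frames": self.aligned.n_frames,
            "width": self.aligned.width,
            "features": [
                {
                    "mean_position": f.mean_position,
                    "polarity": f.polarity.value,
                    "cost": f.cost,
                    "path": f.path.tolist(),
                }
                for f in self.sorted_features()
            ],
            "rejected_regions": [list(r) for r in self.rejected_regions],
        }
        if params is not None:
            out["parameters"] = {
                "feature_half_width": params.feature_half_width,
                "sigma_h": params.preprocess.sigma_h,
                "sigma_v": params.preprocess.sigma_v,
                "sigma_log": params.preprocess.sigma_log,
                "k": params.graph.k,
                "theta": params.graph.theta,
                "source_edge_scheme": params.graph.source_edge_scheme.value,
            }
        return out


# ---------------------------------------------------------------------------
# File I/O


_TIFF_SCALE_KEY = "wpalign_scale"


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix == ".png":
        return "png"
    return "tsv"


def _read_tsv(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                rows.append([float(tok) for tok in line.split("\t")])
            except ValueError as exc:
                raise KymographError(f"non-numeric entry in row {i} of {path}") from exc
    if not rows:
        raise KymographError(f"empty kymograph file: {path}")
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        bad = next(i for i, r in enumerate(rows) if len(r) != len(rows[0]))
        raise KymographError(f"ragged matrix in {path}: row {bad} has {len(rows[bad])} entries, expected {len(rows[0])}")
    return np.asarray(rows, dtype=float)


def _as_matrix(arr: np.ndarray, path: Path, stacked: bool) -> np.ndarray:
    """Coerce image data to 2D.  ``stacked`` distinguishes TIFF page stacks
    (pages, h, w) from single images with a trailing channel axis (h, w, c)."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        if stacked:
            if arr.shape[1] == 1:  # stack of 1 x n frames -> rows
                return arr[:, 0, :]
            raise KymographError(
                f"{path}: multi-frame stack with 2D frames (shape {arr.shape}); "
                "projection of raw movies to kymographs is out of scope")
        if arr.shape[-1] in (3, 4):
            raise KymographError(f"{path}: RGB/RGBA images are not supported; provide grayscale")
    raise KymographError(f"{path}: expected a 2D grayscale image, got shape {arr.shape}")


def read_kymograph(path: str | Path, format: str = "auto", pixel_size: float = 0.16,
                   frame_interval: float | None = None) -> Kymograph:
    """Read a kymograph from a TIFF, PNG, or tab-separated text matrix.

    Intensities are returned as read, with no normalisation, except that a
    TIFF carrying this package's scaling metadata is mapped back to the
    original intensity range.
    """
    path = Path(path)
    if not path.exists():
        raise KymographError(f"no such file: {path}")
    fmt = _detect_format(path, format)
    if fmt == "tsv":
        arr = _read_tsv(path)
    elif fmt == "tiff":
        import tifffile

        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            desc = tif.pages[0].description or ""
        arr = _as_matrix(np.asarray(arr), path, stacked=True).astype(float)
        if _TIFF_SCALE_KEY in desc:
            meta = json.loads(desc)[_TIFF_SCALE_KEY]
            lo, hi = meta["min"], meta["max"]
            arr = lo + arr / 65535.0 * (hi - lo)
    elif fmt == "png":
        import imageio.v3 as iio

        arr = _as_matrix(np.asarray(iio.imread(path)), path, stacked=False).astype(float)
    else:
        raise KymographError(f"unknown kymograph format: {fmt!r}")
    return Kymograph(arr, pixel_size=pixel_size, frame_interval=frame_interval)


def write_kymograph(kymo: Kymograph, path: str | Path, format: str = "auto") -> None:
    """Write a kymograph to disk.

    TSV is lossless (full-precision text).  TIFF and PNG are written as 16-bit
    after min-max linear scaling; for TIFF the scaling is recorded in the image
    description so :func:`read_kymograph` can invert it.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    arr = kymo.intensity
    if fmt == "tsv":
        with open(path, "w") as fh:
            for row in arr:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")
        return
    lo, hi = float(arr.min()), float(arr.max())
    span = hi - lo if hi > lo else 1.0
    scaled = np.round((arr - lo) / span * 65535.0).astype(np.uint16)
    if fmt == "tiff":
        import tifffile

        desc = json.dumps({_TIFF_SCALE_KEY: {"min": lo, "max": hi}})
        tifffile.imwrite(path, scaled, description=desc)
    elif fmt == "png":
        import imageio.v3 as iio

        iio.imwrite(path, scaled)
    else:
        raise KymographError(f"unknown kymograph format: {fmt!r}")


def write_time_trace_tsv(positions: Sequence[int], mean_intensity: Sequence[float],
                         path: str | Path) -> None:
    """Write a two-column (position_px, mean_intensity) TSV time trace."""
    with open(path, "w") as fh:
        fh.write("position_px\tmean_intensity\n")
        for p, v in zip(positions, mean_intensity):
            fh.write(f"{int(p)}\t{float(v)!r}\n")
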