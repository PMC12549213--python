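"""ASC speck detection in the immunostain channel.

Specks are bright, roughly isotropic puncta (one per activated cell) on a
diffuse cytoplasmic background. Detection is a three-stage pipeline:

1. multi-scale Laplacian-of-Gaussian (LoG) blob detection, which finds
   local maxima of the scale-normalised LoG response and reports an
   approximate radius of sqrt(2) * sigma per candidate;
2. a dual intensity threshold: candidates whose local intensity maximum
   falls below ``max(abs_threshold, rel_threshold * channel_max)`` are
   discarded — whichever cut-off is higher wins;
3. greedy non-maximum suppression (NMS) on the surviving circles, keeping
   the brighter of any pair that overlaps more than ``overlap_max``.

All intensities are on the normalised [0, 1] scale (see
:func:`speckquant.io.normalize_channel`); ``peak`` is the image intensity
at the detected centre, not the LoG response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from skimage.feature import blob_log

from .io import ImageField, normalize_channel

# Candidate floor for the LoG response, relative to the strongest response
# in the scale stack. Keeps the candidate stage scale-invariant (so the
# relative intensity threshold behaves identically on dim and bright
# acquisitions) while discarding shot-noise ripples.
_LOG_THRESHOLD_REL = 0.05


@dataclass(frozen=True)
class DetectionParams:
    """Tunables for speck detection.

    min_sigma/max_sigma bound the LoG scale range in pixels (radius is
    about sqrt(2) * sigma, so 1-4 px covers puncta of ~0.7-3 um diameter
    at 0.5 um/px); num_sigma is the number of scales tried. overlap_max
    is the NMS overlap tolerance; abs_threshold and rel_threshold are the
    dual intensity cut-offs on normalised intensity.
    """

    min_sigma: float = 1.0
    max_sigma: float = 4.0
    num_sigma: int = 7
    overlap_max: float = 0.5
    abs_threshold: float = 0.1
    rel_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.min_sigma <= self.max_sigma:
            raise ValueError("require 0 < min_sigma <= max_sigma")
        if self.num_sigma < 1:
            raise ValueError("num_sigma must be >= 1")
        if not 0 <= self.overlap_max <= 1:
            raise ValueError("overlap_max must be in [0, 1]")


@dataclass(frozen=True)
class Speck:
    """One detected ASC punctum (pixel coordinates, 0-based row/col)."""

    row: float
    col: float
    radius: float
    peak: float
    intracellular: bool | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0 <= self.peak <= 1:
            raise ValueError("peak must be in [0, 1]")


def _sort_specks(specks: Sequence[Speck]) -> List[Speck]:
    """Deterministic order: descending peak, ties by ascending row, col."""
    return sorted(specks, key=lambda s: (-s.peak, s.row, s.col))


def detect_blobs_log(
    asc_normalised: np.ndarray, params: DetectionParams
) -> List[Speck]:
    """LoG candidate detection on a normalised ASC raster.

    Returns unfiltered candidates sorted by descending peak intensity.
    Blank rasters yield an empty list.
    """
    raster = np.asarray(asc_normalised, dtype=np.float64)
    if raster.size == 0 or raster.max() <= 0:
        return []
    blobs = blob_log(
        raster,
        min_sigma=params.min_sigma,
        max_sigma=params.max_sigma,
        num_sigma=params.num_sigma,
        threshold=None,
        threshold_rel=_LOG_THRESHOLD_REL,
        overlap=1.0,  # overlap handling is done by our own NMS stage
    )
    specks = []
    for row, col, sigma in blobs:
        r, c = int(round(row)), int(round(col))
        specks.append(
            Speck(
                row=float(row),
                col=float(col),
                radius=float(math.sqrt(2.0) * sigma),
                peak=float(min(raster[r, c], 1.0)),
            )
        )
    return _sort_specks(specks)


def circle_overlap(a: Speck, b: Speck) -> float:
    """Fractional overlap of two circular footprints.

    Defined as the area of intersection divided by the area of the
    *smaller* circle, so a small speck fully inside a large one scores 1.
    """
    d = math.hypot(a.row - b.row, a.col - b.col)
    r1, r2 = max(a.radius, b.radius), min(a.radius, b.radius)
    if d >= r1 + r2:
        return 0.0
    if d <= r1 - r2:
        return 1.0
    # circular-segment ("lens") intersection area
    d2, r1s, r2s = d * d, r1 * r1, r2 * r2
    alpha = math.acos(np.clip((d2 + r1s - r2s) / (2 * d * r1), -1, 1))
    beta = math.acos(np.clip((d2 + r2s - r1s) / (2 * d * r2), -1, 1))
    lens = (
        r1s * (alpha - math.sin(2 * alpha) / 2)
        + r2s * (beta - math.sin(2 * beta) / 2)
    )
    return float(min(lens / (math.pi * r2s), 1.0))


def non_max_suppression(
    specks: Sequence[Speck], overlap_max: float
) -> List[Speck]:
    """Greedy keep-highest NMS.

    Specks are visited in order of descending peak (ties broken by
    ascending row then col); one is discarded iff its overlap with an
    already-kept speck exceeds ``overlap_max``. The surviving set has all
    pairwise overlaps <= overlap_max and preserves the sorted order.
    """
    kept: List[Speck] = []
    kept_rows: List[float] = []
    kept_cols: List[float] = []
    kept_radii: List[float] = []
    for s in _sort_specks(specks):
        if kept:
            # exact lens-area overlap only for circles that can touch
            d = np.hypot(np.array(kept_rows) - s.row, np.array(kept_cols) - s.col)
            near = np.nonzero(d < np.array(kept_radii) + s.radius)[0]
            if any(circle_overlap(s, kept[i]) > overlap_max for i in near):
                continue
        kept.append(s)
        kept_rows.append(s.row)
        kept_cols.append(s.col)
        kept_radii.append(s.radius)
    return kept


def filter_by_threshold(
    specks: Sequence[Speck],
    abs_threshold: float,
    rel_threshold: float,
    channel_max: float,
) -> List[Speck]:
    """Apply the dual cut-off: keep peaks >= max(abs, rel * channel_max)."""
    cutoff = max(abs_threshold, rel_threshold * channel_max)
    return [s for s in specks if s.peak >= cutoff]


def detect_specks(field: ImageField, params: DetectionParams | None = None) -> List[Speck]:
    """Full speck detection for one field: LoG -> threshold -> NMS."""
    params = params or DetectionParams()
    asc = normalize_channel(field.asc, field.bit_depth)
    candidates = detect_blobs_log(asc, params)
    channel_max = float(asc.max()) if asc.size else 0.0
    filtered = filter_by_threshold(
        candidates, params.abs_threshold, params.rel_threshold, channel_max
    )
    return non_max_suppression(filtered, params.overlap_max)


def local_maxima_histogram(
    field: ImageField, params: DetectionParams | None = None, n_bins: int = 50
) -> "np.ndarray":
    """Histogram of candidate local-maximum intensities.

    Mirrors the threshold-tuning view of the assay GUI: the distribution
    of blob local maxima against which the absolute/relative cut-offs are
    chosen. Returns an (n_bins, 2) array of (bin_centre, count).
    """
    params = params or DetectionParams()
    asc = normalize_channel(field.asc, field.bit_depth)
    peaks = [s.peak for s in detect_blobs_log(asc, params)]
    counts, edges = np.histogram(peaks, bins=n_bins, range=(0.0, 1.0))
    centres = (edges[:-1] + edges[1:]) / 2
    return np.column_stack([centres, counts])
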