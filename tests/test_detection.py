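"""Speck detection: LoG candidates, circle overlap, NMS, dual thresholds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speckquant import (
    DetectionParams,
    Speck,
    circle_overlap,
    detect_blobs_log,
    detect_specks,
    filter_by_threshold,
    non_max_suppression,
)
from speckquant.synthetic import tuned_detection_params

from conftest import gaussian_spot, make_field

PARAMS = DetectionParams()


def random_specks(rng, n, span=60.0):
    return [
        Speck(
            row=float(rng.uniform(0, span)),
            col=float(rng.uniform(0, span)),
            radius=float(rng.uniform(1, 8)),
            peak=float(rng.uniform(0.05, 1.0)),
        )
        for _ in range(n)
    ]


# ---------------------------------------------------------------- LoG blobs


def test_blank_raster_yields_no_candidates():
    assert detect_blobs_log(np.zeros((64, 64)), PARAMS) == []


@pytest.mark.parametrize("scale", [1.5, 2.0, 3.0])
def test_single_gaussian_spot_localised_and_sized(scale):
    """One isotropic Gaussian blob: centre within 1 px, radius within 15%
    of the analytic scale-space optimum sqrt(2)*s."""
    img = gaussian_spot((96, 96), 48.0, 40.0, scale, 0.8)
    specks = non_max_suppression(detect_blobs_log(img, PARAMS), 0.5)
    assert len(specks) == 1
    s = specks[0]
    assert math.hypot(s.row - 48, s.col - 40) <= 1.0
    assert abs(s.radius - math.sqrt(2) * scale) <= 0.15 * math.sqrt(2) * scale


def test_two_well_separated_spots_give_two_candidates():
    img = gaussian_spot((128, 128), 40.0, 40.0, 2.0, 0.8) + gaussian_spot(
        (128, 128), 90.0, 40.0, 2.0, 0.6
    )
    specks = non_max_suppression(detect_blobs_log(img, PARAMS), 0.5)
    assert len(specks) == 2
    # descending-peak ordering puts the brighter spot first
    assert specks[0].peak > specks[1].peak


# ---------------------------------------------------------- circle overlap


def _overlap_monte_carlo(a, b, n=10**6, seed=0):
    """Independent oracle: fraction of the smaller circle covered by the
    intersection, by uniform point sampling inside the smaller circle."""
    rng = np.random.default_rng(seed)
    small, large = (a, b) if a.radius <= b.radius else (b, a)
    theta = rng.uniform(0, 2 * np.pi, n)
    r = small.radius * np.sqrt(rng.uniform(0, 1, n))
    pr, pc = small.row + r * np.sin(theta), small.col + r * np.cos(theta)
    inside = (pr - large.row) ** 2 + (pc - large.col) ** 2 <= large.radius**2
    return inside.mean()


def test_circle_overlap_limits():
    a = Speck(row=10, col=10, radius=5, peak=0.5)
    assert circle_overlap(a, a) == 1.0
    far = Speck(row=10, col=25, radius=5, peak=0.5)
    assert circle_overlap(a, far) == 0.0
    inside = Speck(row=11, col=10, radius=1, peak=0.5)
    assert circle_overlap(a, inside) == 1.0


def test_circle_overlap_matches_monte_carlo_oracle():
    a = Speck(row=20, col=20, radius=5, peak=0.5)
    b = Speck(row=20, col=25, radius=5, peak=0.4)
    assert circle_overlap(a, b) == pytest.approx(_overlap_monte_carlo(a, b), abs=0.01)


@given(
    dr=st.floats(0, 20),
    ra=st.floats(1, 8),
    rb=st.floats(1, 8),
)
@settings(max_examples=60, deadline=None)
def test_circle_overlap_symmetric_and_bounded(dr, ra, rb):
    a = Speck(row=0, col=0, radius=ra, peak=0.5)
    b = Speck(row=dr, col=0, radius=rb, peak=0.5)
    o = circle_overlap(a, b)
    assert 0.0 <= o <= 1.0
    assert o == pytest.approx(circle_overlap(b, a), abs=1e-12)


# ------------------------------------------------------------------- NMS


def _nms_brute_force(specks, overlap_max):
    """Independent restatement of greedy keep-highest suppression: examine
    every candidate against every previously accepted one, no shortcuts."""
    order = sorted(specks, key=lambda s: (-s.peak, s.row, s.col))
    accepted = []
    for cand in order:
        ok = True
        for kept in accepted:
            if circle_overlap(cand, kept) > overlap_max:
                ok = False
                break
        if ok:
            accepted.append(cand)
    return accepted


def test_nms_trivial_cases():
    a = Speck(row=10, col=10, radius=3, peak=0.9)
    b = Speck(row=10, col=10, radius=3, peak=0.8)
    assert non_max_suppression([a, b], 0.5) == [a]
    c = Speck(row=40, col=40, radius=3, peak=0.7)
    assert non_max_suppression([a, c], 0.5) == [a, c]


def test_nms_matches_brute_force_on_random_sets(rng):
    for _ in range(200):
        specks = random_specks(rng, int(rng.integers(0, 11)))
        assert non_max_suppression(specks, 0.5) == _nms_brute_force(specks, 0.5)


def test_nms_idempotent_and_pairwise_bounded(rng):
    for _ in range(30):
        specks = random_specks(rng, 25, span=40)
        once = non_max_suppression(specks, 0.4)
        assert non_max_suppression(once, 0.4) == once
        for i, a in enumerate(once):
            for b in once[i + 1 :]:
                assert circle_overlap(a, b) <= 0.4


# ------------------------------------------------------------- thresholds


@pytest.mark.parametrize(
    "abs_t,rel_t,cmax,kept_peaks",
    [
        (0.3, 0.2, 1.0, [0.35]),  # absolute dominates, cut-off 0.3
        (0.1, 0.5, 0.8, []),  # relative dominates, cut-off 0.4
        (0.0, 0.0, 1.0, [0.25, 0.35]),  # no cut-off: identity
    ],
)
def test_dual_threshold_semantics(abs_t, rel_t, cmax, kept_peaks):
    specks = [
        Speck(row=1, col=1, radius=2, peak=0.25),
        Speck(row=5, col=5, radius=2, peak=0.35),
    ]
    kept = filter_by_threshold(specks, abs_t, rel_t, cmax)
    assert sorted(s.peak for s in kept) == kept_peaks


# ----------------------------------------------------------- full pipeline


def test_blank_field_detects_nothing():
    field = make_field(np.zeros((64, 64)))
    assert detect_specks(field) == []


def test_planted_specks_recovered_one_to_one(rng):
    """10 planted high-SNR puncta on a noisy background: each matched
    within 2 px, no extras."""
    shape = (200, 200)
    coords = []
    while len(coords) < 10:
        r, c = rng.uniform(15, 185, 2)
        if all(math.hypot(r - r0, c - c0) > 18 for r0, c0 in coords):
            coords.append((r, c))
    img = rng.normal(0.02, 0.01, shape).clip(0, 1)
    for r, c in coords:
        img += gaussian_spot(shape, r, c, 2.0, 0.7)
    field = make_field(img, bit_depth=16)
    specks = detect_specks(field, tuned_detection_params())
    assert len(specks) == 10
    for s in specks:
        assert min(math.hypot(s.row - r, s.col - c) for r, c in coords) <= 2.0


def test_threshold_above_all_peaks_empties_output(small_field):
    field, _ = small_field
    params = DetectionParams(abs_threshold=0.99, rel_threshold=0.99)
    assert detect_specks(field, params) == []


def test_speck_count_monotone_in_thresholds(small_field):
    """Raising either cut-off never increases the detected count."""
    field, _ = small_field
    counts = {}
    grid = [0.05, 0.2, 0.35, 0.5, 0.8]
    for abs_t in grid:
        for rel_t in grid:
            params = DetectionParams(abs_threshold=abs_t, rel_threshold=rel_t)
            counts[(abs_t, rel_t)] = len(detect_specks(field, params))
    for i, a in enumerate(grid[:-1]):
        for r in grid:
            assert counts[(grid[i + 1], r)] <= counts[(a, r)]
            assert counts[(r, grid[i + 1])] <= counts[(r, a)]


def test_translation_equivariance():
    img = gaussian_spot((120, 120), 50.0, 44.0, 2.0, 0.8)
    shifted = np.roll(np.roll(img, 13, axis=0), -9, axis=1)
    base = detect_specks(make_field(img, bit_depth=16), tuned_detection_params())
    moved = detect_specks(make_field(shifted, bit_depth=16), tuned_detection_params())
    assert len(base) == len(moved) == 1
    assert moved[0].row - base[0].row == pytest.approx(13, abs=0.5)
    assert moved[0].col - base[0].col == pytest.approx(-9, abs=0.5)


@pytest.mark.parametrize("k", [0.25, 0.5, 1.0])
def test_relative_threshold_scale_invariance(k):
    """With abs_threshold = 0, a uniform dimming of the raster leaves the
    detected set unchanged."""
    img = gaussian_spot((96, 96), 30.0, 30.0, 2.0, 0.8) + gaussian_spot(
        (96, 96), 70.0, 60.0, 2.0, 0.2
    )
    params = DetectionParams(abs_threshold=0.0, rel_threshold=0.3)
    base = detect_specks(make_field(img, bit_depth=16), params)
    dimmed = detect_specks(make_field(img * k, bit_depth=16), params)
    assert len(base) == len(dimmed) == 1
    assert (dimmed[0].row, dimmed[0].col) == (base[0].row, base[0].col)
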