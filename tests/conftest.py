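"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
import shapely
import shapely.affinity

import palsymetry as pm


@pytest.fixture
def scheme():
    return pm.WFLW_SCHEME


@pytest.fixture
def symmetric_subject():
    """Noise-free, perfectly symmetric synthetic clip (30 fps, 5 s)."""
    return pm.generate_subject(pm.SyntheticParams())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately brute-force / closed-form; they never
# call the code paths they are used to check)


def mwu_exact_oracle(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney p by full enumeration of rank assignments
    (tie-free data only).  Returns (U_of_a, p)."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n_a, n_b = len(a), len(b)
    u_obs = sum(ranks[v] for v in a) - n_a * (n_a + 1) / 2
    n = n_a + n_b
    us = []
    for combo in combinations(range(1, n + 1), n_a):
        us.append(sum(combo) - n_a * (n_a + 1) / 2)
    us = np.array(us)
    lo = min(u_obs, n_a * n_b - u_obs)
    hi = max(u_obs, n_a * n_b - u_obs)
    p = (np.sum(us <= lo) + np.sum(us >= hi)) / len(us)
    return u_obs, float(min(p, 1.0))


def fold_area_ratio_oracle(polygon_xy: np.ndarray) -> float:
    """Exact continuous fold-asymmetry of a simple polygon about the line
    x = 0, by polygon clipping: |R xor L'| / (|R| + |L|) in area."""
    poly = shapely.Polygon(polygon_xy)
    assert poly.is_valid and poly.area > 0
    minx, miny, maxx, maxy = poly.bounds
    big = max(abs(minx), abs(maxx), 1.0) * 2
    right = poly.intersection(shapely.box(-big, miny - 1, 0.0, maxy + 1))
    left = poly.intersection(shapely.box(0.0, miny - 1, big, maxy + 1))
    left_folded = shapely.affinity.scale(left, xfact=-1, yfact=1, origin=(0, 0))
    inter = right.intersection(left_folded)
    a_r, a_l, a_i = right.area, left.area, inter.area
    return (a_r + a_l - 2 * a_i) / (a_r + a_l)


def random_simple_polygon(rng: np.random.Generator, n_vertices: int = 12) -> np.ndarray:
    """Star-shaped (hence simple) polygon around a random center near the
    midline, with anisotropic radii so left/right areas differ.  Angles are
    jittered-regular so every angular gap stays below pi, which guarantees
    the angular-sort construction yields a simple polygon."""
    angles = 2 * np.pi * (np.arange(n_vertices) + rng.uniform(0, 0.9, n_vertices)) / n_vertices
    radii = rng.uniform(0.3, 1.0, n_vertices)
    cx = rng.uniform(-0.3, 0.3)
    cy = rng.uniform(-0.5, 0.5)
    x = cx + radii * np.cos(angles) * rng.uniform(0.7, 1.3)
    y = cy + radii * np.sin(angles)
    return np.column_stack([x, y])


def youden_bruteforce_oracle(labels, probs) -> tuple[float, float]:
    """Best (cutoff, J) by trying every candidate threshold directly."""
    labels = np.asarray(labels)
    probs = np.asarray(probs)
    best_j, best_cut = -np.inf, None
    for cut in sorted(set(probs), reverse=True):
        called = probs >= cut
        tpr = np.sum(called & (labels == 1)) / np.sum(labels == 1)
        fpr = np.sum(called & (labels == 0)) / np.sum(labels == 0)
        j = tpr - fpr
        if j > best_j:  # ties keep the larger (earlier) threshold
            best_j, best_cut = j, cut
    return best_cut, best_j


def similarity_transform(points: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random rotation + uniform scale + translation of (..., 2) points."""
    theta = rng.uniform(0, 2 * np.pi)
    scale = rng.uniform(0.25, 4.0)
    shift = rng.uniform(-500, 500, size=2)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    return scale * points @ rot.T + shift
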