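"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive each operation from its definition
(queue floods, exhaustive scans) rather than reusing any package code, so
agreement between the two routes is meaningful.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from ichseg.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default ellipsoid phantom without HU noise (truth is exact)."""
    return make_phantom(PhantomSpec(noise_sigma=0.0, rng_seed=11))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Multi-slice ellipsoid phantom with the standard 4 HU noise."""
    return make_phantom(PhantomSpec(noise_sigma=4.0, rng_seed=12,
                                    semi_axes_mm=(16.0, 20.0, 18.0)))


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A coarse grid spec that keeps slow tests fast."""
    return PhantomSpec(grid=(6, 96, 96), spacing=(7.2, 0.726, 0.644),
                       semi_axes_mm=(7.2, 10.0, 8.0), noise_sigma=0.0,
                       rng_seed=21)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def bfs_flood(img: np.ndarray, seeds, tau: float, connectivity: int,
              domain: np.ndarray | None = None) -> np.ndarray:
    """Literal queue-based seeded flood: iterate inclusion to fixpoint.

    Each seed carries its own reference intensity; a pixel joins when it
    is adjacent to an included pixel of the same flood and differs from
    the flood's reference by at most tau.
    """
    img = np.asarray(img, dtype=float)
    dom = np.ones(img.shape, bool) if domain is None else np.asarray(domain, bool)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    out = np.zeros(img.shape, bool)
    for seed in seeds:
        ref = img[tuple(seed)]
        seen = np.zeros(img.shape, bool)
        q = deque([tuple(seed)])
        seen[tuple(seed)] = True
        while q:
            r, c = q.popleft()
            if not dom[r, c] or abs(img[r, c] - ref) > tau + 1e-12:
                continue
            out[r, c] = True
            for dr, dc in nbrs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < img.shape[0] and 0 <= cc < img.shape[1] \
                        and not seen[rr, cc]:
                    seen[rr, cc] = True
                    q.append((rr, cc))
    return out


def otsu_exhaustive(values, bins: int = 256):
    """Exhaustive scan over interior bin edges, maximizing the
    between-class variance computed from first principles."""
    values = np.asarray(values, dtype=float).ravel()
    edges = np.histogram_bin_edges(values, bins=bins)
    best_t, best_s = None, -1.0
    n = values.size
    for t in edges[1:-1]:
        lo = values[values < t]
        hi = values[values >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / n, hi.size / n
        s = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if s > best_s + 1e-15:  # strict improvement: ties keep smaller t
            best_s, best_t = s, t
    return best_t, best_s


def feret_exhaustive(points_mm: np.ndarray) -> float:
    """Maximum pairwise distance by the O(n^2) double loop."""
    best = 0.0
    pts = np.asarray(points_mm, dtype=float)
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = float(np.hypot(*(pts[i] - pts[j])))
            if d > best:
                best = d
    return best


def anova_icc21(a, b):
    """ICC(2,1) from an independent from-scratch two-way ANOVA."""
    x = np.column_stack([np.asarray(a, float), np.asarray(b, float)])
    n, k = x.shape
    grand = x.mean()
    ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
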