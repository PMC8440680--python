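"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately recomputes results by the most literal route
available (explicit window enumeration, explicit normal equations) and
shares no code path with the package internals it checks.
"""

from __future__ import annotations

import numpy as np


def phansalkar_brute_force(pixels: np.ndarray, radius: int, k: float, r: float,
                           p: float, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel Phansalkar by explicit circular-window enumeration.

    Mirror padding via ``np.pad(mode="symmetric")``; exact integer window
    sums followed by the same closed-form threshold expression.  Returns
    (threshold map, FD mask).
    """
    pixels = np.asarray(pixels)
    h, w = pixels.shape
    padded = np.pad(pixels, radius, mode="symmetric").astype(np.int64)
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    disk = (yy * yy + xx * xx) <= radius * radius
    n = int(disk.sum())
    t = np.empty((h, w), dtype=float)
    for i in range(h):
        for j in range(w):
            win = padded[i:i + 2 * radius + 1, j:j + 2 * radius + 1][disk]
            s1 = int(win.sum())
            s2 = int((win * win).sum())
            mu = s1 / (255.0 * n)
            var = s2 / (255.0**2 * n) - mu * mu
            sd = np.sqrt(max(var, 0.0))
            t[i, j] = mu * (1.0 + p * np.exp(-q * mu) + k * (sd / r - 1.0))
    mask = (pixels / 255.0) < t
    return t, mask


def fit_line_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line by explicit 2x2 normal equations; (slope, intercept, rss)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    A = np.array([[x.size, x.sum()], [x.sum(), (x * x).sum()]])
    b = np.array([y.sum(), (x * y).sum()])
    c0, c1 = np.linalg.solve(A, b)
    resid = y - (c0 + c1 * x)
    return float(c1), float(c0), float((resid**2).sum())


def nested_slope_f_oracle(x1, y1, x2, y2) -> tuple[float, float]:
    """Slope-equality and intercept-equality F by fitting the three nested
    models through explicit design matrices; returns (F_slopes, F_intercepts)."""
    x1, y1, x2, y2 = (np.asarray(v, float) for v in (x1, y1, x2, y2))
    n = x1.size + x2.size

    def rss(X, y):
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    g = np.concatenate([np.zeros(x1.size), np.ones(x2.size)])
    x = np.concatenate([x1, x2])
    y = np.concatenate([y1, y2])
    one = np.ones(n)
    X_sep = np.column_stack([one, g, x, g * x])          # separate lines
    X_common = np.column_stack([one, g, x])              # common slope
    X_single = np.column_stack([one, x])                 # single line
    rss_sep, rss_common, rss_single = rss(X_sep, y), rss(X_common, y), rss(X_single, y)
    f_slope = (rss_common - rss_sep) / (rss_sep / (n - 4))
    f_inter = (rss_single - rss_common) / (rss_common / (n - 3))
    return float(f_slope), float(f_inter)


def binned_slope_oracle(areas_um2: np.ndarray, bin_decades: float) -> tuple[float, float]:
    """Bin areas in equal log10 bins spanning [min, max] and fit the occupied
    bins by normal equations; returns (slope, intercept)."""
    la = np.log10(np.asarray(areas_um2, float))
    lo, hi = la.min(), la.max()
    n_bins = max(1, int(np.ceil((hi - lo) / bin_decades - 1e-9)))
    edges = lo + np.arange(n_bins + 1) * bin_decades
    counts, _ = np.histogram(la, bins=edges)
    centers = edges[:-1] + bin_decades / 2.0
    keep = counts > 0
    slope, intercept, _ = fit_line_normal_equations(
        centers[keep], np.log10(counts[keep].astype(float))
    )
    return slope, intercept
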