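"""Independent brute-force oracles used by unit and acceptance tests."""

import numpy as np


def exhaustive_moment_threshold(hist: np.ndarray, centers: np.ndarray):
    """Exhaustive moment-preservation threshold search.

    For every candidate threshold bin t, construct the bilevel image with
    below-fraction q = cumulative mass through t and the two levels that
    preserve the first two gray-level moments exactly (the unique
    two-point distribution with mean m1 and variance m2 - m1^2 carrying
    mass q below the mean-side level); score it by the absolute error of
    the third moment and return the argmin bin. Independent of the
    closed-form implementation route.
    """
    p = np.asarray(hist, dtype=np.float64)
    p = p / p.sum()
    z = np.asarray(centers, dtype=np.float64)
    m1 = float(np.sum(p * z))
    m2 = float(np.sum(p * z**2))
    m3 = float(np.sum(p * z**3))
    d = m2 - m1 * m1
    cum = np.cumsum(p)
    best, best_err = None, np.inf
    for t in range(len(z) - 1):
        q = cum[t]
        pr = 1.0 - q
        if q <= 0 or pr <= 0:
            continue
        z0 = m1 - np.sqrt(d * pr / q)
        z1 = m1 + np.sqrt(d * q / pr)
        err = abs(q * z0**3 + pr * z1**3 - m3)
        if err < best_err:
            best_err, best = err, t
    return best


def occupied_level_distance(hist: np.ndarray, idx_a: int, idx_b: int) -> int:
    """Distance between two threshold bins counted in occupied gray levels.

    Thresholds separated only by empty histogram bins yield identical
    binarizations, so agreement "within one gray level" is measured on
    the occupied-bin scale.
    """
    rank = np.cumsum(np.asarray(hist) > 0)
    return abs(int(rank[idx_a]) - int(rank[idx_b]))


def brute_force_ks_d(a, b) -> float:
    """KS D by direct ECDF evaluation at every pooled sample point."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    pooled = np.concatenate([a, b])
    return max(
        abs(np.mean(a <= x) - np.mean(b <= x)) for x in pooled
    )


def gaussian_halfmax_area_px(sigma_major_px: float, sigma_minor_px: float) -> float:
    """Pixels enclosed by the half-maximum contour of an elliptical Gaussian.

    The contour is the ellipse (u/sa)^2 + (v/sb)^2 = 2 ln 2 with area
    pi * sa * sb * 2 ln 2.
    """
    return np.pi * sigma_major_px * sigma_minor_px * 2.0 * np.log(2.0)
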