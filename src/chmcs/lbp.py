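"""Extended opponent-color local binary patterns (EOCLBP) and histogram statistics.

The LBP operator labels each pixel with a P-bit code obtained by comparing
the P neighbors on a circle of radius delta against the center value; bit p
is 1 when the neighbor is greater than or equal to the center. The opponent
color extension compares the *center* taken in channel Cg against *neighbors*
taken in channel Cg', for all 9 ordered channel pairs (3 within-component,
6 between-component). Comparing against a circle of neighbors in all
directions and thresholding (rather than differencing) makes the codes
invariant to monotonic intensity changes.

Circle positions are pre-sampled: each neighbor offset is rounded to the
nearest integer pixel, with no bilinear interpolation. Neighbor p = 0 sits
east of the center and the circle is traversed counter-clockwise.

Rather than using the 2^P histogram bins directly as features, each code
histogram is summarized by 17 statistics: 6 first-order (mean, median, mode,
standard deviation and two spread ranges of the code distribution) and 11
second-order Haralick-style features evaluated on the product measure
``q(i, j) = p(i) p(j)`` induced by the histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "LBP_SETTINGS",
    "LBP_PAIRS",
    "STAT17_NAMES",
    "LbpCodeImage",
    "sample_offsets",
    "compute_lbp",
    "lbp_histogram",
    "stats17",
]

#: The 13 (P, delta) settings of the standard grid.
LBP_SETTINGS = (
    (8, 1), (8, 2), (8, 3), (8, 5), (8, 10),
    (12, 2), (12, 3), (12, 5), (12, 10),
    (16, 2), (16, 3), (16, 5), (16, 10),
)

#: The 9 ordered component pairs (center channel, neighbor channel):
#: 3 within-component followed by the 6 between-component pairs.
LBP_PAIRS = (
    (1, 1), (2, 2), (3, 3),
    (1, 2), (1, 3), (2, 3), (2, 1), (3, 1), (3, 2),
)

#: Names of the 17 histogram statistics: 6 first-order then 11 second-order.
STAT17_NAMES = (
    "mean", "median", "mode", "std", "iqr", "idr",
    "energy", "contrast", "correlation", "variance", "idm",
    "sum_average", "sum_entropy", "entropy",
    "difference_variance", "difference_entropy", "homogeneity",
)


@dataclass(frozen=True)
class LbpCodeImage:
    """LBP codes of the valid (non-margin) pixels of one image."""

    codes: np.ndarray  # (H - 2 delta) x (W - 2 delta) integers in [0, 2^P - 1]
    p_neighbors: int
    delta: int


def _check_setting(setting: tuple[int, int]) -> tuple[int, int]:
    p, delta = setting
    if (p, delta) not in LBP_SETTINGS:
        raise ValueError(f"(P, delta) = {setting} is not in the supported list {LBP_SETTINGS}")
    return p, delta


def sample_offsets(setting: tuple[int, int]) -> list[tuple[int, int]]:
    """Pre-sampled integer (row, col) offsets of the P neighbors.

    Offset p is ``(round(-delta sin(2 pi p / P)), round(delta cos(2 pi p / P)))``
    so neighbor 0 is the east pixel and the circle is walked
    counter-clockwise in image coordinates (row axis pointing down).
    Rounding is to nearest, ties to even.
    """
    p, delta = setting
    angles = 2.0 * np.pi * np.arange(p) / p
    rows = np.rint(-delta * np.sin(angles)).astype(int)
    cols = np.rint(delta * np.cos(angles)).astype(int)
    return [(int(r), int(c)) for r, c in zip(rows, cols)]


def compute_lbp(
    center_plane: np.ndarray,
    neighbor_plane: np.ndarray,
    setting: tuple[int, int],
) -> LbpCodeImage:
    """LBP code image for the ordered pair (center channel, neighbor channel).

    ``code(x) = sum_p s(neighbor_plane[x + o_p] - center_plane[x]) 2^p`` with
    ``s(t) = 1`` iff ``t >= 0``, computed for every pixel at distance >= delta
    from all four borders.
    """
    p, delta = _check_setting(setting)
    c = np.asarray(center_plane, dtype=np.int64)
    nb = np.asarray(neighbor_plane, dtype=np.int64)
    if c.shape != nb.shape:
        raise ValueError(f"planes must share dimensions, got {c.shape} and {nb.shape}")
    h, w = c.shape
    if h <= 2 * delta or w <= 2 * delta:
        raise ValueError(
            f"image of shape {c.shape} is too small for the margin delta={delta}"
        )
    center = c[delta:h - delta, delta:w - delta]
    codes = np.zeros_like(center)
    for bit, (dr, dc) in enumerate(sample_offsets((p, delta))):
        neigh = nb[delta + dr:h - delta + dr, delta + dc:w - delta + dc]
        codes |= (neigh >= center).astype(np.int64) << bit
    return LbpCodeImage(codes=codes, p_neighbors=p, delta=delta)


def lbp_histogram(code_image: LbpCodeImage) -> np.ndarray:
    """2^P bin counts of the code image; counts sum to the valid-pixel count."""
    n_bins = 1 << code_image.p_neighbors
    return np.bincount(code_image.codes.ravel(), minlength=n_bins)


def _lower_quantile(values: np.ndarray, cdf: np.ndarray, q: float) -> float:
    """Smallest code value whose cumulative probability reaches q."""
    return float(values[np.searchsorted(cdf, q)])


def stats17(hist: np.ndarray) -> np.ndarray:
    """The 17 statistics of an LBP histogram, ordered as :data:`STAT17_NAMES`.

    First-order statistics describe the discrete code-value distribution
    ``p(v) = counts[v] / sum(counts)``: mean, median, mode (smallest index on
    ties), standard deviation, interquartile range Q3 - Q1 and interdecile
    range P90 - P10 (quantiles are the smallest code reaching the target
    cumulative probability).

    Second-order statistics evaluate 11 Haralick formulas on the product
    measure ``q(i, j) = p(i) p(j)``. Because q factorizes, every feature
    reduces to the marginal p and its sum/difference distributions, which are
    obtained by FFT convolution; the 2^P x 2^P matrix is never materialized.
    Independence makes the correlation feature identically 0; constant
    features like this one are tolerated and filtered out later by the
    zero-variance screen of the feature selection stage.
    """
    counts = np.asarray(hist, dtype=np.float64)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("a non-empty 1-D histogram is required")
    if (counts < 0).any():
        raise ValueError("histogram counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("histogram must contain at least one count")
    p = counts / total
    n = p.size
    v = np.arange(n, dtype=np.float64)

    mean = float(v @ p)
    var = float(((v - mean) ** 2) @ p)
    sd = float(np.sqrt(var))
    cdf = np.cumsum(p)
    median = _lower_quantile(v, cdf, 0.5)
    mode = float(np.argmax(counts))
    q1 = _lower_quantile(v, cdf, 0.25)
    q3 = _lower_quantile(v, cdf, 0.75)
    p10 = _lower_quantile(v, cdf, 0.10)
    p90 = _lower_quantile(v, cdf, 0.90)
    iqr = q3 - q1
    idr = p90 - p10

    # Sum and difference distributions of the product measure q = p (x) p.
    if n > 1:
        p_sum = fftconvolve(p, p)  # length 2n - 1, support 0..2n-2
        cross = fftconvolve(p, p[::-1])  # lag k at index n - 1 + k
        p_diff = np.empty(n)
        p_diff[0] = cross[n - 1]
        p_diff[1:] = cross[n:] + cross[n - 2::-1]
        p_sum = np.clip(p_sum, 0.0, None)
        p_diff = np.clip(p_diff, 0.0, None)
    else:
        p_sum = np.array([1.0])
        p_diff = np.array([1.0])
    k_sum = np.arange(p_sum.size, dtype=np.float64)
    k_diff = np.arange(p_diff.size, dtype=np.float64)

    marg_energy = float((p ** 2).sum())
    energy = marg_energy ** 2
    contrast = float((k_diff ** 2) @ p_diff)  # = 2 var
    correlation = 0.0  # product measure: channels are independent
    idm = float((p_diff / (1.0 + k_diff ** 2)).sum())
    homogeneity = float((p_diff / (1.0 + k_diff)).sum())
    sum_average = float(k_sum @ p_sum)

    def entropy(dist: np.ndarray) -> float:
        d = dist[dist > 1e-300]
        return float(-(d * np.log2(d)).sum())

    sum_entropy = entropy(p_sum)
    ent = 2.0 * entropy(p)
    mu_d = float(k_diff @ p_diff)
    difference_variance = float(((k_diff - mu_d) ** 2) @ p_diff)
    difference_entropy = entropy(p_diff)

    return np.array([
        mean, median, mode, sd, iqr, idr,
        energy, contrast, correlation, var, idm,
        sum_average, sum_entropy, ent,
        difference_variance, difference_entropy, homogeneity,
    ])
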