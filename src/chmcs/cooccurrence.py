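"""Reduced-size chromatic cooccurrence matrices (RSCCM) and Haralick features.

An RSCCM is a ``Q x Q`` normalized two-dimensional histogram of quantized
value pairs between each pixel (taken in channel Cg) and its neighbors
(taken in channel Cg'). With ``g = g'`` it is the classical gray-level
cooccurrence matrix of one channel; with ``g != g'`` it captures the spatial
interaction *between* channels. The quantization level Q is reduced below
256 to keep the matrices small, and the neighborhood is the isotropic
8-neighbor set at infinity-norm distance delta, which makes the descriptor
insensitive to texture orientation.

Thirteen Haralick statistics summarize each matrix: energy, homogeneity,
contrast, correlation, variance, inverse difference moment, sum average,
sum entropy, entropy, difference variance, difference entropy and the two
information measures of correlation. Logarithms are base 2 with the
convention ``0 * log 0 = 0``; correlation is defined as 0 when a marginal
standard deviation vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RSCCM_DELTAS",
    "RSCCM_Q_LEVELS",
    "RSCCM_SETTINGS",
    "RSCCM_PAIRS",
    "HARALICK_NAMES",
    "Rsccm",
    "quantize_channel",
    "isotropic_offsets",
    "compute_rsccm",
    "haralick13",
]

#: Neighborhood distances of the standard setting grid.
RSCCM_DELTAS = (1, 2, 3, 5, 10)
#: Quantization levels of the standard setting grid.
RSCCM_Q_LEVELS = (16, 32, 64, 128, 256)
#: The 25 (delta, Q) settings of the full grid.
RSCCM_SETTINGS = tuple((d, q) for d in RSCCM_DELTAS for q in RSCCM_Q_LEVELS)
#: The 6 unordered component pairs (g, g') with g <= g'. The pair (g', g)
#: would give the transpose of (g, g') because the 8-offset set is symmetric.
RSCCM_PAIRS = ((1, 1), (2, 2), (3, 3), (1, 2), (1, 3), (2, 3))

HARALICK_NAMES = (
    "energy",
    "homogeneity",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)


@dataclass(frozen=True)
class Rsccm:
    """A normalized cooccurrence matrix with its configuration."""

    entries: np.ndarray  # Q x Q, sums to 1
    q_levels: int
    pair: tuple[int, int]
    setting: tuple[int, int]  # (delta, Q)
    n_pairs_counted: int


def _check_setting(setting: tuple[int, int]) -> tuple[int, int]:
    delta, q = setting
    if delta not in RSCCM_DELTAS or q not in RSCCM_Q_LEVELS:
        raise ValueError(
            f"(delta, Q) = {setting} is not in the supported grid "
            f"{RSCCM_DELTAS} x {RSCCM_Q_LEVELS}"
        )
    return delta, q


def quantize_channel(plane: np.ndarray, q_levels: int) -> np.ndarray:
    """Requantize an 8-bit plane to ``q_levels`` levels.

    Value v maps to ``floor(v * Q / 256)``, giving levels in [0, Q-1].
    """
    if q_levels not in RSCCM_Q_LEVELS:
        raise ValueError(f"Q = {q_levels} is not in the supported grid {RSCCM_Q_LEVELS}")
    plane = np.asarray(plane)
    if not np.issubdtype(plane.dtype, np.integer):
        raise ValueError("an integer 8-bit plane is required")
    if plane.min() < 0 or plane.max() > 255:
        raise ValueError("plane values must lie in [0, 255]")
    return (plane.astype(np.int64) * q_levels) // 256


def isotropic_offsets(delta: int) -> tuple[tuple[int, int], ...]:
    """The 8 neighbor offsets at infinity-norm distance delta (4 directions)."""
    d = int(delta)
    return (
        (0, d), (0, -d), (d, 0), (-d, 0),
        (d, d), (d, -d), (-d, d), (-d, -d),
    )


def compute_rsccm(
    plane_g: np.ndarray,
    plane_gp: np.ndarray,
    setting: tuple[int, int],
    pair: tuple[int, int] = (1, 1),
    offsets: tuple[tuple[int, int], ...] | None = None,
) -> Rsccm:
    """Count cooccurrences of quantized values between two planes.

    Entry (a, b) is the number of ordered (pixel, neighbor) pairs whose value
    is ``a`` in ``plane_g`` at the pixel and ``b`` in ``plane_gp`` at the
    neighbor, over the 8 isotropic offsets at distance delta, divided by the
    total number of in-bounds pairs. Pairs whose neighbor falls outside the
    image are skipped, so normalization uses the actual pair count.

    ``offsets`` overrides the neighbor set (e.g. a two-pixel directional
    neighborhood); the default is :func:`isotropic_offsets`.
    """
    delta, q = _check_setting(setting)
    a = np.asarray(plane_g)
    b = np.asarray(plane_gp)
    if a.shape != b.shape:
        raise ValueError(f"planes must share dimensions, got {a.shape} and {b.shape}")
    if a.min() < 0 or a.max() >= q or b.min() < 0 or b.max() >= q:
        raise ValueError(f"planes must be quantized to [0, {q - 1}] before counting")
    if offsets is None:
        offsets = isotropic_offsets(delta)

    h, w = a.shape
    counts = np.zeros(q * q, dtype=np.int64)
    total = 0
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        center = a[r0:r1, c0:c1]
        neigh = b[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        flat = center.astype(np.int64) * q + neigh.astype(np.int64)
        counts += np.bincount(flat.ravel(), minlength=q * q)
        total += flat.size
    if total == 0:
        raise ValueError(
            f"no valid pixel pair at delta={delta} for an image of shape {a.shape}"
        )
    entries = counts.reshape(q, q) / total
    return Rsccm(entries=entries, q_levels=q, pair=tuple(pair), setting=(delta, q),
                 n_pairs_counted=total)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def haralick13(m: Rsccm | np.ndarray) -> np.ndarray:
    """The 13 Haralick features of a normalized cooccurrence matrix.

    Returns the features in the order of :data:`HARALICK_NAMES`.
    """
    p = m.entries if isinstance(m, Rsccm) else np.asarray(m, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("a square matrix is required")
    if abs(p.sum() - 1.0) > 1e-8 or (p < 0).any():
        raise ValueError("a normalized matrix (non-negative entries summing to 1) is required")
    n = p.shape[0]
    i = np.arange(n, dtype=np.float64)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sd_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((i - mu_y) ** 2) @ py))

    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = np.abs(ii - jj).astype(np.int64)
    # p_{x+y} over k = 0..2n-2 and p_{|x-y|} over k = 0..n-1
    p_sum = np.bincount((ii + jj).astype(np.int64).ravel(), weights=p.ravel(),
                        minlength=2 * n - 1)
    p_diff = np.bincount(diff.ravel(), weights=p.ravel(), minlength=n)
    k_sum = np.arange(2 * n - 1, dtype=np.float64)
    k_diff = np.arange(n, dtype=np.float64)

    energy = float((p ** 2).sum())
    homogeneity = float((p_diff / (1.0 + k_diff)).sum())
    contrast = float((k_diff ** 2) @ p_diff)
    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float(((i - mu_x) ** 2) @ px)
    idm = float((p_diff / (1.0 + k_diff ** 2)).sum())
    sum_average = float(k_sum @ p_sum)
    sum_entropy = _entropy(p_sum)
    entropy = _entropy(p.ravel())
    mu_d = float(k_diff @ p_diff)
    difference_variance = float(((k_diff - mu_d) ** 2) @ p_diff)
    difference_entropy = _entropy(p_diff)

    hx = _entropy(px)
    hy = _entropy(py)
    pxy = np.outer(px, py)
    mask = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[mask] * np.log2(pxy[mask])).sum())
    hxy2 = _entropy(pxy.ravel())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array([
        energy, homogeneity, contrast, correlation, variance, idm,
        sum_average, sum_entropy, entropy, difference_variance,
        difference_entropy, imc1, imc2,
    ])
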