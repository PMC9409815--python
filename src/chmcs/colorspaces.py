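"""Device-dependent color space conversions for 8-bit RGB texture images.

Color textures are described here in five device-dependent spaces, one
representative per classical family:

* ``RGB`` — the acquisition (primary) space, returned unchanged;
* ``RnGnBn`` — normalized primaries, each channel divided by the channel sum
  (chromaticity coordinates, insensitive to intensity scaling);
* ``YCbCr`` — a luminance–chrominance space (ITU-R BT.601, full range);
* ``I1I2I3`` — Ohta's approximately decorrelated components;
* ``HSV`` — a perceptual hue/saturation/value space (hexcone model).

Device-independent spaces (Lab, Luv) are deliberately excluded: they require
knowledge of the illuminant and acquisition device, which is unavailable for
typical texture collections.

All conversions return three integer planes in [0, 255] so that downstream
descriptors (cooccurrence matrices, local binary patterns) can treat every
channel of every space uniformly as an 8-bit plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SPACES", "ColorPlanes", "convert"]

#: The closed set of supported color space codes.
SPACES = ("RGB", "HSV", "YCbCr", "I1I2I3", "RnGnBn")


@dataclass(frozen=True)
class ColorPlanes:
    """Three 8-bit channel planes of one image in a named color space.

    Channels are denoted C1, C2, C3 whatever the space (e.g. C1=H, C2=S,
    C3=V in HSV).
    """

    space: str
    c1: np.ndarray
    c2: np.ndarray
    c3: np.ndarray

    @property
    def height(self) -> int:
        return self.c1.shape[0]

    @property
    def width(self) -> int:
        return self.c1.shape[1]

    def channel(self, g: int) -> np.ndarray:
        """Return plane Cg for g in {1, 2, 3}."""
        if g not in (1, 2, 3):
            raise ValueError(f"channel index must be 1, 2 or 3, got {g}")
        return (self.c1, self.c2, self.c3)[g - 1]


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 2:
        raise ValueError("grayscale images are not supported; a 3-channel RGB image is required")
    if image.ndim != 3:
        raise ValueError(f"expected an H x W x 3 array, got shape {image.shape}")
    if image.shape[2] == 4:  # drop alpha
        image = image[:, :, :3]
    if image.shape[2] != 3:
        raise ValueError(f"expected 3 color channels, got {image.shape[2]}")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("image must have at least one pixel")
    if not np.issubdtype(image.dtype, np.integer):
        raise ValueError("8-bit integer pixel values are required")
    if image.min() < 0 or image.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    return image


def _finalize(plane: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(plane), 0, 255).astype(np.uint8)


def _rgb_to_hsv(r: np.ndarray, g: np.ndarray, b: np.ndarray):
    # Hexcone model; H rescaled from [0, 360) degrees to [0, 255],
    # S and V scaled to [0, 255]. Achromatic pixels get H = 0, S = 0.
    maxc = np.maximum(np.maximum(r, g), b)
    minc = np.minimum(np.minimum(r, g), b)
    delta = maxc - minc
    v = maxc

    s = np.zeros_like(r)
    nonzero_v = maxc > 0
    s[nonzero_v] = 255.0 * delta[nonzero_v] / maxc[nonzero_v]

    h = np.zeros_like(r)
    chrom = delta > 0
    safe = np.where(chrom, delta, 1.0)
    rc = (maxc - r) / safe
    gc = (maxc - g) / safe
    bc = (maxc - b) / safe
    h = np.where(maxc == r, bc - gc, h)
    h = np.where((maxc == g) & (maxc != r), 2.0 + rc - bc, h)
    h = np.where((maxc == b) & (maxc != r) & (maxc != g), 4.0 + gc - rc, h)
    h = np.where(chrom, (h / 6.0) % 1.0, 0.0)  # fraction of a turn
    return h * 255.0, s, v


def _rgb_to_ycbcr(r: np.ndarray, g: np.ndarray, b: np.ndarray):
    # ITU-R BT.601 full-range (JPEG convention), chrominance offset by 128.
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    return y, cb, cr


def _rgb_to_i1i2i3(r: np.ndarray, g: np.ndarray, b: np.ndarray):
    # Ohta components; I2, I3 shifted by +127.5 so all planes share [0, 255].
    i1 = (r + g + b) / 3.0
    i2 = (r - b) / 2.0 + 127.5
    i3 = (2.0 * g - r - b) / 4.0 + 127.5
    return i1, i2, i3


def _rgb_to_rngnbn(r: np.ndarray, g: np.ndarray, b: np.ndarray):
    # Chromaticity coordinates: Cn = 255 * C / (R + G + B). A black pixel
    # (zero sum) maps to equal thirds (85, 85, 85) for continuity with the
    # achromatic axis.
    s = r + g + b
    safe = np.where(s > 0, s, 1.0)
    rn = np.where(s > 0, 255.0 * r / safe, 85.0)
    gn = np.where(s > 0, 255.0 * g / safe, 85.0)
    bn = np.where(s > 0, 255.0 * b / safe, 85.0)
    return rn, gn, bn


_CONVERTERS = {
    "HSV": _rgb_to_hsv,
    "YCbCr": _rgb_to_ycbcr,
    "I1I2I3": _rgb_to_i1i2i3,
    "RnGnBn": _rgb_to_rngnbn,
}


def convert(image: np.ndarray, space: str) -> ColorPlanes:
    """Convert an 8-bit RGB image to ``space`` and return 8-bit planes.

    Parameters
    ----------
    image : ndarray
        ``H x W x 3`` (or ``H x W x 4``; alpha is dropped) integer array with
        values in [0, 255]. Grayscale input is rejected.
    space : str
        One of :data:`SPACES`.

    Returns
    -------
    ColorPlanes
        Planes C1, C2, C3 rounded to the nearest integer and clipped to
        [0, 255]. ``space="RGB"`` returns the input channels unchanged.
    """
    if space not in SPACES:
        raise ValueError(f"unknown color space {space!r}; expected one of {SPACES}")
    image = _validate_rgb(image)
    if space == "RGB":
        u8 = image.astype(np.uint8)
        return ColorPlanes("RGB", u8[:, :, 0].copy(), u8[:, :, 1].copy(), u8[:, :, 2].copy())
    r = image[:, :, 0].astype(np.float64)
    g = image[:, :, 1].astype(np.float64)
    b = image[:, :, 2].astype(np.float64)
    p1, p2, p3 = _CONVERTERS[space](r, g, b)
    return ColorPlanes(space, _finalize(p1), _finalize(p2), _finalize(p3))
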