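"""Image transforms feeding object scoring and plane selection.

Three transforms are used:

* the grey-scale white top-hat (image minus its morphological opening with a
  disc), which subtracts smooth local background and preserves small bright
  peaks;
* the "local curvature" transform, a correlation with a fixed 5x5 integer
  kernel approximating a Laplacian of Gaussian, maximal for blob-shaped
  maxima of roughly the kernel scale;
* the Sobel gradient magnitude, used to pick the sharpest z-plane.

All arithmetic is carried out in floating point even for 8-bit input so that
the signed local-curvature response is never quantized.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import correlate, grey_opening

#: 5x5 integer Laplacian-of-Gaussian approximation used by the local
#: curvature transform (Gaussian smoothing followed by the Laplace operator,
#: folded into a single kernel).  Centre coefficient 32.
LOG_KERNEL = np.array(
    [
        [-2, -4, -4, -4, -2],
        [-4, 0, 10, 0, -4],
        [-4, 10, 32, 10, -4],
        [-4, 0, 10, 0, -4],
        [-2, -4, -4, -4, -2],
    ],
    dtype=float,
)

_SOBEL_ROW = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float)
_SOBEL_COL = _SOBEL_ROW.T


def disc_element(diameter: float) -> np.ndarray:
    """Boolean disc: all pixels within Euclidean distance ``diameter / 2``
    of the centre of a square window."""
    radius = diameter / 2.0
    n = int(np.floor(radius))
    rr, cc = np.mgrid[-n : n + 1, -n : n + 1]
    return (rr * rr + cc * cc) <= radius * radius


def top_hat(image: np.ndarray, structuring_diameter: float = 10.0) -> np.ndarray:
    """White top-hat: image minus its grey-scale opening with a disc.

    The structuring element is clipped at the borders (``grey_opening`` with
    ``mode='nearest'`` replicates edge values, so a flat image maps to zero
    everywhere and no artificial edge maxima appear).  Output is >= 0.
    """
    if structuring_diameter < 3:
        raise ValueError("structuring element diameter must be >= 3 px")
    img = np.asarray(image, dtype=float)
    footprint = disc_element(structuring_diameter)
    opened = grey_opening(img, footprint=footprint, mode="nearest")
    return img - opened


def local_curvature(image: np.ndarray) -> np.ndarray:
    """Correlate the image with the 5x5 LoG-like kernel.

    The kernel is symmetric under flips and transpose, so correlation and
    convolution coincide.  Borders use reflect padding; the signed output is
    returned at full float precision without clipping.
    """
    img = np.asarray(image, dtype=float)
    if img.shape[0] < 5 or img.shape[1] < 5:
        raise ValueError("image must be at least 5x5 for the local curvature transform")
    return correlate(img, LOG_KERNEL, mode="reflect")


def sobel_magnitude(image: np.ndarray) -> np.ndarray:
    """Euclidean magnitude of the two orthogonal 3x3 Sobel responses."""
    img = np.asarray(image, dtype=float)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("image must be at least 3x3 for the Sobel operator")
    gr = correlate(img, _SOBEL_ROW, mode="reflect")
    gc = correlate(img, _SOBEL_COL, mode="reflect")
    return np.hypot(gr, gc)
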