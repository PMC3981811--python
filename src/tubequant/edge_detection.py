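"""Tube detection: Canny edges plus morphological cleanup.

Produces the "Image Edges" binary mask marking every location where a
tube-like structure was detected.  The Canny detector finds pixels of
high spatial intensity derivative; detected edge points within
``canny_connect`` pixels of each other are then connected (morphological
closing), the mask is dilated and contracted again (``dilate``), small
enclosed false-negative holes are filled (``fill``) and small
false-positive specks are cleared (``clean``).

Foreground connected-component analyses use 8-connectivity; holes use
the complementary 4-connectivity (see :func:`fill_holes`).  The fill and
clean thresholds are strict: a region survives when its area is greater
than or equal to the parameter ("smaller than" is removed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, morphology

from .parameters import ParameterProfile

_EIGHT = np.ones((3, 3), dtype=bool)

#: Canny hyperparameters are not user-facing analysis parameters; the
#: detector is treated as a black box with a fixed Gaussian sigma and
#: hysteresis thresholds derived from the gradient-magnitude histogram
#: (Otsu high threshold, low = 0.4 x high).
CANNY_SIGMA = 2.0
CANNY_LOW_FRACTION = 0.4


@dataclass
class EdgeMask:
    """Binary mask of detected tube-like structures with its step history."""

    mask: np.ndarray
    provenance: tuple = field(default_factory=tuple)

    @property
    def shape(self):
        return self.mask.shape


def canny_edges(
    img: np.ndarray,
    sigma: float = CANNY_SIGMA,
    low_fraction: float = CANNY_LOW_FRACTION,
) -> np.ndarray:
    """Detect edge points with the Canny method.

    The grayscale image is normalized to [0, 1]; the hysteresis high
    threshold is the Otsu threshold of the Gaussian gradient magnitude
    and the low threshold ``low_fraction`` times that.  A constant image
    has zero spatial derivative everywhere and yields an empty mask.
    """
    g = np.asarray(img, dtype=np.float64)
    if g.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got shape {g.shape}")
    lo, hi = g.min(), g.max()
    if hi <= lo:
        return np.zeros(g.shape, dtype=bool)
    g = (g - lo) / (hi - lo)
    grad = ndi.gaussian_gradient_magnitude(g, sigma=sigma)
    if grad.max() <= 0:
        return np.zeros(g.shape, dtype=bool)
    high = filters.threshold_otsu(grad)
    low = low_fraction * high
    return feature.canny(g, sigma=sigma, low_threshold=low, high_threshold=high)


def _bridge_components(m: np.ndarray, reach: int) -> np.ndarray:
    """Draw a 1-px line between the closest pixels of every pair of
    connected components whose minimum distance is <= *reach*.

    Guarantees that any two foreground pixels within *reach* of each
    other end up in one component (single-linkage at that threshold),
    which morphological closing alone cannot do for isolated points —
    its erosion step re-separates them.
    """
    from scipy.spatial import cKDTree
    from skimage.draw import line as draw_line

    labels, n = ndi.label(m, structure=_EIGHT)
    if n <= 1:
        return m.copy()
    pts = np.argwhere(m)
    labs = labels[pts[:, 0], pts[:, 1]]
    pairs = cKDTree(pts).query_pairs(r=reach, output_type="ndarray")
    out = m.copy()
    if len(pairs) == 0:
        return out
    cross = labs[pairs[:, 0]] != labs[pairs[:, 1]]
    best: dict[tuple, tuple] = {}
    for i, j in pairs[cross]:
        key = tuple(sorted((labs[i], labs[j])))
        d = float(np.hypot(*(pts[i] - pts[j])))
        if key not in best or d < best[key][0]:
            best[key] = (d, i, j)
    for _, i, j in best.values():
        rr, cc = draw_line(*pts[i], *pts[j])
        out[rr, cc] = True
    return out


def bridge_and_close(edges: np.ndarray, canny_connect: int, dilate: int) -> np.ndarray:
    """Connect edge points within *canny_connect* pixels, then close.

    Point pairs from different objects within *canny_connect* pixels are
    joined by explicit one-pixel bridges, then the mask is dilated and
    contracted twice (morphological closing with disks of radius
    *canny_connect* and *dilate*) to merge and solidify nearby objects.
    Every step is extensive: the output is a superset of the input
    foreground.
    """
    m = np.asarray(edges).astype(bool)
    if canny_connect > 0:
        # reach cc+1: a gap of cc background pixels separates foreground
        # pixels by cc+1, and such gaps are meant to be spanned
        m = _bridge_components(m, canny_connect + 1)
    for r in (canny_connect, dilate):
        if r > 0:
            m = morphology.closing(m, morphology.disk(r))
    return m


def fill_holes(m: np.ndarray, fill: int) -> np.ndarray:
    """Fill enclosed background regions strictly smaller than *fill* pixels.

    Background components fully surrounded by foreground (not touching
    the image border) with area < *fill* become foreground; larger holes
    and the unbounded background are untouched.

    Holes are labeled with 4-connectivity, the complement of the
    foreground's 8-connectivity: with matching connectivities the
    background would leak diagonally through a one-pixel 8-connected
    contour and an enclosed hole would never be detected.
    """
    m = np.asarray(m).astype(bool)
    if fill <= 0:
        return m.copy()
    labels, n = ndi.label(~m)  # default cross structure = 4-connectivity
    if n == 0:
        return m.copy()
    border = np.zeros(m.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    open_labels = np.unique(labels[border & ~m])
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    fill_label = np.zeros(n + 1, dtype=bool)
    fill_label[1:] = counts[1:] < fill
    fill_label[open_labels] = False
    out = m.copy()
    out[fill_label[labels]] = True
    return out


def clean_specks(m: np.ndarray, clean: int) -> np.ndarray:
    """Remove foreground components strictly smaller than *clean* pixels."""
    m = np.asarray(m).astype(bool)
    if clean <= 0:
        return m.copy()
    # strict "smaller than": components of area <= clean - 1 are removed
    return morphology.remove_small_objects(m, max_size=clean - 1, connectivity=2)


def detect_tubes(
    img: np.ndarray,
    p: ParameterProfile,
    roi: np.ndarray | None = None,
) -> EdgeMask:
    """Run the full tube-detection chain on a grayscale image.

    Composition: Canny -> restrict to roi -> bridge/close -> fill ->
    clean, with the roi re-applied at the end so the output never
    exceeds it (closing could otherwise leak past the roi boundary).

    Parameters
    ----------
    img : 2D array
        Grayscale intensity image.
    p : ParameterProfile
        Analysis parameters (canny_connect, dilate, fill, clean used).
    roi : 2D bool array, optional
        Restrict detection to this region (e.g. the non-black part of a
        retinal fundus photograph).
    """
    g = np.asarray(img, dtype=np.float64)
    steps = ["canny"]
    m = canny_edges(g)
    if roi is not None:
        roi = np.asarray(roi).astype(bool)
        if roi.shape != g.shape:
            raise ValueError(f"roi shape {roi.shape} does not match image shape {g.shape}")
        m &= roi
        steps.append("roi")
    m = bridge_and_close(m, p.canny_connect, p.dilate)
    steps += ["bridge", "close"]
    m = fill_holes(m, p.fill)
    steps.append("fill")
    m = clean_specks(m, p.clean)
    steps.append("clean")
    if roi is not None:
        m &= roi
    return EdgeMask(mask=m, provenance=tuple(steps))
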