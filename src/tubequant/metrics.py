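"""Tube morphometry: length, branch points, area and average thickness.

Length is measured on the one-pixel skeleton by its pixel connectivity:
every horizontally or vertically adjacent pixel pair contributes one
pixel length, every diagonally adjacent pair contributes 1.414 pixel
lengths, and the sum is scaled to microns.  Each adjacency is counted
exactly once, and a diagonal adjacency that is redundant — the two
pixels are also joined through a shared orthogonal foreground neighbor —
is skipped, so an L-shaped corner is not double counted.

Branch points are skeleton pixels with three or more foreground
8-neighbors.  Because thinning frequently marks several branch pixels at
one junction, nearby branch pixels are consolidated: raw node pixels are
grouped by single-linkage clustering at a user radius and each group is
replaced by its spatial average.

Tube area counts only objects that contribute to the skeleton: an edge-
mask component is included when its intersection with the skeleton holds
at least ``overlap`` pixels.  Average thickness is total area divided by
total length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .skeleton import neighbor_counts

#: Diagonal adjacency weight, the literal constant used in the length rule.
DIAGONAL_WEIGHT = 1.414

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class BranchPoint:
    """A consolidated tube junction.

    ``row``/``col`` are the spatial average of the raw node pixels
    merged into this point; ``support`` is how many were merged.
    """

    row: float
    col: float
    support: int


@dataclass(frozen=True)
class TubeMetrics:
    """Summary morphometry for one analyzed image.

    ``avg_thickness`` is NaN when length is zero but area is not
    (undefined ratio, reported as a missing value).
    """

    total_length: float  # µm
    total_area: float  # µm²
    n_branch_points: int
    avg_thickness: float  # µm
    source_file: str = ""


def measure_length(skel: np.ndarray, scale: float) -> float:
    """Total skeleton length in microns.

    Sums over every distinct 8-adjacent foreground pixel pair: 1 per
    orthogonal pair, :data:`DIAGONAL_WEIGHT` per non-redundant diagonal
    pair, times *scale* (µm/px).
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale!r}")
    m = np.asarray(skel).astype(bool)
    if not m.any():
        return 0.0
    horiz = int(np.count_nonzero(m[:, :-1] & m[:, 1:]))
    vert = int(np.count_nonzero(m[:-1, :] & m[1:, :]))
    # main diagonal pair (r,c)-(r+1,c+1); redundant if (r,c+1) or (r+1,c) set
    d1 = m[:-1, :-1] & m[1:, 1:] & ~(m[:-1, 1:] | m[1:, :-1])
    # anti-diagonal pair (r,c+1)-(r+1,c); redundant if (r,c) or (r+1,c+1) set
    d2 = m[:-1, 1:] & m[1:, :-1] & ~(m[:-1, :-1] | m[1:, 1:])
    diag = int(np.count_nonzero(d1)) + int(np.count_nonzero(d2))
    return (horiz + vert + DIAGONAL_WEIGHT * diag) * scale


def find_branch_pixels(skel: np.ndarray) -> np.ndarray:
    """Mask of skeleton pixels connected to 3 or more foreground pixels."""
    m = np.asarray(skel).astype(bool)
    return m & (neighbor_counts(m) >= 3)


def consolidate_nodes(nodes: np.ndarray, radius: float) -> list[BranchPoint]:
    """Merge raw branch pixels within *radius* into single branch points.

    Single-linkage grouping: any chain of node pixels pairwise within
    *radius* collapses to one :class:`BranchPoint` at the coordinate
    mean.  Deterministic (raster-order pixel enumeration); the returned
    list is sorted by (row, col).
    """
    pts = np.argwhere(np.asarray(nodes).astype(bool))  # raster order
    n = len(pts)
    if n == 0:
        return []
    if radius > 0:
        pairs = cKDTree(pts).query_pairs(r=radius, output_type="ndarray")
    else:
        pairs = np.empty((0, 2), dtype=int)
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    out = []
    for lab in np.unique(labels):
        group = pts[labels == lab]
        r, c = group.mean(axis=0)
        out.append(BranchPoint(row=float(r), col=float(c), support=len(group)))
    out.sort(key=lambda b: (b.row, b.col))
    return out


def included_area_mask(edges: np.ndarray, skel: np.ndarray, overlap: int) -> np.ndarray:
    """Edge-mask components whose skeleton intersection has >= *overlap* pixels."""
    em = np.asarray(getattr(edges, "mask", edges)).astype(bool)
    sk = np.asarray(skel).astype(bool)
    if em.shape != sk.shape:
        raise ValueError(f"mask shapes differ: {em.shape} vs {sk.shape}")
    labels, n = ndi.label(em, structure=_EIGHT)
    if n == 0:
        return np.zeros_like(em)
    inter = ndi.sum_labels(sk.astype(np.int64), labels, index=np.arange(1, n + 1))
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = inter >= overlap
    return keep[labels]


def measure_area(edges: np.ndarray, skel: np.ndarray, overlap: int, scale: float) -> float:
    """Total tube area in µm² over skeleton-supported edge components."""
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale!r}")
    kept = included_area_mask(edges, skel, overlap)
    return float(np.count_nonzero(kept)) * scale * scale


def average_thickness(total_area: float, total_length: float) -> float:
    """Average tube thickness (µm): total area divided by total length.

    Returns 0 for an empty image (both zero) and NaN when length is
    zero but area is positive (undefined, reported as missing).
    """
    if total_length < 0 or total_area < 0:
        raise ValueError("area and length must be non-negative")
    if total_length == 0:
        return 0.0 if total_area == 0 else math.nan
    return total_area / total_length


def relative_percent_difference(l1: float, l2: float) -> float:
    """Percent difference between two length measurements.

    ``|l1 - l2| / min(l1, l2) * 100`` — a symmetric inter-operator
    variability statistic.  NaN when both inputs are zero (undefined).
    """
    if l1 < 0 or l2 < 0:
        raise ValueError("lengths must be non-negative")
    if l1 == 0 and l2 == 0:
        return math.nan
    lo = min(l1, l2)
    if lo == 0:
        return math.inf
    return abs(l1 - l2) / lo * 100.0
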