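"""Single-image ("sandbox") and batch analysis orchestration.

``analyze_image`` runs the full chain on one TIFF — load, grayscale
conversion, tube detection, skeletonization, spur clipping, metrics —
and optionally writes the overlay record (grayscale, detected edges,
skeleton and nodes dilated by 10 px over the original, and the
area-inclusion overlay).  ``run_batch`` applies one parameter profile to
a whole file list with no further input, writing a CSV (optionally
XLSX) report with one row per image; a failure on one image is recorded
in its row and never aborts the batch.

For retinal fundus photographs, ``nonblack_roi`` restricts detection to
the non-black circular field; no other modification is needed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import morphology

from . import image_io
from .edge_detection import detect_tubes
from .metrics import (
    TubeMetrics,
    average_thickness,
    consolidate_nodes,
    find_branch_pixels,
    included_area_mask,
    measure_length,
)
from .parameters import ParameterProfile
from .skeleton import clip_spurs, skeletonize

logger = logging.getLogger("tubequant")

#: Dilation applied to skeleton and node masks before overlaying, so the
#: one-pixel structures are visible on the original image.
OVERLAY_DILATION = 10

_OVERLAY_COLORS = {
    "edges": (255, 0, 0),
    "skeleton": (0, 255, 0),
    "area": (0, 0, 255),
    "nodes": (255, 0, 255),
}

REPORT_COLUMNS = ["file", "length_um", "area_um2", "n_nodes", "thickness_um", "error"]


@dataclass
class AnalysisRecord:
    """Outcome of analyzing a single image."""

    source_file: str
    metrics: TubeMetrics | None
    profile_used: ParameterProfile
    outputs_written: list = field(default_factory=list)
    n_raw_branch_pixels: int = 0
    error: str | None = None


def nonblack_roi(img: np.ndarray, threshold: float = 10) -> np.ndarray:
    """Region of interest covering the non-black part of an image.

    Pixels with mean-channel luminance above *threshold* (default 10 of
    255), eroded by 3 px to avoid spurious edges at the rim of the
    imaged field (e.g. the circular fundus boundary).
    """
    img = np.asarray(img, dtype=np.float64)
    lum = img.mean(axis=-1) if img.ndim == 3 else img
    mask = lum > threshold
    if mask.any():
        mask = morphology.erosion(mask, morphology.disk(3))
    return mask


def analyze_arrays(
    rgb: np.ndarray,
    p: ParameterProfile,
    roi_mode: str = "none",
    source: str = "<array>",
):
    """Run the analysis chain on an in-memory RGB image.

    Returns ``(metrics, masks)`` where *masks* holds the intermediate
    binary images (``gray``, ``edges``, ``skeleton``, ``nodes``,
    ``area`` and the consolidated ``branch_points`` list) for overlay
    writing or inspection.
    """
    if roi_mode not in ("none", "nonblack"):
        raise ValueError(f"unknown roi_mode {roi_mode!r}")
    gray = image_io.to_grayscale(rgb)
    roi = nonblack_roi(rgb) if roi_mode == "nonblack" else None
    em = detect_tubes(gray, p, roi=roi)
    skel = skeletonize(em.mask)
    skel = clip_spurs(skel, p.clip)
    length = measure_length(skel, p.scale)
    raw_nodes = find_branch_pixels(skel)
    branch_points = consolidate_nodes(raw_nodes, p.radius)
    area_mask = included_area_mask(em.mask, skel, p.overlap)
    area = float(np.count_nonzero(area_mask)) * p.scale * p.scale
    metrics = TubeMetrics(
        total_length=length,
        total_area=area,
        n_branch_points=len(branch_points),
        avg_thickness=average_thickness(area, length),
        source_file=source,
    )
    masks = {
        "gray": gray,
        "edges": em.mask,
        "skeleton": skel,
        "raw_nodes": raw_nodes,
        "area": area_mask,
        "branch_points": branch_points,
    }
    return metrics, masks


def _node_mask(branch_points, shape) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    for bp in branch_points:
        r = min(max(int(round(bp.row)), 0), shape[0] - 1)
        c = min(max(int(round(bp.col)), 0), shape[1] - 1)
        m[r, c] = True
    return m


def _write_overlays(rgb, masks, stem: str, out_dir: Path, per_type_dirs: bool) -> list:
    """Write the analysis record images; returns the file paths."""
    disk10 = morphology.disk(OVERLAY_DILATION)
    node_mask = _node_mask(masks["branch_points"], masks["skeleton"].shape)
    layers = {
        "gray": None,
        "edges": masks["edges"],
        "skeleton": morphology.dilation(masks["skeleton"], disk10),
        "area": ~masks["area"],  # inverted: retained tubes show through untinted
        "nodes": morphology.dilation(node_mask, disk10),
    }
    written = []
    for kind, layer in layers.items():
        if per_type_dirs:
            d = out_dir / kind
            d.mkdir(parents=True, exist_ok=True)
            path = d / f"{stem}.tif"
        else:
            path = out_dir / f"{stem}_{kind}.tif"
        if kind == "gray":
            image_io.write_tiff(
                np.clip(np.round(masks["gray"]), 0, 255).astype(np.uint8), path
            )
        else:
            image_io.write_overlay(rgb, layer, _OVERLAY_COLORS[kind], path)
        written.append(path)
    return written


def analyze_image(
    path,
    p: ParameterProfile,
    save_images: bool = False,
    roi_mode: str = "none",
    out_dir=None,
    per_type_dirs: bool = False,
) -> AnalysisRecord:
    """Analyze one TIFF file and (optionally) write its overlay record."""
    path = Path(path)
    t0 = time.perf_counter()
    rgb = image_io.load_image(path)
    metrics, masks = analyze_arrays(rgb, p, roi_mode=roi_mode, source=path.name)
    outputs = []
    if save_images:
        out_dir = Path(out_dir) if out_dir is not None else path.parent
        out_dir.mkdir(parents=True, exist_ok=True)
        outputs = _write_overlays(rgb, masks, path.stem, out_dir, per_type_dirs)
    logger.info(
        json.dumps(
            {
                "file": path.name,
                "length_um": metrics.total_length,
                "area_um2": metrics.total_area,
                "n_nodes": metrics.n_branch_points,
                "thickness_um": metrics.avg_thickness,
                "seconds": round(time.perf_counter() - t0, 3),
            }
        )
    )
    return AnalysisRecord(
        source_file=path.name,
        metrics=metrics,
        profile_used=p,
        outputs_written=outputs,
        n_raw_branch_pixels=int(np.count_nonzero(masks["raw_nodes"])),
    )


def run_batch(
    file_list,
    p: ParameterProfile,
    out_dir,
    save_images: bool = False,
    xlsx: bool = False,
) -> Path:
    """Analyze every file in *file_list* with one profile; write a report.

    The report (``report.csv`` in *out_dir*; ``report.xlsx`` too when
    *xlsx*) has one row per input: file, length_um, area_um2, n_nodes,
    thickness_um, error.  An unreadable or failing image gets its error
    text recorded and the batch continues.  Overlay images go to
    per-type subdirectories when *save_images* is set.
    """
    files = [Path(f) for f in file_list]
    if not files:
        raise ValueError("file_list must contain at least one file")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in files:
        try:
            rec = analyze_image(
                f, p, save_images=save_images, out_dir=out_dir, per_type_dirs=True
            )
            m = rec.metrics
            rows.append(
                {
                    "file": f.name,
                    "length_um": m.total_length,
                    "area_um2": m.total_area,
                    "n_nodes": m.n_branch_points,
                    "thickness_um": m.avg_thickness,
                    "error": "",
                }
            )
        except Exception as exc:  # one bad image never aborts the batch
            logger.warning("analysis failed for %s: %s", f, exc)
            rows.append(
                {
                    "file": f.name,
                    "length_um": np.nan,
                    "area_um2": np.nan,
                    "n_nodes": np.nan,
                    "thickness_um": np.nan,
                    "error": f"{type(exc).__name__}: {exc}",
                }
            )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    report = out_dir / "report.csv"
    df.to_csv(report, index=False, lineterminator="\r\n")
    if xlsx:
        df.to_excel(out_dir / "report.xlsx", index=False)
    return report
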