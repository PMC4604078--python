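"""Muscle-fiber morphometry from membrane/nuclei channel pairs.

Reimplements the classic ImageJ macro workflow for dystrophic muscle
cross-sections: background subtraction and thresholding of the membrane
(collagen-IV) channel, gap-closing dilation, skeletonization into a
1-px border mask, particle labeling of the enclosed fiber regions with a
size filter, and per-fiber measurement of area and minimum Feret diameter,
plus classification of centrally nucleated (C/N) fibers from the nuclei
channel.

Geometry conventions: pixel origin top-left, row-major, 0-based.  Fiber
regions are 4-connected; border skeletons 8-connected.  Each pixel is
treated as a unit square, so a 30-px-wide rectangle of pixels has caliper
width exactly 30.  Feret measures are taken on the convex hull (the caliper
definition).  Fibers touching the image edge are censored and excluded from
per-fiber measurements; their count is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import filters, morphology
from skimage.measure import label as sk_label, regionprops

log = logging.getLogger(__name__)

_PIXEL_CORNERS = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])


@dataclass
class MorphometryConfig:
    """Parameters of the border-mask macro and the C/N classifier.

    All length-like entries are in the units their names state; ``um_per_px``
    converts pixel measures to micrometres.  ``bandpass_low/high`` default to
    None, in which case an Otsu threshold on the background-subtracted
    membrane channel is used (the macro's band-pass thresholds are
    image-specific and have no universal values).
    """

    background_radius_px: int = 15
    bandpass_low: float | None = None
    bandpass_high: float | None = None
    dilation_radius_px: int = 2
    min_fiber_area_um2: float = 50.0
    max_fiber_area_um2: float = 10_000.0
    nucleus_threshold: float | None = None
    central_margin_fraction: float = 0.1
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        if not self.min_fiber_area_um2 < self.max_fiber_area_um2:
            raise ValueError("min_fiber_area_um2 must be < max_fiber_area_um2")
        if not 0 < self.central_margin_fraction < 1:
            raise ValueError("central_margin_fraction must be in (0, 1)")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")


@dataclass
class LabeledFiberMap:
    """Per-pixel fiber labels: 0 = border/background, k > 0 = fiber k."""

    labels: np.ndarray
    um_per_px: float
    tissue_area_um2: float
    n_removed_size: int = 0
    n_removed_edge: int = 0

    @property
    def n_fibers(self) -> int:
        return int(self.labels.max())


@dataclass
class FiberRecord:
    label: int
    area_um2: float
    min_feret_um: float
    centroid_px: tuple[float, float]
    is_central_nucleated: bool = False
    n_central_nuclei: int = 0


@dataclass
class MorphometrySummary:
    n_fibers: int
    fibers_per_mm2: float
    pct_central_nucleated: float
    mean_min_feret_um: float
    mean_min_feret_um_cn: float
    mean_min_feret_um_non_cn: float
    feret_bin_edges_um: np.ndarray = field(repr=False, default=None)
    feret_histogram: np.ndarray = field(repr=False, default=None)
    central_margin_fraction: float = 0.1


# ---------------------------------------------------------------------------
# minimum Feret diameter (rotating calipers)
# ---------------------------------------------------------------------------

def _hull_points(region: np.ndarray) -> np.ndarray:
    region = np.asarray(region)
    if region.ndim == 2 and region.dtype == bool:
        coords = np.argwhere(region).astype(float)
        if coords.size == 0:
            raise ValueError("empty region")
        pts = (coords[:, None, :] + _PIXEL_CORNERS[None, :, :]).reshape(-1, 2)
    elif region.ndim == 2 and region.shape[1] == 2:
        pts = region.astype(float)
        if pts.shape[0] == 0:
            raise ValueError("empty region")
    else:
        raise ValueError("region must be a boolean mask or an (N, 2) point array")
    try:
        hull = ConvexHull(pts)
        return pts[hull.vertices]
    except QhullError:
        # collinear/degenerate point sets: fall back to the raw points
        return pts


def min_feret(region: np.ndarray, um_per_px: float = 1.0) -> float:
    """Minimum caliper (projection) width of a region's convex hull.

    Exact for convex polygons: the minimum width is attained with one jaw
    flush against a hull edge, so it equals the minimum over hull edges of
    the farthest vertex-to-edge distance.  ``region`` is either a boolean
    pixel mask (pixels treated as unit squares) or an (N, 2) array of
    polygon vertices in pixel units.
    """
    hull = _hull_points(region)
    n = hull.shape[0]
    if n == 1:
        return float(um_per_px)  # single degenerate point: one pixel pitch
    if n == 2:
        return 0.0  # line segment: zero caliper width
    edges = np.roll(hull, -1, axis=0) - hull
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    keep = lengths > 0
    if not keep.any():
        return float(um_per_px)
    edges, origins, lengths = edges[keep], hull[keep], lengths[keep]
    normals = np.stack([-edges[:, 1], edges[:, 0]], axis=1) / lengths[:, None]
    # farthest vertex-to-edge-line distance, per edge
    rel = hull[None, :, :] - origins[:, None, :]          # (edges, verts, 2)
    d = np.abs(np.einsum("ej,evj->ev", normals, rel))
    widths = d.max(axis=1)
    return float(widths.min() * um_per_px)


def max_feret(region: np.ndarray, um_per_px: float = 1.0) -> float:
    """Maximum caliper width (largest pairwise hull-vertex distance)."""
    hull = _hull_points(region)
    if hull.shape[0] == 1:
        return float(um_per_px)
    diff = hull[:, None, :] - hull[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max() * um_per_px)


# ---------------------------------------------------------------------------
# macro steps
# ---------------------------------------------------------------------------

def build_border_mask(membrane: np.ndarray, cfg: MorphometryConfig) -> np.ndarray:
    """Construct the 1-px-wide closed fiber-border skeleton.

    Steps: white-tophat background subtraction, band-pass (or Otsu)
    threshold, dilation to bridge gaps up to ``dilation_radius_px``, then
    skeletonization.
    """
    membrane = np.asarray(membrane, dtype=float)
    if membrane.ndim != 2:
        raise ValueError("membrane image must be single-channel")
    if not membrane.any():
        log.warning("empty membrane image: returning empty border mask")
        return np.zeros(membrane.shape, dtype=bool)
    flat = morphology.white_tophat(
        membrane, morphology.disk(cfg.background_radius_px))
    if cfg.bandpass_low is None:
        thr = filters.threshold_otsu(flat)
        binary = flat > thr
    else:
        hi = np.inf if cfg.bandpass_high is None else cfg.bandpass_high
        binary = (flat >= cfg.bandpass_low) & (flat <= hi)
    dilated = morphology.dilation(
        binary, morphology.disk(cfg.dilation_radius_px))
    return morphology.skeletonize(dilated)


def label_fibers(border_mask: np.ndarray, cfg: MorphometryConfig) -> LabeledFiberMap:
    """Label enclosed fiber regions (4-connected), size- and edge-filtered."""
    border_mask = np.asarray(border_mask, dtype=bool)
    raw = sk_label(~border_mask, connectivity=1)
    px_area_um2 = cfg.um_per_px ** 2
    n_edge = n_size = 0
    keep_ids = []
    edge_ids = set(np.concatenate([raw[0, :], raw[-1, :], raw[:, 0], raw[:, -1]]))
    edge_ids.discard(0)
    for rid in range(1, raw.max() + 1):
        area = np.count_nonzero(raw == rid) * px_area_um2
        if rid in edge_ids:
            n_edge += 1
        elif not (cfg.min_fiber_area_um2 <= area <= cfg.max_fiber_area_um2):
            n_size += 1
        else:
            keep_ids.append(rid)
    labels = np.zeros_like(raw)
    for new, rid in enumerate(keep_ids, start=1):
        labels[raw == rid] = new
    log.info("label_fibers: kept %d, removed %d (edge) + %d (size)",
             len(keep_ids), n_edge, n_size)
    tissue_area = border_mask.size * px_area_um2
    return LabeledFiberMap(labels, cfg.um_per_px, tissue_area,
                           n_removed_size=n_size, n_removed_edge=n_edge)


def measure_fibers(fiber_map: LabeledFiberMap) -> list[FiberRecord]:
    """Per-fiber area, minimum Feret diameter and centroid."""
    records = []
    scale = fiber_map.um_per_px
    for prop in regionprops(fiber_map.labels):
        mask = fiber_map.labels == prop.label
        records.append(FiberRecord(
            label=int(prop.label),
            area_um2=float(prop.area) * scale ** 2,
            min_feret_um=min_feret(mask, scale),
            centroid_px=(float(prop.centroid[0]), float(prop.centroid[1])),
        ))
    return records


def classify_central_nucleation(fiber_map: LabeledFiberMap,
                                nuclei: np.ndarray,
                                cfg: MorphometryConfig,
                                records: list[FiberRecord] | None = None,
                                ) -> dict[int, int]:
    """Count central nuclei per fiber; returns {fiber label: n central}.

    A nucleus object (threshold-then-label of the nuclei channel) is central
    to fiber k when its centroid falls inside fiber k at a depth of at least
    ``central_margin_fraction`` times the fiber's equivalent-circle radius
    from the fiber border.  If ``records`` is given, their C/N fields are
    filled in place.
    """
    nuclei = np.asarray(nuclei, dtype=float)
    if nuclei.shape != fiber_map.labels.shape:
        raise ValueError("nuclei image must be co-registered with the label map")
    thr = (filters.threshold_otsu(nuclei) if cfg.nucleus_threshold is None
           else cfg.nucleus_threshold)
    nuc_labels = sk_label(nuclei > thr, connectivity=1)
    depth = ndimage.distance_transform_edt(fiber_map.labels > 0)
    areas = ndimage.sum_labels(np.ones_like(fiber_map.labels),
                               fiber_map.labels,
                               index=np.arange(1, fiber_map.n_fibers + 1))
    eq_radius = np.sqrt(areas / np.pi)  # px
    counts: dict[int, int] = {k: 0 for k in range(1, fiber_map.n_fibers + 1)}
    for prop in regionprops(nuc_labels):
        r, c = (int(round(prop.centroid[0])), int(round(prop.centroid[1])))
        r = min(max(r, 0), fiber_map.labels.shape[0] - 1)
        c = min(max(c, 0), fiber_map.labels.shape[1] - 1)
        fiber = int(fiber_map.labels[r, c])
        if fiber == 0:
            continue
        margin = cfg.central_margin_fraction * eq_radius[fiber - 1]
        if depth[r, c] >= margin:
            counts[fiber] += 1
    if records is not None:
        for rec in records:
            rec.n_central_nuclei = counts.get(rec.label, 0)
            rec.is_central_nucleated = rec.n_central_nuclei > 0
    return counts


def summarize_morphometry(records: list[FiberRecord],
                          tissue_area_um2: float,
                          bin_width_um: float = 5.0,
                          central_margin_fraction: float = 0.1,
                          ) -> MorphometrySummary:
    """Aggregate fiber records: density, %C/N, per-class Feret means, histogram."""
    if not records:
        raise ValueError("cannot summarize zero fibers")
    ferets = np.array([r.min_feret_um for r in records])
    cn = np.array([r.is_central_nucleated for r in records])
    top = np.ceil(ferets.max() / bin_width_um) * bin_width_um
    edges = np.arange(0.0, max(top, bin_width_um) + bin_width_um / 2, bin_width_um)
    hist, _ = np.histogram(ferets, bins=edges)
    mm2 = tissue_area_um2 / 1e6
    def _mean(v):
        return float(v.mean()) if v.size else float("nan")
    return MorphometrySummary(
        n_fibers=len(records),
        fibers_per_mm2=len(records) / mm2,
        pct_central_nucleated=100.0 * cn.mean(),
        mean_min_feret_um=_mean(ferets),
        mean_min_feret_um_cn=_mean(ferets[cn]),
        mean_min_feret_um_non_cn=_mean(ferets[~cn]),
        feret_bin_edges_um=edges,
        feret_histogram=hist,
        central_margin_fraction=central_margin_fraction,
    )


def run_morphometry(membrane: np.ndarray, nuclei: np.ndarray,
                    cfg: MorphometryConfig,
                    ) -> tuple[LabeledFiberMap, list[FiberRecord], MorphometrySummary]:
    """Full macro: border mask -> labels -> measures -> C/N -> summary."""
    mask = build_border_mask(membrane, cfg)
    fiber_map = label_fibers(mask, cfg)
    records = measure_fibers(fiber_map)
    classify_central_nucleation(fiber_map, nuclei, cfg, records)
    summary = summarize_morphometry(
        records, fiber_map.tissue_area_um2,
        central_margin_fraction=cfg.central_margin_fraction)
    return fiber_map, records, summary
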