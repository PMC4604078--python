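"""Thresholded cell enumeration and area-fraction quantification.

Covers the region-level readouts of an immunofluorescence / trichrome
workflow: counting immunopositive cells per unit area with field-of-view
averaging, percent-positive area fractions (automatic threshold or replayed
manual ROI polygons), blue-dominance trichrome (fibrosis) fractions on RGB
bright-field images, and revertant-fiber densities from binary masks.

Counted objects are 8-connected.  Area fractions are percentages of the
tissue area: the whole frame for single-channel images, the non-background
(non-near-white) pixels for bright-field RGB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from skimage import filters
from skimage.measure import label as sk_label, regionprops


@dataclass
class CountResult:
    n_objects: int
    area_mm2: float
    density_per_mm2: float
    threshold_used: float
    saturated: bool = False


@dataclass
class AreaFractionResult:
    positive_area_um2: float
    total_area_um2: float
    percent_positive: float
    mode: str = "threshold"   # "threshold" or "roi"


def count_positive_cells(image: np.ndarray,
                         um_per_px: float,
                         threshold: float | None = None,
                         min_area_um2: float = 20.0,
                         max_area_um2: float = 500.0,
                         ) -> CountResult:
    """Threshold -> label (8-connected) -> size filter -> count.

    ``threshold`` defaults to Otsu on the image.  A fully positive image is
    flagged ``saturated`` (the count is then meaningless).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel image")
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    if threshold is None:
        if image.min() == image.max():
            threshold = image.max() + 1  # flat image: nothing positive
        else:
            threshold = float(filters.threshold_otsu(image))
    binary = image > threshold
    saturated = bool(binary.all())
    labels = sk_label(binary, connectivity=2)
    px2 = um_per_px ** 2
    n = sum(1 for p in regionprops(labels)
            if min_area_um2 <= p.area * px2 <= max_area_um2)
    area_mm2 = image.size * px2 / 1e6
    return CountResult(n, area_mm2, n / area_mm2, float(threshold),
                       saturated=saturated)


def average_fov_density(counts: list[CountResult]) -> float:
    """Arithmetic mean of per-field-of-view densities."""
    if not counts:
        raise ValueError("need at least one field of view")
    return float(np.mean([c.density_per_mm2 for c in counts]))


def area_fraction(image: np.ndarray,
                  um_per_px: float,
                  threshold: float | None = None,
                  roi_polygons: list[np.ndarray] | None = None,
                  ) -> AreaFractionResult:
    """Percent positive area, by threshold or by replayed ROI polygons.

    With ``roi_polygons`` (each an (N, 2) array of x,y pixel vertices, the
    manual-delineation workflow) the positive area is the summed polygon
    area; otherwise pixels above ``threshold`` (Otsu by default) count.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel image")
    h, w = image.shape
    total_um2 = h * w * um_per_px ** 2
    if total_um2 == 0:
        raise ValueError("empty section")
    if roi_polygons is not None:
        pos_px = 0.0
        for verts in roi_polygons:
            poly = Polygon(np.asarray(verts, dtype=float))
            if not poly.is_valid:
                poly = poly.buffer(0)
            minx, miny, maxx, maxy = poly.bounds
            if minx < -1e-9 or miny < -1e-9 or maxx > w + 1e-9 or maxy > h + 1e-9:
                raise ValueError("ROI polygon extends outside the image")
            pos_px += poly.area
        pos_um2 = pos_px * um_per_px ** 2
        mode = "roi"
    else:
        if threshold is None:
            if image.min() == image.max():
                threshold = image.max() + 1
            else:
                threshold = float(filters.threshold_otsu(image))
        pos_um2 = np.count_nonzero(image > threshold) * um_per_px ** 2
        mode = "threshold"
    return AreaFractionResult(pos_um2, total_um2,
                              100.0 * pos_um2 / total_um2, mode=mode)


def trichrome_fraction(rgb: np.ndarray,
                       um_per_px: float = 1.0,
                       margin: float = 20.0,
                       background_luminance: float = 235.0,
                       ) -> AreaFractionResult:
    """Blue (collagen) area percent of the tissue area in a trichrome image.

    A pixel is positive when its blue channel dominates red and green by
    ``margin`` (8-bit counts).  Near-white pixels (mean channel value above
    ``background_luminance``) are background, excluded from the tissue area.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an RGB image")
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    tissue = rgb.mean(axis=2) < background_luminance
    positive = (b > r + margin) & (b > g + margin) & tissue
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("no tissue pixels below the background cutoff")
    px2 = um_per_px ** 2
    return AreaFractionResult(
        positive_area_um2=float(positive.sum()) * px2,
        total_area_um2=n_tissue * px2,
        percent_positive=100.0 * positive.sum() / n_tissue,
        mode="trichrome")


def revertant_density(mask: np.ndarray, section_area_mm2: float) -> float:
    """Dystrophin-positive fiber count per mm^2 of section.

    Connected components of the binary mask are counted under
    8-connectivity, so a cluster of mutually touching positive fibers
    counts once; this convention is deliberate and documented because
    published cluster handling is ambiguous.
    """
    if section_area_mm2 <= 0:
        raise ValueError("section area must be positive")
    labels = sk_label(np.asarray(mask, dtype=bool), connectivity=2)
    return float(labels.max()) / section_area_mm2
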