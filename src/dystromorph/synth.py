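"""Synthetic fixtures with exact ground truth for every pipeline stage.

Real dystrophic-muscle micrographs, uCT volumes and qPCR plates are not
distributable with the package, so each analysis stage is validated against
a generator that emits the same kind of input with known, independently
recomputable truth:

* tessellated fiber fields (bright-membrane channel + nuclei channel) with
  per-fiber polygon, area, minimum Feret diameter and central-nucleation
  labels;
* RGB images with an exactly known positive-area fraction (trichrome / IgG
  stand-ins);
* fields of disjoint bright blobs for cell counting;
* rod / plate / sphere trabecular volumes with constructive BV/TV, Tb.Th
  and Tb.Sp;
* Ct tables with planted stable and unstable reference genes, and FPKM
  matrices with a planted sample clustering;
* group measurement tables with stated distributions and effect sizes.

All randomness flows from one explicit integer seed through a local
``numpy.random.Generator``; identical seeds give byte-identical outputs.
The generators emulate geometry and noise, not staining chemistry or
photorealistic texture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Point, Polygon, box
from shapely.ops import polylabel
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse
from skimage.filters import gaussian
from skimage.segmentation import find_boundaries

from .fibers import min_feret

__all__ = [
    "FiberFieldTruth", "VolumeTruth", "GroupSpec",
    "generate_fiber_field", "generate_area_fraction_image",
    "generate_cell_field", "generate_trabecular_volume",
    "generate_group_measurements", "generate_ct_table",
    "generate_fpkm_matrix", "rotation_sweep_min_feret",
]


class DensityError(ValueError):
    """Requested object density cannot be honored at the given sizes."""


@dataclass
class FiberFieldTruth:
    fiber_id: int
    polygon: np.ndarray          # (V, 2) vertices, (x, y) pixel coordinates
    area_um2: float
    min_feret_um: float
    has_central_nucleus: bool
    n_nuclei: int


@dataclass
class VolumeTruth:
    bvtv: float
    tb_th_um: float
    tb_sp_um: float
    geometry_kind: str


@dataclass
class GroupSpec:
    group_name: str
    n: int
    distribution: str = "normal"   # {"normal", "lognormal", "contaminated"}
    mean: float = 0.0
    sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.distribution not in {"normal", "lognormal", "contaminated"}:
            raise ValueError(f"unknown distribution {self.distribution!r}")


# ---------------------------------------------------------------------------
# independent geometry oracle
# ---------------------------------------------------------------------------

def _projection_width(pts: np.ndarray, theta: np.ndarray) -> np.ndarray:
    dirs = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    proj = pts @ dirs.T
    return proj.max(axis=0) - proj.min(axis=0)


def rotation_sweep_min_feret(points: np.ndarray, step_deg: float = 0.1) -> float:
    """Brute-force minimum projection width over a dense rotation sweep.

    Independent of the rotating-calipers kernel: projects the raw points
    onto directions spaced ``step_deg`` apart, then refines around the grid
    minimum by golden-section search.  The refinement matters because the
    width function has a V-shaped (one-sided-slope) minimum at the optimal
    orientation, so the bare grid converges only linearly in the step.
    """
    pts = np.asarray(points, dtype=float)
    step = math.radians(step_deg)
    theta = np.arange(0.0, math.pi, step)
    widths = _projection_width(pts, theta)
    k = int(np.argmin(widths))
    lo, hi = theta[k] - step, theta[k] + step
    gr = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc, fd = _projection_width(pts, np.array([c, d]))
    for _ in range(80):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = _projection_width(pts, np.array([c]))[0]
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = _projection_width(pts, np.array([d]))[0]
    return float(min(widths.min(), fc, fd))


# ---------------------------------------------------------------------------
# fiber fields
# ---------------------------------------------------------------------------

def _grid_shape(n: int) -> tuple[int, int]:
    best = (1, n)
    for r in range(1, int(math.isqrt(n)) + 1):
        if n % r == 0:
            best = (r, n // r)
    return best


def generate_fiber_field(n_fibers: int,
                         size_px: tuple[int, int] = (512, 512),
                         border_width_px: float = 3.0,
                         pct_central: float = 0.3,
                         noise_sd: float = 4.0,
                         um_per_px: float = 1.0,
                         seed: int = 0,
                         verify_feret: bool = True,
                         jitter: float = 0.3,
                         ) -> tuple[np.ndarray, np.ndarray, list[FiberFieldTruth]]:
    """Tessellated fiber field with membrane and nuclei channels.

    The field is a jittered-grid Voronoi tessellation.  ``n_fibers``
    interior cells (whose polygons never touch the image edge) carry ground
    truth; a surrounding ring of sacrificial cells absorbs the image
    boundary, mimicking fibers censored at the edge of a montage.
    ``round(pct_central * n_fibers)`` interior fibers receive a nucleus at
    their interior pole (central), the rest a nucleus hugging the border
    (peripheral).
    """
    if n_fibers < 1:
        raise ValueError("n_fibers must be >= 1")
    if border_width_px < 1:
        raise ValueError("border_width_px must be >= 1")
    if not 0 <= pct_central <= 1:
        raise ValueError("pct_central must be in [0, 1]")
    h, w = size_px
    rows, cols = _grid_shape(n_fibers)
    # swap so the longer grid axis follows the longer image axis
    if (h >= w) != (rows >= cols):
        rows, cols = cols, rows
    gr, gc = rows + 2, cols + 2
    cell_h, cell_w = h / gr, w / gc
    if min(cell_h, cell_w) < 4 * border_width_px + 6:
        raise DensityError(
            f"{n_fibers} fibers at border width {border_width_px} px do not "
            f"fit into a {h}x{w} image; enlarge the image or thin the border")

    if not 0 <= jitter < 0.5:
        raise ValueError("jitter must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-jitter, jitter, size=(gr, gc, 2))
    seeds = np.empty((gr * gc, 2))       # (x, y)
    interior_idx = []
    k = 0
    for i in range(gr):
        for j in range(gc):
            y = (i + 0.5 + jitter[i, j, 0]) * cell_h
            x = (j + 0.5 + jitter[i, j, 1]) * cell_w
            seeds[k] = (x, y)
            if 1 <= i <= gr - 2 and 1 <= j <= gc - 2:
                interior_idx.append(k)
            k += 1

    # per-pixel nearest-seed labels (equals the Voronoi partition)
    yy, xx = np.mgrid[0:h, 0:w]
    centers = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
    _, nearest = cKDTree(seeds).query(centers)
    labels = (nearest + 1).reshape(h, w).astype(np.int32)

    # membrane channel: inter-cell boundaries thickened to ~border_width_px
    bounds = find_boundaries(labels, mode="thick")
    if border_width_px > 2:
        from scipy.ndimage import distance_transform_edt
        d = distance_transform_edt(~bounds)
        bounds = d <= (border_width_px - 2) / 2.0
    membrane = np.where(bounds, 200.0, 0.0)
    membrane = gaussian(membrane, sigma=1.0, preserve_range=True)
    membrane += rng.normal(0.0, noise_sd, size=membrane.shape)
    membrane = np.clip(membrane, 0, 255).astype(np.uint8)

    # exact cell polygons for the interior fibers
    vor = Voronoi(seeds)
    frame = box(0, 0, w, h)
    n_central = int(round(pct_central * n_fibers))
    central_mask = np.zeros(n_fibers, dtype=bool)
    central_mask[rng.permutation(n_fibers)[:n_central]] = True

    nuclei = np.zeros((h, w), dtype=float)
    truths: list[FiberFieldTruth] = []
    for fid, sidx in enumerate(interior_idx, start=1):
        region = vor.regions[vor.point_region[sidx]]
        assert -1 not in region, "interior Voronoi cell must be finite"
        verts = vor.vertices[region]
        poly = Polygon(verts)
        if not poly.is_valid:
            poly = poly.buffer(0)
        poly = poly.intersection(frame)
        verts = np.asarray(poly.exterior.coords[:-1])
        area_px = poly.area
        mf_px = min_feret(verts, 1.0)
        if verify_feret:
            sweep = rotation_sweep_min_feret(verts, step_deg=0.1)
            if not (abs(sweep - mf_px) <= 1e-6 * max(sweep, 1.0)):
                raise AssertionError(
                    f"calipers/sweep mismatch on fiber {fid}: {mf_px} vs {sweep}")
        is_central = bool(central_mask[fid - 1])
        _draw_nucleus(nuclei, poly, area_px, is_central, rng)
        truths.append(FiberFieldTruth(
            fiber_id=fid, polygon=verts,
            area_um2=area_px * um_per_px ** 2,
            min_feret_um=mf_px * um_per_px,
            has_central_nucleus=is_central, n_nuclei=1))

    nuclei = gaussian(nuclei, sigma=0.8, preserve_range=True)
    nuclei += rng.normal(0.0, noise_sd, size=nuclei.shape)
    nuclei = np.clip(nuclei, 0, 255).astype(np.uint8)
    return membrane, nuclei, truths


def _draw_nucleus(canvas: np.ndarray, poly: Polygon, area_px: float,
                  central: bool, rng: np.random.Generator) -> None:
    """Paint one elliptical nucleus, centrally or border-adjacent.

    Central nuclei sit at least 25% of the equivalent-circle radius from
    the border; peripheral nuclei have their centroid within ~1 px of it.
    The gap between the two keeps truth labels far from the classifier's
    decision margin.
    """
    r_eq = math.sqrt(area_px / math.pi)
    cx, cy = poly.centroid.x, poly.centroid.y
    if central:
        need = 0.25 * r_eq + 1.0
        if poly.exterior.distance(Point(cx, cy)) < need:
            pole = polylabel(poly, tolerance=0.5)
            cx, cy = pole.x, pole.y
        assert poly.exterior.distance(Point(cx, cy)) >= 0.25 * r_eq
    else:
        coords = np.asarray(poly.exterior.coords)
        e = rng.integers(0, len(coords) - 1)
        mx, my = (coords[e] + coords[e + 1]) / 2.0
        dx, dy = cx - mx, cy - my
        norm = math.hypot(dx, dy) or 1.0
        cx, cy = mx + dx / norm * 1.0, my + dy / norm * 1.0
    a = rng.uniform(2.5, 4.0)
    b = rng.uniform(1.8, 2.5)
    rr, cc = draw_ellipse(cy, cx, a, b, shape=canvas.shape,
                          rotation=rng.uniform(0, math.pi))
    canvas[rr, cc] = 220.0


# ---------------------------------------------------------------------------
# area-fraction and cell-count fixtures
# ---------------------------------------------------------------------------

def generate_area_fraction_image(true_fraction: float,
                                 size_px: tuple[int, int] = (256, 256),
                                 positive_color: tuple[int, int, int] = (40, 60, 200),
                                 background_color: tuple[int, int, int] = (200, 120, 120),
                                 seed: int = 0,
                                 ) -> tuple[np.ndarray, float]:
    """RGB image with an exactly realized positive-pixel fraction.

    Random small patches of ``positive_color`` (default aniline blue) on a
    reddish counterstained-tissue background; the last few pixels are
    painted individually so that the painted count equals
    ``round(true_fraction * n_pixels)`` exactly.
    """
    if not 0 <= true_fraction <= 1:
        raise ValueError("true_fraction must be in [0, 1]")
    h, w = size_px
    total = h * w
    target = int(round(true_fraction * total))
    rng = np.random.default_rng(seed)
    mask = np.zeros((h, w), dtype=bool)
    painted = 0
    max_patch = math.pi * 6 ** 2
    while painted < target - max_patch:
        r = rng.uniform(3, 6)
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        rr, cc = draw_disk((cy, cx), r, shape=(h, w))
        mask[rr, cc] = True
        painted = int(mask.sum())
    if painted < target:
        free = np.flatnonzero(~mask.ravel())
        extra = rng.choice(free, size=target - painted, replace=False)
        mask.ravel()[extra] = True
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[...] = np.asarray(background_color, dtype=np.uint8)
    img[mask] = np.asarray(positive_color, dtype=np.uint8)
    realized = mask.sum() / total
    assert abs(realized - true_fraction) <= 0.005 + 1e-12
    return img, float(realized)


def generate_cell_field(n_cells: int,
                        size_px: tuple[int, int] = (512, 512),
                        radius_px: float = 6.0,
                        seed: int = 0,
                        noise_sd: float = 3.0,
                        ) -> tuple[np.ndarray, int]:
    """Exactly ``n_cells`` disjoint bright blobs on a dark background."""
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    h, w = size_px
    min_sep = 2 * radius_px + 3
    if n_cells * (2 * radius_px + 3) ** 2 > 0.45 * h * w:
        raise DensityError(
            f"{n_cells} cells of radius {radius_px} px cannot be placed "
            f"disjointly in a {h}x{w} image")
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_cells:
        attempts += 1
        if attempts > 20000 * max(n_cells, 1):
            raise DensityError("cell placement failed; density too high")
        cy = rng.uniform(radius_px + 2, h - radius_px - 2)
        cx = rng.uniform(radius_px + 2, w - radius_px - 2)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep ** 2 for y, x in centers):
            centers.append((cy, cx))
    img = np.full((h, w), 20.0)
    for cy, cx in centers:
        rr, cc = draw_disk((cy, cx), radius_px, shape=(h, w))
        img[rr, cc] = 220.0
    img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), n_cells


# ---------------------------------------------------------------------------
# trabecular volumes
# ---------------------------------------------------------------------------

def generate_trabecular_volume(kind: str,
                               tb_th_um: float,
                               tb_sp_um: float,
                               size_vox: tuple[int, int, int] = (128, 128, 128),
                               um_per_vox: float = 8.0,
                               noise_sd: float = 0.0,
                               seed: int = 0,
                               fg: float = 200.0,
                               bg: float = 50.0,
                               ) -> tuple[np.ndarray, VolumeTruth]:
    """Grayscale trabecular phantom with constructive morphometric truth.

    ``parallel_plates``: slabs of thickness t separated by gaps of s along
    axis 0 (BV/TV = t/(t+s) exactly; the axis-0 extent must hold a whole
    number of t+s periods).  ``rods``: cylinders along axis 0 on a square
    lattice of pitch t+s.  ``spheres``: spheres on a cubic lattice.  For
    rods and spheres the truth BV/TV is the realized voxel fraction.
    """
    t = tb_th_um / um_per_vox
    s = tb_sp_um / um_per_vox
    if abs(t - round(t)) > 1e-9 or abs(s - round(s)) > 1e-9:
        raise ValueError("tb_th_um and tb_sp_um must be whole numbers of voxels")
    t, s = int(round(t)), int(round(s))
    if t < 1:
        raise ValueError("tb_th_um must be at least one voxel")
    nz, ny, nx = size_vox
    period = t + s
    if kind == "parallel_plates":
        if s and nz % period:
            raise ValueError("axis-0 size must be a whole number of t+s periods")
        z = np.arange(nz)
        mask = (z % period < t)[:, None, None] & np.ones((1, ny, nx), bool)
        bvtv = 1.0 if s == 0 else t / period
    elif kind == "rods":
        y, x = np.mgrid[0:ny, 0:nx]
        dy = (y % period) + 0.5 - period / 2.0
        dx = (x % period) + 0.5 - period / 2.0
        sect = dy ** 2 + dx ** 2 <= (t / 2.0) ** 2
        mask = np.broadcast_to(sect[None, :, :], (nz, ny, nx)).copy()
        bvtv = mask.mean()
    elif kind == "spheres":
        z, y, x = np.mgrid[0:nz, 0:ny, 0:nx]
        d2 = sum(((a % period) + 0.5 - period / 2.0) ** 2 for a in (z, y, x))
        mask = d2 <= (t / 2.0) ** 2
        bvtv = mask.mean()
    else:
        raise ValueError(f"unknown geometry kind {kind!r}")
    vol = np.where(mask, fg, bg)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape)
    vol = np.clip(vol, 0, 255).astype(np.uint8)
    truth = VolumeTruth(bvtv=float(bvtv), tb_th_um=float(t * um_per_vox),
                        tb_sp_um=float(s * um_per_vox), geometry_kind=kind)
    return vol, truth


# ---------------------------------------------------------------------------
# group measurements
# ---------------------------------------------------------------------------

def generate_group_measurements(specs: list[GroupSpec]) -> pd.DataFrame:
    """Long-format (group, value) table drawn per GroupSpec."""
    if len(specs) < 2:
        raise ValueError("need at least two groups")
    frames = []
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        if spec.distribution == "normal":
            vals = rng.normal(spec.mean, spec.sd, size=spec.n)
        elif spec.distribution == "lognormal":
            vals = np.exp(rng.normal(math.log(max(spec.mean, 1e-12)),
                                     spec.sd, size=spec.n))
        else:  # contaminated normal: 10% of draws at 5x the sd
            vals = rng.normal(spec.mean, spec.sd, size=spec.n)
            bad = rng.random(spec.n) < 0.1
            vals[bad] = rng.normal(spec.mean, 5 * spec.sd, size=int(bad.sum()))
        frames.append(pd.DataFrame({"group": spec.group_name, "value": vals}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# expression fixtures
# ---------------------------------------------------------------------------

def generate_ct_table(n_samples: int,
                      genes: list[str],
                      stable_refs: int = 3,
                      noise_sd: float = 0.5,
                      seed: int = 0,
                      ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """qPCR Ct table (genes x samples) with planted reference stability.

    The first ``stable_refs`` genes co-vary tightly with the per-sample
    loading offset (their pairwise log-ratio SD is ~20x below the rest by
    construction); the remaining genes carry full ``noise_sd`` scatter.
    Returns the table and a truth dict with ``stable`` and ``noisy`` names.
    """
    if stable_refs < 2:
        raise ValueError("need at least two stable reference genes")
    if stable_refs > len(genes):
        raise ValueError("stable_refs exceeds the gene list")
    rng = np.random.default_rng(seed)
    base = rng.uniform(18.0, 30.0, size=len(genes))
    offset = rng.normal(0.0, 1.0, size=n_samples)
    ct = base[:, None] + offset[None, :]
    noise = rng.normal(0.0, noise_sd, size=ct.shape)
    noise[:stable_refs] *= 0.05
    ct = ct + noise
    df = pd.DataFrame(ct, index=list(genes),
                      columns=[f"s{i + 1}" for i in range(n_samples)])
    truth = {"stable": list(genes[:stable_refs]),
             "noisy": list(genes[stable_refs:])}
    return df, truth


def generate_fpkm_matrix(n_genes: int,
                         n_samples: int,
                         cluster_structure: tuple[int, int] | None = None,
                         seed: int = 0,
                         effect_log2: float = 3.0,
                         noise_sd: float = 0.5,
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """FPKM matrix (genes x samples) with a planted two-group sample split.

    ``cluster_structure`` gives the two sample-cluster sizes (defaults to an
    even split).  Half of the genes are shifted by ``effect_log2`` (log2
    units) in the second cluster.  Returns the matrix and the true sample
    labels (0/1).
    """
    if cluster_structure is None:
        cluster_structure = (n_samples // 2, n_samples - n_samples // 2)
    n_a, n_b = cluster_structure
    if n_a + n_b != n_samples:
        raise ValueError("cluster sizes must sum to n_samples")
    rng = np.random.default_rng(seed)
    base = rng.normal(5.0, 2.0, size=n_genes)
    log2_expr = base[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    labels = np.r_[np.zeros(n_a, int), np.ones(n_b, int)]
    shifted = rng.permutation(n_genes)[: n_genes // 2]
    log2_expr[np.ix_(shifted, np.flatnonzero(labels == 1))] += effect_log2
    fpkm = np.power(2.0, log2_expr)
    df = pd.DataFrame(fpkm, index=[f"gene{i + 1}" for i in range(n_genes)],
                      columns=[f"s{i + 1}" for i in range(n_samples)])
    return df, labels
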