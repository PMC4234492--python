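"""Colony measurement on single-plate images.

The measurement engine works on 8-bit greyscale images and follows the
classic particle-analysis approach: invert so colonies are dark on a
light background, binarize at a histogram-derived grey level, find
connected components ("particles"), locate the array grid from the
particle layout, and assign each particle to its nearest grid position
subject to distance, size and circularity criteria.  Grid positions
left empty are re-scanned for pixel content and optionally recovered in
a low-stringency pass that ignores circularity (for smeared colonies).

The output of measurement is a :class:`PlateMeasurement`: one pixel
area per (row, column) position plus provenance flags, written to a
tab-delimited raw-area file consumed by the scoring stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from skimage import measure as skmeasure
from skimage import transform as sktransform

__all__ = [
    "GridPreset",
    "GridFit",
    "Particle",
    "ColonyRecord",
    "PlateMeasurement",
    "MeasureParams",
    "GridNotFoundError",
    "PRESETS",
    "auto_threshold",
    "threshold_with_retry",
    "find_particles",
    "locate_grid",
    "assign_and_measure",
    "rescan_positions",
    "classify_plate",
    "measure_plate",
    "write_raw_file",
    "read_raw_file",
]

STATUS_VALUES = ("auto", "low_stringency", "manual", "empty", "bad")


class GridNotFoundError(RuntimeError):
    """Raised when no acceptable grid fit could be established."""


@dataclass(frozen=True)
class GridPreset:
    """Array geometry prior: grid dimensions and mean colony spacing.

    ``dx``/``dy`` are the expected horizontal and vertical spacings in
    pixels between adjacent colony centres.  The stock presets assume
    300 dpi scans of standard-footprint plates.
    """

    rows: int
    cols: int
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid must have at least 2 rows and 2 columns")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("spacings must be positive")


#: Stock presets for the common array densities (pitch at 300 dpi).
PRESETS: dict[int, GridPreset] = {
    96: GridPreset(8, 12, 106.0, 106.0),
    384: GridPreset(16, 24, 53.0, 53.0),
    1536: GridPreset(32, 48, 26.5, 26.5),
    6144: GridPreset(64, 96, 13.3, 13.3),
}


@dataclass(frozen=True)
class GridFit:
    """Located array geometry on an image.

    ``origin_x``/``origin_y`` are the pixel coordinates of the centre
    of the (row 1, column 1) cell on the image *after* rotating it by
    ``rotation`` degrees.  The fitted spacings must lie within 20% of
    the preset used for the search.
    """

    origin_x: float
    origin_y: float
    dx: float
    dy: float
    rotation: float = 0.0
    n_support: int = 0
    mean_dev_x: float = 0.0
    mean_dev_y: float = 0.0

    def node(self, row: int, col: int) -> tuple[float, float]:
        """Centre (x, y) of the 1-based (row, col) grid position."""
        return (self.origin_x + (col - 1) * self.dx,
                self.origin_y + (row - 1) * self.dy)


@dataclass(frozen=True)
class Particle:
    """A connected foreground component: centroid, area, circularity."""

    cx: float
    cy: float
    area: int
    circularity: float


@dataclass(frozen=True)
class ColonyRecord:
    """Measured state of one grid position (1-based, (1,1) = top-left)."""

    row: int
    col: int
    area: int
    status: str = "auto"

    def __post_init__(self) -> None:
        if self.status not in STATUS_VALUES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "empty" and self.area != 0:
            raise ValueError("empty positions must have area 0")


@dataclass
class PlateMeasurement:
    """All colony areas for one plate plus identity and quality."""

    base_name: str
    set_number: int
    plate_number: int
    rows: int
    cols: int
    areas: np.ndarray  # int array (rows, cols)
    status: np.ndarray  # str array (rows, cols)
    grid: GridFit | None = None
    threshold_level: int = 0
    quality: str = "ok"

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=np.int64)
        self.status = np.asarray(self.status, dtype="U14")
        if self.areas.shape != (self.rows, self.cols):
            raise ValueError("areas shape does not match grid dimensions")
        if self.status.shape != (self.rows, self.cols):
            raise ValueError("status shape does not match grid dimensions")

    @property
    def records(self) -> list[ColonyRecord]:
        return [
            ColonyRecord(r + 1, c + 1, int(self.areas[r, c]),
                         str(self.status[r, c]))
            for r in range(self.rows) for c in range(self.cols)
        ]

    def bad_spot_count(self) -> int:
        return int(np.sum(self.status == "bad"))


@dataclass(frozen=True)
class MeasureParams:
    """Tunable criteria for particle-to-colony assignment.

    ``max_offset_fraction`` is the maximum deviation of a particle
    centroid from its grid-cell centre, as a fraction of the cell pitch
    (the classic quarter-cell rule).  ``max_area`` defaults to one full
    grid cell (dx*dy) when None.
    """

    min_area: int = 20
    max_area: int | None = None
    min_circularity: float = 0.8
    max_offset_fraction: float = 0.25
    rescan_min_pixels: int = 25
    low_stringency: bool = True


def auto_threshold(grey: np.ndarray) -> int:
    """Histogram-based automatic threshold (iterative intermeans).

    Starting from the overall image mean, the grey level is repeatedly
    replaced by the mean of the two class means it induces (pixels at
    or below the level vs. above it) until it stops moving.  The result
    is deterministic for a given histogram.  Input must be 8-bit
    greyscale with colonies dark on a light background (i.e. already
    inverted); colony pixels are those *below* the returned level.
    """
    grey = np.asarray(grey)
    if grey.ndim != 2:
        raise ValueError("expected a 2-D greyscale raster")
    hist = np.bincount(grey.ravel().astype(np.uint8), minlength=256).astype(np.float64)
    nz = np.nonzero(hist)[0]
    if nz.size < 2:
        raise ValueError("degenerate histogram: image is constant")
    levels = np.arange(256, dtype=np.float64)
    t = int(round(float(np.sum(levels * hist) / np.sum(hist))))
    for _ in range(256):
        lo, hi = hist[: t + 1], hist[t + 1:]
        if lo.sum() == 0:
            m0 = float(t)
        else:
            m0 = float(np.sum(levels[: t + 1] * lo) / lo.sum())
        if hi.sum() == 0:
            m1 = float(t)
        else:
            m1 = float(np.sum(levels[t + 1:] * hi) / hi.sum())
        t_new = int(round((m0 + m1) / 2.0))
        if t_new == t:
            return t
        t = t_new
    return t


def find_particles(
    binary: np.ndarray,
    region: tuple[int, int, int, int] | None = None,
    min_area: int = 1,
    min_circularity: float = 0.0,
) -> list[Particle]:
    """Connected-component particle analysis.

    Components are 8-connected foreground regions of ``binary``,
    optionally restricted to ``region`` = (x0, y0, x1, y1) (half-open).
    Circularity is 4*pi*area/perimeter^2 with the perimeter taken from
    the component boundary polygon approximation, clamped to 1.
    Centroids are pixel-centroid coordinates in the frame of the full
    raster.
    """
    binary = np.asarray(binary, dtype=bool)
    ox = oy = 0
    if region is not None:
        x0, y0, x1, y1 = region
        x0 = max(0, x0); y0 = max(0, y0)
        x1 = min(binary.shape[1], x1); y1 = min(binary.shape[0], y1)
        if x0 >= x1 or y0 >= y1:
            return []
        binary = binary[y0:y1, x0:x1]
        ox, oy = x0, y0
    labels = skmeasure.label(binary, connectivity=2)
    out: list[Particle] = []
    for prop in skmeasure.regionprops(labels):
        if prop.area < min_area:
            continue
        perim = prop.perimeter
        if perim <= 0:
            circ = 1.0
        else:
            circ = min(1.0, 4.0 * math.pi * prop.area / (perim * perim))
        if circ < min_circularity:
            continue
        cy, cx = prop.centroid
        out.append(Particle(cx=cx + ox, cy=cy + oy, area=int(prop.area),
                            circularity=circ))
    return out


def _rotate_binary(binary: np.ndarray, angle: float) -> np.ndarray:
    """Rotate a binary raster about its centre, nearest-neighbour."""
    if angle == 0.0:
        return binary
    rot = sktransform.rotate(binary.astype(float), angle, order=0,
                             preserve_range=True)
    return rot > 0.5


def _fit_lattice(
    particles: list[Particle],
    preset: GridPreset,
    rect_x0: float,
    rect_y0: float,
    support_tol: float = 0.30,
    accept_tol: float = 0.05,
    min_support_fraction: float = 0.25,
) -> GridFit | None:
    """Try to fit an axis-aligned lattice seeded from the rectangle at
    (rect_x0, rect_y0) spanning the expected array extent.

    Seeds the fit from the four particles nearest the rectangle
    corners, then iteratively assigns particles to nearest lattice
    nodes, keeps those within ``support_tol`` of a node in both axes,
    and refits origin and spacing by least squares.  Accepts when the
    mean absolute deviations are below ``accept_tol`` of the pitch.
    """
    rows, cols = preset.rows, preset.cols
    W = (cols - 1) * preset.dx
    H = (rows - 1) * preset.dy
    if not particles:
        return None
    xs = np.array([p.cx for p in particles])
    ys = np.array([p.cy for p in particles])

    corners = np.array([
        (rect_x0, rect_y0), (rect_x0 + W, rect_y0),
        (rect_x0, rect_y0 + H), (rect_x0 + W, rect_y0 + H),
    ])
    # seed origin/spacing from the corner-most particles
    idx = [int(np.argmin((xs - cx) ** 2 + (ys - cy) ** 2)) for cx, cy in corners]
    tl, tr, bl, br = (np.array([xs[i], ys[i]]) for i in idx)
    dx0 = ((tr[0] - tl[0]) + (br[0] - bl[0])) / 2.0 / (cols - 1)
    dy0 = ((bl[1] - tl[1]) + (br[1] - tr[1])) / 2.0 / (rows - 1)
    if dx0 <= 0 or dy0 <= 0:
        return None
    ox = (tl[0] + bl[0]) / 2.0
    oy = (tl[1] + tr[1]) / 2.0

    fit = _refine_lattice(xs, ys, preset, ox, oy, dx0, dy0,
                          support_tol, accept_tol, min_support_fraction)
    if fit is not None:
        return fit
    # corner seeding fails when corner colonies are absent (the
    # corner-most particle then sits a cell inward, biasing the pitch);
    # fall back to 1-D projection clustering for the seed, keeping the
    # same support/acceptance criteria
    seed = _projection_seed(xs, ys, preset, rect_x0, rect_y0)
    if seed is None:
        return None
    ox, oy, dx0, dy0 = seed
    return _refine_lattice(xs, ys, preset, ox, oy, dx0, dy0,
                           support_tol, accept_tol, min_support_fraction)


def _cluster_positions(vals: np.ndarray, pitch: float) -> np.ndarray:
    """1-D cluster means of projected particle coordinates, split at
    gaps larger than half the expected pitch."""
    vals = np.sort(vals)
    splits = np.where(np.diff(vals) > 0.5 * pitch)[0]
    return np.array([g.mean() for g in np.split(vals, splits + 1)])


def _projection_seed(xs, ys, preset, rect_x0, rect_y0):
    """Seed origin/pitch by clustering the x and y projections."""
    out = []
    for vals, pitch, r0 in ((xs, preset.dx, rect_x0),
                            (ys, preset.dy, rect_y0)):
        means = _cluster_positions(vals, pitch)
        if means.size < 2:
            return None
        diffs = np.diff(means)
        step = float(np.median(diffs))
        if step <= 0:
            return None
        k = np.round((means - means[0]) / step)
        fitp = np.polyfit(k, means, 1)
        step, first = float(fitp[0]), float(fitp[1])
        if step <= 0:
            return None
        # snap the rectangle edge to the nearest lattice line
        origin = first + round((r0 - first) / step) * step
        out.append((origin, step))
    (ox, dx0), (oy, dy0) = out
    return ox, oy, dx0, dy0


def _refine_lattice(xs, ys, preset, ox, oy, dx, dy,
                    support_tol, accept_tol, min_support_fraction):
    rows, cols = preset.rows, preset.cols
    support = np.zeros(xs.size, dtype=bool)
    for _ in range(4):
        ci = np.clip(np.round((xs - ox) / dx), 0, cols - 1)
        ri = np.clip(np.round((ys - oy) / dy), 0, rows - 1)
        ex = xs - (ox + ci * dx)
        ey = ys - (oy + ri * dy)
        support = (np.abs(ex) < support_tol * dx) & (np.abs(ey) < support_tol * dy)
        if support.sum() < 4:
            return None
        # separable least-squares refit of origin and pitch
        A = np.column_stack([np.ones(support.sum()), ci[support]])
        sol_x, *_ = np.linalg.lstsq(A, xs[support], rcond=None)
        B = np.column_stack([np.ones(support.sum()), ri[support]])
        sol_y, *_ = np.linalg.lstsq(B, ys[support], rcond=None)
        if sol_x[1] <= 0 or sol_y[1] <= 0:
            return None
        ox, dx = float(sol_x[0]), float(sol_x[1])
        oy, dy = float(sol_y[0]), float(sol_y[1])

    if abs(dx - preset.dx) > 0.2 * preset.dx or abs(dy - preset.dy) > 0.2 * preset.dy:
        return None
    ci = np.clip(np.round((xs - ox) / dx), 0, cols - 1)
    ri = np.clip(np.round((ys - oy) / dy), 0, rows - 1)
    ex = xs - (ox + ci * dx)
    ey = ys - (oy + ri * dy)
    support = (np.abs(ex) < support_tol * dx) & (np.abs(ey) < support_tol * dy)
    n_sup = int(support.sum())
    if n_sup < min_support_fraction * rows * cols:
        return None
    mdx = float(np.mean(np.abs(ex[support])))
    mdy = float(np.mean(np.abs(ey[support])))
    if mdx >= accept_tol * dx or mdy >= accept_tol * dy:
        return None
    return GridFit(origin_x=ox, origin_y=oy, dx=dx, dy=dy, rotation=0.0,
                   n_support=n_sup, mean_dev_x=mdx, mean_dev_y=mdy)


def _rotation_schedule(max_deg: float = 3.0, step: float = 0.5):
    """Angles to try when the axis-aligned fit fails: |angle| ascending,
    positive before negative."""
    n = int(round(max_deg / step))
    for k in range(1, n + 1):
        yield k * step
        yield -k * step


def locate_grid(
    binary: np.ndarray,
    preset: GridPreset,
    allow_rotation: bool = True,
    particle_min_area: int = 5,
    min_support_fraction: float = 0.25,
) -> GridFit:
    """Locate the colony array on a binarized plate image.

    A rectangle of the expected array extent is scanned over the image,
    starting centred on the particle cloud; the fit is seeded from the
    particles nearest its corners.  A particle supports the fit when
    both coordinate deviations from its nearest lattice node are below
    30% of the pitch, and the fit is accepted when the mean horizontal
    and vertical deviations of supporting particles are each below 5%
    of the pitch.  On failure the rectangle is repositioned on a spiral
    of half-cell offsets; if that fails too and ``allow_rotation`` is
    set, the image is rotated by +/-0.5 deg steps up to +/-3 deg
    (smallest magnitude first, positive first) and the search repeated.

    The returned :class:`GridFit` records the rotation at which the
    grid was accepted; its origin/spacing refer to the rotated image.
    """
    def _attempt(mask: np.ndarray) -> GridFit | None:
        particles = find_particles(mask, min_area=particle_min_area)
        if len(particles) < 4:
            return None
        xs = np.array([p.cx for p in particles])
        ys = np.array([p.cy for p in particles])
        W = (preset.cols - 1) * preset.dx
        H = (preset.rows - 1) * preset.dy
        cx0 = float(np.median(xs)) - W / 2.0
        cy0 = float(np.median(ys)) - H / 2.0
        # spiral of half-cell offsets, up to +/-2 cells
        offsets = [(0, 0)]
        for radius in range(1, 5):
            ring = []
            for a in range(-radius, radius + 1):
                for b in range(-radius, radius + 1):
                    if max(abs(a), abs(b)) == radius:
                        ring.append((a, b))
            ring.sort(key=lambda t: (t[0] ** 2 + t[1] ** 2, t))
            offsets.extend(ring)
        for a, b in offsets:
            fit = _fit_lattice(particles, preset,
                               cx0 + a * preset.dx / 2.0,
                               cy0 + b * preset.dy / 2.0,
                               min_support_fraction=min_support_fraction)
            if fit is not None:
                return fit
        return None

    fit = _attempt(binary)
    if fit is not None:
        return fit
    if allow_rotation:
        for angle in _rotation_schedule():
            fit = _attempt(_rotate_binary(binary, angle))
            if fit is not None:
                return replace(fit, rotation=angle)
    raise GridNotFoundError(
        f"grid not found for {preset.rows}x{preset.cols} preset "
        f"(dx={preset.dx}, dy={preset.dy})"
    )


def threshold_with_retry(
    grey: np.ndarray,
    preset: GridPreset,
    start_level: int | None = None,
    step: int = 5,
    allow_rotation: bool = True,
    max_retries: int = 20,
) -> tuple[np.ndarray, int, GridFit]:
    """Binarize with automatic retry at decreasing grey levels.

    ``grey`` must be inverted (colonies dark).  Starting from
    ``start_level`` (the automatic histogram threshold when None), the
    image is binarized at decreasing levels until :func:`locate_grid`
    succeeds.  Too high a level merges the background with the
    colonies; decreasing it separates them, at the risk of eroding
    colony area, so the first successful level is kept.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    level = auto_threshold(grey) if start_level is None else int(start_level)
    last_err: Exception | None = None
    for k in range(max_retries + 1):
        lvl = level - k * step
        if lvl <= 0:
            break
        binary = np.asarray(grey) < lvl
        try:
            fit = locate_grid(binary, preset, allow_rotation=allow_rotation)
            return binary, lvl, fit
        except GridNotFoundError as exc:
            last_err = exc
    raise GridNotFoundError(
        f"unthresholdable: no grid found from level {level} "
        f"down in steps of {step}"
    ) from last_err


def assign_and_measure(
    particles: list[Particle],
    grid: GridFit,
    preset: GridPreset,
    params: MeasureParams = MeasureParams(),
) -> PlateMeasurement:
    """Map particles to grid positions and record colony areas.

    A particle is accepted as the colony of its nearest grid node iff
    (a) both centroid offsets are within ``max_offset_fraction`` of the
    pitch (quarter-cell by default), (b) its area lies within the size
    limits, and (c) its circularity meets the minimum.  When several
    candidates satisfy (a)-(c) for one node, the one nearest the node
    centre wins.  Unassigned nodes get area 0 and status ``empty``.
    """
    rows, cols = preset.rows, preset.cols
    max_area = params.max_area if params.max_area is not None else int(grid.dx * grid.dy)
    areas = np.zeros((rows, cols), dtype=np.int64)
    status = np.full((rows, cols), "empty", dtype="U14")
    best_d2 = np.full((rows, cols), np.inf)
    for p in particles:
        ci = int(np.clip(round((p.cx - grid.origin_x) / grid.dx), 0, cols - 1))
        ri = int(np.clip(round((p.cy - grid.origin_y) / grid.dy), 0, rows - 1))
        nx, ny = grid.node(ri + 1, ci + 1)
        ex, ey = p.cx - nx, p.cy - ny
        if abs(ex) >= params.max_offset_fraction * grid.dx:
            continue
        if abs(ey) >= params.max_offset_fraction * grid.dy:
            continue
        if not (params.min_area <= p.area <= max_area):
            continue
        if p.circularity < params.min_circularity:
            continue
        d2 = ex * ex + ey * ey
        if d2 < best_d2[ri, ci]:
            best_d2[ri, ci] = d2
            areas[ri, ci] = p.area
            status[ri, ci] = "auto"
    return PlateMeasurement(
        base_name="", set_number=0, plate_number=0,
        rows=rows, cols=cols, areas=areas, status=status, grid=grid,
    )


def rescan_positions(
    binary: np.ndarray,
    pm: PlateMeasurement,
    params: MeasureParams = MeasureParams(),
) -> PlateMeasurement:
    """Re-examine empty grid positions for undetected growth.

    Each empty node's cell is checked for foreground pixel content;
    cells exceeding ``rescan_min_pixels`` are flagged as possibly
    occupied.  When ``low_stringency`` is enabled, flagged cells get a
    second particle-finding pass with the circularity requirement
    dropped to zero (recovering e.g. smeared colonies), assigned under
    the usual quarter-cell rule with status ``low_stringency``.  Cells
    flagged but still unrecovered are marked ``bad``.
    """
    grid = pm.grid
    if grid is None:
        raise ValueError("measurement has no grid fit")
    areas = pm.areas.copy()
    status = pm.status.copy()
    h, w = binary.shape
    half_x, half_y = grid.dx / 2.0, grid.dy / 2.0
    for ri in range(pm.rows):
        for ci in range(pm.cols):
            if status[ri, ci] != "empty":
                continue
            nx, ny = grid.node(ri + 1, ci + 1)
            x0, x1 = int(round(nx - half_x)), int(round(nx + half_x))
            y0, y1 = int(round(ny - half_y)), int(round(ny + half_y))
            cell = binary[max(0, y0):min(h, y1), max(0, x0):min(w, x1)]
            count = int(np.count_nonzero(cell))
            if count <= params.rescan_min_pixels:
                continue
            recovered = False
            if params.low_stringency:
                cands = find_particles(binary, region=(x0, y0, x1, y1),
                                       min_area=params.min_area,
                                       min_circularity=0.0)
                best = None
                best_d2 = np.inf
                for p in cands:
                    ex, ey = p.cx - nx, p.cy - ny
                    if abs(ex) >= params.max_offset_fraction * grid.dx:
                        continue
                    if abs(ey) >= params.max_offset_fraction * grid.dy:
                        continue
                    d2 = ex * ex + ey * ey
                    if d2 < best_d2:
                        best_d2, best = d2, p
                if best is not None:
                    areas[ri, ci] = best.area
                    status[ri, ci] = "low_stringency"
                    recovered = True
            if not recovered:
                status[ri, ci] = "bad"
    out = replace(pm)
    out.areas = areas
    out.status = status
    return out


def classify_plate(
    pm: PlateMeasurement,
    fail_threshold: int | None = None,
) -> str:
    """Grade a measurement by its bad-spot count.

    ``ok`` with no bad spots, ``warn`` when the count is positive but
    at most ``fail_threshold`` (default 5% of positions), else
    ``fail``.
    """
    if fail_threshold is None:
        fail_threshold = max(1, int(0.05 * pm.rows * pm.cols))
    n_bad = pm.bad_spot_count()
    if n_bad == 0:
        return "ok"
    if n_bad <= fail_threshold:
        return "warn"
    return "fail"


def measure_plate(
    grey: np.ndarray,
    preset: GridPreset,
    base_name: str = "",
    set_number: int = 1,
    plate_number: int = 1,
    params: MeasureParams = MeasureParams(),
    invert: bool = True,
    start_level: int | None = None,
    retry_step: int = 5,
    allow_rotation: bool = True,
) -> PlateMeasurement:
    """Measure every colony on an 8-bit greyscale plate image.

    Orchestrates the full engine: inversion (scans normally show light
    colonies), thresholding with retry, grid localization (with
    rotation retries), particle assignment, rescan/low-stringency
    recovery and quality classification.
    """
    grey = np.asarray(grey)
    if grey.ndim == 3:
        grey = grey.mean(axis=2)
    grey = grey.astype(np.uint8)
    if invert:
        grey = (255 - grey).astype(np.uint8)
    binary, level, grid = threshold_with_retry(
        grey, preset, start_level=start_level, step=retry_step,
        allow_rotation=allow_rotation,
    )
    if grid.rotation != 0.0:
        binary = _rotate_binary(binary, grid.rotation)
    particles = find_particles(binary, min_area=params.min_area)
    pm = assign_and_measure(particles, grid, preset, params)
    pm.base_name = base_name
    pm.set_number = set_number
    pm.plate_number = plate_number
    pm.threshold_level = level
    pm = rescan_positions(binary, pm, params)
    pm.quality = classify_plate(pm)
    return pm


def write_raw_file(pm: PlateMeasurement, path: str | Path) -> None:
    """Write a raw colony-area table (tab-delimited, UTF-8).

    Metadata lines are ``#``-prefixed; the body has one line per grid
    position with columns ``row  col  area  status``.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# base_name\t{pm.base_name}\n")
        fh.write(f"# set\t{pm.set_number}\n")
        fh.write(f"# plate\t{pm.plate_number}\n")
        fh.write(f"# rows\t{pm.rows}\n")
        fh.write(f"# cols\t{pm.cols}\n")
        fh.write(f"# threshold\t{pm.threshold_level}\n")
        fh.write(f"# quality\t{pm.quality}\n")
        fh.write("row\tcol\tarea\tstatus\n")
        for r in range(pm.rows):
            for c in range(pm.cols):
                fh.write(f"{r + 1}\t{c + 1}\t{int(pm.areas[r, c])}\t"
                         f"{pm.status[r, c]}\n")


def read_raw_file(path: str | Path) -> PlateMeasurement:
    """Read a raw colony-area table written by :func:`write_raw_file`."""
    path = Path(path)
    meta: dict[str, str] = {}
    body: list[tuple[int, int, int, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: malformed metadata line")
                meta[parts[0].strip()] = parts[1].strip()
                continue
            if line.startswith("row\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, "
                                 f"got {len(parts)}")
            try:
                body.append((int(parts[0]), int(parts[1]), int(parts[2]),
                             parts[3]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    for key in ("base_name", "set", "plate"):
        if key not in meta:
            raise ValueError(f"{path}: missing metadata header {key!r}")
    if "rows" in meta and "cols" in meta:
        rows, cols = int(meta["rows"]), int(meta["cols"])
    else:
        rows = max(r for r, *_ in body)
        cols = max(c for _, c, *_ in body)
    areas = np.zeros((rows, cols), dtype=np.int64)
    status = np.full((rows, cols), "empty", dtype="U14")
    for r, c, a, s in body:
        if not (1 <= r <= rows and 1 <= c <= cols):
            raise ValueError(f"{path}: position ({r},{c}) outside "
                             f"{rows}x{cols} grid")
        areas[r - 1, c - 1] = a
        status[r - 1, c - 1] = s
    return PlateMeasurement(
        base_name=meta["base_name"],
        set_number=int(meta["set"]),
        plate_number=int(meta["plate"]),
        rows=rows, cols=cols, areas=areas, status=status,
        threshold_level=int(meta.get("threshold", 0)),
        quality=meta.get("quality", "ok"),
    )
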