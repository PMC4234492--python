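"""Ground-truthed synthetic inputs for every pipeline stage.

Two families of generators:

* **Rendered plate images** (:func:`render_plate`): anti-aliasing-free
  filled ellipses on a flat background, with known grid geometry and
  planted artifacts — edge growth boost, smooth spatial gradients,
  missing colonies, smeared (elongated) colonies, sub-degree plate
  rotation, and Gaussian sensor noise.  Truth areas are the exact
  rasterized pixel counts.

* **Simulated screens** (:func:`simulate_screen`): paired control and
  experimental raw-area files across replicate sets with planted
  genetic interactions (true colony-size ratios), multiplicative
  lognormal noise, and an optional linkage block of positions with
  strongly depressed experimental growth — mimicking the reduced
  recombination of genes physically near the query locus.

Value-grid helpers (:func:`edge_boost_plate`, :func:`gradient_plate`,
:func:`competition_plate`) plant the systematic effects the
normalization corrections target, at the area level, without going
through image rendering.

The edge model is separable: each outermost row and column carries a
per-axis growth advantage, so a corner colony (boosted on both axes)
reaches about +67% area over the plate mean — the magnitude reported
for real uniform-strain test arrays — while a non-corner edge colony
gets about +29%.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import draw as skdraw

from colonyarray.colony_quant import PlateMeasurement, write_raw_file

__all__ = [
    "PlateSpec",
    "ScreenSpec",
    "render_plate",
    "render_from_areas",
    "simulate_screen",
    "simulate_screen_areas",
    "edge_boost_plate",
    "gradient_plate",
    "competition_plate",
    "write_key_file",
]

#: Default corner area boost: corner colonies grow up to ~67% larger
#: than the plate mean on uniform-strain arrays.
DEFAULT_CORNER_BOOST = 1.67

#: Typical mean colony area (pixels) for a 1536-density array at 300 dpi.
DEFAULT_BASE_AREA = 140.0


@dataclass(frozen=True)
class PlateSpec:
    """Geometry and planted artifacts for one rendered plate image."""

    rows: int = 32
    cols: int = 48
    dx: float = 18.0
    dy: float = 18.0
    origin: tuple[float, float] = (30.0, 30.0)  # (x, y) of node (1,1)
    # non-integer radius avoids knife-edge rasterization (pixels at an
    # exactly-integer distance flip in/out as centres shift sub-pixel)
    base_radius: float = 5.2
    background_level: int = 40
    colony_level: int = 220
    noise_sd: float = 0.0
    rotation: float = 0.0  # degrees; undone by rotating the image by +rotation
    corner_boost: float = 1.0  # area factor at corners (separable per axis)
    gradient: tuple[tuple[float, float], tuple[float, float]] | None = None
    missing: frozenset[tuple[int, int]] = frozenset()
    smeared: dict[tuple[int, int], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if self.background_level == self.colony_level:
            raise ValueError("background and colony levels must differ")
        for r, c in self.missing:
            if not (1 <= r <= self.rows and 1 <= c <= self.cols):
                raise ValueError(f"missing position ({r},{c}) outside grid")
        for r, c in self.smeared:
            if not (1 <= r <= self.rows and 1 <= c <= self.cols):
                raise ValueError(f"smeared position ({r},{c}) outside grid")


def _area_factors(rows: int, cols: int, corner_boost: float,
                  gradient) -> np.ndarray:
    """Per-position multiplicative area factors (separable model)."""
    row_f = np.ones(rows)
    col_f = np.ones(cols)
    if corner_boost != 1.0:
        axis = math.sqrt(corner_boost)
        row_f[[0, -1]] *= axis
        col_f[[0, -1]] *= axis
    if gradient is not None:
        (r_lo, r_hi), (c_lo, c_hi) = gradient
        row_f *= np.linspace(r_lo, r_hi, rows)
        col_f *= np.linspace(c_lo, c_hi, cols)
    return np.outer(row_f, col_f)


def render_plate(spec: PlateSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a plate image with known per-colony pixel areas.

    Colonies are drawn as exactly rasterized filled ellipses (no
    anti-aliasing) at grid nodes, with radii scaled by the square root
    of the planted area factors; a smeared colony keeps its area but is
    stretched to the given axis ratio along x.  Returns the 8-bit
    greyscale image (light colonies on a dark background, as scanned
    against black card) and the truth table of drawn pixel counts, one
    per grid position.
    """
    rows, cols = spec.rows, spec.cols
    factors = _area_factors(rows, cols, spec.corner_boost, spec.gradient)
    max_radius = spec.base_radius * math.sqrt(float(factors.max()))
    max_ratio = max(spec.smeared.values(), default=1.0)
    if max_radius * math.sqrt(max_ratio) > min(spec.dx, spec.dy) / 2.0:
        raise ValueError(
            f"colony radius {max_radius:.1f} px would overlap neighbours "
            f"at pitch ({spec.dx}, {spec.dy})"
        )
    ox, oy = spec.origin
    width = int(round(2 * ox + (cols - 1) * spec.dx))
    height = int(round(2 * oy + (rows - 1) * spec.dy))
    img = np.full((height, width), spec.background_level, dtype=np.float64)
    truth = np.zeros((rows, cols), dtype=np.int64)

    theta = math.radians(spec.rotation)
    cx0, cy0 = (width - 1) / 2.0, (height - 1) / 2.0

    for r in range(1, rows + 1):
        for c in range(1, cols + 1):
            if (r, c) in spec.missing:
                continue
            x = ox + (c - 1) * spec.dx
            y = oy + (r - 1) * spec.dy
            if theta:
                # plant the grid rotated so that rotating the image by
                # +spec.rotation (counter-clockwise in display) restores
                # an axis-aligned array
                dxp, dyp = x - cx0, y - cy0
                x = cx0 + dxp * math.cos(theta) - dyp * math.sin(theta)
                y = cy0 + dxp * math.sin(theta) + dyp * math.cos(theta)
            radius = spec.base_radius * math.sqrt(float(factors[r - 1, c - 1]))
            ratio = spec.smeared.get((r, c), 1.0)
            rx = radius * math.sqrt(ratio)
            ry = radius / math.sqrt(ratio)
            rr, cc = skdraw.ellipse(y, x, ry, rx, shape=img.shape)
            img[rr, cc] = spec.colony_level
            truth[r - 1, c - 1] = rr.size
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8), truth


def render_from_areas(areas: np.ndarray, spec: PlateSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a plate image whose colonies have the given target areas.

    Each colony is drawn as a disk of radius sqrt(area/pi) at its grid
    node (zero areas are left empty); the truth table holds the exact
    drawn pixel counts, which differ from the targets only by
    rasterization.  Geometry, grey levels and noise come from ``spec``.
    """
    areas = np.asarray(areas)
    if areas.shape != (spec.rows, spec.cols):
        raise ValueError("areas shape does not match spec grid")
    max_r = math.sqrt(float(areas.max()) / math.pi)
    if max_r > min(spec.dx, spec.dy) / 2.0:
        raise ValueError("largest colony would overlap neighbours")
    ox, oy = spec.origin
    width = int(round(2 * ox + (spec.cols - 1) * spec.dx))
    height = int(round(2 * oy + (spec.rows - 1) * spec.dy))
    img = np.full((height, width), spec.background_level, dtype=np.float64)
    truth = np.zeros((spec.rows, spec.cols), dtype=np.int64)
    for r in range(spec.rows):
        for c in range(spec.cols):
            if areas[r, c] <= 0:
                continue
            x = ox + c * spec.dx
            y = oy + r * spec.dy
            radius = math.sqrt(float(areas[r, c]) / math.pi)
            rr, cc = skdraw.disk((y, x), radius, shape=img.shape)
            img[rr, cc] = spec.colony_level
            truth[r, c] = rr.size
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8), truth


@dataclass(frozen=True)
class ScreenSpec:
    """Layout and planted interactions for a simulated paired screen."""

    plates: int = 1
    rows: int = 32
    cols: int = 48
    replicates: int = 3
    planted_interactions: dict[tuple[int, int, int], float] = field(
        default_factory=dict)  # (plate,row,col) -> true size ratio
    noise_cv: float = 0.05
    linkage_block: tuple[tuple[int, int, int], ...] = ()
    linkage_ratio: float = 0.2
    base_area: float = DEFAULT_BASE_AREA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        for ratio in self.planted_interactions.values():
            if ratio <= 0:
                raise ValueError("true ratios must be positive")


def _lognormal_factor(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of
    variation ``cv`` (identically 1 when cv == 0)."""
    if cv <= 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    mu = -0.5 * sigma * sigma
    return rng.lognormal(mu, sigma, shape)


def simulate_screen_areas(spec: ScreenSpec) -> list[tuple[str, int, int, np.ndarray]]:
    """Generate the per-plate colony-area matrices of a paired screen.

    Returns a list of (arm, set, plate, areas) with arm in
    {"control", "experiment"}, in a fixed deterministic order.
    Control sizes fluctuate around ``base_area``; experimental sizes
    are the noiseless base times the planted ratio times independent
    noise, so with zero noise the observed ratio equals the planted
    ratio exactly.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.rows, spec.cols)
    linkage = set(spec.linkage_block)
    out: list[tuple[str, int, int, np.ndarray]] = []
    for s in range(1, spec.replicates + 1):
        for p in range(1, spec.plates + 1):
            ratio = np.ones(shape)
            for (pp, r, c), q in spec.planted_interactions.items():
                if pp == p:
                    ratio[r - 1, c - 1] = q
            for (pp, r, c) in linkage:
                if pp == p:
                    ratio[r - 1, c - 1] = spec.linkage_ratio
            ctrl = spec.base_area * _lognormal_factor(rng, spec.noise_cv, shape)
            expt = (spec.base_area * ratio
                    * _lognormal_factor(rng, spec.noise_cv, shape))
            out.append(("control", s, p, np.round(ctrl).astype(np.int64)))
            out.append(("experiment", s, p, np.round(expt).astype(np.int64)))
    return out


def simulate_screen(
    spec: ScreenSpec,
    out_dir: str | Path,
    control_name: str = "ctrl",
    experiment_name: str = "expt",
) -> dict:
    """Simulate a paired control/experiment screen as raw-area files.

    Control colony sizes fluctuate around ``base_area`` with
    multiplicative lognormal noise of the given coefficient of
    variation; experimental sizes are the control *truth* times the
    planted interaction ratio times independent noise, so with zero
    noise the observed ratio equals the planted ratio exactly.
    Positions in the linkage block get strongly reduced experimental
    growth regardless of planted interactions.  One raw file is written
    per (arm, set, plate) in the measurement dialect.

    Returns a manifest dict with the file lists, the key-file path and
    the truth map of planted ratios.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    control_files: list[str] = []
    experiment_files: list[str] = []
    shape = (spec.rows, spec.cols)
    linkage = set(spec.linkage_block)
    names = {"control": control_name, "experiment": experiment_name}
    files = {"control": control_files, "experiment": experiment_files}
    for arm, s, p, areas in simulate_screen_areas(spec):
        pm = PlateMeasurement(
            base_name=names[arm], set_number=s, plate_number=p,
            rows=spec.rows, cols=spec.cols, areas=areas,
            status=np.full(shape, "auto", dtype="U14"),
        )
        fname = f"{names[arm]}_set-{s}_plate-{p}.txt"
        write_raw_file(pm, out_dir / fname)
        files[arm].append(fname)

    key_path = out_dir / "array.key"
    write_key_file(key_path, spec.plates, spec.rows, spec.cols)
    return {
        "control_files": control_files,
        "experiment_files": experiment_files,
        "key_file": str(key_path),
        "truth": dict(spec.planted_interactions),
        "linkage_block": list(linkage),
    }


def write_key_file(path: str | Path, plates: int, rows: int, cols: int,
                   with_gene_names: bool = True) -> None:
    """Write a synthetic array key file mapping positions to invented
    systematic ORF names (five tab-delimited columns)."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in range(1, plates + 1):
            for r in range(1, rows + 1):
                for c in range(1, cols + 1):
                    idx = (r - 1) * cols + c
                    orf = f"YS{p:02d}{idx:04d}W"
                    if with_gene_names:
                        fh.write(f"{p}\t{r}\t{c}\t{orf}\tGEN{p}{idx:04d}\n")
                    else:
                        fh.write(f"{p}\t{r}\t{c}\t{orf}\n")


def edge_boost_plate(
    rows: int = 32,
    cols: int = 48,
    corner_boost: float = DEFAULT_CORNER_BOOST,
    base_area: float = DEFAULT_BASE_AREA,
    noise_cv: float = 0.02,
    seed: int = 0,
) -> np.ndarray:
    """Uniform-strain plate areas with a planted edge growth advantage.

    The boost is separable per axis (square root of ``corner_boost`` on
    each outermost row and column), so corners carry the full boost and
    edges roughly its square root — emulating reduced competition at
    the array border.
    """
    rng = np.random.default_rng(seed)
    factors = _area_factors(rows, cols, corner_boost, None)
    areas = base_area * factors * _lognormal_factor(rng, noise_cv, (rows, cols))
    return np.round(areas).astype(np.int64)


def gradient_plate(
    rows: int = 32,
    cols: int = 48,
    row_ramp: tuple[float, float] = (1.0, 1.0),
    col_ramp: tuple[float, float] = (0.8, 1.2),
    base_area: float = DEFAULT_BASE_AREA,
    noise_cv: float = 0.02,
    seed: int = 0,
) -> np.ndarray:
    """Plate areas with a planted separable spatial gradient (e.g. from
    uneven media thickness): area(r,c) = base * ramp_r(r) * ramp_c(c)."""
    rng = np.random.default_rng(seed)
    factors = _area_factors(rows, cols, 1.0, (row_ramp, col_ramp))
    areas = base_area * factors * _lognormal_factor(rng, noise_cv, (rows, cols))
    return np.round(areas).astype(np.int64)


def competition_plate(
    rows: int = 32,
    cols: int = 48,
    n_gaps: int = 40,
    response_slope: float = 0.5,
    base_area: float = DEFAULT_BASE_AREA,
    noise_cv: float = 0.005,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Plate areas with a planted reduced-competition response.

    Random interior positions are emptied (area 0); the remaining
    colonies obey the linear competition law

        value = 1 + response_slope * (1 - mean of 8 neighbours)

    solved to a fixed point, so a colony next to several empty spots
    grows faster in proportion to its neighbourhood deficit.  Returns
    (areas, candidate_mask) where the mask marks colonies whose
    8-neighbour mean is below 75% of the plate median — the colonies
    the competition correction should rescale back to ~1.
    """
    rng = np.random.default_rng(seed)
    values = np.ones((rows, cols))
    empty = np.zeros((rows, cols), dtype=bool)
    interior = [(r, c) for r in range(2, rows - 2) for c in range(2, cols - 2)]
    chosen = rng.choice(len(interior), size=n_gaps, replace=False)
    for k in chosen:
        r, c = interior[k]
        empty[r, c] = True
        # empty a couple of that spot's neighbours too, deepening deficits
        for dr, dc in ((0, 1), (1, 0)):
            empty[r + dr, c + dc] = True
    values[empty] = 0.0
    for _ in range(60):  # fixed-point iteration of the competition law
        nbr = _neighbour_mean(values)
        new = 1.0 + response_slope * (1.0 - nbr)
        new[empty] = 0.0
        if np.allclose(new, values, atol=1e-12):
            break
        values = new
    noisy = values * _lognormal_factor(rng, noise_cv, (rows, cols))
    noisy[empty] = 0.0
    areas = np.round(base_area * noisy).astype(np.int64)
    nbr = _neighbour_mean(values)
    med = float(np.median(values[~empty]))
    candidates = (~empty) & (nbr < 0.75 * med)
    return areas, candidates


def _neighbour_mean(values: np.ndarray) -> np.ndarray:
    """Mean of the 8 surrounding positions, existing neighbours only."""
    padded = np.pad(values.astype(float), 1, constant_values=np.nan)
    stacks = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            stacks.append(padded[1 + dr:padded.shape[0] - 1 + dr,
                                 1 + dc:padded.shape[1] - 1 + dc])
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.stack(stacks), axis=0)
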