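"""Colony-size normalization: raw pixel areas to unitless fitness.

The first step divides every colony area by the plate median, so a
colony growing at the average rate for its plate scores ~1 regardless
of scanner, incubation time or media batch.  Three optional corrections
then target known systematic effects of arrayed growth:

* **Row/column** — colonies on the plate border grow faster because
  they compete with fewer neighbours.  Any row or column whose median
  exceeds 1 is divided by that median (rows first, then columns).
* **Spatial** — media thickness varies across a plate; per-row and
  per-column medians are LOESS-smoothed and their product used as a
  per-position correction field.
* **Competition** — a colony surrounded by slow growers has extra
  nutrients available.  Colonies whose 8-neighbour mean is below 75%
  of the plate median are rescaled using a plate-wide linear regression
  of colony size on neighbourhood mean, applied only when the
  regression is robust (R^2 > 0.1, slope in (-1, 0.1]).

Corrections are applied in the fixed order median -> row/column ->
spatial -> competition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from colonyarray.colony_quant import PlateMeasurement

__all__ = [
    "NormalizedPlate",
    "plate_median_normalize",
    "row_column_correct",
    "spatial_correct",
    "competition_correct",
    "normalize_plate",
    "neighbour_mean",
    "CORRECTIONS",
]

_EPS = 1e-6


@dataclass
class NormalizedPlate:
    """Per-position unitless colony sizes after normalization."""

    values: np.ndarray  # float array (rows, cols), >= 0
    corrections_applied: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")
        if np.any(self.values < 0):
            raise ValueError("normalized values must be non-negative")

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]


def _as_areas(plate) -> np.ndarray:
    if isinstance(plate, PlateMeasurement):
        return plate.areas.astype(float)
    return np.asarray(plate, dtype=float)


def _plate_median(values: np.ndarray, empty_fraction_cutoff: float = 0.10) -> float:
    """Plate median for normalization.

    Computed over all positions, unless more than 10% of positions are
    empty (zero), in which case only nonzero positions enter — arrays
    with many planted blanks would otherwise drag the median down.
    """
    flat = values.ravel()
    nonzero = flat[flat > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero plate: cannot normalize")
    if (flat.size - nonzero.size) / flat.size > empty_fraction_cutoff:
        return float(np.median(nonzero))
    return float(np.median(flat))


def plate_median_normalize(plate) -> NormalizedPlate:
    """Divide every colony area by the plate median colony size.

    Accepts a :class:`PlateMeasurement` or a 2-D array of areas.  After
    this step a colony growing near the plate-average rate has a value
    of ~1.
    """
    areas = _as_areas(plate)
    med = _plate_median(areas)
    return NormalizedPlate(values=areas / med, corrections_applied=())


def row_column_correct(np_plate: NormalizedPlate,
                       symmetric: bool = False) -> NormalizedPlate:
    """Correct border growth advantage via row/column medians.

    For each row, then each column: if the median value exceeds 1, the
    whole row (column) is divided by its median.  With ``symmetric``
    the division is applied for medians below 1 as well (the one-sided
    rule deliberately leaves slow rows alone, since the effect being
    corrected — reduced competition at the border — only inflates
    sizes).
    """
    vals = np_plate.values.copy()
    for r in range(vals.shape[0]):
        m = float(np.median(vals[r, :]))
        if m > 1 or (symmetric and 0 < m < 1):
            vals[r, :] /= m
    for c in range(vals.shape[1]):
        m = float(np.median(vals[:, c]))
        if m > 1 or (symmetric and 0 < m < 1):
            vals[:, c] /= m
    return NormalizedPlate(
        values=vals,
        corrections_applied=np_plate.corrections_applied + ("row_column",),
    )


def spatial_correct(np_plate: NormalizedPlate,
                    loess_span: float = 0.5) -> NormalizedPlate:
    """Correct smooth spatial trends (e.g. media-thickness gradients).

    Per-row and per-column medians, expressed relative to the plate
    median, are each smoothed along the plate axis with LOESS (locally
    weighted linear regression).  The correction factor at (r, c) is
    the product of the smoothed row and column profiles, floor-clamped
    at a small epsilon, and each value is divided by its factor.
    """
    if not (0 < loess_span <= 1):
        raise ValueError(f"loess_span must be in (0, 1], got {loess_span}")
    vals = np_plate.values
    rows, cols = vals.shape
    if rows < 4 or cols < 4:
        raise ValueError("spatial correction needs at least a 4x4 grid")
    plate_med = float(np.median(vals))
    if plate_med <= 0:
        plate_med = float(np.median(vals[vals > 0]))
    row_med = np.median(vals, axis=1) / plate_med
    col_med = np.median(vals, axis=0) / plate_med
    l_row = lowess(row_med, np.arange(rows), frac=loess_span, it=0,
                   return_sorted=False)
    l_col = lowess(col_med, np.arange(cols), frac=loess_span, it=0,
                   return_sorted=False)
    factor = np.outer(l_row, l_col)
    factor = np.maximum(factor, _EPS)
    return NormalizedPlate(
        values=vals / factor,
        corrections_applied=np_plate.corrections_applied + ("spatial",),
    )


def neighbour_mean(values: np.ndarray) -> np.ndarray:
    """Mean value of the 8 surrounding positions; border positions use
    their existing neighbours only."""
    values = np.asarray(values, dtype=float)
    ones = np.ones_like(values)
    ksum = np.zeros_like(values)
    kcnt = np.zeros_like(values)
    rows, cols = values.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            src_r = slice(max(0, -dr), rows - max(0, dr))
            src_c = slice(max(0, -dc), cols - max(0, dc))
            dst_r = slice(max(0, dr), rows - max(0, -dr))
            dst_c = slice(max(0, dc), cols - max(0, -dc))
            ksum[dst_r, dst_c] += values[src_r, src_c]
            kcnt[dst_r, dst_c] += ones[src_r, src_c]
    return ksum / kcnt


def competition_correct(
    np_plate: NormalizedPlate,
    neighbour_fraction: float = 0.75,
    min_r2: float = 0.1,
    slope_bounds: tuple[float, float] = (-1.0, 0.1),
) -> NormalizedPlate:
    """Correct reduced-competition growth advantage.

    Candidates are colonies whose 8-neighbour mean is below
    ``neighbour_fraction`` of the plate median.  Colony value is
    regressed linearly on neighbourhood mean over all nonzero
    positions; if the fit is robust (R^2 above ``min_r2`` and slope
    within ``slope_bounds`` — competition implies a negative slope),
    each candidate is rescaled by

        predicted(median neighbourhood) / predicted(own neighbourhood)

    where ``predicted`` is the fitted line, pulling colonies that grew
    fast only because their neighbours were small back toward the
    plate norm.  Otherwise the plate is returned unchanged (but marked
    as having had the correction considered).
    """
    vals = np_plate.values.copy()
    applied = np_plate.corrections_applied + ("competition",)
    occupied = vals > 0
    if occupied.sum() < 9:
        return replace(np_plate, corrections_applied=applied)
    med = float(np.median(vals[occupied]))
    nbr = neighbour_mean(vals)
    candidates = occupied & (nbr < neighbour_fraction * med)
    if not candidates.any():
        return replace(np_plate, corrections_applied=applied)

    x = nbr[occupied]
    y = vals[occupied]
    fit = stats.linregress(x, y)
    r2 = fit.rvalue ** 2
    lo, hi = slope_bounds
    if r2 <= min_r2 or not (lo < fit.slope <= hi):
        return replace(np_plate, corrections_applied=applied)

    med_nbr = float(np.median(x))
    pred_ref = fit.intercept + fit.slope * med_nbr
    pred = fit.intercept + fit.slope * nbr[candidates]
    ok = pred > _EPS
    scale = np.ones(pred.shape)
    scale[ok] = pred_ref / pred[ok]
    vals[candidates] = vals[candidates] * scale
    vals = np.maximum(vals, 0.0)
    return NormalizedPlate(values=vals, corrections_applied=applied)


#: Correction registry in the fixed application order.
CORRECTIONS = ("row_column", "spatial", "competition")


def normalize_plate(plate, corrections: tuple[str, ...] | list[str] = (),
                    loess_span: float = 0.5,
                    neighbour_fraction: float = 0.75,
                    min_r2: float = 0.1,
                    symmetric_row_column: bool = False) -> NormalizedPlate:
    """Apply plate-median normalization followed by the requested
    corrections, always in the fixed order row_column -> spatial ->
    competition."""
    unknown = set(corrections) - set(CORRECTIONS)
    if unknown:
        raise ValueError(f"unknown corrections: {sorted(unknown)}")
    out = plate_median_normalize(plate)
    if "row_column" in corrections:
        out = row_column_correct(out, symmetric=symmetric_row_column)
    if "spatial" in corrections:
        out = spatial_correct(out, loess_span=loess_span)
    if "competition" in corrections:
        out = competition_correct(out, neighbour_fraction=neighbour_fraction,
                                  min_r2=min_r2)
    return out
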