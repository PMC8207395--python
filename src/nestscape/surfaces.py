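"""Land-use surfaces: class-percentage moving windows, resistance
transformations, patch-configuration metrics, and small-study-area placement.

The resistance transformations map a class-percentage surface (PLAND, the
percent of a focal window occupied by one land-use class) into a resistance
surface on [1, M].  With ``x = PLAND/100`` the base curves are

* linear:          g(x) = x
* monomolecular:   g(x) = (1 - exp(-s*x)) / (1 - exp(-s))   (saturating)
* Ricker:          g(x) = x*exp(-s*x), rescaled so max over [0, 1] is 1
                   (unimodal, peak at x = min(1, 1/s))

with two modifiers: "reverse" replaces x by 1-x and "inverse" replaces g by
1-g.  Resistance is R = 1 + (M-1)*g.  The default shape s = 2 and maximum
resistance M = 100 match common practice for percent-cover predictors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .grids import Raster

__all__ = [
    "TransformSpec",
    "ResistanceSurface",
    "PatchMetrics",
    "TRANSFORM_FAMILIES",
    "WINDOW_SIDES",
    "transform_curve",
    "window_area_km2",
    "pland_moving_window",
    "transform_surface",
    "candidate_surfaces",
    "patch_metrics",
    "place_subregion",
]

#: The nine transformation families: the untransformed linear relationship
#: plus the eight monomolecular/Ricker variants.
TRANSFORM_FAMILIES: tuple[str, ...] = (
    "linear",
    "monomolecular",
    "reverse monomolecular",
    "inverse monomolecular",
    "inverse-reverse monomolecular",
    "ricker",
    "reverse ricker",
    "inverse ricker",
    "inverse-reverse ricker",
)

#: Moving-window side lengths (m) used for scale optimization.
WINDOW_SIDES: tuple[float, ...] = (100.0, 250.0, 500.0, 750.0, 1000.0)


@dataclass(frozen=True)
class TransformSpec:
    """A resistance transformation: family name, shape s, max resistance M."""

    family: str
    shape: float = 2.0
    rmax: float = 100.0

    def __post_init__(self) -> None:
        if self.family not in TRANSFORM_FAMILIES:
            raise ValueError(
                f"unknown transformation family {self.family!r}; "
                f"expected one of {TRANSFORM_FAMILIES}"
            )
        if not self.shape > 0:
            raise ValueError("shape must be positive")
        if not self.rmax > 1:
            raise ValueError("maximum resistance must exceed 1")


@dataclass
class ResistanceSurface:
    """A continuous resistance raster tagged with its provenance."""

    raster: Raster
    class_id: int
    window_side: float
    transform: TransformSpec

    @property
    def label(self) -> str:
        return f"class{self.class_id}|{self.window_side:g}m|{self.transform.family}"


@dataclass(frozen=True)
class PatchMetrics:
    """Patch configuration summary for one land-use class.

    patch_density
        Patches per 100 ha of total landscape area.
    cohesion
        Patch cohesion index, percent (0 when the class is absent).
    correlation_length
        Area-weighted mean radius of gyration, meters — the average distance
        an individual dropped at random in a patch could move before leaving
        it.
    """

    patch_density: float
    cohesion: float
    correlation_length: float
    n_patches: int


def transform_curve(x: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Evaluate the unit-interval curve g(x) of a transformation family."""
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("transformation input must lie in [0, 1]")
    family = spec.family
    if "reverse" in family.split(" ") or "inverse-reverse" in family:
        # "reverse" flips the input axis
        if family != "linear":
            x = 1.0 - x
    s = spec.shape
    if family == "linear":
        g = x
    elif "monomolecular" in family:
        g = (1.0 - np.exp(-s * x)) / (1.0 - np.exp(-s))
    else:  # ricker
        peak = min(1.0, 1.0 / s)
        gmax = peak * np.exp(-s * peak)
        g = x * np.exp(-s * x) / gmax
    if family.startswith("inverse"):
        g = 1.0 - g
    return g


def window_area_km2(window_side: float) -> float:
    """Area covered by a square moving window of the given side (m), in km²."""
    if window_side <= 0:
        raise ValueError("window side must be positive")
    return window_side**2 / 1e6


def _window_cells(window_side: float, cell_size: float) -> int:
    """Odd number of cells spanning a square window of the given side."""
    n = int(round(window_side / cell_size))
    n = max(n, 1)
    if n % 2 == 0:
        n += 1
    return n


def pland_moving_window(raster: Raster, class_id: int, window_side: float) -> Raster:
    """Percent of a square moving window occupied by one land-use class.

    Windows truncated at the raster edge are normalized by the number of
    in-bounds cells only, so values stay true percentages everywhere.
    """
    if window_side < raster.cell_size:
        raise ValueError(
            f"window side {window_side} m is smaller than the cell size "
            f"{raster.cell_size} m"
        )
    valid = raster.valid_mask()
    mask = (raster.values == class_id) & valid
    if not mask.any():
        warnings.warn(
            f"class {class_id} is absent from the raster; PLAND surface is all zero",
            stacklevel=2,
        )
    n = _window_cells(window_side, raster.cell_size)
    # uniform_filter with zero padding: ratio of the two box means equals the
    # ratio of in-window sums, which truncates windows at the edges.
    hits = ndimage.uniform_filter(mask.astype(float), size=n, mode="constant", cval=0.0)
    avail = ndimage.uniform_filter(valid.astype(float), size=n, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(avail > 0, 100.0 * hits / avail, np.nan)
    pct = np.clip(pct, 0.0, 100.0)
    return raster.like(pct)


def transform_surface(
    pland: Raster, spec: TransformSpec, class_id: int = -1, window_side: float = float("nan")
) -> ResistanceSurface:
    """Map a PLAND surface into a resistance surface on [1, rmax]."""
    vals = np.asarray(pland.values, dtype=float)
    finite = np.isfinite(vals)
    if np.any((vals[finite] < 0) | (vals[finite] > 100)):
        raise ValueError("PLAND values must lie in [0, 100]")
    g = np.full_like(vals, np.nan)
    g[finite] = transform_curve(vals[finite] / 100.0, spec)
    resistance = 1.0 + (spec.rmax - 1.0) * g
    return ResistanceSurface(pland.like(resistance), class_id, window_side, spec)


def candidate_surfaces(
    raster: Raster,
    class_id: int,
    window_sides: tuple[float, ...] = WINDOW_SIDES,
    shape: float = 2.0,
    rmax: float = 100.0,
) -> list[ResistanceSurface]:
    """All scale x transformation candidates for one class (5 x 9 = 45)."""
    out = []
    for side in window_sides:
        pland = pland_moving_window(raster, class_id, side)
        for family in TRANSFORM_FAMILIES:
            spec = TransformSpec(family, shape=shape, rmax=rmax)
            out.append(transform_surface(pland, spec, class_id=class_id, window_side=side))
    return out


def _patch_perimeters(labels: np.ndarray, n_patches: int) -> np.ndarray:
    """Perimeter of each patch in cell-edge units, counting border edges."""
    perim = np.zeros(n_patches + 1, dtype=float)
    padded = np.pad(labels, 1, constant_values=0)
    for axis in (0, 1):
        for shift in (1, -1):
            neighbor = np.roll(padded, shift, axis=axis)
            edge = (padded != 0) & (padded != neighbor)
            perim += np.bincount(padded[edge], minlength=n_patches + 1)
    return perim[1:]


def patch_metrics(
    raster: Raster, class_id: int, connectivity: str = "queen"
) -> PatchMetrics:
    """Patch density, cohesion, and correlation length for one class.

    ``connectivity`` chooses the neighbor rule for patch delineation:
    "queen" (8 neighbors, diagonal cells join a patch) or "rook" (4).
    Perimeters are always counted on the 4-neighbor cell-edge lattice.
    """
    if connectivity not in ("rook", "queen"):
        raise ValueError("connectivity must be 'rook' or 'queen'")
    mask = (raster.values == class_id) & raster.valid_mask()
    total_cells = int(raster.valid_mask().sum())
    cell = raster.cell_size
    total_area_ha = total_cells * cell * cell / 1e4
    if not mask.any():
        return PatchMetrics(0.0, 0.0, 0.0, 0)
    labels, n_patches = measure.label(
        mask, connectivity=2 if connectivity == "queen" else 1, return_num=True
    )
    areas = np.bincount(labels.ravel())[1:].astype(float)  # cells per patch
    perims = _patch_perimeters(labels, n_patches)

    patch_density = n_patches / total_area_ha * 100.0

    if total_cells > 1:
        cohesion = (
            (1.0 - perims.sum() / (perims * np.sqrt(areas)).sum())
            / (1.0 - 1.0 / np.sqrt(total_cells))
            * 100.0
        )
    else:
        cohesion = 0.0

    rows, cols = np.nonzero(labels)
    lab = labels[rows, cols]
    cy = np.bincount(lab, weights=rows)[1:] / areas
    cx = np.bincount(lab, weights=cols)[1:] / areas
    d = np.hypot(rows - cy[lab - 1], cols - cx[lab - 1]) * cell
    gyrate = np.bincount(lab, weights=d)[1:] / areas
    correlation_length = float((areas / areas.sum() * gyrate).sum())

    return PatchMetrics(
        patch_density=float(patch_density),
        cohesion=float(cohesion),
        correlation_length=correlation_length,
        n_patches=int(n_patches),
    )


def place_subregion(
    raster: Raster, side: float, stride: int = 1, tolerance: float = 6.3
) -> dict:
    """Find the square subregion whose class composition best matches the
    whole raster.

    Scans all candidate windows of the given side (in meters) at the given
    stride (in cells), scoring each by the largest absolute difference, over
    classes, between the window's class percentages and the full raster's.
    Returns the best offset, its per-class deltas, and whether the worst
    delta is within ``tolerance`` percentage points.
    """
    side_cells = int(round(side / raster.cell_size))
    if side_cells < 1 or side_cells > min(raster.n_rows, raster.n_cols):
        raise ValueError("subregion side must fit inside the raster")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    classes = np.unique(raster.values[raster.valid_mask()])
    full_pct = {
        int(c): 100.0 * np.mean(raster.values == c) for c in classes
    }
    # integral image per class for O(1) window sums
    cums = {
        int(c): np.pad((raster.values == c).astype(np.int64), ((1, 0), (1, 0))).cumsum(
            axis=0
        ).cumsum(axis=1)
        for c in classes
    }
    n_win = side_cells * side_cells
    best = None
    for r0 in range(0, raster.n_rows - side_cells + 1, stride):
        for c0 in range(0, raster.n_cols - side_cells + 1, stride):
            worst = 0.0
            deltas = {}
            for c, cum in cums.items():
                count = (
                    cum[r0 + side_cells, c0 + side_cells]
                    - cum[r0, c0 + side_cells]
                    - cum[r0 + side_cells, c0]
                    + cum[r0, c0]
                )
                delta = 100.0 * count / n_win - full_pct[c]
                deltas[c] = delta
                worst = max(worst, abs(delta))
            if best is None or worst < best["objective"]:
                best = {
                    "offset": (r0, c0),
                    "objective": worst,
                    "deltas": deltas,
                }
    assert best is not None
    best["within_tolerance"] = best["objective"] <= tolerance
    x0 = raster.xll + best["offset"][1] * raster.cell_size
    y1 = raster.yll + (raster.n_rows - best["offset"][0]) * raster.cell_size
    best["bounds"] = (x0, y1 - side_cells * raster.cell_size, x0 + side_cells * raster.cell_size, y1)
    return best
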