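"""Synthetic landscapes, nested sampling designs, genotypes, and pairwise
distances with known ground truth.

Every generator here is a stylized stand-in for field data, not a model of
salamander biology: the landscape is kernel-smoothed categorical noise, the
genotypes follow a spatial logistic-normal allele-frequency model rather
than any forward-time process, and pairwise genetic distances can be drawn
directly from the MLPE generative model

    y_pair = beta0 + beta * x_pair + u_i + u_j + eps_pair,

with one Gaussian random effect per individual (sd ``sigma_u``) and
independent pair noise (sd ``sigma_e``).  That known truth is what makes the
downstream optimization and model-ranking machinery testable end to end.
All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import Raster
from .surfaces import ResistanceSurface, TRANSFORM_FAMILIES, WINDOW_SIDES

__all__ = [
    "SimTruth",
    "SamplingDesign",
    "PackingInfeasibleError",
    "generate_landscape",
    "place_sampling_design",
    "simulate_pairwise_distances",
    "simulate_genotypes",
    "location_allele_frequencies",
]


class PackingInfeasibleError(RuntimeError):
    """Raised when a sampling design cannot satisfy its spacing constraint."""


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated study.

    beta is the landscape effect in response units per SD of the (residual,
    standardized) predictor; sigma_u and sigma_e are the individual
    random-effect and residual SDs of the MLPE generative model.
    """

    focal_class: int
    true_window_side: float
    true_transform: str
    beta: float
    sigma_u: float
    sigma_e: float
    seed: int
    beta0: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be > 0")
        if self.true_transform not in TRANSFORM_FAMILIES:
            raise ValueError(f"unknown transformation {self.true_transform!r}")
        if self.true_window_side not in WINDOW_SIDES:
            raise ValueError(
                f"window side {self.true_window_side} not in the configured set "
                f"{WINDOW_SIDES}"
            )


@dataclass
class SamplingDesign:
    """Sampling locations and the individuals collected at them.

    ``locations``: columns id, x, y (meters) and optional boolean scheme
    flags (e.g. ``large``); ``individuals``: columns id, location_id, x, y
    (individuals inherit their location's coordinates).
    """

    locations: pd.DataFrame
    individuals: pd.DataFrame
    extent: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    spacing_target: float

    def __post_init__(self) -> None:
        known = set(self.locations["id"])
        orphans = set(self.individuals["location_id"]) - known
        if orphans:
            raise ValueError(f"individuals reference unknown locations: {sorted(orphans)}")
        xmin, ymin, xmax, ymax = self.extent
        x, y = self.locations["x"], self.locations["y"]
        if ((x < xmin) | (x > xmax) | (y < ymin) | (y > ymax)).any():
            raise ValueError("all locations must lie inside the extent")

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    def location_coords(self) -> np.ndarray:
        return self.locations[["x", "y"]].to_numpy(float)

    def min_location_distance(self) -> float:
        from scipy.spatial.distance import pdist

        return float(pdist(self.location_coords()).min())


def generate_landscape(
    seed: int,
    n_rows: int,
    n_cols: int,
    cell_size: float,
    n_classes: int,
    smoothing: float,
) -> Raster:
    """Seeded patchy categorical landscape.

    Per class, independent white noise is smoothed with an isotropic
    Gaussian kernel of the given length scale (in cells) and each cell takes
    the argmax class.  Larger smoothing produces larger, fewer patches.
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("raster dimensions must be positive")
    if n_classes < 2:
        raise ValueError("need at least two land-use classes")
    if n_classes > 255:
        raise ValueError("at most 255 classes supported")
    if smoothing < 0:
        raise ValueError("smoothing length scale must be >= 0")
    rng = np.random.default_rng(seed)
    fields = rng.standard_normal((n_classes, n_rows, n_cols))
    if smoothing > 0:
        fields = np.stack(
            [ndimage.gaussian_filter(f, sigma=smoothing, mode="reflect") for f in fields]
        )
    classes = np.argmax(fields, axis=0).astype(np.uint8)
    return Raster(classes, cell_size=cell_size)


def place_sampling_design(
    extent: tuple[float, float, float, float],
    n_locations: int,
    min_spacing: float,
    n_per_location: int,
    seed: int,
    attempt_budget: int = 10_000,
    id_prefix: str = "L",
) -> SamplingDesign:
    """Rejection-sample locations with a minimum pairwise spacing.

    Uniform draws over the extent are accepted when at least ``min_spacing``
    from every accepted location; a fixed attempt budget turns infeasible
    packings into an explicit error instead of a silent violation.
    """
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate extent")
    rng = np.random.default_rng(seed)
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < n_locations:
        if attempts >= attempt_budget:
            raise PackingInfeasibleError(
                f"placed only {len(pts)}/{n_locations} locations with spacing "
                f">= {min_spacing} m in extent {extent} after {attempt_budget} draws"
            )
        attempts += 1
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_spacing**2 for px, py in pts):
            pts.append((x, y))
    locations = pd.DataFrame(
        {
            "id": [f"{id_prefix}{k:02d}" for k in range(n_locations)],
            "x": [p[0] for p in pts],
            "y": [p[1] for p in pts],
        }
    )
    individuals = pd.DataFrame(
        {
            "id": [
                f"{loc}-{k}" for loc in locations["id"] for k in range(n_per_location)
            ],
            "location_id": np.repeat(locations["id"].to_numpy(), n_per_location),
            "x": np.repeat(locations["x"].to_numpy(), n_per_location),
            "y": np.repeat(locations["y"].to_numpy(), n_per_location),
        }
    )
    return SamplingDesign(locations, individuals, extent, min_spacing)


def simulate_pairwise_distances(
    pairs: pd.DataFrame, x, truth: SimTruth, n_individuals: int
) -> np.ndarray:
    """Draw a pairwise-distance matrix from the MLPE generative model.

    ``pairs`` carries ``i_index``/``j_index`` over ``n_individuals``
    individuals; ``x`` is the (standardized) predictor per pair.  Returns a
    symmetric matrix with zero diagonal; entries for pairs not listed stay 0.
    """
    x = np.asarray(x, dtype=float)
    if len(x) != len(pairs):
        raise ValueError("predictor length does not match the pair table")
    rng = np.random.default_rng(truth.seed)
    u = rng.normal(0.0, truth.sigma_u, size=n_individuals)
    eps = rng.normal(0.0, truth.sigma_e, size=len(pairs))
    ii = pairs["i_index"].to_numpy()
    jj = pairs["j_index"].to_numpy()
    if ii.max(initial=-1) >= n_individuals or jj.max(initial=-1) >= n_individuals:
        raise ValueError("pair indices exceed the declared number of individuals")
    y = truth.beta0 + truth.beta * x + u[ii] + u[jj] + eps
    mat = np.zeros((n_individuals, n_individuals))
    mat[ii, jj] = y
    mat[jj, ii] = y
    np.fill_diagonal(mat, 0.0)
    return mat


def simulate_genotypes(
    design: SamplingDesign,
    surface: ResistanceSurface | Raster,
    n_loci: int = 8,
    alleles_per_locus: int = 10,
    drift_scale: float = 1.0,
    seed: int = 0,
    neighborhood: int = 8,
):
    """Genotypes whose spatial structure follows a resistance surface.

    Location-level allele frequencies are logistic-normal: per locus and
    allele, a Gaussian field over locations with covariance
    ``drift_scale^2 * exp(-D / L)`` is added to shared log-weights, where D
    is the commute-time distance between locations on ``surface`` and L its
    mean off-diagonal value.  ``drift_scale = 0`` gives identical
    frequencies everywhere (no spatial signal).  Individuals are
    Hardy-Weinberg draws from their location's frequencies.  A stylized
    drift model, not a forward-time simulation.
    """
    from .genotypes import GenotypeTable
    from .resistance import build_graph, commute_distance

    if alleles_per_locus < 2:
        raise ValueError("need at least two alleles per locus")
    graph = build_graph(surface, neighborhood=neighborhood)
    D = commute_distance(graph, design.location_coords())
    off = D[np.triu_indices_from(D, k=1)]
    L = float(off.mean()) if off.size and off.mean() > 0 else 1.0
    K = np.exp(-D / L)
    # nugget for numerical positive definiteness
    chol = np.linalg.cholesky(K + 1e-10 * np.eye(len(K)))

    rng = np.random.default_rng(seed)
    n_loc = design.n_locations
    loc_index = {loc: k for k, loc in enumerate(design.locations["id"])}
    data = {
        "id": design.individuals["id"],
        "location_id": design.individuals["location_id"],
        "x": design.individuals["x"],
        "y": design.individuals["y"],
    }
    ind_loc = design.individuals["location_id"].map(loc_index).to_numpy()
    for locus in range(n_loci):
        base = rng.normal(0.0, 1.0, size=alleles_per_locus)
        eta = drift_scale * (chol @ rng.standard_normal((n_loc, alleles_per_locus)))
        logits = base[None, :] + eta
        w = np.exp(logits - logits.max(axis=1, keepdims=True))
        freqs = w / w.sum(axis=1, keepdims=True)  # locations x alleles
        draws = np.empty((len(ind_loc), 2), dtype=np.int64)
        for k, li in enumerate(ind_loc):
            draws[k] = rng.choice(alleles_per_locus, size=2, p=freqs[li])
        # allele ids offset to look like fragment sizes
        name = f"loc{locus + 1}"
        data[f"{name}_1"] = pd.array(100 + 2 * draws[:, 0], dtype="Int64")
        data[f"{name}_2"] = pd.array(100 + 2 * draws[:, 1], dtype="Int64")
    return GenotypeTable(pd.DataFrame(data))


def location_allele_frequencies(
    design: SamplingDesign, table, locus: str
) -> pd.DataFrame:
    """Observed allele frequencies per location for one locus (sums to 1)."""
    a, b = table.alleles(locus)
    df = pd.DataFrame(
        {
            "location_id": pd.concat(
                [table.data["location_id"], table.data["location_id"]]
            ),
            "allele": pd.concat([a, b]),
        }
    ).dropna()
    counts = df.groupby(["location_id", "allele"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)
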