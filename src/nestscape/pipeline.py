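"""End-to-end synthetic experiments: simulate a study with known truth, run
the optimization/ranking machinery, and score recovery.

The experiments here run a deliberately scaled-down study so a full
multi-replicate run stays interactive: an 80 x 80 cell landscape with 50 m
cells (a 4 x 4 km study area), ten sampling locations at >= 500 m spacing
with four individuals each, and the standard window set {100..1000} m.
Effect sizes default to the "strong truth" regime (|beta| large against
sigma_u, sigma_e) under which scale/transformation recovery is expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grids import Raster
from .mlpe import MLPEFit, enumerate_pairs, fit_mlpe, optimize_surface, rank_model_set
from .nested import SCHEME_NAMES, build_scheme_datasets
from .resistance import build_graph, commute_distance, homogeneous_distance, residualize
from .surfaces import candidate_surfaces, place_subregion
from .synthetic import (
    SamplingDesign,
    SimTruth,
    generate_landscape,
    place_sampling_design,
    simulate_pairwise_distances,
)

__all__ = [
    "StudyConfig",
    "simulate_study",
    "pair_predictor",
    "recovery_replicate",
    "recovery_experiment",
    "model_ranking_replicate",
    "model_ranking_experiment",
    "sign_congruence_experiment",
]


@dataclass(frozen=True)
class StudyConfig:
    """Scaled-down synthetic study conditions."""

    n_rows: int = 80
    n_cols: int = 80
    cell_size: float = 50.0
    n_classes: int = 5
    smoothing: float = 6.0
    n_locations: int = 10
    min_spacing: float = 500.0
    n_per_location: int = 4
    focal_class: int = 0
    true_window_side: float = 500.0
    true_transform: str = "monomolecular"
    beta: float = 1.0
    sigma_u: float = 0.2
    sigma_e: float = 0.3
    neighborhood: int = 8


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("constant predictor column")
    return (v - v.mean()) / sd


def pair_predictor(
    graph_or_surface, design: SamplingDesign, pairs: pd.DataFrame, neighborhood: int = 8
) -> np.ndarray:
    """Per-pair commute distance read off a location-level commute matrix."""
    graph = (
        graph_or_surface
        if hasattr(graph_or_surface, "laplacian")
        else build_graph(graph_or_surface, neighborhood=neighborhood)
    )
    C = commute_distance(graph, design.location_coords())
    loc_index = {loc: k for k, loc in enumerate(design.locations["id"])}
    li = pairs["location_i"].map(loc_index).to_numpy()
    lj = pairs["location_j"].map(loc_index).to_numpy()
    return C[li, lj]


def simulate_study(seed: int, config: StudyConfig = StudyConfig()):
    """Landscape + sampling design + included pair table for one replicate."""
    ss = np.random.SeedSequence(seed)
    s_land, s_design, s_truth = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    landscape = generate_landscape(
        s_land,
        config.n_rows,
        config.n_cols,
        config.cell_size,
        config.n_classes,
        config.smoothing,
    )
    design = place_sampling_design(
        landscape.extent,
        config.n_locations,
        config.min_spacing,
        config.n_per_location,
        s_design,
    )
    pairs = enumerate_pairs(design.individuals)
    included = pairs[pairs["included"]].reset_index(drop=True)
    truth = SimTruth(
        focal_class=config.focal_class,
        true_window_side=config.true_window_side,
        true_transform=config.true_transform,
        beta=config.beta,
        sigma_u=config.sigma_u,
        sigma_e=config.sigma_e,
        seed=s_truth,
    )
    return landscape, design, included, truth


def _residual_candidates(
    landscape: Raster,
    design: SamplingDesign,
    pairs: pd.DataFrame,
    class_id: int,
    neighborhood: int = 8,
):
    """Residualized, standardized commute predictors for all 45 candidates."""
    gd_raw = pair_predictor(
        landscape.like(np.ones(landscape.values.shape)), design, pairs, neighborhood
    )
    surfaces = candidate_surfaces(landscape, class_id)
    cols, window_of, transform_of = {}, {}, {}
    for surf in surfaces:
        raw = pair_predictor(surf, design, pairs, neighborhood)
        cols[surf.label] = _zscore(residualize(raw, gd_raw))
        window_of[surf.label] = surf.window_side
        transform_of[surf.label] = surf.transform.family
    return pd.DataFrame(cols), _zscore(gd_raw), window_of, transform_of, surfaces


def recovery_replicate(seed: int, config: StudyConfig = StudyConfig()) -> dict:
    """One scale/transformation recovery replicate.

    Simulates the response from the true candidate's residualized predictor
    and checks whether the 45-candidate AICc optimization picks the true
    (window, transformation) and the right sign of effect.
    """
    landscape, design, pairs, truth = simulate_study(seed, config)
    cands, gd, window_of, transform_of, _ = _residual_candidates(
        landscape, design, pairs, config.focal_class, config.neighborhood
    )
    true_label = next(
        lab
        for lab in cands.columns
        if window_of[lab] == truth.true_window_side
        and transform_of[lab] == truth.true_transform
    )
    x_true = cands[true_label].to_numpy()
    y_mat = simulate_pairwise_distances(pairs, x_true, truth, len(design.individuals))
    y = y_mat[pairs["i_index"], pairs["j_index"]]
    window, transform, fit, board = optimize_surface(
        y, cands, gd, pairs, window_of, transform_of
    )
    winner_label = board.iloc[0]["label"]
    coef = fit.coefficients[winner_label]
    return {
        "selected_window": window,
        "selected_transform": transform,
        "correct_pair": (window == truth.true_window_side)
        and (transform == truth.true_transform),
        "correct_sign": np.sign(coef) == np.sign(truth.beta),
        "coefficient": coef,
        "leaderboard": board,
    }


def recovery_experiment(
    seed: int, n_replicates: int = 20, config: StudyConfig = StudyConfig()
) -> dict:
    """Fraction of replicates recovering the true (window, transform) and sign."""
    seeds = [
        int(c.generate_state(1)[0] % 2**31)
        for c in np.random.SeedSequence(seed).spawn(n_replicates)
    ]
    results = [recovery_replicate(s, config) for s in seeds]
    return {
        "n_replicates": n_replicates,
        "pair_recovery_rate": float(np.mean([r["correct_pair"] for r in results])),
        "sign_recovery_rate": float(np.mean([r["correct_sign"] for r in results])),
        "replicates": results,
    }


_CLASS_KEYS = ("A", "H", "P", "M", "W")
#: Generative effects (per-SD) used when all five classes act at once.
_FULL_BETAS = {"A": 0.9, "H": 0.7, "P": -0.6, "M": -0.5, "W": 0.8}


def model_ranking_replicate(
    seed: int, config: StudyConfig = StudyConfig(), betas: dict[str, float] | None = None
) -> dict:
    """Simulate all five class effects active and rank the ten-model set."""
    if betas is None:
        betas = _FULL_BETAS
    landscape, design, pairs, truth = simulate_study(seed, config)
    gd_raw = pair_predictor(
        landscape.like(np.ones(landscape.values.shape)), design, pairs, config.neighborhood
    )
    gd = _zscore(gd_raw)
    from .surfaces import TransformSpec, pland_moving_window, transform_surface

    predictors: dict[str, np.ndarray] = {}
    for class_id, key in enumerate(_CLASS_KEYS):
        pland = pland_moving_window(landscape, class_id, config.true_window_side)
        surf = transform_surface(
            pland,
            TransformSpec(config.true_transform),
            class_id=class_id,
            window_side=config.true_window_side,
        )
        raw = pair_predictor(surf, design, pairs, config.neighborhood)
        predictors[key] = _zscore(residualize(raw, gd_raw))
    effect = sum(betas[k] * predictors[k] for k in _CLASS_KEYS)
    truth = replace(truth, beta=1.0)
    y_mat = simulate_pairwise_distances(pairs, effect, truth, len(design.individuals))
    y = y_mat[pairs["i_index"], pairs["j_index"]]
    board, fits = rank_model_set(y, predictors, gd, pairs)
    return {"leaderboard": board, "top_model": board.iloc[0]["model"], "fits": fits}


def model_ranking_experiment(
    seed: int, n_replicates: int = 20, config: StudyConfig = StudyConfig()
) -> dict:
    """How often the full model wins AICc when every class effect is active."""
    seeds = [
        int(c.generate_state(1)[0] % 2**31)
        for c in np.random.SeedSequence(seed).spawn(n_replicates)
    ]
    tops = [model_ranking_replicate(s, config)["top_model"] for s in seeds]
    return {
        "n_replicates": n_replicates,
        "full_model_first_rate": float(np.mean([t == "Full model" for t in tops])),
        "top_models": tops,
    }


def mantel_null_calibration(
    seed: int,
    n_replicates: int = 100,
    n_individuals: int = 25,
    n_classes: int = 30,
    n_perm: int = 199,
    alpha: float = 0.05,
) -> dict:
    """Type-I error calibration of the Mantel correlogram.

    Genetic distances drawn independently of geography: the fraction of
    distance classes flagged significant at alpha (raw permutation p) should
    sit near alpha.
    """
    from scipy.spatial.distance import pdist, squareform

    from .spatial import mantel_correlogram

    rng = np.random.default_rng(seed)
    total = significant = 0
    for rep in range(n_replicates):
        xy = rng.uniform(0, 10_000, size=(n_individuals, 2))
        geo = squareform(pdist(xy))
        gd = squareform(rng.uniform(0.5, 2.0, size=n_individuals * (n_individuals - 1) // 2))
        cor = mantel_correlogram(
            gd, geo, n_classes=n_classes, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        occupied = cor[cor["n_pairs"] > 0]
        total += len(occupied)
        significant += int((occupied["p_raw"] <= alpha).sum())
    return {
        "n_replicates": n_replicates,
        "n_classes_tested": total,
        "significant_fraction": significant / total,
    }


@dataclass(frozen=True)
class NestedConfig:
    """Scaled-down nested-design conditions for the congruence experiment."""

    n_rows: int = 120
    n_cols: int = 120
    cell_size: float = 50.0
    n_classes: int = 5
    smoothing: float = 6.0
    n_large: int = 12
    large_spacing: float = 1200.0
    small_side: float = 3000.0
    n_small: int = 10
    small_spacing: float = 500.0
    n_per_location: int = 3
    focal_class: int = 0
    true_window_side: float = 500.0
    true_transform: str = "monomolecular"
    beta: float = 1.0
    sigma_u: float = 0.2
    sigma_e: float = 0.3


def nested_design(seed: int, config: NestedConfig = NestedConfig()):
    """A nested sampling design over one synthetic landscape.

    Sparse locations cover the full extent; the small study area is placed
    where its class composition best matches the whole landscape; dense
    locations fill the small area, reusing any sparse locations inside it.
    """
    ss = np.random.SeedSequence(seed)
    s_land, s_large, s_small = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    landscape = generate_landscape(
        s_land, config.n_rows, config.n_cols, config.cell_size, config.n_classes, config.smoothing
    )
    large = place_sampling_design(
        landscape.extent,
        config.n_large,
        config.large_spacing,
        config.n_per_location,
        s_large,
        id_prefix="S",
    )
    placement = place_subregion(landscape, config.small_side, stride=4)
    bounds = placement["bounds"]
    locs = large.locations.copy()
    locs["large"] = True
    inside = (
        (locs["x"] >= bounds[0])
        & (locs["x"] <= bounds[2])
        & (locs["y"] >= bounds[1])
        & (locs["y"] <= bounds[3])
    )
    pts = list(zip(locs.loc[inside, "x"], locs.loc[inside, "y"]))
    rng = np.random.default_rng(s_small)
    attempts = 0
    new_pts: list[tuple[float, float]] = []
    while len(pts) + len(new_pts) < config.n_small:
        if attempts >= 10_000:
            from .synthetic import PackingInfeasibleError

            raise PackingInfeasibleError(
                f"could not place {config.n_small} dense locations with spacing "
                f">= {config.small_spacing} m inside {bounds}"
            )
        attempts += 1
        x = rng.uniform(bounds[0], bounds[2])
        y = rng.uniform(bounds[1], bounds[3])
        if all(
            (x - px) ** 2 + (y - py) ** 2 >= config.small_spacing**2
            for px, py in pts + new_pts
        ):
            new_pts.append((x, y))
    add = pd.DataFrame(
        {
            "id": [f"D{k:02d}" for k in range(len(new_pts))],
            "x": [p[0] for p in new_pts],
            "y": [p[1] for p in new_pts],
            "large": False,
        }
    )
    locations = pd.concat([locs, add], ignore_index=True)
    individuals = pd.DataFrame(
        {
            "id": [
                f"{loc}-{k}"
                for loc in locations["id"]
                for k in range(config.n_per_location)
            ],
            "location_id": np.repeat(locations["id"].to_numpy(), config.n_per_location),
            "x": np.repeat(locations["x"].to_numpy(), config.n_per_location),
            "y": np.repeat(locations["y"].to_numpy(), config.n_per_location),
        }
    )
    design = SamplingDesign(locations, individuals, landscape.extent, config.large_spacing)
    return landscape, design, bounds


def _crop(landscape: Raster, bounds) -> Raster:
    xmin, ymin, xmax, ymax = bounds
    c0 = int(round((xmin - landscape.xll) / landscape.cell_size))
    c1 = int(round((xmax - landscape.xll) / landscape.cell_size))
    r1 = landscape.n_rows - int(round((ymin - landscape.yll) / landscape.cell_size))
    r0 = landscape.n_rows - int(round((ymax - landscape.yll) / landscape.cell_size))
    return Raster(
        landscape.values[r0:r1, c0:c1],
        landscape.cell_size,
        xll=landscape.xll + c0 * landscape.cell_size,
        yll=landscape.yll + (landscape.n_rows - r1) * landscape.cell_size,
        nodata=landscape.nodata,
    )


def sign_congruence_experiment(
    seed: int, n_replicates: int = 10, config: NestedConfig = NestedConfig()
) -> dict:
    """End-to-end nested-scheme property: a strong scheme-independent effect
    should give outcome A (all three schemes agree) for sign of the focal
    class in the majority of replicates.

    Each scheme's predictor is computed on its own study-area raster (the
    small schemes on the cropped landscape), mirroring how a real analysis
    would treat the nested datasets; the response is simulated once over all
    individuals from the full-landscape predictor.
    """
    from .nested import classify_congruence
    from .surfaces import TransformSpec, pland_moving_window, transform_surface

    seeds = [
        int(c.generate_state(1)[0] % 2**31)
        for c in np.random.SeedSequence(seed).spawn(n_replicates)
    ]
    outcomes = []
    for s in seeds:
        landscape, design, bounds = nested_design(s, config)
        schemes = build_scheme_datasets(design, bounds, sparse_threshold=config.large_spacing)
        truth = SimTruth(
            focal_class=config.focal_class,
            true_window_side=config.true_window_side,
            true_transform=config.true_transform,
            beta=config.beta,
            sigma_u=config.sigma_u,
            sigma_e=config.sigma_e,
            seed=s,
        )

        def scheme_predictor(individuals, pairs, raster, spacing):
            sub = SamplingDesign(
                design.locations[
                    design.locations["id"].isin(individuals["location_id"])
                ].reset_index(drop=True),
                individuals,
                raster.extent,
                spacing,
            )
            pland = pland_moving_window(raster, config.focal_class, config.true_window_side)
            surf = transform_surface(pland, TransformSpec(config.true_transform))
            raw = pair_predictor(surf, sub, pairs)
            gd_raw = pair_predictor(
                raster.like(np.ones(raster.values.shape)), sub, pairs
            )
            return _zscore(residualize(raw, gd_raw)), _zscore(gd_raw)

        # one response over all individuals, from the full-landscape predictor
        all_pairs = enumerate_pairs(design.individuals)
        included = all_pairs[all_pairs["included"]].reset_index(drop=True)
        x_full, _ = scheme_predictor(
            design.individuals, included, landscape, config.large_spacing
        )
        y_mat = simulate_pairwise_distances(included, x_full, truth, len(design.individuals))
        id_index = {iid: k for k, iid in enumerate(design.individuals["id"])}

        signs = {}
        small = _crop(landscape, bounds)
        for name, raster in (
            ("Sparse-Large", landscape),
            ("Dense-Small", small),
            ("Sparse-Small", small),
        ):
            scheme = schemes[name]
            x, gd = scheme_predictor(scheme.individuals, scheme.pairs, raster, scheme.spacing)
            gi = scheme.pairs["i"].map(id_index).to_numpy()
            gj = scheme.pairs["j"].map(id_index).to_numpy()
            y = y_mat[gi, gj]
            fit = fit_mlpe(y, pd.DataFrame({"GD": gd, "focal": x}), scheme.pairs)
            signs[name] = "+" if fit.coefficients["focal"] > 0 else "-"
        outcomes.append(classify_congruence(tuple(signs[n] for n in SCHEME_NAMES)))
    return {
        "n_replicates": n_replicates,
        "outcome_a_rate": float(np.mean([o == "A" for o in outcomes])),
        "outcomes": outcomes,
    }
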