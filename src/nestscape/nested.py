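"""Nested sampling-scheme datasets and congruence classification.

Three datasets are carved from one study: Sparse-Large (widely spaced
locations over the full extent), Dense-Small (all locations inside a nested
small study area), and Sparse-Small (the Dense-Small pairs whose geographic
separation exceeds the sparse spacing threshold).  Comparing a best-fit
model attribute across the three yields one of five outcome codes:

    A  all three agree            -> insensitive to density and area size
    B  Sparse-Large = Sparse-Small -> sampling density drives outcomes
    C  Dense-Small = Sparse-Small  -> study area size drives outcomes
    D  Sparse-Large = Dense-Small  -> total sampling effort (threshold)
    E  all three differ            -> combined effects

For a binary attribute such as sign of effect, E cannot occur and is
reported as NA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mlpe import enumerate_pairs
from .synthetic import SamplingDesign

__all__ = [
    "SchemeDataset",
    "SCHEME_NAMES",
    "build_scheme_datasets",
    "classify_congruence",
    "comparison_report",
]

SCHEME_NAMES = ("Sparse-Large", "Dense-Small", "Sparse-Small")

CRITERIA = ("rank", "sign", "scale", "transformation")


@dataclass
class SchemeDataset:
    """One nested dataset: its individuals and included model pairs."""

    name: str
    individuals: pd.DataFrame
    pairs: pd.DataFrame  # included (between-location) pairs only
    bounds: tuple[float, float, float, float]
    spacing: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_keys(self) -> set[tuple[str, str]]:
        return set(zip(self.pairs["i"], self.pairs["j"]))


def _inside(df: pd.DataFrame, bounds) -> pd.Series:
    xmin, ymin, xmax, ymax = bounds
    return (df["x"] >= xmin) & (df["x"] <= xmax) & (df["y"] >= ymin) & (df["y"] <= ymax)


def build_scheme_datasets(
    design: SamplingDesign,
    small_bounds: tuple[float, float, float, float],
    sparse_threshold: float = 7000.0,
) -> dict[str, SchemeDataset]:
    """Split one nested design into the three scheme datasets.

    Locations flagged ``large`` in ``design.locations`` form the
    Sparse-Large scheme (all of them, over the full extent); every location
    inside ``small_bounds`` joins Dense-Small; Sparse-Small keeps the
    Dense-Small pairs separated by more than ``sparse_threshold`` meters.
    Within-location pairs are excluded from every scheme.
    """
    locs = design.locations
    if "large" in locs.columns:
        large_ids = set(locs.loc[locs["large"].astype(bool), "id"])
    else:
        large_ids = set(locs["id"])
    small_ids = set(locs.loc[_inside(locs, small_bounds), "id"])
    if not small_ids & large_ids:
        raise ValueError("no sampling locations shared between the two study areas")

    def subset(ids: set[str]) -> pd.DataFrame:
        return (
            design.individuals[design.individuals["location_id"].isin(ids)]
            .reset_index(drop=True)
            .copy()
        )

    out: dict[str, SchemeDataset] = {}
    ind_sl = subset(large_ids)
    pairs_sl = enumerate_pairs(ind_sl)
    out["Sparse-Large"] = SchemeDataset(
        "Sparse-Large",
        ind_sl,
        pairs_sl[pairs_sl["included"]].reset_index(drop=True),
        design.extent,
        design.spacing_target,
    )
    ind_ds = subset(small_ids)
    pairs_ds = enumerate_pairs(ind_ds)
    included_ds = pairs_ds[pairs_ds["included"]].reset_index(drop=True)
    out["Dense-Small"] = SchemeDataset(
        "Dense-Small", ind_ds, included_ds, small_bounds, design.spacing_target
    )
    far = included_ds[included_ds["geographic_distance"] > sparse_threshold]
    if far.empty:
        raise ValueError(
            f"no Dense-Small pairs exceed the sparse threshold {sparse_threshold} m; "
            "the Sparse-Small dataset would be empty"
        )
    out["Sparse-Small"] = SchemeDataset(
        "Sparse-Small",
        ind_ds,
        far.reset_index(drop=True),
        small_bounds,
        sparse_threshold,
    )
    return out


def classify_congruence(values) -> str:
    """Outcome code A-E for one attribute observed under the three schemes.

    ``values`` is the (Sparse-Large, Dense-Small, Sparse-Small) triple of a
    shared categorical domain.
    """
    values = tuple(values)
    if len(values) != 3:
        raise ValueError("need exactly three values (Sparse-Large, Dense-Small, Sparse-Small)")
    sl, ds, ss = values
    if sl == ds == ss:
        return "A"
    if sl == ss and sl != ds:
        return "B"
    if ds == ss and ds != sl:
        return "C"
    if sl == ds and sl != ss:
        return "D"
    return "E"


def comparison_report(scheme_values: dict[str, dict[str, dict[str, object]]]) -> pd.DataFrame:
    """Outcome codes per land-use class x criterion across the three schemes.

    ``scheme_values[scheme][cls]`` maps criterion name (rank, sign, scale,
    transformation) to its categorical value in that scheme's best-fit
    model.  The sign criterion is binary, so an all-distinct triple is
    reported NA rather than E.
    """
    missing = [s for s in SCHEME_NAMES if s not in scheme_values]
    if missing:
        raise ValueError(f"missing schemes: {missing}")
    classes = set(scheme_values[SCHEME_NAMES[0]])
    for s in SCHEME_NAMES[1:]:
        if set(scheme_values[s]) != classes:
            raise ValueError("schemes report different land-use classes")
    rows = []
    for cls in sorted(classes):
        for crit in CRITERIA:
            triple = tuple(scheme_values[s][cls][crit] for s in SCHEME_NAMES)
            code = classify_congruence(triple)
            if crit == "sign" and code == "E":
                code = "NA"
            rows.append(
                {
                    "class": cls,
                    "criterion": crit,
                    "sparse_large": triple[0],
                    "dense_small": triple[1],
                    "sparse_small": triple[2],
                    "outcome": code,
                }
            )
    return pd.DataFrame(rows)
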