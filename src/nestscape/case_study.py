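"""Published best-fit summaries from the motivating field study.

The package's design follows a nested landscape-genetics field study of the
Mississippi slimy salamander (*Plethodon mississippi*) in Holly Springs
National Forest, Mississippi: 183 individuals at 8 microsatellite loci,
three nested datasets (Sparse-Large: 103 individuals, 5,253 pairwise
comparisons; Dense-Small: 89 individuals, 3,916 comparisons; Sparse-Small:
the 2,375 Dense-Small comparisons beyond 7 km), and five land-use classes.

This module transcribes the *categorical* attributes of that study's
published best-fit models — rank of effect, sign, optimized window side, and
optimized transformation per land-use class and scheme.  They serve as
reference inputs for the congruence classifier; the underlying genotypes
and rasters are not bundled (the study's raw data live in an external
repository and are never required here).
"""

from __future__ import annotations

__all__ = ["PUBLISHED_BEST_FITS", "PUBLISHED_PAIR_COUNTS", "LAND_USE_CLASSES"]

LAND_USE_CLASSES = ("Agriculture", "Hardwoods", "Manmade structures", "Pine", "Wetlands")

#: Individuals and included pairwise comparisons per scheme.
PUBLISHED_PAIR_COUNTS = {
    "Sparse-Large": {"individuals": 103, "pairs": 5253},
    "Dense-Small": {"individuals": 89, "pairs": 3916},
    "Sparse-Small": {"individuals": 89, "pairs": 2375},
}

#: Best-fit model attributes per scheme and land-use class: rank of |effect|,
#: sign (+ restriction / - facilitation), optimized window side (m), and
#: optimized transformation family.
PUBLISHED_BEST_FITS: dict[str, dict[str, dict[str, object]]] = {
    "Sparse-Large": {
        "Agriculture": {
            "rank": 2, "sign": "+", "scale": 500, "transformation": "inverse-reverse ricker",
        },
        "Hardwoods": {
            "rank": 3, "sign": "+", "scale": 500, "transformation": "inverse ricker",
        },
        "Manmade structures": {
            "rank": 4, "sign": "-", "scale": 250, "transformation": "inverse ricker",
        },
        "Pine": {
            "rank": 5, "sign": "-", "scale": 750, "transformation": "inverse-reverse ricker",
        },
        "Wetlands": {
            "rank": 1, "sign": "+", "scale": 1000, "transformation": "inverse ricker",
        },
    },
    "Dense-Small": {
        "Agriculture": {
            "rank": 4, "sign": "+", "scale": 500, "transformation": "inverse ricker",
        },
        "Hardwoods": {
            "rank": 5, "sign": "+", "scale": 100, "transformation": "reverse monomolecular",
        },
        "Manmade structures": {
            "rank": 3, "sign": "-", "scale": 500, "transformation": "inverse ricker",
        },
        "Pine": {
            "rank": 2, "sign": "+", "scale": 250, "transformation": "inverse ricker",
        },
        "Wetlands": {
            "rank": 1, "sign": "+", "scale": 1000, "transformation": "inverse ricker",
        },
    },
    "Sparse-Small": {
        "Agriculture": {
            "rank": 5, "sign": "-", "scale": 1000, "transformation": "inverse-reverse ricker",
        },
        "Hardwoods": {
            "rank": 4, "sign": "+", "scale": 750, "transformation": "inverse-reverse ricker",
        },
        "Manmade structures": {
            "rank": 2, "sign": "-", "scale": 500, "transformation": "linear",
        },
        "Pine": {
            "rank": 1, "sign": "+", "scale": 1000, "transformation": "monomolecular",
        },
        "Wetlands": {
            "rank": 3, "sign": "+", "scale": 250, "transformation": "inverse-reverse monomolecular",
        },
    },
}

#: Standardized coefficients of the published best-fit (full) models, by
#: scheme, in the W/A/H/M/P ordering convention of the source tables.
PUBLISHED_COEFFICIENTS = {
    "Sparse-Large": {"W": 0.91, "A": 0.69, "H": 0.65, "M": -0.43, "P": -0.25},
    "Dense-Small": {"W": 0.81, "P": 0.68, "M": -0.60, "A": 0.58, "H": 0.23},
    "Sparse-Small": {"P": 0.84, "M": -0.74, "W": 0.67, "H": -0.41, "A": -0.09},
}
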