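"""Individual multilocus genotypes and the PCA-based genetic distance.

Genotypes are diploid codominant calls (e.g. microsatellite allele sizes) at
a handful of loci.  The individual-based genetic distance is built by (1)
encoding each observed allele as a dosage column (copies carried / 2, i.e.
0, 0.5 or 1), (2) mean-imputing missing calls and centering columns, (3)
projecting onto the leading principal components, and (4) taking Euclidean
distances between individuals in the retained-axis space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "PCAScores",
    "read_genotypes",
    "write_genotypes",
    "summarize_genotypes",
    "encode_and_pca",
    "pca_distance",
]

_META_COLS = ("id", "location_id", "x", "y")


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls with site coordinates.

    ``data`` holds columns id, location_id, x, y, then two nullable-integer
    allele columns per locus named ``<locus>_1`` / ``<locus>_2``.  A missing
    call blanks both slots of a locus; one-sided missingness is rejected at
    construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in _META_COLS:
            if col not in df.columns:
                raise ValueError(f"genotype table is missing column {col!r}")
        if len(df) == 0:
            raise ValueError("genotype table contains no individuals")
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate individual id {dup!r}")
        if not np.isfinite(df[["x", "y"]].to_numpy(float)).all():
            raise ValueError("coordinates must be finite")
        allele_cols = [c for c in df.columns if c not in _META_COLS]
        if len(allele_cols) % 2 != 0:
            raise ValueError(
                f"odd number of allele columns ({len(allele_cols)}); "
                "each locus needs exactly two"
            )
        loci = []
        for k in range(0, len(allele_cols), 2):
            a, b = allele_cols[k], allele_cols[k + 1]
            name = a[:-2] if a.endswith("_1") else a
            loci.append((name, a, b))
        self._loci = loci
        for name, a, b in loci:
            va = df[a].isna().to_numpy()
            vb = df[b].isna().to_numpy()
            half = va != vb
            if half.any():
                row = df.loc[half, "id"].iloc[0]
                raise ValueError(
                    f"individual {row!r} has one missing allele at locus {name!r}; "
                    "a missing call must blank both slots"
                )

    @property
    def loci(self) -> list[str]:
        return [name for name, _, _ in self._loci]

    @property
    def n_individuals(self) -> int:
        return len(self.data)

    def alleles(self, locus: str) -> tuple[pd.Series, pd.Series]:
        for name, a, b in self._loci:
            if name == locus:
                return self.data[a], self.data[b]
        raise KeyError(locus)


def write_genotypes(table: GenotypeTable, path) -> None:
    """Write a genotype table as tab-separated text (missing calls blank)."""
    table.data.to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> GenotypeTable:
    """Read a tab-separated genotype table.

    Layout: one row per individual — id, location_id, x, y, then two integer
    allele columns per locus.  Empty/NA cells mark missing calls.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"genotype file {path!r} contains no individuals")
    allele_cols = [c for c in df.columns if c not in _META_COLS]
    for c in allele_cols:
        try:
            df[c] = df[c].astype("Int64")
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-integer allele call in column {c!r}: {exc}") from exc
    return GenotypeTable(df)


def summarize_genotypes(table: GenotypeTable) -> dict:
    """Per-locus allele counts, mean alleles per locus, percent missing.

    Allele counts ignore missing calls; a locus with no observed alleles is
    reported with count 0 rather than dropped.
    """
    counts = {}
    missing = 0
    total = 0
    for locus in table.loci:
        a, b = table.alleles(locus)
        observed = pd.concat([a.dropna(), b.dropna()])
        counts[locus] = int(observed.nunique())
        missing += int(a.isna().sum())
        total += len(a)
    return {
        "alleles_per_locus": counts,
        "mean_alleles_per_locus": float(np.mean(list(counts.values()))),
        "percent_missing": 100.0 * missing / total if total else 0.0,
        "n_individuals": table.n_individuals,
        "n_loci": len(table.loci),
    }


@dataclass
class PCAScores:
    """Principal-component scores of the encoded genotype matrix."""

    ids: np.ndarray
    scores: np.ndarray  # n_individuals x k
    eigenvalues: np.ndarray  # variance per retained axis, non-increasing


def encode_genotypes(table: GenotypeTable, scale: bool = False) -> np.ndarray:
    """Per-allele dosage encoding with mean imputation and centering.

    One column per observed allele per locus, value = copies carried / 2.
    Missing locus-calls are imputed with the column mean; columns without
    missing entries are untouched by imputation.  ``scale`` additionally
    divides centered columns by their standard deviation.
    """
    cols = []
    for locus in table.loci:
        a, b = table.alleles(locus)
        av, bv = a.to_numpy(dtype="float64", na_value=np.nan), b.to_numpy(
            dtype="float64", na_value=np.nan
        )
        for allele in np.unique(np.r_[av[~np.isnan(av)], bv[~np.isnan(bv)]]):
            dosage = ((av == allele).astype(float) + (bv == allele).astype(float)) / 2.0
            dosage[np.isnan(av)] = np.nan
            cols.append(dosage)
    if not cols:
        raise ValueError("no observed alleles: every call is missing")
    M = np.column_stack(cols)
    col_mean = np.nanmean(M, axis=0)
    nan_mask = np.isnan(M)
    M[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    M -= M.mean(axis=0)
    if scale:
        sd = M.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        M /= sd
    return M


def encode_and_pca(table: GenotypeTable, n_axes: int = 64, scale: bool = False) -> PCAScores:
    """PCA of the encoded genotype matrix, capped at its rank.

    The default of 64 retained axes balances explained variance against
    dimensionality for microsatellite panels; datasets with fewer effective
    dimensions simply keep all of them.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    if table.n_individuals < 2:
        raise ValueError("PCA needs at least two individuals")
    M = encode_genotypes(table, scale=scale)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    tol = s.max(initial=0.0) * max(M.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    k = min(n_axes, rank)
    eigenvalues = (s[:k] ** 2) / (table.n_individuals - 1)
    scores = U[:, :k] * s[:k]
    return PCAScores(table.data["id"].to_numpy(), scores, eigenvalues)


def pca_distance(scores: PCAScores) -> pd.DataFrame:
    """Pairwise Euclidean distance between individuals in PC space."""
    if not np.all(np.isfinite(scores.scores)):
        raise ValueError("PCA scores contain non-finite values")
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(scores.scores, metric="euclidean"))
    return pd.DataFrame(D, index=scores.ids, columns=scores.ids)
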