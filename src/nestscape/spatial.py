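"""Spatial genetic structure: Mantel correlogram and semivariogram.

The correlogram splits pairwise geographic distances into equal-width
classes and, for each class, correlates genetic distance with the 0/1
within-class indicator.  The sign is flipped so that positive Mantel r means
individuals within the class are genetically *more similar* than average —
positive spatial autocorrelation.  Significance comes from permuting
individual labels, and the largest distance class that is still positive and
significant estimates the genetic neighborhood size.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "mantel_correlogram",
    "semivariogram",
    "neighborhood_size",
    "holm_adjust",
]


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment of a vector of p-values (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.flatnonzero(~np.isnan(p))
    m = len(ok)
    if m == 0:
        return out
    order = ok[np.argsort(p[ok], kind="stable")]
    # step-down: multiply by decreasing factor, enforce monotonicity, cap at 1
    stepped = (m - np.arange(m)) * p[order]
    out[order] = np.minimum(np.maximum.accumulate(stepped), 1.0)
    return out


def _check_square(gd: np.ndarray, geo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gd = np.asarray(gd, dtype=float)
    geo = np.asarray(geo, dtype=float)
    if gd.shape != geo.shape or gd.ndim != 2 or gd.shape[0] != gd.shape[1]:
        raise ValueError("genetic and geographic matrices must be square and congruent")
    if not (np.allclose(gd, gd.T) and np.allclose(geo, geo.T)):
        raise ValueError("distance matrices must be symmetric")
    return gd, geo


def mantel_correlogram(
    gd,
    geo,
    n_classes: int = 30,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    min_spacing: float | None = None,
) -> pd.DataFrame:
    """Mantel correlogram of genetic vs. geographic distance.

    Distance classes are equal-width over (0, max(geo)].  For class k the
    statistic is minus the Pearson correlation between the off-diagonal
    genetic distances and the within-class 0/1 indicator, so positive r
    reads as positive autocorrelation.  p_raw is a two-sided permutation
    p-value (|r| under label permutation); p_adjusted applies Holm across
    classes.  Classes without pairs get NaN statistics.
    """
    gd, geo = _check_square(gd, geo)
    if n_classes < 2:
        raise ValueError("need at least two distance classes")
    n = gd.shape[0]
    iu = np.triu_indices(n, k=1)
    d_geo = geo[iu]
    breaks = np.linspace(0.0, d_geo.max(), n_classes + 1)
    if min_spacing is not None and breaks[1] > min_spacing:
        warnings.warn(
            f"class width {breaks[1]:.1f} m exceeds the minimum site spacing "
            f"{min_spacing:.1f} m; the first class may mix within- and "
            "between-site pairs",
            stacklevel=2,
        )
    which = np.clip(np.searchsorted(breaks, d_geo, side="left"), 1, n_classes) - 1
    indicators = np.zeros((len(d_geo), n_classes))
    indicators[np.arange(len(d_geo)), which] = 1.0
    n_pairs = indicators.sum(axis=0).astype(int)
    if (n_pairs > 0).sum() < 2:
        raise ValueError("all pairs fall in a single distance class")

    ind_c = indicators - indicators.mean(axis=0)
    ind_ss = np.sqrt((ind_c**2).sum(axis=0))

    def class_r(dvec: np.ndarray) -> np.ndarray:
        dc = dvec - dvec.mean()
        denom = ind_ss * np.sqrt((dc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = -(ind_c.T @ dc) / denom
        r[n_pairs == 0] = np.nan
        return r

    r_obs = class_r(gd[iu])
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_classes)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = class_r(gd[perm][:, perm][iu])
        exceed += np.abs(r_perm) >= np.abs(r_obs) - 1e-12
    p_raw = (1.0 + exceed) / (n_perm + 1.0)
    p_raw[n_pairs == 0] = np.nan

    mid = (breaks[:-1] + breaks[1:]) / 2.0
    return pd.DataFrame(
        {
            "class_index": np.arange(n_classes),
            "lower": breaks[:-1],
            "upper": breaks[1:],
            "midpoint": mid,
            "n_pairs": n_pairs,
            "mantel_r": r_obs,
            "p_raw": p_raw,
            "p_adjusted": holm_adjust(p_raw),
            "significant": p_raw <= alpha,
        }
    )


def semivariogram(gd, geo, interval: float = 1500.0, n_bins: int = 52) -> pd.DataFrame:
    """Semivariance of genetic distance by geographic lag.

    gamma(bin) = sum of squared genetic distances over the bin's pairs
    divided by 2 * n_pairs; bins are contiguous [k*interval, (k+1)*interval).
    Empty bins are reported with n_pairs = 0 and gamma = NaN.
    """
    gd, geo = _check_square(gd, geo)
    if interval <= 0:
        raise ValueError("lag interval must be positive")
    iu = np.triu_indices(gd.shape[0], k=1)
    lag = np.floor(geo[iu] / interval).astype(int)
    inside = lag < n_bins
    counts = np.bincount(lag[inside], minlength=n_bins)
    ss = np.bincount(lag[inside], weights=gd[iu][inside] ** 2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, ss / (2.0 * counts), np.nan)
    return pd.DataFrame(
        {
            "bin_index": np.arange(n_bins),
            "lower": np.arange(n_bins) * interval,
            "upper": (np.arange(n_bins) + 1) * interval,
            "n_pairs": counts,
            "gamma": gamma,
        }
    )


def neighborhood_size(
    classes: pd.DataFrame, alpha: float = 0.05, use_adjusted: bool = False
) -> dict | None:
    """Genetic neighborhood size from a Mantel correlogram.

    The largest distance class with mantel_r > 0 and p <= alpha; returns its
    upper bound and midpoint, or None when no class qualifies.  Raw
    permutation p-values are used by default (adjusted optionally).
    """
    if len(classes) == 0:
        raise ValueError("empty correlogram")
    p = classes["p_adjusted"] if use_adjusted else classes["p_raw"]
    hit = classes[(classes["mantel_r"] > 0) & (p <= alpha)]
    if hit.empty:
        return None
    last = hit.iloc[-1]
    return {
        "upper": float(last["upper"]),
        "midpoint": float(last["midpoint"]),
        "class_index": int(last["class_index"]),
        "mantel_r": float(last["mantel_r"]),
        "p": float(p.loc[last.name]),
    }
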