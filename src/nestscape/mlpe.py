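"""Maximum-likelihood population effects (MLPE) models for pairwise
genetic distances.

The response is a vector of pairwise distances y over unordered individual
pairs.  Pairs sharing an individual are not independent; the MLPE model
captures this with one Gaussian random effect per individual:

    y = X beta + Z u + eps,   u ~ N(0, sigma_u^2 I_m),   eps ~ N(0, sigma_e^2 I_n)

where Z is the n_pairs x m incidence matrix with a 1 in the columns of the
two members of each pair.  The induced correlation between two pairs sharing
one individual is rho = sigma_u^2 / (2 sigma_u^2 + sigma_e^2) <= 1/2.

Fitting maximizes the full ML likelihood (not REML, so AICc comparisons
across fixed-effect structures are valid) by a 1-D profile over
theta = sigma_u^2 / sigma_e^2: for fixed theta, beta and sigma_e^2 have
closed-form GLS solutions.  All linear algebra goes through the Woodbury
identity on Z, so the cost is O(n_pairs * m + m^3) per likelihood
evaluation rather than O(n_pairs^3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "MLPEFit",
    "enumerate_pairs",
    "aicc",
    "fit_mlpe",
    "optimize_surface",
    "rank_model_set",
    "effect_signs",
    "MODEL_SET",
]

#: The ten-model comparison set: a full model, isolation by distance, three
#: ecologically themed multivariate models, and one univariate model per
#: class.  Keys A/H/P/M/W name agriculture, hardwoods, pine, manmade
#: structures, and wetlands; GD (homogeneous-landscape distance) is implicit
#: in every model.
MODEL_SET: dict[str, tuple[str, ...]] = {
    "Full model": ("A", "H", "P", "M", "W"),
    "Isolation by distance": (),
    "Moderate habitat": ("A", "P"),
    "Modified habitat": ("A", "M"),
    "Forest cover": ("P", "H", "W"),
    "Agriculture only": ("A",),
    "Manmade structures only": ("M",),
    "Pine only": ("P",),
    "Hardwoods only": ("H",),
    "Wetlands only": ("W",),
}


@dataclass
class MLPEFit:
    """A fitted MLPE model."""

    coefficients: dict[str, float]  # includes "(Intercept)"
    sigma_u2: float
    sigma_e2: float
    log_likelihood: float
    k: int
    n: int
    aicc: float
    theta: float
    predictor_names: tuple[str, ...]
    standardized: bool

    @property
    def rho(self) -> float:
        """Correlation between two pairs sharing one individual."""
        denom = 2 * self.sigma_u2 + self.sigma_e2
        return self.sigma_u2 / denom if denom > 0 else 0.0


def enumerate_pairs(
    individuals: pd.DataFrame, exclude_within_location: bool = True
) -> pd.DataFrame:
    """All unordered pairs of individuals, with within-location pairs flagged.

    ``individuals`` needs columns ``id``, ``location_id``, ``x``, ``y``.
    Pairs of individuals from the same sampling location carry no
    between-site landscape signal and by default are excluded from model
    rows (``included`` column); the full pair set is always returned so
    counts both ways are available.
    """
    if len(individuals) < 2:
        raise ValueError("need at least two individuals to form pairs")
    idx_i, idx_j = np.triu_indices(len(individuals), k=1)
    ind = individuals.reset_index(drop=True)
    pairs = pd.DataFrame(
        {
            "i": ind["id"].to_numpy()[idx_i],
            "j": ind["id"].to_numpy()[idx_j],
            "i_index": idx_i,
            "j_index": idx_j,
            "location_i": ind["location_id"].to_numpy()[idx_i],
            "location_j": ind["location_id"].to_numpy()[idx_j],
        }
    )
    pairs["geographic_distance"] = np.hypot(
        ind["x"].to_numpy()[idx_i] - ind["x"].to_numpy()[idx_j],
        ind["y"].to_numpy()[idx_i] - ind["y"].to_numpy()[idx_j],
    )
    pairs["same_location"] = pairs["location_i"] == pairs["location_j"]
    pairs["included"] = ~pairs["same_location"] if exclude_within_location else True
    return pairs


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Corrected Akaike information criterion; requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


class _MLPEProblem:
    """Profiled-likelihood engine for one (y, X, pairs) problem."""

    def __init__(self, y, X, i_index, j_index):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n = len(self.y)
        # relabel individuals to a dense range
        members = np.unique(np.r_[i_index, j_index])
        self.m = len(members)
        lookup = {v: k for k, v in enumerate(members)}
        self.ii = np.array([lookup[v] for v in i_index])
        self.jj = np.array([lookup[v] for v in j_index])
        # ZtZ is m x m: diag = pair counts per individual, offdiag = 1 per
        # observed pair
        ZtZ = np.zeros((self.m, self.m))
        np.add.at(ZtZ, (self.ii, self.jj), 1.0)
        np.add.at(ZtZ, (self.jj, self.ii), 1.0)
        counts = np.bincount(np.r_[self.ii, self.jj], minlength=self.m).astype(float)
        ZtZ[np.diag_indices(self.m)] = counts
        self.ZtZ = ZtZ

    def _Zt(self, v: np.ndarray) -> np.ndarray:
        out = np.zeros((self.m,) + v.shape[1:])
        np.add.at(out, self.ii, v)
        np.add.at(out, self.jj, v)
        return out

    def _Z(self, w: np.ndarray) -> np.ndarray:
        return w[self.ii] + w[self.jj]

    def profile(self, theta: float):
        """GLS profile at fixed theta = sigma_u^2/sigma_e^2.

        Returns (log-likelihood, beta, sigma_e^2).
        """
        n, X, y = self.n, self.X, self.y
        if theta > 0:
            M = np.eye(self.m) + theta * self.ZtZ
            cho = np.linalg.cholesky(M)
            logdetW = 2.0 * np.log(np.diag(cho)).sum()

            def Winv(v):
                t = self._Zt(v)
                s = np.linalg.solve(M, t)
                return v - theta * self._Z(s)

        else:
            logdetW = 0.0

            def Winv(v):
                return v

        WiX = Winv(X)
        Wiy = Winv(y)
        XtWiX = X.T @ WiX
        beta = np.linalg.solve(XtWiX, X.T @ Wiy)
        r = y - X @ beta
        q = float(r @ Winv(r))
        sigma_e2 = q / n
        ll = -0.5 * (n * math.log(2 * math.pi * sigma_e2) + logdetW + n)
        return ll, beta, sigma_e2


def fit_mlpe(
    y,
    X: pd.DataFrame | np.ndarray,
    pairs: pd.DataFrame,
    standardize: bool = True,
    theta_max: float = 50.0,
) -> MLPEFit:
    """Fit an MLPE model by profiled maximum likelihood.

    Parameters
    ----------
    y
        Response (pairwise genetic distance) over the included pairs.
    X
        Predictor columns over the same pairs (no intercept column; one is
        added).  A DataFrame supplies predictor names.
    pairs
        Pair table with ``i_index``/``j_index`` columns identifying the two
        members of each pair (as produced by :func:`enumerate_pairs`,
        restricted to the same rows as ``y``).
    standardize
        Z-score the predictor columns before fitting so coefficients are
        comparable in magnitude across predictors (used for rank-of-effect).
    """
    if isinstance(X, pd.DataFrame):
        names = tuple(str(c) for c in X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.atleast_2d(np.asarray(X, dtype=float))
        if Xv.shape[0] != len(np.asarray(y)):
            Xv = Xv.T
        names = tuple(f"x{k}" for k in range(Xv.shape[1]))
    y = np.asarray(y, dtype=float)
    if Xv.shape[0] != len(y) or len(pairs) != len(y):
        raise ValueError("y, X, and pairs must have the same number of rows")
    if standardize and Xv.shape[1]:
        sd = Xv.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = [names[k] for k in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant predictor column(s): {bad}")
        Xv = (Xv - Xv.mean(axis=0)) / sd
    Xd = np.column_stack([np.ones(len(y)), Xv])
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("design matrix is rank deficient")
    k = Xd.shape[1] + 2  # slopes + intercept + two variance components
    if len(y) <= k + 1:
        raise ValueError(f"too few pairs (n={len(y)}) for k={k} parameters")

    prob = _MLPEProblem(y, Xd, pairs["i_index"].to_numpy(), pairs["j_index"].to_numpy())

    res = minimize_scalar(
        lambda t: -prob.profile(t)[0],
        bounds=(0.0, theta_max),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"MLPE profile optimization failed: {res.message}")
    theta = float(res.x)
    ll0, *_ = prob.profile(0.0)
    ll, beta, sigma_e2 = prob.profile(theta)
    if ll0 >= ll:  # boundary solution: no individual-level variance
        theta = 0.0
        ll, beta, sigma_e2 = ll0, *prob.profile(0.0)[1:]
    coefficients = {"(Intercept)": float(beta[0])}
    coefficients.update({name: float(b) for name, b in zip(names, beta[1:])})
    return MLPEFit(
        coefficients=coefficients,
        sigma_u2=theta * sigma_e2,
        sigma_e2=sigma_e2,
        log_likelihood=float(ll),
        k=k,
        n=len(y),
        aicc=aicc(float(ll), k, len(y)),
        theta=theta,
        predictor_names=names,
        standardized=standardize,
    )


def optimize_surface(
    y,
    candidates: pd.DataFrame,
    gd,
    pairs: pd.DataFrame,
    window_of: dict[str, float],
    transform_of: dict[str, str],
    transform_order: tuple[str, ...] | None = None,
) -> tuple[float, str, MLPEFit, pd.DataFrame]:
    """Select the best (window side, transformation) for one land-use class.

    Fits one two-predictor MLPE (homogeneous distance GD + one candidate
    residual) per candidate column and ranks by AICc.  Returns the winning
    window side, transformation label, its fit, and the full leaderboard.
    Ties in AICc break toward the smallest window, then the fixed
    transformation-family order.
    """
    from .surfaces import TRANSFORM_FAMILIES

    if transform_order is None:
        transform_order = TRANSFORM_FAMILIES
    rows = []
    fits = {}
    for label in candidates.columns:
        X = pd.DataFrame({"GD": np.asarray(gd, float), label: candidates[label].to_numpy()})
        try:
            fit = fit_mlpe(y, X, pairs)
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
            import warnings

            warnings.warn(f"candidate {label!r} failed to fit: {exc}", stacklevel=2)
            continue
        fits[label] = fit
        rows.append(
            {
                "label": label,
                "window_side": window_of[label],
                "transform": transform_of[label],
                "aicc": fit.aicc,
                "log_likelihood": fit.log_likelihood,
                "coefficient": fit.coefficients[label],
            }
        )
    if not rows:
        raise RuntimeError("every candidate fit failed")
    board = pd.DataFrame(rows)
    board["_t"] = board["transform"].map({t: k for k, t in enumerate(transform_order)})
    board = board.sort_values(["aicc", "window_side", "_t"], kind="stable").drop(columns="_t")
    board = board.reset_index(drop=True)
    best = board.iloc[0]
    return float(best["window_side"]), str(best["transform"]), fits[best["label"]], board


def rank_model_set(
    y,
    predictors: dict[str, np.ndarray],
    gd,
    pairs: pd.DataFrame,
    model_set: dict[str, tuple[str, ...]] | None = None,
) -> tuple[pd.DataFrame, dict[str, MLPEFit]]:
    """Fit and AICc-rank the fixed ten-model comparison set.

    ``predictors`` maps class keys (A/H/P/M/W by default) to their optimized
    residual predictor columns; GD enters every model.  Returns the ranked
    leaderboard and the fit for each model.
    """
    if model_set is None:
        model_set = MODEL_SET
    needed = {c for spec in model_set.values() for c in spec}
    missing = needed - set(predictors)
    if missing:
        raise KeyError(f"missing optimized predictors for classes: {sorted(missing)}")
    gd = np.asarray(gd, dtype=float)
    fits: dict[str, MLPEFit] = {}
    rows = []
    for name, classes in model_set.items():
        X = pd.DataFrame({"GD": gd})
        for c in classes:
            X[c] = np.asarray(predictors[c], dtype=float)
        fit = fit_mlpe(y, X, pairs)
        fits[name] = fit
        rows.append(
            {
                "model": name,
                "variables": "GD" + ("," + ",".join(classes) if classes else ""),
                "k": fit.k,
                "log_likelihood": fit.log_likelihood,
                "aicc": fit.aicc,
            }
        )
    board = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
    board["delta_aicc"] = board["aicc"] - board["aicc"].iloc[0]
    return board, fits


def effect_signs(fit: MLPEFit, exclude: tuple[str, ...] = ("GD",)) -> pd.DataFrame:
    """Sign, gene-flow label, and rank of effect per landscape predictor.

    A positive standardized coefficient marks gene-flow restriction, a
    negative one facilitation.  Rank orders predictors by |coefficient|
    descending (GD and the intercept excluded); exact zeros rank last with
    sign "0", and ties in magnitude break by class name (flagged).
    """
    rows = []
    for name in fit.predictor_names:
        if name in exclude:
            continue
        coef = fit.coefficients[name]
        if coef > 0:
            sign, label = "+", "restriction"
        elif coef < 0:
            sign, label = "-", "facilitation"
        else:
            sign, label = "0", "none"
        rows.append({"class": name, "coefficient": coef, "sign": sign, "label": label})
    if not rows:
        raise ValueError("fit has no landscape predictors to rank")
    df = pd.DataFrame(rows)
    df["_mag"] = np.where(df["sign"] == "0", -np.inf, np.abs(df["coefficient"]))
    df = df.sort_values(["_mag", "class"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    df["tied"] = df["_mag"].duplicated(keep=False)
    return df.drop(columns="_mag").reset_index(drop=True)
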