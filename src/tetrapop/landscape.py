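"""Isolation by distance vs isolation by environment.

Distance-matrix construction (great-circle geographic, Euclidean
environmental on z-scored covariates, linearized-F_ST genetic),
collinearity pruning of covariates, simple and partial Mantel tests,
multiple matrix regression with randomization (MMRR), and two-predictor
commonality analysis decomposing the regression R^2 into variance unique
to each predictor and variance shared through their collinearity.

All permutation tests permute rows and columns of one matrix jointly
(preserving its distance structure) and use the add-one permutation
p-value ``(1 + #{extreme}) / (n_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "haversine_km",
    "geographic_distance",
    "environmental_distance",
    "linearize_fst",
    "prune_collinear",
    "mantel",
    "partial_mantel",
    "mmrr",
    "MmrrResult",
    "commonality_two",
    "CommonalityResult",
]

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points in decimal degrees."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _check_square(D: np.ndarray, name: str = "matrix") -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError(f"{name} must be symmetric")
    return D


def lower_triangle(D: np.ndarray) -> np.ndarray:
    """Strict lower-triangle entries of a square matrix as a vector."""
    D = np.asarray(D)
    i, j = np.tril_indices(D.shape[0], k=-1)
    return D[i, j]


def geographic_distance(pops, log_transform: bool = True) -> pd.DataFrame:
    """Pairwise haversine distance (km) between localities.

    With ``log_transform`` the natural log of km is returned, the usual
    transform before regressing genetic on geographic distance; any
    coincident pair of localities then raises, as log(0) is undefined.
    """
    frame = pops.frame if hasattr(pops, "frame") else pops
    lat = frame["lat"].to_numpy(dtype=float)
    lon = frame["lon"].to_numpy(dtype=float)
    ids = list(frame["locality"])
    D = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    if log_transform:
        off = lower_triangle(D)
        if (off <= 0).any():
            raise ValueError("zero geographic distance: log transform undefined")
        with np.errstate(divide="ignore"):
            D = np.where(np.eye(len(ids), dtype=bool), 0.0, np.log(D))
    return pd.DataFrame(D, index=ids, columns=ids)


def environmental_distance(covariates: pd.DataFrame, selected=None) -> pd.DataFrame:
    """Euclidean distance between localities on z-scored covariates.

    ``covariates`` is a localities x covariates table (index = locality
    ids); ``selected`` optionally restricts to a subset of columns.
    """
    if selected is not None:
        if len(selected) == 0:
            raise ValueError("selected covariate list is empty")
        covariates = covariates[list(selected)]
    if len(covariates) < 2:
        raise ValueError("need at least 2 localities")
    X = covariates.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = covariates.columns[sd == 0].tolist()
        raise ValueError(f"constant covariates cannot be z-scored: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    diff = Z[:, None, :] - Z[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    return pd.DataFrame(D, index=covariates.index, columns=covariates.index)


def linearize_fst(fst: pd.DataFrame) -> pd.DataFrame:
    """Linearized genetic distance F_ST / (1 - F_ST)."""
    F = _check_square(np.asarray(fst, dtype=float), "fst")
    if (F >= 1.0).any():
        raise ValueError("F_ST must be < 1 to linearize")
    D = F / (1.0 - F)
    if isinstance(fst, pd.DataFrame):
        return pd.DataFrame(D, index=fst.index, columns=fst.columns)
    return pd.DataFrame(D)


def prune_collinear(covariates: pd.DataFrame, cutoff: float = 0.9) -> list[str]:
    """Greedily drop covariates until no pair has |Pearson r| > cutoff.

    While any pair exceeds the cutoff, the member of the worst pair with
    the larger mean absolute correlation against all remaining variables
    is removed (ties broken by name).  Constant covariates, whose
    correlation is undefined, are removed first.
    """
    if covariates.shape[1] < 2:
        return list(covariates.columns)
    keep = [c for c in covariates.columns if covariates[c].std() > 0]
    while len(keep) > 1:
        corr = covariates[keep].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        worst = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[worst] <= cutoff:
            break
        a, b = keep[worst[0]], keep[worst[1]]
        mean_a = corr[worst[0]].sum() / (len(keep) - 1)
        mean_b = corr[worst[1]].sum() / (len(keep) - 1)
        if mean_a > mean_b or (mean_a == mean_b and a > b):
            keep.remove(a)
        else:
            keep.remove(b)
    return keep


def _perm_indices(rng: np.random.Generator, n: int, n_perm: int) -> np.ndarray:
    return np.array([rng.permutation(n) for _ in range(n_perm)])


def mantel(
    A, B, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Simple Mantel test: Pearson r of two distance matrices.

    The null distribution is generated by jointly permuting rows and
    columns of ``B``; the one-sided (greater) p-value is
    ``(1 + #{r_perm >= r_obs}) / (n_perm + 1)``.
    """
    A = _check_square(np.asarray(A, dtype=float), "A")
    B = _check_square(np.asarray(B, dtype=float), "B")
    if A.shape != B.shape:
        raise ValueError("matrices must be conformable")
    a = lower_triangle(A)
    b = lower_triangle(B)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant off-diagonal entries: Mantel r undefined")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    il, jl = np.tril_indices(n, k=-1)
    perms = _perm_indices(rng, n, n_perm)
    b_perm = B[perms[:, il], perms[:, jl]]  # (n_perm, n_pairs)
    az = (a - a.mean()) / a.std()
    bz = (b_perm - b_perm.mean(axis=1, keepdims=True)) / b_perm.std(axis=1, keepdims=True)
    r_perm = (bz * az).mean(axis=1)
    p = (1 + int((r_perm >= r_obs - 1e-12).sum())) / (n_perm + 1)
    return r_obs, p


def partial_mantel(
    A, B, C, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Partial Mantel: correlation of A and B controlling for C.

    Lower triangles of A and B are each regressed on C's by OLS and the
    residuals correlated.  The null permutes B (rows/columns jointly),
    recomputing its residuals each time.
    """
    A = _check_square(np.asarray(A, dtype=float), "A")
    B = _check_square(np.asarray(B, dtype=float), "B")
    C = _check_square(np.asarray(C, dtype=float), "C")
    a, b, c = lower_triangle(A), lower_triangle(B), lower_triangle(C)
    if c.std() == 0:
        raise ValueError("constant control matrix")

    def _resid(y: np.ndarray, x: np.ndarray) -> np.ndarray:
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return y - X @ beta

    ra = _resid(a, c)
    rb = _resid(b, c)
    if rb.std() < 1e-12:
        raise ValueError("B is fully explained by the control matrix; partial r undefined")
    if ra.std() < 1e-12:
        # A fully explained by the control: nothing left to correlate
        return 0.0, 1.0
    r_obs = float(np.corrcoef(ra, rb)[0, 1])
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    il, jl = np.tril_indices(n, k=-1)
    perms = _perm_indices(rng, n, n_perm)
    count = 0
    for k in range(n_perm):
        bp = B[perms[k][:, None], perms[k][None, :]][il, jl]
        rbp = _resid(bp, c)
        if rbp.std() < 1e-12:
            continue
        if np.corrcoef(ra, rbp)[0, 1] >= r_obs - 1e-12:
            count += 1
    return r_obs, (1 + count) / (n_perm + 1)


@dataclass
class MmrrResult:
    """Multiple matrix regression with randomization fit."""

    r_squared: float
    betas: np.ndarray  # raw-scale coefficients, intercept first
    betas_std: np.ndarray  # standardized coefficients (no intercept)
    beta_pvalues: np.ndarray  # per-predictor permutation p (no intercept)
    model_pvalue: float
    predictor_names: list[str]
    n_permutations: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.betas[1:],
                "beta_std": self.betas_std,
                "p_value": self.beta_pvalues,
            },
            index=self.predictor_names,
        )


def mmrr(
    Y, X: list, n_perm: int = 1000, seed: int = 0, names: list[str] | None = None
) -> MmrrResult:
    """OLS of one distance matrix on several, permutation inference.

    Significance of each coefficient (|t|) and of the model (F) comes
    from jointly permuting rows and columns of the response matrix.
    """
    Y = _check_square(np.asarray(Y, dtype=float), "Y")
    Xm = [_check_square(np.asarray(x, dtype=float), "X") for x in X]
    if not Xm:
        raise ValueError("need at least one predictor")
    if names is None:
        names = [f"X{i + 1}" for i in range(len(Xm))]
    y = lower_triangle(Y)
    xs = np.column_stack([lower_triangle(x) for x in Xm])
    design = np.column_stack([np.ones(len(y)), xs])
    if np.linalg.cond(design) > 1e8:
        raise ValueError("collinear predictor distance matrices; prune before MMRR")

    def _fit(yv: np.ndarray):
        beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
        resid = yv - design @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yv - yv.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        dof = len(yv) - design.shape[1]
        sigma2 = ss_res / dof
        XtX_inv = np.linalg.inv(design.T @ design)
        se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 1e-300))
        t = beta / se
        k = design.shape[1] - 1
        F = (r2 / k) / ((1 - r2) / dof) if r2 < 1 else np.inf
        return beta, t, r2, F

    beta_obs, t_obs, r2_obs, F_obs = _fit(y)
    rng = np.random.default_rng(seed)
    n = Y.shape[0]
    il, jl = np.tril_indices(n, k=-1)
    perms = _perm_indices(rng, n, n_perm)
    count_t = np.zeros(len(Xm), dtype=int)
    count_F = 0
    for k in range(n_perm):
        yp = Y[perms[k][:, None], perms[k][None, :]][il, jl]
        _, t_p, _, F_p = _fit(yp)
        count_t += np.abs(t_p[1:]) >= np.abs(t_obs[1:]) - 1e-12
        count_F += F_p >= F_obs - 1e-12
    beta_std = beta_obs[1:] * xs.std(axis=0) / y.std()
    return MmrrResult(
        r_squared=r2_obs,
        betas=beta_obs,
        betas_std=beta_std,
        beta_pvalues=(1 + count_t) / (n_perm + 1),
        model_pvalue=(1 + count_F) / (n_perm + 1),
        predictor_names=list(names),
        n_permutations=n_perm,
    )


@dataclass
class CommonalityResult:
    """Two-predictor commonality decomposition of a regression R^2."""

    r_squared: float
    unique: dict[str, float]
    common: float
    totals: dict[str, float]

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.unique:
            u = self.unique[name]
            rows.append(
                {
                    "predictor": name,
                    "unique": u,
                    "common": self.common,
                    "total": self.totals[name],
                    "unique_pct": 100 * u / self.r_squared if self.r_squared else np.nan,
                    "common_pct": 100 * self.common / self.r_squared
                    if self.r_squared
                    else np.nan,
                    "total_pct": 100 * self.totals[name] / self.r_squared
                    if self.r_squared
                    else np.nan,
                }
            )
        return pd.DataFrame(rows).set_index("predictor")


def _r_squared(y: np.ndarray, cols: list[np.ndarray]) -> float:
    X = np.column_stack([np.ones(len(y))] + cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0


def commonality_two(Y, X1, X2, names: tuple[str, str] = ("GEO", "ENV")) -> CommonalityResult:
    """Decompose R^2 of Y ~ X1 + X2 into unique and common components.

    U_i = R^2_full - R^2 of the model without predictor i;
    C = R^2_full - U_1 - U_2.  The identity U_1 + U_2 + C = R^2_full
    holds by construction and is asserted.
    """
    y = lower_triangle(_check_square(np.asarray(Y, dtype=float), "Y"))
    x1 = lower_triangle(_check_square(np.asarray(X1, dtype=float), "X1"))
    x2 = lower_triangle(_check_square(np.asarray(X2, dtype=float), "X2"))
    identical = np.allclose(x1, x2)
    if identical:
        # Degenerate case: drop the duplicate from the full fit.
        r2_full = _r_squared(y, [x1])
    else:
        r2_full = _r_squared(y, [x1, x2])
    r2_1 = _r_squared(y, [x1])
    r2_2 = _r_squared(y, [x2])
    u1 = r2_full - r2_2
    u2 = r2_full - r2_1
    c = r2_full - u1 - u2
    assert abs(u1 + u2 + c - r2_full) < 1e-9
    return CommonalityResult(
        r_squared=r2_full,
        unique={names[0]: u1, names[1]: u2},
        common=c,
        totals={names[0]: u1 + c, names[1]: u2 + c},
    )
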