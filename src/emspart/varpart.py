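"""Redundancy analysis, spatial predictors and variation partitioning.

Community composition (Hellinger-transformed abundances) is regressed
on up to three predictor blocks — environment (E), space (S) and time
(T) — by multivariate least squares (RDA).  Explained variance is
reported as Ezekiel-adjusted R-squared and decomposed by inclusion–
exclusion into pure and shared fractions.  Spatial predictors are the
nine monomials of a third-degree trend surface of the (centred) site
coordinates, or classic PCNM eigenvectors of the truncated inter-site
distance matrix.  Forward selection with the double stopping rule
(candidate permutation p-value and the adjusted-R-squared cap of the
full model) reduces each block before partitioning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .io_types import Coordinates

__all__ = [
    "SpatialPredictors",
    "VarpartResult",
    "build_tsa_terms",
    "build_pcnm",
    "build_temporal_dummies",
    "rda_adjusted_r2",
    "partial_rda_test",
    "forward_select",
    "variation_partition",
    "per_variable_F",
]

TSA_COLUMNS = ["x", "y", "x2", "y2", "xy", "x3", "y3", "x2y", "xy2"]

#: canonical fraction keys of the 3-block partition
FRACTION_KEYS = (
    "pure_env", "pure_space", "pure_time",
    "env_space", "env_time", "space_time",
    "triple", "residual",
)


@dataclass
class SpatialPredictors:
    """Spatial predictor columns for a set of sites.

    ``kind`` is ``"tsa"`` (the 9 centred trend-surface monomials) or
    ``"pcnm"`` (eigenvectors of the truncated distance matrix with
    positive eigenvalues, scaled by the square root of the eigenvalue).
    """

    kind: str
    data: pd.DataFrame  # indexed by site_id
    eigenvalues: np.ndarray | None = None


@dataclass
class VarpartResult:
    """Adjusted-R2 fractions of a variation partition.

    ``fractions`` holds the eight canonical fractions (absent blocks
    contribute zero); they sum to one by the algebra of the
    inclusion–exclusion scheme.  ``total_explained`` is the adjusted R2
    of the full model; negative fractions are reported as computed.
    """

    fractions: dict[str, float]
    total_explained: float
    selected: dict[str, list[str]] = field(default_factory=dict)
    F_ratios: pd.DataFrame | None = None
    block_r2: dict[str, float] = field(default_factory=dict)

    def truncated(self) -> dict[str, float]:
        """Fractions with negative values clipped to zero (display aid)."""
        return {k: max(v, 0.0) for k, v in self.fractions.items()}


# ---------------------------------------------------------------------------
# spatial predictors
# ---------------------------------------------------------------------------

def build_tsa_terms(coords: Coordinates) -> SpatialPredictors:
    """Third-degree trend-surface monomials of centred coordinates.

    Coordinates are centred on their means before expansion; each of
    the nine monomial columns (x, y, x2, y2, xy, x3, y3, x2y, xy2) is
    then centred as well so the block enters RDA mean-free.
    """
    xy = coords.xy()
    if len(xy) < 10:
        raise ValueError("trend surface needs at least 10 sites")
    x = xy[:, 0] - xy[:, 0].mean()
    y = xy[:, 1] - xy[:, 1].mean()
    cols = np.column_stack(
        [x, y, x**2, y**2, x * y, x**3, y**3, x**2 * y, x * y**2]
    )
    cols = cols - cols.mean(axis=0)
    rank = np.linalg.matrix_rank(cols)
    if rank < 9:
        warnings.warn(
            f"trend-surface block is rank deficient (rank {rank} of 9); "
            "degenerate site geometry", stacklevel=2,
        )
    return SpatialPredictors(
        kind="tsa",
        data=pd.DataFrame(cols, index=coords.data.index, columns=TSA_COLUMNS),
    )


def build_pcnm(
    coords: Coordinates, truncation: float | None = None
) -> SpatialPredictors:
    """Classic PCNM eigenvectors of the truncated distance matrix.

    Distances above the truncation threshold (default: the longest edge
    of the minimum spanning tree) are replaced by four times the
    threshold; the modified matrix is double-centred (Gower) and
    eigen-decomposed; eigenvectors with positive eigenvalues are kept,
    scaled by the square root of their eigenvalue.
    """
    xy = coords.xy()
    if len(xy) < 3:
        raise ValueError("PCNM needs at least 3 sites")
    d = pdist(xy)
    if (d == 0).any():
        raise ValueError("duplicate coordinates: PCNM distances must be positive")
    D = squareform(d)
    if truncation is None:
        mst = minimum_spanning_tree(D)
        truncation = float(mst.data.max())
    Dt = np.where(D <= truncation, D, 4.0 * truncation)
    np.fill_diagonal(Dt, 0.0)
    A = -0.5 * Dt**2
    n = len(A)
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10 * abs(eigval[0]), 1e-12)
    keep = eigval > tol
    vecs = eigvec[:, keep] * np.sqrt(eigval[keep])
    cols = [f"PCNM{i+1}" for i in range(vecs.shape[1])]
    return SpatialPredictors(
        kind="pcnm",
        data=pd.DataFrame(vecs, index=coords.data.index, columns=cols),
        eigenvalues=eigval[keep],
    )


def build_temporal_dummies(
    years: pd.Series, sessions: pd.Series
) -> pd.DataFrame:
    """Centred dummy coding of year and session for the temporal block."""
    idx = years.index
    out = {}
    levels = sorted(pd.unique(years))
    for lev in levels[1:]:  # drop first level
        out[f"year_{lev}"] = (years == lev).astype(float)
    for lev in sorted(pd.unique(sessions))[1:]:
        out[f"session_{lev}"] = (sessions == lev).astype(float)
    df = pd.DataFrame(out, index=idx)
    return df - df.mean(axis=0)


# ---------------------------------------------------------------------------
# RDA core
# ---------------------------------------------------------------------------

def _as_array(X) -> np.ndarray:
    if X is None:
        return np.empty((0, 0))
    if isinstance(X, (pd.DataFrame, pd.Series)):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _fit_r2(Y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Raw multivariate R2 of centred Y on centred X, and the rank used."""
    Yc = Y - Y.mean(axis=0)
    ss_tot = float((Yc**2).sum())
    if ss_tot == 0:
        raise ValueError("response matrix has zero total variance")
    if X.size == 0:
        return 0.0, 0
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        warnings.warn(
            f"predictor block rank deficient ({rank}/{Xc.shape[1]}); "
            "dependent columns contribute no extra fit", stacklevel=3,
        )
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ beta
    return float((fitted**2).sum()) / ss_tot, int(rank)


def _adjust(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjustment 1 - (1 - R2)(n - 1)/(n - p - 1)."""
    if p == 0:
        return 0.0
    if n - p - 1 <= 0:
        raise ValueError("too few observations for adjustment")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def rda_adjusted_r2(Y, X) -> float:
    """Adjusted R2 of the redundancy analysis of Y on X.

    Y is the (Hellinger-transformed) community matrix; X a predictor
    block.  Both are centred internally; the raw multivariate R2 (sum
    of squares of fitted values over total sum of squares) is adjusted
    with Ezekiel's formula using the rank of X as the parameter count.
    """
    Y, X = _as_array(Y), _as_array(X)
    if X.size and Y.shape[0] != X.shape[0]:
        raise ValueError("Y and X row counts differ")
    r2, rank = _fit_r2(Y, X)
    return _adjust(r2, Y.shape[0], rank)


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    Mc = M - M.mean(axis=0)
    if Z.size == 0:
        return Mc
    Zc = Z - Z.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Zc, Mc, rcond=None)
    return Mc - Zc @ beta


def partial_rda_test(
    Y, X, Z=None, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Permutation F-test of X on Y, conditioning on Z.

    Y and X are residualized on Z (reduced model); the pseudo-F
    statistic F = (SS_X / p) / (SS_res / (n - p - q - 1)) is compared
    against the distribution obtained by permuting the rows of the
    reduced-model residuals.  Returns (F, p) with the usual
    (hits + 1)/(n_perm + 1) permutation p-value.
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    Y, X, Z = _as_array(Y), _as_array(X), _as_array(Z)
    n = Y.shape[0]
    Yr = _residualize(Y, Z)
    Xr = _residualize(X, Z)
    # X entirely inside the span of Z: nothing left to test
    x_scale = np.linalg.norm(X - X.mean(axis=0)) if X.size else 0.0
    if np.linalg.norm(Xr) <= 1e-10 * max(x_scale, 1.0):
        return 0.0, 1.0
    p = np.linalg.matrix_rank(Xr) or 1
    q = np.linalg.matrix_rank(Z - Z.mean(axis=0)) if Z.size else 0
    df_res = n - p - q - 1
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def _F(Yin: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(Xr, Yin, rcond=None)
        fitted = Xr @ beta
        ss_fit = float((fitted**2).sum())
        ss_res = float(((Yin - fitted) ** 2).sum())
        if ss_res <= 0:
            return np.inf
        return (ss_fit / p) / (ss_res / df_res)

    F_obs = _F(Yr)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _F(Yr[perm]) >= F_obs:
            hits += 1
    return F_obs, (hits + 1) / (n_perm + 1)


def forward_select(
    Y,
    X: pd.DataFrame,
    alpha: float = 0.05,
    r2_cap: float | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> list[str]:
    """Forward selection of predictor columns with the double stopping rule.

    At each step the candidate giving the largest raw R2 together with
    the already-selected set is tested by a partial-RDA permutation
    test conditioned on the selected set.  Selection stops when that
    candidate's p-value exceeds ``alpha``, or — after inclusion — when
    the cumulative adjusted R2 exceeds ``r2_cap`` (default: the
    adjusted R2 of the model with all candidate columns; the crossing
    variable is retained, as in the classic implementations).  Columns
    containing missing values are excluded with a warning; an empty
    selection is a valid outcome.
    """
    Ya = _as_array(Y)
    usable = []
    for c in X.columns:
        col = X[c].to_numpy(dtype=float)
        if not np.isfinite(col).all():
            warnings.warn(f"column {c!r} has missing values; excluded",
                          stacklevel=2)
        elif np.std(col) == 0:
            warnings.warn(f"column {c!r} is constant; excluded", stacklevel=2)
        else:
            usable.append(c)
    if not usable:
        return []
    if r2_cap is None:
        r2_cap = rda_adjusted_r2(Ya, X[usable])
    selected: list[str] = []
    rng = np.random.default_rng(seed)
    remaining = list(usable)
    while remaining:
        best, best_r2 = None, -np.inf
        for c in remaining:
            r2, _ = _fit_r2(Ya, _as_array(X[selected + [c]]))
            if r2 > best_r2:
                best, best_r2 = c, r2
        Z = _as_array(X[selected]) if selected else None
        _, p_val = partial_rda_test(
            Ya, _as_array(X[[best]]), Z,
            n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
        )
        if p_val > alpha:
            break
        selected.append(best)
        remaining.remove(best)
        # cumulative cap: the variable that crosses the full-model
        # adjusted R2 is retained and the procedure stops (matching the
        # classic forward-selection implementations)
        if rda_adjusted_r2(Ya, X[selected]) > r2_cap + 1e-12:
            break
    return selected


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

def _combo_adj(Y: np.ndarray, blocks: dict[str, np.ndarray], names) -> float:
    mats = [blocks[n] for n in names if blocks[n].size]
    if not mats:
        return 0.0
    return rda_adjusted_r2(Y, np.hstack(mats))


def variation_partition(
    Y,
    E=None,
    S=None,
    T=None,
    truncate_negative: bool = False,
) -> VarpartResult:
    """Three-block variation partitioning by adjusted R2 subtraction.

    Fits the seven RDAs (E, S, T, ES, ET, ST, EST), converts each to
    adjusted R2, and solves the inclusion–exclusion system for the
    pure, pairwise-shared and triple-shared fractions plus the
    residual.  Absent blocks degrade gracefully to a two- or one-block
    partition (their fractions are zero).  Negative fractions are
    reported as computed unless ``truncate_negative``.
    """
    Ya = _as_array(Y)
    blocks = {"E": _as_array(E), "S": _as_array(S), "T": _as_array(T)}
    present = [k for k, v in blocks.items() if v.size]
    if not present:
        raise ValueError("at least one predictor block is required")

    aE = _combo_adj(Ya, blocks, "E")
    aS = _combo_adj(Ya, blocks, "S")
    aT = _combo_adj(Ya, blocks, "T")
    aES = _combo_adj(Ya, blocks, "ES")
    aET = _combo_adj(Ya, blocks, "ET")
    aST = _combo_adj(Ya, blocks, "ST")
    aEST = _combo_adj(Ya, blocks, "EST")

    has = {k: blocks[k].size > 0 for k in "EST"}
    f = dict.fromkeys(FRACTION_KEYS, 0.0)
    if all(has.values()):
        g = aE + aS + aT - aES - aET - aST + aEST
        f["pure_env"] = aEST - aST
        f["pure_space"] = aEST - aET
        f["pure_time"] = aEST - aES
        f["env_space"] = aE + aS - aES - g
        f["space_time"] = aS + aT - aST - g
        f["env_time"] = aE + aT - aET - g
        f["triple"] = g
    elif has["E"] and has["S"]:
        f["pure_env"] = aES - aS
        f["pure_space"] = aES - aE
        f["env_space"] = aE + aS - aES
    elif has["E"] and has["T"]:
        f["pure_env"] = aET - aT
        f["pure_time"] = aET - aE
        f["env_time"] = aE + aT - aET
    elif has["S"] and has["T"]:
        f["pure_space"] = aST - aT
        f["pure_time"] = aST - aS
        f["space_time"] = aS + aT - aST
    elif has["E"]:
        f["pure_env"] = aE
    elif has["S"]:
        f["pure_space"] = aS
    elif has["T"]:
        f["pure_time"] = aT
    f["residual"] = 1.0 - aEST
    if truncate_negative:
        f = {k: max(v, 0.0) for k, v in f.items()}
    return VarpartResult(
        fractions=f,
        total_explained=aEST,
        block_r2={"E": aE, "S": aS, "T": aT, "ES": aES, "ET": aET,
                  "ST": aST, "EST": aEST},
    )


def per_variable_F(
    Y,
    E_selected: pd.DataFrame,
    Z=None,
    n_perm: int = 199,
    seed: int = 0,
) -> pd.DataFrame:
    """Marginal F-ratio of each selected environmental variable.

    Each variable is tested by partial RDA with all other selected
    variables (plus any extra conditioning block Z) as covariables;
    relative contributions are reported as F_i / sum(F).
    """
    if E_selected.shape[1] == 0:
        raise ValueError("no selected variables")
    Ya = _as_array(Y)
    rng = np.random.default_rng(seed)
    rows = []
    for c in E_selected.columns:
        others = [o for o in E_selected.columns if o != c]
        zparts = []
        if others:
            zparts.append(_as_array(E_selected[others]))
        if Z is not None and _as_array(Z).size:
            zparts.append(_as_array(Z))
        Zm = np.hstack(zparts) if zparts else None
        F, p = partial_rda_test(
            Ya, _as_array(E_selected[[c]]), Zm,
            n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
        )
        rows.append({"variable": c, "F": F, "p": p})
    out = pd.DataFrame(rows)
    tot = out["F"].sum()
    out["share"] = out["F"] / tot if tot > 0 else 1.0 / len(out)
    return out
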