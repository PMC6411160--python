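"""Correspondence analysis (reciprocal averaging) and matrix ordering.

The site-by-species matrix is ordinated by correspondence analysis so
that neighbouring rows hold sites of similar composition and
neighbouring columns hold species of similar distribution.  Computation
is by singular value decomposition of the chi-square standardized
correspondence matrix, which is algebraically equivalent to iterating
the classic reciprocal-averaging scheme to its fixed point; tests verify
the two routes against each other.

Scaling is row-principal: site scores are the weighted averages of the
(standard) species scores, matching the reciprocal-averaging semantics
used for ordering the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_types import EnvironmentTable, SiteBySpeciesMatrix

__all__ = [
    "OrdinationResult",
    "DegenerateOrdinationError",
    "correspondence_analysis",
    "order_matrix",
    "axis_environment_correlation",
]


class DegenerateOrdinationError(ValueError):
    """Raised when the table carries no inertia (e.g. identical rows)."""


@dataclass
class OrdinationResult:
    """Scores and inertia decomposition of a correspondence analysis.

    ``site_scores`` are row-principal coordinates, ``species_scores``
    column-standard coordinates; axes are ordered by decreasing
    eigenvalue and ``inertia_fraction`` sums to one over the full
    spectrum (of which only ``n_axes`` score columns are retained).
    """

    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    eigenvalues: np.ndarray
    inertia_fraction: np.ndarray
    total_inertia: float
    dropped_sites: list = field(default_factory=list)
    dropped_species: list = field(default_factory=list)

    @property
    def n_axes(self) -> int:
        return self.site_scores.shape[1]


def _ca_scores_array(
    arr: np.ndarray, n_axes: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CA on a dense non-negative array with positive margins.

    Returns (row principal scores, column standard scores, eigenvalues of
    the full spectrum).  Sign convention: the first nonzero column
    loading of each axis is positive.
    """
    total = arr.sum()
    if total <= 0:
        raise DegenerateOrdinationError("matrix has zero grand total")
    P = arr / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    # chi-square standardized residuals of the independence model
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    eig = sv**2
    if eig.sum() <= 1e-12:
        raise DegenerateOrdinationError("zero total inertia")
    k = min(n_axes, len(sv))
    col_std = Vt[:k].T / np.sqrt(c)[:, None]
    # row principal = weighted average of column standard scores
    row_prin = (P / r[:, None]) @ col_std
    for a in range(k):
        nz = np.nonzero(np.abs(col_std[:, a]) > 1e-12)[0]
        if len(nz) and col_std[nz[0], a] < 0:
            col_std[:, a] *= -1
            row_prin[:, a] *= -1
    return row_prin, col_std, eig


def correspondence_analysis(
    m: SiteBySpeciesMatrix,
    n_axes: int = 2,
    anchor: pd.Series | None = None,
) -> OrdinationResult:
    """Correspondence analysis of a non-negative site-by-species table.

    Empty rows and columns are dropped before the analysis (with a
    warning) and reported as unscored.  When ``anchor`` (a per-site
    covariate such as species richness) is supplied, each axis is
    oriented so that its correlation with the anchor is positive; this
    gives the latent gradient a reproducible direction.

    Raises
    ------
    DegenerateOrdinationError
        If fewer than two non-empty rows or columns remain, or the table
        carries no inertia.
    """
    df = m.values
    row_ok = df.sum(axis=1) > 0
    col_ok = df.sum(axis=0) > 0
    dropped_sites = list(df.index[~row_ok])
    dropped_species = list(df.columns[~col_ok])
    if dropped_sites or dropped_species:
        warnings.warn(
            f"dropping {len(dropped_sites)} empty site(s) and "
            f"{len(dropped_species)} empty species before ordination",
            stacklevel=2,
        )
    sub = df.loc[row_ok, col_ok]
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        raise DegenerateOrdinationError(
            "need at least 2 non-empty rows and columns"
        )
    arr = sub.to_numpy(dtype=float)
    row_prin, col_std, eig = _ca_scores_array(arr, n_axes)
    k = row_prin.shape[1]
    site_scores = pd.DataFrame(
        row_prin, index=sub.index, columns=[f"axis{i+1}" for i in range(k)]
    )
    species_scores = pd.DataFrame(
        col_std, index=sub.columns, columns=site_scores.columns
    )
    if anchor is not None:
        a = anchor.reindex(site_scores.index).to_numpy(dtype=float)
        if np.std(a) > 0:
            for col in site_scores.columns:
                r_ = np.corrcoef(site_scores[col].to_numpy(), a)[0, 1]
                if np.isfinite(r_) and r_ < 0:
                    site_scores[col] *= -1
                    species_scores[col] *= -1
    total = float(eig.sum())
    return OrdinationResult(
        site_scores=site_scores,
        species_scores=species_scores,
        eigenvalues=eig,
        inertia_fraction=eig / total,
        total_inertia=total,
        dropped_sites=dropped_sites,
        dropped_species=dropped_species,
    )


def order_matrix(
    m: SiteBySpeciesMatrix, ordination: OrdinationResult, axis: int = 1
) -> SiteBySpeciesMatrix:
    """Reorder sites and species along one ordination axis.

    Rows are sorted by site score and columns by species score on the
    chosen (1-based) axis with a stable sort, so ties keep their
    original relative order.  Unscored (empty) rows/columns are appended
    at the end in their original order.
    """
    col = f"axis{axis}"
    if col not in ordination.site_scores.columns:
        raise ValueError(f"axis {axis} not present in ordination result")
    site_order = list(
        ordination.site_scores[col].sort_values(kind="stable").index
    )
    species_order = list(
        ordination.species_scores[col].sort_values(kind="stable").index
    )
    site_order += [s for s in m.values.index if s not in set(site_order)]
    species_order += [s for s in m.values.columns if s not in set(species_order)]
    return SiteBySpeciesMatrix(
        m.values.loc[site_order, species_order], mode=m.mode
    )


def axis_environment_correlation(
    ordination: OrdinationResult,
    env: EnvironmentTable | pd.DataFrame,
    richness: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson correlation of ordination axes with measured predictors.

    Returns a long table with columns ``axis``, ``predictor``, ``r`` and
    ``p`` (two-sided).  The per-site species-richness gradient is
    appended as predictor ``"richness"`` when supplied.  Pairs are
    evaluated on sites with finite values in both series; fewer than
    three overlapping sites is an error.
    """
    frame = env.predictor_frame() if isinstance(env, EnvironmentTable) else env
    frame = frame.copy()
    if richness is not None:
        frame["richness"] = richness
    scores = ordination.site_scores
    common = scores.index.intersection(frame.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 overlapping sites")
    rows = []
    for ax_i, ax_col in enumerate(scores.columns, start=1):
        s = scores.loc[common, ax_col].to_numpy(dtype=float)
        for pred in frame.columns:
            v = frame.loc[common, pred].to_numpy(dtype=float)
            ok = np.isfinite(v) & np.isfinite(s)
            if ok.sum() < 3 or np.std(v[ok]) == 0 or np.std(s[ok]) == 0:
                r_, p_ = np.nan, np.nan
            else:
                r_, p_ = stats.pearsonr(s[ok], v[ok])
            rows.append(
                {"axis": ax_i, "predictor": pred, "r": r_, "p": p_}
            )
    return pd.DataFrame(rows)
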