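"""Elements of Metacommunity Structure (EMS).

Implements the Leibold–Mikkelson / Presley analysis of an ordinated
incidence matrix through three indices:

* **coherence** — the number of embedded absences (gaps strictly inside
  a species' range along the site ordering); fewer gaps than expected
  under the null indicates species responding to a common gradient,
  more gaps a checkerboard of mutual exclusions;
* **species turnover** — the number of replacements, counted over every
  pair of sites and pair of species on the range-filled matrix; fewer
  replacements than expected indicates nestedness;
* **boundary clumping** — Morisita's index of dispersion of the range
  boundaries across sites; clumped boundaries (M > 1) indicate groups
  of species sharing range limits (Clementsian), independent boundaries
  (M near 1) individualistic Gleasonian ranges, over-dispersed
  boundaries (M < 1) evenly spaced ranges.

Coherence and turnover are judged against a Monte-Carlo null in which
each site keeps its observed richness but draws species with
probability proportional to their overall occurrence frequency (sites
differ in suitability; common species are common everywhere).  Each
null replicate is re-ordinated by its own correspondence analysis
before the indices are recomputed, mirroring the treatment of the
observed matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_types import SiteBySpeciesMatrix
from .ordination import DegenerateOrdinationError, _ca_scores_array

__all__ = [
    "NullModelSpec",
    "EMSResult",
    "embedded_absences",
    "fill_ranges",
    "turnover_replacements",
    "morisita_boundary_index",
    "morisita_index",
    "null_metacommunities",
    "ems_analysis",
    "classify_structure",
]


@dataclass
class NullModelSpec:
    """Null model configuration.

    ``fixed_richness_proportional``: every replicate preserves each
    site's observed richness exactly while species are drawn without
    replacement with probability proportional to their occurrence
    frequency.  200 iterations is the conventional default.
    """

    algorithm: str = "fixed_richness_proportional"
    iterations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm != "fixed_richness_proportional":
            raise ValueError(f"unknown null algorithm {self.algorithm!r}")
        if self.iterations < 2:
            raise ValueError("need at least 2 null iterations")


@dataclass
class EMSResult:
    """The ten null-model statistics plus the structure label.

    Field names follow the conventional index table: ``Abs`` embedded
    absences with p-value ``Apr`` and null moments ``MA``/``SA``;
    ``Re`` replacements with ``Rpr``/``MR``/``SR``; Morisita index ``M``
    with ``Mpr``.  ``Apr`` and ``Rpr`` are two-tailed normal-deviate
    p-values; exact Monte-Carlo counterparts are reported alongside.
    """

    Abs: int
    Apr: float
    MA: float
    SA: float
    Re: int
    Rpr: float
    MR: float
    SR: float
    M: float
    Mpr: float
    z_coherence: float
    z_turnover: float
    label: str
    axis: int = 1
    p_coherence_mc: float = float("nan")
    p_turnover_mc: float = float("nan")
    n_null: int = 0

    def to_dict(self) -> dict:
        return {
            "Abs": self.Abs, "Apr": self.Apr, "MA": self.MA, "SA": self.SA,
            "Re": self.Re, "Rpr": self.Rpr, "MR": self.MR, "SR": self.SR,
            "M": self.M, "Mpr": self.Mpr,
            "z_coherence": self.z_coherence, "z_turnover": self.z_turnover,
            "label": self.label, "axis": self.axis,
            "p_coherence_mc": self.p_coherence_mc,
            "p_turnover_mc": self.p_turnover_mc, "n_null": self.n_null,
        }


# ---------------------------------------------------------------------------
# index primitives (array fast paths + container wrappers)
# ---------------------------------------------------------------------------

def _as_incidence_array(m: SiteBySpeciesMatrix | np.ndarray) -> np.ndarray:
    if isinstance(m, SiteBySpeciesMatrix):
        if m.mode != "incidence":
            raise ValueError("EMS indices require an incidence matrix")
        return m.to_numpy()
    return np.asarray(m, dtype=float)


def _embedded_absences_array(arr: np.ndarray) -> int:
    """Gaps strictly inside each species' range along the row order.

    Counted over species columns only (ranges along the site ordering),
    per the Leibold–Mikkelson operationalization.
    """
    total = 0
    for j in range(arr.shape[1]):
        occ = np.nonzero(arr[:, j] > 0)[0]
        if len(occ) == 0:
            continue
        total += int(occ[-1] - occ[0] + 1 - len(occ))
    return total


def embedded_absences(m: SiteBySpeciesMatrix | np.ndarray) -> int:
    """Total embedded absences of an ordered incidence matrix.

    Species with no occurrences contribute zero (with a warning when a
    container is passed).
    """
    arr = _as_incidence_array(m)
    if isinstance(m, SiteBySpeciesMatrix):
        empty = (arr.sum(axis=0) == 0).sum()
        if empty:
            warnings.warn(
                f"{int(empty)} species with no occurrences contribute 0",
                stacklevel=2,
            )
    return _embedded_absences_array(arr)


def _fill_ranges_array(arr: np.ndarray) -> np.ndarray:
    out = arr.copy()
    for j in range(arr.shape[1]):
        occ = np.nonzero(arr[:, j] > 0)[0]
        if len(occ):
            out[occ[0]: occ[-1] + 1, j] = 1.0
    return out


def fill_ranges(m: SiteBySpeciesMatrix) -> SiteBySpeciesMatrix:
    """Set embedded absences to presences (contiguous species ranges)."""
    arr = _fill_ranges_array(_as_incidence_array(m))
    return SiteBySpeciesMatrix(
        pd.DataFrame(arr, index=m.values.index, columns=m.values.columns),
        mode="incidence",
    )


def _turnover_array(arr: np.ndarray) -> int:
    """Replacements over all site pairs and species pairs, filled ranges."""
    F = _fill_ranges_array(arr)
    # A[i, j] = number of sites holding species i but not species j
    A = F.T @ (1.0 - F)
    prod = A * A.T
    return int(round(np.triu(prod, k=1).sum()))


def turnover_replacements(m: SiteBySpeciesMatrix | np.ndarray) -> int:
    """Species turnover: count of checkerboard replacements.

    Ranges are filled first; then for every unordered pair of species
    (i, j) and unordered pair of sites (a, b), one replacement is
    counted when i occurs only at a and j only at b.
    """
    return _turnover_array(_as_incidence_array(m))


def _boundary_counts(arr: np.ndarray) -> np.ndarray:
    """Number of species range boundaries at each ordered site."""
    F = _fill_ranges_array(arr)
    counts = np.zeros(arr.shape[0])
    for j in range(F.shape[1]):
        occ = np.nonzero(F[:, j] > 0)[0]
        if len(occ) == 0:
            continue
        counts[occ[0]] += 1
        counts[occ[-1]] += 1
    return counts


def morisita_index(counts: np.ndarray) -> float:
    """Morisita's index of dispersion of counts over units.

    I_d = n * sum f(f-1) / (F(F-1)); 1 for random placement, > 1 for
    clumped counts, < 1 for over-dispersed counts.
    """
    f = np.asarray(counts, dtype=float)
    n = len(f)
    F = f.sum()
    if F < 2:
        return float("nan")
    return n * float((f * (f - 1)).sum()) / (F * (F - 1))


def morisita_boundary_index(
    m: SiteBySpeciesMatrix | np.ndarray,
) -> tuple[float, float]:
    """Morisita index of dispersion of range boundaries, with p-value.

    Each species contributes its first and last occurrence (on filled
    ranges) as boundaries; the per-site boundary counts f_i are then
    scored with Morisita's index I_d = n * sum f(f-1) / (F(F-1)).
    Significance is from the large-sample chi-square statistic
    I_d*(F-1) + n - F on n-1 degrees of freedom (two-tailed), testing
    departure from randomly placed boundaries.
    """
    arr = _as_incidence_array(m)
    f = _boundary_counts(arr)
    n = len(f)
    F = f.sum()
    if F < 2 or n < 2:
        return float("nan"), float("nan")
    Id = morisita_index(f)
    chi2 = Id * (F - 1) + n - F
    cdf = stats.chi2.cdf(chi2, df=n - 1)
    p = float(2 * min(cdf, 1 - cdf))
    if (f > 0).sum() == 1:
        warnings.warn("all range boundaries fall on a single site", stacklevel=2)
    return float(Id), min(p, 1.0)


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------

def _null_replicates_array(
    arr: np.ndarray, iterations: int, rng: np.random.Generator
) -> list[np.ndarray]:
    n, s = arr.shape
    occ = arr.sum(axis=0)
    if occ.sum() == 0:
        raise ValueError("empty matrix has no occurrence weights")
    weights = occ / occ.sum()
    richness = arr.sum(axis=1).astype(int)
    pool = int((occ > 0).sum())
    if richness.max(initial=0) > pool:
        raise ValueError("site richness exceeds species pool with weight > 0")
    reps = []
    for _ in range(iterations):
        rep = np.zeros((n, s))
        for i in range(n):
            k = richness[i]
            if k:
                idx = rng.choice(s, size=k, replace=False, p=weights)
                rep[i, idx] = 1.0
        reps.append(rep)
    return reps


def null_metacommunities(
    m: SiteBySpeciesMatrix, spec: NullModelSpec
) -> list[SiteBySpeciesMatrix]:
    """Draw fixed-richness, proportional-occurrence null matrices.

    Every replicate preserves each site's richness exactly; species are
    drawn without replacement with probability proportional to their
    observed occurrence frequency.  Reproducible under ``spec.seed``.
    """
    arr = _as_incidence_array(m)
    rng = np.random.default_rng(spec.seed)
    return [
        SiteBySpeciesMatrix(
            pd.DataFrame(r, index=m.values.index, columns=m.values.columns),
            mode="incidence",
        )
        for r in _null_replicates_array(arr, spec.iterations, rng)
    ]


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

def _ordinated_array(arr: np.ndarray, axis: int) -> np.ndarray:
    """Drop empty margins, ordinate by CA, return the reordered array."""
    row_ok = arr.sum(axis=1) > 0
    col_ok = arr.sum(axis=0) > 0
    sub = arr[np.ix_(row_ok, col_ok)]
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        raise DegenerateOrdinationError("too few non-empty rows/columns")
    row_sc, col_sc, _ = _ca_scores_array(sub, axis)
    if row_sc.shape[1] < axis:
        raise DegenerateOrdinationError(f"axis {axis} unavailable")
    ri = np.argsort(row_sc[:, axis - 1], kind="stable")
    ci = np.argsort(col_sc[:, axis - 1], kind="stable")
    return sub[np.ix_(ri, ci)]


def _two_tailed(observed: float, null: np.ndarray) -> tuple[float, float, float, float]:
    mu = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd == 0:
        z = 0.0 if observed == mu else float(np.sign(observed - mu)) * np.inf
    else:
        z = (observed - mu) / sd
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return mu, sd, z, min(p, 1.0)


def ems_analysis(
    m: SiteBySpeciesMatrix,
    axis: int = 1,
    spec: NullModelSpec | None = None,
    alpha: float = 0.05,
) -> EMSResult:
    """Full EMS analysis of an incidence matrix on one ordination axis.

    The observed matrix is ordinated by correspondence analysis, the
    three indices computed on the ordered matrix, and coherence and
    turnover compared against the null distribution obtained by
    re-ordinating every null replicate individually.  The structure
    label follows the Presley decision tree (see
    :func:`classify_structure`); a degenerate ordination yields the
    label ``"undefined"``.
    """
    if spec is None:
        spec = NullModelSpec()
    arr = _as_incidence_array(m)
    try:
        ordered = _ordinated_array(arr, axis)
    except DegenerateOrdinationError as exc:
        warnings.warn(f"degenerate ordination: {exc}", stacklevel=2)
        nan = float("nan")
        return EMSResult(0, nan, nan, nan, 0, nan, nan, nan, nan, nan,
                         nan, nan, "undefined", axis=axis)
    obs_abs = _embedded_absences_array(ordered)
    obs_re = _turnover_array(ordered)
    M, Mpr = morisita_boundary_index(ordered)

    rng = np.random.default_rng(spec.seed)
    null_abs, null_re = [], []
    for rep in _null_replicates_array(arr, spec.iterations, rng):
        try:
            rep_ord = _ordinated_array(rep, axis)
        except DegenerateOrdinationError:
            continue
        null_abs.append(_embedded_absences_array(rep_ord))
        null_re.append(_turnover_array(rep_ord))
    null_abs = np.array(null_abs, dtype=float)
    null_re = np.array(null_re, dtype=float)
    if len(null_abs) < 2:
        raise RuntimeError("all null replicates degenerate")

    MA, SA, z_abs, Apr = _two_tailed(obs_abs, null_abs)
    p_abs_mc = (
        np.sum(np.abs(null_abs - MA) >= abs(obs_abs - MA)) + 1
    ) / (len(null_abs) + 1)
    MR, SR, z_re, Rpr = _two_tailed(obs_re, null_re)
    p_re_mc = (
        np.sum(np.abs(null_re - MR) >= abs(obs_re - MR)) + 1
    ) / (len(null_re) + 1)

    label = classify_structure(z_abs, Apr, z_re, Rpr, M, Mpr, alpha=alpha)
    return EMSResult(
        Abs=int(obs_abs), Apr=Apr, MA=MA, SA=SA,
        Re=int(obs_re), Rpr=Rpr, MR=MR, SR=SR,
        M=M, Mpr=Mpr, z_coherence=z_abs, z_turnover=z_re,
        label=label, axis=axis,
        p_coherence_mc=float(p_abs_mc), p_turnover_mc=float(p_re_mc),
        n_null=len(null_abs),
    )


def classify_structure(
    coherence_z: float,
    coherence_p: float,
    turnover_z: float,
    turnover_p: float,
    morisita: float,
    morisita_p: float,
    alpha: float = 0.05,
) -> str:
    """Presley decision tree over the three EMS indices.

    Coherence first: significantly *more* embedded absences than the
    null (positive z on Abs) is a checkerboard; non-significant is
    random.  Within coherent metacommunities (significantly fewer
    absences), significantly negative turnover is nested; significant
    positive turnover is resolved by boundary clumping into Clementsian
    (clumped), Gleasonian (independent) or evenly spaced (over-
    dispersed) ranges.  Non-significant turnover yields the
    corresponding ``quasi_`` structure, directed by the sign of the
    turnover deviate.
    """
    if not np.isfinite(coherence_z) or not np.isfinite(coherence_p):
        return "undefined"
    if coherence_p > alpha:
        return "random"
    if coherence_z > 0:
        return "checkerboard"
    # coherent: fewer embedded absences than expected
    def _by_clumping(prefix: str = "") -> str:
        if np.isfinite(morisita_p) and morisita_p <= alpha:
            return prefix + ("clementsian" if morisita > 1 else "evenly_spaced")
        return prefix + "gleasonian"

    significant_turn = np.isfinite(turnover_p) and turnover_p <= alpha
    if significant_turn:
        if turnover_z < 0:
            return "nested"
        return _by_clumping()
    if np.isfinite(turnover_z) and turnover_z < 0:
        return "quasi_nested"
    return _by_clumping("quasi_")
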