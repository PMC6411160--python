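"""Core data containers, readers and elementary transforms.

Every stage of the pipeline speaks in terms of a small set of tabular
containers: a long-format survey table (one row per site x year x session),
a site-by-species matrix (abundance or incidence), per-grain environment
tables, site coordinates, and the tree-cover gradient used for landscape
classification.  All containers wrap :class:`pandas.DataFrame` so that the
usual indexing, joining and CSV round-tripping behaviour applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurveyTable",
    "SiteBySpeciesMatrix",
    "EnvironmentTable",
    "Coordinates",
    "TreeCoverGradient",
    "read_survey_table",
    "pool_surveys",
    "to_incidence",
    "hellinger_transform",
]

#: Buffer radii (metres) at which environmental predictors are measured.
VALID_GRAINS = (200, 400, 600, 800, 1000, 1200, 1400)

_KEY_COLUMNS = ("site_id", "year", "session")


@dataclass
class SurveyTable:
    """Long-format point-count table: one row per (site, year, session).

    Parameters
    ----------
    data
        DataFrame with columns ``site_id``, ``year``, ``session`` followed
        by one non-negative integer abundance column per species.  Column
        order of the species block is preserved throughout the pipeline.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _KEY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"survey table missing key columns: {missing}")
        if not self.species:
            raise ValueError("survey table has no species columns")
        dup = self.data.duplicated(subset=list(_KEY_COLUMNS))
        if dup.any():
            bad = self.data.loc[dup, list(_KEY_COLUMNS)].iloc[0].tolist()
            raise ValueError(f"duplicated (site, year, session) row: {bad}")
        block = self.data[self.species]
        if (block.to_numpy() < 0).any():
            raise ValueError("negative abundances in survey table")

    @property
    def species(self) -> list[str]:
        return [c for c in self.data.columns if c not in _KEY_COLUMNS]

    @property
    def sites(self) -> list:
        return list(pd.unique(self.data["site_id"]))

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class SiteBySpeciesMatrix:
    """Sites x species table of abundances or occurrences.

    ``values`` is indexed by site identifier with one column per species.
    ``mode`` is ``"abundance"`` (non-negative reals) or ``"incidence"``
    (strictly 0/1).
    """

    values: pd.DataFrame
    mode: str = "abundance"

    def __post_init__(self) -> None:
        if self.mode not in ("abundance", "incidence"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicated site identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicated species identifiers")
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("negative values in site-by-species matrix")
        if self.mode == "incidence" and not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError("incidence matrix must contain only 0/1")

    @property
    def site_ids(self) -> list:
        return list(self.values.index)

    @property
    def species_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def richness(self) -> pd.Series:
        """Species count per site (presences, regardless of mode)."""
        return (self.values > 0).sum(axis=1)


@dataclass
class EnvironmentTable:
    """Per-site landscape predictors at one buffer grain.

    Columns follow the ``<category>_M`` / ``<category>_CV`` convention:
    the mean and the coefficient of variation of each land-use variable
    over the study years.  A CV is undefined (NaN) wherever the mean is
    zero; such columns are excluded from predictor sets downstream.
    """

    grain: int
    data: pd.DataFrame  # indexed by site_id

    def __post_init__(self) -> None:
        if self.grain not in VALID_GRAINS:
            raise ValueError(f"grain {self.grain} not in {VALID_GRAINS}")
        cv_cols = [c for c in self.data.columns if c.endswith("_CV")]
        cv = self.data[cv_cols].to_numpy(dtype=float)
        if np.nanmin(cv, initial=0.0) < 0:
            raise ValueError("negative CV values")

    def predictor_frame(self, drop_all_nan: bool = True) -> pd.DataFrame:
        """Numeric predictors with all-missing columns removed."""
        df = self.data.select_dtypes(include=[np.number])
        if drop_all_nan:
            df = df.dropna(axis=1, how="all")
        return df


@dataclass
class Coordinates:
    """Projected (metric) site coordinates, one row per site."""

    data: pd.DataFrame  # indexed by site_id, columns x, y

    def __post_init__(self) -> None:
        for c in ("x", "y"):
            if c not in self.data.columns:
                raise ValueError(f"coordinates missing column {c!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicated site identifiers in coordinates")
        if not np.isfinite(self.data[["x", "y"]].to_numpy(dtype=float)).all():
            raise ValueError("non-finite coordinates")

    def xy(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)


@dataclass
class TreeCoverGradient:
    """Fraction of a 200 m buffer covered by forest plus widened hedgerows."""

    data: pd.Series  # indexed by site_id, values in [0, 1]

    def __post_init__(self) -> None:
        v = self.data.to_numpy(dtype=float)
        if ((v < 0) | (v > 1)).any():
            raise ValueError("tree-cover fractions must lie in [0, 1]")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_survey_table(
    path: str | Path,
    site_col: str = "site_id",
    year_col: str = "year",
    session_col: str = "session",
    species_cols: Sequence[str] | None = None,
) -> SurveyTable:
    """Read a survey table from delimited text or an XLS/XLSX workbook.

    CSV/TSV input is delimiter-sniffed and must carry a header row.  For
    spreadsheet input the station-database layout is accepted, where the
    site column is named ``IdPoint``; columns that are neither keys nor
    listed species are dropped with a warning unless ``species_cols``
    restricts the species block explicitly.
    """
    path = Path(path)
    if path.suffix.lower() in (".xls", ".xlsx"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    rename = {}
    for want, aliases in (
        (site_col, ("IdPoint", "idpoint", "site", "site_id")),
        (year_col, ("Year", "year", "annee")),
        (session_col, ("Session", "session")),
    ):
        if want not in df.columns:
            for a in aliases:
                if a in df.columns:
                    rename[a] = want
                    break
    df = df.rename(columns=rename)
    df = df.rename(
        columns={site_col: "site_id", year_col: "year", session_col: "session"}
    )
    if species_cols is not None:
        keep = list(_KEY_COLUMNS) + list(species_cols)
        df = df[keep]
    return SurveyTable(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------

def pool_surveys(table: SurveyTable) -> SiteBySpeciesMatrix:
    """Pool repeated counts per station into mean abundances.

    Each station is surveyed ``n_years x n_sessions`` times; the pooled
    value for a species at a station is the arithmetic mean of its counts
    over all surveys of that station.
    """
    if len(table) == 0:
        raise ValueError("empty survey table")
    pooled = (
        table.data.groupby("site_id", sort=False)[table.species].mean()
    )
    return SiteBySpeciesMatrix(pooled, mode="abundance")


def to_incidence(
    m: SiteBySpeciesMatrix, threshold: float = 0.0
) -> SiteBySpeciesMatrix:
    """Convert abundances to presence/absence.

    A species is scored present at a site when its (mean) abundance
    exceeds ``threshold``; the default of zero marks any detection as a
    presence.  Idempotent on incidence input.
    """
    if m.mode == "incidence":
        return SiteBySpeciesMatrix(m.values.copy(), mode="incidence")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    inc = (m.values > threshold).astype(float)
    return SiteBySpeciesMatrix(inc, mode="incidence")


def hellinger_transform(m: SiteBySpeciesMatrix) -> SiteBySpeciesMatrix:
    """Hellinger transformation: sqrt of relative abundance per site.

    y'_ij = sqrt(y_ij / sum_j y_ij).  Rows with zero total are mapped to
    zero rows and reported with a warning; every non-empty transformed
    row has unit Euclidean norm, which makes Euclidean-based ordination
    (RDA, PCA) appropriate for sparse count data.
    """
    if m.mode != "abundance":
        raise ValueError("Hellinger transform expects an abundance matrix")
    arr = m.to_numpy()
    row_sums = arr.sum(axis=1)
    empty = row_sums == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} empty site row(s) mapped to zeros in "
            "Hellinger transform",
            stacklevel=2,
        )
    safe = np.where(empty, 1.0, row_sums)
    out = np.sqrt(arr / safe[:, None])
    out[empty] = 0.0
    return SiteBySpeciesMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        mode="abundance",
    )
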