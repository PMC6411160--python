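"""Deconstruction of the analysis by species group and landscape class.

Species are clustered into three classes from their position along the
first ordination axis (which tracks the tree-cover gradient), and sites
are binned into open / intermediate / wooded landscapes by the fraction
of tree cover in a 200 m buffer.  The EMS and variation-partitioning
stages are then re-run inside each class to reveal drivers that the
pooled analysis masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .io_types import SiteBySpeciesMatrix, TreeCoverGradient
from .ordination import OrdinationResult

__all__ = [
    "SpeciesClassAssignment",
    "LandscapeClassAssignment",
    "cluster_species",
    "classify_landscape",
]

SPECIES_CLASS_LABELS = ("open_land", "intermediate", "woodland")
LANDSCAPE_CLASS_LABELS = ("open", "intermediate", "wooded")


@dataclass
class SpeciesClassAssignment:
    """Species membership in ordination-based habitat-use classes."""

    data: pd.DataFrame  # columns: class, axis1_score; indexed by species_id

    def members(self, cls: str) -> list:
        return list(self.data.index[self.data["class"] == cls])

    def sizes(self) -> dict[str, int]:
        return self.data["class"].value_counts().to_dict()


@dataclass
class LandscapeClassAssignment:
    """Site membership in tree-cover landscape classes."""

    data: pd.DataFrame  # columns: class, tree_cover_fraction; by site_id

    def members(self, cls: str) -> list:
        return list(self.data.index[self.data["class"] == cls])

    def sizes(self) -> dict[str, int]:
        return self.data["class"].value_counts().to_dict()


def cluster_species(
    ordination: OrdinationResult,
    k: int = 3,
    method: str = "complete",
) -> SpeciesClassAssignment:
    """Hierarchical clustering of species along the first ordination axis.

    Axis-1 species scores are turned into pairwise Euclidean distances,
    a dendrogram is built (complete linkage by default; Ward available
    via ``method``) and cut at the ``k``-cluster level.  Classes are
    labelled by ascending mean axis score: with the axis oriented along
    the tree-cover gradient the lowest-scoring class holds the
    open-land species and the highest the woodland species.
    """
    scores = ordination.species_scores["axis1"]
    if len(scores) < k:
        raise ValueError(f"need at least {k} species with axis-1 scores")
    vals = scores.to_numpy(dtype=float)[:, None]
    if np.allclose(vals, vals[0]):
        raise ValueError("all species scores identical; clustering degenerate")
    Z = linkage(pdist(vals), method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    means = {c: vals[raw == c, 0].mean() for c in np.unique(raw)}
    order = sorted(means, key=means.get)
    if k == 3:
        names = dict(zip(order, SPECIES_CLASS_LABELS))
    else:
        names = {c: f"class_{i+1}" for i, c in enumerate(order)}
    out = pd.DataFrame(
        {"class": [names[c] for c in raw], "axis1_score": vals[:, 0]},
        index=scores.index,
    )
    return SpeciesClassAssignment(out)


def classify_landscape(
    gradient: TreeCoverGradient,
    boundaries: tuple[float, float] = (0.35, 0.70),
) -> LandscapeClassAssignment:
    """Bin sites by tree-cover fraction into three landscape classes.

    Half-open binning: [0, b1) open, [b1, b2) intermediate, [b2, 1]
    wooded, so a site exactly at a boundary falls in the upper class.
    """
    b1, b2 = boundaries
    if not 0 < b1 < b2 <= 1:
        raise ValueError("boundaries must satisfy 0 < b1 < b2 <= 1")
    frac = gradient.data.astype(float)
    cls = np.where(
        frac < b1, LANDSCAPE_CLASS_LABELS[0],
        np.where(frac < b2, LANDSCAPE_CLASS_LABELS[1],
                 LANDSCAPE_CLASS_LABELS[2]),
    )
    out = pd.DataFrame(
        {"class": cls, "tree_cover_fraction": frac}, index=frac.index
    )
    return LandscapeClassAssignment(out)


def subset_matrix(
    m: SiteBySpeciesMatrix,
    sites: list | None = None,
    species: list | None = None,
    min_sites: int = 10,
    min_species: int = 3,
) -> SiteBySpeciesMatrix | None:
    """Restrict a matrix to a class; None when the cell is too small."""
    df = m.values
    if sites is not None:
        df = df.loc[[s for s in df.index if s in set(sites)]]
    if species is not None:
        df = df[[s for s in df.columns if s in set(species)]]
    if df.shape[0] < min_sites or df.shape[1] < min_species:
        warnings.warn(
            f"class subset {df.shape} below minimum "
            f"({min_sites} sites, {min_species} species); skipped",
            stacklevel=2,
        )
        return None
    return SiteBySpeciesMatrix(df, mode=m.mode)
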