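"""Synthetic metacommunities with known structure and variance shares.

Generates spatially explicit, temporally replicated survey data shaped
like a multi-year farmland point-count campaign: sites on a jittered
grid, a spatially autocorrelated tree-cover gradient, per-grain
land-use tables (means and coefficients of variation over years),
species occupancies arranged into one of the six idealized
metacommunity structures, and Poisson-sampled counts over years and
sessions.  Every realization records its ground truth (structure
label, group memberships, generating parameters) so each analytical
stage can be verified against what was simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_types import (
    VALID_GRAINS,
    Coordinates,
    EnvironmentTable,
    SiteBySpeciesMatrix,
    SurveyTable,
    TreeCoverGradient,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate_gradient",
    "simulate_occupancy",
    "simulate_surveys",
    "simulate_dataset",
    "community_with_shares",
]

STRUCTURES = (
    "clementsian", "gleasonian", "evenly_spaced",
    "nested", "checkerboard", "random",
)


@dataclass
class SyntheticConfig:
    """Generator settings.

    Defaults mirror the shape of a five-year, two-session farmland
    point-count campaign on 260 stations with 40 retained species: one
    station per square kilometre, a tree-cover gradient autocorrelated
    over about 2 km, and mean per-survey abundances of a few
    individuals per occupied station.  ``noise_flip`` is the per-cell
    probability that an occupancy is flipped away from the idealized
    structural template; ``beta_env``/``beta_space``/``beta_time``
    weight the environmental, purely spatial and temporal signals in
    the expected abundances.
    """

    n_sites: int = 260
    n_species: int = 40
    structure: str = "clementsian"
    n_groups: int = 3
    grid_spacing: float = 1000.0
    gradient_autocorrelation_range: float = 2000.0
    beta_env: float = 1.0
    beta_space: float = 0.0
    beta_time: float = 0.3
    noise_flip: float = 0.05
    n_years: int = 5
    n_sessions: int = 2
    mean_abundance: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.n_sessions not in (1, 2):
            raise ValueError("n_sessions must be 1 or 2")
        for w in (self.beta_env, self.beta_space, self.beta_time):
            if w < 0:
                raise ValueError("signal weights must be non-negative")


@dataclass
class SyntheticDataset:
    """A full realization plus its ground truth."""

    config: SyntheticConfig
    coordinates: Coordinates
    tree_cover: TreeCoverGradient
    environment: dict[int, EnvironmentTable]
    occupancy: SiteBySpeciesMatrix
    surveys: SurveyTable
    truth: dict


# ---------------------------------------------------------------------------
# gradient and environment
# ---------------------------------------------------------------------------

def _site_ids(n: int) -> list[str]:
    return [f"S{i+1:03d}" for i in range(n)]


def simulate_gradient(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[Coordinates, TreeCoverGradient, dict[int, EnvironmentTable]]:
    """Coordinates, tree-cover field and per-grain environment tables.

    Sites sit on a jittered square grid (one per ``grid_spacing``
    square).  Tree cover is a Gaussian random field with exponential
    covariance ``exp(-d / range)`` squashed through the normal CDF, so
    its marginal is near-uniform on [0, 1] while staying spatially
    autocorrelated.  Land-use areas per category are drawn per site and
    per year (crops trade off against the wooded component), giving
    non-degenerate coefficients of variation; predictors at larger
    grains are distance-weighted local averages of the 200 m values, so
    coarse-grain fields are smoother than fine-grain ones.
    """
    if cfg.n_sites < 20:
        raise ValueError("need at least 20 sites")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    ids = _site_ids(cfg.n_sites)

    side = int(np.ceil(np.sqrt(cfg.n_sites)))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    pts = np.column_stack([gx.ravel(), gy.ravel()])[: cfg.n_sites].astype(float)
    xy = pts * cfg.grid_spacing + rng.uniform(
        -0.3 * cfg.grid_spacing, 0.3 * cfg.grid_spacing, size=(cfg.n_sites, 2)
    )
    coords = Coordinates(pd.DataFrame(xy, index=ids, columns=["x", "y"]))

    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    cov = np.exp(-d / cfg.gradient_autocorrelation_range)
    L = np.linalg.cholesky(cov + 1e-8 * np.eye(cfg.n_sites))
    z = L @ rng.standard_normal(cfg.n_sites)
    from scipy.stats import norm

    tree = norm.cdf(z / np.sqrt(np.diag(cov)))
    gradient = TreeCoverGradient(pd.Series(tree, index=ids, name="tree_cover"))

    crop_names = ["alfalfa", "grassland", "rapeseed", "cereals", "maize",
                  "sunflower", "urban"]
    env: dict[int, EnvironmentTable] = {}
    base_crop_w = rng.dirichlet(np.ones(len(crop_names)) * 2.0,
                                size=cfg.n_sites)
    for grain in VALID_GRAINS:
        # coarse grains: distance-weighted smoothing of the 200 m field
        w = np.exp(-(d / max(grain, 200.0)) ** 2)
        w /= w.sum(axis=1, keepdims=True)
        tree_g = w @ tree
        area = np.pi * grain**2
        cols: dict[str, np.ndarray] = {}
        per_year = {}
        for name_i, name in enumerate(crop_names):
            yearly = []
            for _ in range(cfg.n_years):
                frac = base_crop_w[:, name_i] * (1.0 - tree_g)
                frac = frac * np.exp(rng.normal(0.0, 0.3, size=cfg.n_sites))
                yearly.append(frac * area)
            per_year[name] = np.column_stack(yearly)
        hedww = 0.6 * tree_g
        forww = 0.4 * tree_g
        per_year["hedgerows"] = np.column_stack([
            hedww * area * np.exp(rng.normal(0, 0.05, cfg.n_sites))
            for _ in range(cfg.n_years)
        ])
        per_year["forest"] = np.column_stack([
            forww * area * np.exp(rng.normal(0, 0.05, cfg.n_sites))
            for _ in range(cfg.n_years)
        ])
        per_year["roads"] = np.column_stack([
            rng.gamma(4.0, grain / 2.0, cfg.n_sites)
            for _ in range(cfg.n_years)
        ])
        for name, Y in per_year.items():
            mean = Y.mean(axis=1)
            sd = Y.std(axis=1, ddof=1)
            cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
            cols[f"{name}_M"] = mean
            cols[f"{name}_CV"] = cv
        env[grain] = EnvironmentTable(
            grain=grain, data=pd.DataFrame(cols, index=ids)
        )
    return coords, gradient, env


# ---------------------------------------------------------------------------
# occupancy under the six idealized structures
# ---------------------------------------------------------------------------

def _flatten_cooccurrence(
    occ: np.ndarray, rng: np.random.Generator, n_swaps: int
) -> np.ndarray:
    """Equalize pairwise species co-occurrence by margin-preserving swaps.

    Greedy swaps of 2x2 checkerboard units (which preserve both site
    richness and species totals) are accepted when they reduce the
    variance of the off-diagonal co-occurrence counts.  The result is a
    maximally over-dispersed co-occurrence structure at the given
    margins — diffuse exclusion with no residual association for an
    ordination to exploit.
    """
    occ = occ.copy()
    n, s = occ.shape
    C = occ.T @ occ
    # the sum over pairs is fixed by the site-richness margins, so
    # minimizing the sum of squares minimizes the variance
    for _ in range(n_swaps):
        i1, i2 = rng.integers(n, size=2)
        if i1 == i2:
            continue
        a = np.nonzero((occ[i1] == 1) & (occ[i2] == 0))[0]
        b = np.nonzero((occ[i1] == 0) & (occ[i2] == 1))[0]
        if len(a) == 0 or len(b) == 0:
            continue
        j1 = a[rng.integers(len(a))]
        j2 = b[rng.integers(len(b))]
        old_sq = float((C[j1] ** 2).sum() + (C[j2] ** 2).sum()
                       - C[j1, j2] ** 2 - C[j1, j1] ** 2 - C[j2, j2] ** 2)
        occ[i1, j1] = 0; occ[i2, j1] = 1
        occ[i1, j2] = 1; occ[i2, j2] = 0
        new_r1 = occ[:, j1] @ occ
        new_r2 = occ[:, j2] @ occ
        new_sq = float((new_r1 ** 2).sum() + (new_r2 ** 2).sum()
                       - new_r1[j2] ** 2 - new_r1[j1] ** 2 - new_r2[j2] ** 2)
        if new_sq <= old_sq:
            C[j1, :] = new_r1; C[:, j1] = new_r1
            C[j2, :] = new_r2; C[:, j2] = new_r2
        else:
            occ[i1, j1] = 1; occ[i2, j1] = 0
            occ[i1, j2] = 0; occ[i2, j2] = 1
    return occ


def _structural_template(
    cfg: SyntheticConfig, g: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    n, s = cfg.n_sites, cfg.n_species
    occ = np.zeros((n, s))
    truth: dict = {"structure": cfg.structure}
    if cfg.structure == "clementsian":
        groups = np.repeat(np.arange(cfg.n_groups),
                           int(np.ceil(s / cfg.n_groups)))[:s]
        centers = (np.arange(cfg.n_groups) + 0.5) / cfg.n_groups
        width = 0.5 / cfg.n_groups
        for j in range(s):
            mu = centers[groups[j]]
            occ[:, j] = (np.abs(g - mu) <= width).astype(float)
        truth["groups"] = groups
        truth["centers"] = centers
    elif cfg.structure == "gleasonian":
        # individualistic ranges kept interior so edges do not pile up
        # at the ends of the gradient
        widths = rng.uniform(0.1, 0.2, s)
        mus = np.array([
            rng.uniform(widths[j] + 0.03, 0.97 - widths[j]) for j in range(s)
        ])
        for j in range(s):
            occ[:, j] = (np.abs(g - mus[j]) <= widths[j]).astype(float)
        truth["optima"] = mus
        truth["widths"] = widths
    elif cfg.structure == "evenly_spaced":
        # equal widths, evenly spaced optima: the two edge grids
        # interleave, spreading boundaries maximally
        mus = (np.arange(s) + 0.5) / s
        width = 1.6 / s
        for j in range(s):
            occ[:, j] = (np.abs(g - mus[j]) <= width).astype(float)
        truth["optima"] = mus
    elif cfg.structure == "nested":
        thresholds = np.linspace(0.03, 0.97, s)
        order = rng.permutation(s)
        for rank, j in enumerate(order):
            occ[:, j] = (g >= thresholds[rank]).astype(float)
        truth["thresholds"] = thresholds[np.argsort(order)]
    elif cfg.structure == "checkerboard":
        # community-wide competitive exclusion: species-poor sites and a
        # co-occurrence network flattened by margin-preserving swaps, so
        # that no single ordering can make ranges contiguous.  A literal
        # set of exclusive pairs is perfectly separable by one ordination
        # axis and therefore reads as coherent; the diffuse-exclusion
        # network is the configuration that produces the canonical
        # negative-coherence checkerboard.
        k_site = max(4, s // 7)
        for i in range(n):
            occ[i, rng.choice(s, k_site, replace=False)] = 1.0
        occ = _flatten_cooccurrence(occ, rng, n_swaps=40 * n)
        truth["site_richness"] = k_site
    else:  # random
        # random assembly under site-suitability and species-commonness
        # differences: each site draws its richness worth of species
        # without replacement, weighted by species commonness — the
        # no-structure hypothesis of the pattern analysis
        weights = rng.lognormal(0.0, 0.8, s)
        weights /= weights.sum()
        richness = rng.binomial(s, rng.uniform(0.25, 0.75, n))
        richness = np.clip(richness, 1, s)
        for i in range(n):
            occ[i, rng.choice(s, int(richness[i]), replace=False,
                              p=weights)] = 1.0
        truth["weights"] = weights
    return occ, truth


def simulate_occupancy(
    cfg: SyntheticConfig,
    gradient: TreeCoverGradient,
    rng: np.random.Generator | None = None,
) -> tuple[SiteBySpeciesMatrix, dict]:
    """Incidence matrix under the configured idealized structure.

    The noiseless template follows the structure exactly (shared
    Gaussian niche edges for Clementsian groups, independent niches for
    Gleasonian, threshold occupancy for nested, exclusive pairs for
    checkerboard, independent Bernoulli for random); each cell is then
    flipped with probability ``noise_flip``.  Empty rows/columns that
    noise may create are repaired deterministically (the most suitable
    cell is restored) so the matrix remains a valid ordination input.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    g = gradient.data.to_numpy(dtype=float)
    occ, truth = _structural_template(cfg, g, rng)
    template = occ.copy()
    # the random template is already a draw from the no-structure
    # hypothesis; layering observation noise on it would change its law
    if cfg.noise_flip > 0 and cfg.structure != "random":
        # asymmetric observation noise: detection dropouts anywhere at
        # rate noise_flip; stray presences are rarer and occur only as
        # spillover near a species' occupied sites along the gradient
        # (a far-flung stray would stretch the apparent range across
        # the whole gradient, which point-count noise does not do)
        n = len(g)
        rank = np.empty(n, dtype=int)
        rank[np.argsort(g, kind="stable")] = np.arange(n)
        order = np.argsort(rank)
        near = np.zeros_like(occ, dtype=bool)
        for j in range(occ.shape[1]):
            by_rank = occ[order, j] > 0
            dil = by_rank.copy()
            for shift in range(1, 4):
                dil[:-shift] |= by_rank[shift:]
                dil[shift:] |= by_rank[:-shift]
            near[order, j] = dil
        u1 = rng.random(occ.shape)
        u2 = rng.random(occ.shape)
        drop = (occ == 1) & (u1 < cfg.noise_flip)
        add = (occ == 0) & near & (u2 < 0.2 * cfg.noise_flip)
        if cfg.structure == "checkerboard":
            # the exclusion network has no niche ranges along the
            # gradient; spillover strays would fabricate one
            add &= False
        occ = np.where(drop, 0.0, np.where(add, 1.0, occ))
    # repair empty margins so CA stays defined: restore one of the
    # species' template presences (or a random cell if it never had any)
    for j in np.nonzero(occ.sum(axis=0) == 0)[0]:
        had = np.nonzero(template[:, j] > 0)[0]
        i = had[rng.integers(len(had))] if len(had) \
            else rng.integers(occ.shape[0])
        occ[int(i), j] = 1.0
    for i in np.nonzero(occ.sum(axis=1) == 0)[0]:
        had = np.nonzero(template[i] > 0)[0]
        j = had[rng.integers(len(had))] if len(had) \
            else rng.integers(occ.shape[1])
        occ[i, int(j)] = 1.0
    ids = list(gradient.data.index)
    m = SiteBySpeciesMatrix(
        pd.DataFrame(occ, index=ids,
                     columns=[f"sp{j+1:02d}" for j in range(cfg.n_species)]),
        mode="incidence",
    )
    return m, truth


# ---------------------------------------------------------------------------
# surveys
# ---------------------------------------------------------------------------

def simulate_surveys(
    cfg: SyntheticConfig,
    occupancy: SiteBySpeciesMatrix,
    gradient: TreeCoverGradient,
    rng: np.random.Generator | None = None,
) -> SurveyTable:
    """Poisson counts over years and sessions at occupied sites.

    Expected abundance at an occupied cell is
    ``mean_abundance * suitability * exp(beta_time * (year effect +
    session effect))`` with a log-linear temporal layer; unoccupied
    cells are structural zeros.  Suitability is a Gaussian function of
    the distance between the site's tree cover and the species' niche
    optimum (the occupancy-weighted mean tree cover of its sites).
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    occ = occupancy.to_numpy()
    g = gradient.data.to_numpy(dtype=float)
    # empirical niche optimum per species
    w = occ / np.maximum(occ.sum(axis=0), 1.0)
    mu = (w * g[:, None]).sum(axis=0)
    suit = np.exp(-((g[:, None] - mu[None, :]) ** 2) / (2 * 0.3**2))
    lam0 = cfg.mean_abundance * (0.25 + 0.75 * suit) * occ

    # species-specific temporal responses: a shared year/session score
    # times a per-species loading, so composition (not just total
    # abundance) varies through time when beta_time > 0
    year_eff = rng.normal(0.0, 1.0, cfg.n_years)
    year_eff -= year_eff.mean()
    sess_eff = np.array([1.0, -1.0])[: cfg.n_sessions]
    year_load = rng.normal(0.0, 0.4, len(mu))
    sess_load = rng.normal(0.0, 0.3, len(mu))
    rows = []
    ids = occupancy.site_ids
    for yi in range(cfg.n_years):
        for si in range(cfg.n_sessions):
            eff = year_eff[yi] * year_load + sess_eff[si] * sess_load
            lam = lam0 * np.exp(cfg.beta_time * eff[None, :])
            counts = rng.poisson(lam)
            df = pd.DataFrame(counts, index=ids,
                              columns=occupancy.species_ids)
            df.insert(0, "session", si + 1)
            df.insert(0, "year", 2009 + yi)
            df.insert(0, "site_id", ids)
            rows.append(df)
    data = pd.concat(rows, ignore_index=True)
    return SurveyTable(data)


def simulate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """One full realization: gradient, occupancy, surveys and truth."""
    rng = np.random.default_rng(cfg.seed)
    coords, gradient, env = simulate_gradient(cfg, rng)
    occupancy, truth = simulate_occupancy(cfg, gradient, rng)
    surveys = simulate_surveys(cfg, occupancy, gradient, rng)
    truth["seed"] = cfg.seed
    truth["beta"] = {"env": cfg.beta_env, "space": cfg.beta_space,
                     "time": cfg.beta_time}
    return SyntheticDataset(
        config=cfg, coordinates=coords, tree_cover=gradient,
        environment=env, occupancy=occupancy, surveys=surveys, truth=truth,
    )


# ---------------------------------------------------------------------------
# calibrated variance shares for partition recovery
# ---------------------------------------------------------------------------

def community_with_shares(
    n_rows: int,
    n_species: int,
    share_env: float,
    share_space: float,
    share_time: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Response matrix with known generating variance shares.

    Builds mutually orthonormal (in-sample) predictor columns e, s, t
    and a response whose population R2 against each block equals the
    requested share: every species column is
    ``sqrt(share)*predictor*sign + sqrt(residual_share)*noise`` with
    the noise orthogonalized against the predictors and standardized.
    Returns (Y, E, S, T) as column arrays; pure fractions of a
    partition of Y on (E, S, T) target exactly the given shares.
    """
    total = share_env + share_space + share_time
    if total > 1:
        raise ValueError("shares must sum to at most 1")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_rows, 3))
    Q, _ = np.linalg.qr(raw - raw.mean(axis=0))
    basis = Q * np.sqrt(n_rows - 1)  # exactly orthogonal, unit sample variance
    e, s, t = basis.T
    Y = np.empty((n_rows, n_species))
    for j in range(n_species):
        eps = rng.standard_normal(n_rows)
        # orthogonalize noise against all predictors
        eps = eps - basis @ np.linalg.lstsq(basis, eps, rcond=None)[0]
        eps = (eps - eps.mean()) / eps.std(ddof=1)
        signs = rng.choice([-1.0, 1.0], size=3)
        Y[:, j] = (
            np.sqrt(share_env) * signs[0] * e
            + np.sqrt(share_space) * signs[1] * s
            + np.sqrt(share_time) * signs[2] * t
            + np.sqrt(1.0 - total) * eps
        )
    return Y, e[:, None], s[:, None], t[:, None]
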