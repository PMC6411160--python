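"""One-call reproduction of the full analysis graph.

Chains the stages: pool surveys -> correspondence analysis -> EMS on
axes 1 and 2 -> per-grain variation partitioning (with forward
selection of environmental and spatial predictors) -> deconstruction
by species class and landscape class.  Every artifact is CSV or JSON,
carries the configuration hash and seed, and is bit-reproducible from
(inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .deconstruction import (
    LANDSCAPE_CLASS_LABELS,
    SPECIES_CLASS_LABELS,
    classify_landscape,
    cluster_species,
    subset_matrix,
)
from .ems import NullModelSpec, ems_analysis
from .io_types import (
    SiteBySpeciesMatrix,
    SurveyTable,
    hellinger_transform,
    pool_surveys,
    to_incidence,
)
from .ordination import axis_environment_correlation, correspondence_analysis
from .synthetic import SyntheticDataset
from .varpart import (
    build_pcnm,
    build_temporal_dummies,
    build_tsa_terms,
    forward_select,
    per_variable_F,
    variation_partition,
)

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    """Settings of a full pipeline run."""

    grains: tuple[int, ...] = (200, 400, 600, 800, 1000, 1200, 1400)
    spatial_method: str = "tsa"  # or "pcnm"
    null_iterations: int = 200
    alpha: float = 0.05
    n_perm: int = 199
    deconstruction: bool = True
    truncate_negative: bool = False
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _log(msg: str) -> None:
    print(f"[emspart] {msg}", file=sys.stderr)


def _varpart_unit(
    dataset: SyntheticDataset | dict,
    surveys: SurveyTable,
    grain: int,
    cfg: RunConfig,
    sites: list | None = None,
    species: list | None = None,
    seed_offset: int = 0,
) -> dict | None:
    """Variation partition at one grain for one (sites, species) cell."""
    env = dataset.environment[grain] if hasattr(dataset, "environment") \
        else dataset["environment"][grain]
    coords = dataset.coordinates if hasattr(dataset, "coordinates") \
        else dataset["coordinates"]
    df = surveys.data
    if sites is not None:
        df = df[df["site_id"].isin(set(sites))]
    df = df.reset_index(drop=True)
    sp = [s for s in surveys.species if species is None or s in set(species)]
    if df.empty or len(sp) < 3 or df["site_id"].nunique() < 10:
        return None
    abund = SiteBySpeciesMatrix(df[sp], mode="abundance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Y = hellinger_transform(abund).to_numpy()
    keep = Y.sum(axis=1) > 0
    if not keep.all():
        df = df.loc[keep].reset_index(drop=True)
        Y = Y[keep]
    if np.allclose(Y.var(axis=0).sum(), 0):
        return None

    from .io_types import Coordinates

    site_index = df["site_id"]
    Edf = env.predictor_frame().reindex(site_index).reset_index(drop=True)
    sub_coords = Coordinates(
        coords.data.loc[coords.data.index.isin(set(site_index))]
    )
    if cfg.spatial_method == "pcnm":
        sp_pred = build_pcnm(sub_coords)
    else:
        sp_pred = build_tsa_terms(sub_coords)
    Sdf = sp_pred.data.reindex(site_index).reset_index(drop=True)
    Tdf = build_temporal_dummies(
        df["year"].reset_index(drop=True), df["session"].reset_index(drop=True)
    )

    rng = np.random.default_rng(cfg.seed + 7919 * seed_offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel_E = forward_select(Y, Edf, alpha=cfg.alpha, n_perm=cfg.n_perm,
                               seed=int(rng.integers(2**31 - 1)))
        sel_S = forward_select(Y, Sdf, alpha=cfg.alpha, n_perm=cfg.n_perm,
                               seed=int(rng.integers(2**31 - 1)))
        res = variation_partition(
            Y,
            Edf[sel_E] if sel_E else None,
            Sdf[sel_S] if sel_S else None,
            Tdf,
            truncate_negative=cfg.truncate_negative,
        )
        fshares = None
        if sel_E:
            fshares = per_variable_F(
                Y, Edf[sel_E], Z=None, n_perm=cfg.n_perm,
                seed=int(rng.integers(2**31 - 1)),
            )
    out = {
        "grain": grain,
        "fractions": res.fractions,
        "total_explained": res.total_explained,
        "selected_env": sel_E,
        "selected_space": sel_S,
        "n_rows": int(Y.shape[0]),
    }
    if fshares is not None:
        out["env_F_shares"] = {
            r["variable"]: {"F": r["F"], "share": r["share"]}
            for _, r in fshares.iterrows()
        }
    return out


def _ems_unit(
    m: SiteBySpeciesMatrix, cfg: RunConfig, seed_offset: int = 0
) -> dict:
    spec1 = NullModelSpec(iterations=cfg.null_iterations,
                          seed=cfg.seed + 104729 * seed_offset)
    spec2 = NullModelSpec(iterations=cfg.null_iterations,
                          seed=cfg.seed + 104729 * seed_offset + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = ems_analysis(m, axis=1, spec=spec1, alpha=cfg.alpha)
        r2 = ems_analysis(m, axis=2, spec=spec2, alpha=cfg.alpha)
    return {"axis1": r1.to_dict(), "axis2": r2.to_dict()}


def run_full_analysis(
    dataset: SyntheticDataset,
    cfg: RunConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute the full analysis graph on a dataset.

    Returns a report dictionary (and, when ``out_dir`` is given, writes
    ``report.json`` plus CSV tables for the label table, the per-grain
    fraction curves and the axis-correlation screen).  Partial failure
    in one deconstruction cell is recorded and the run continues.
    """
    t0 = time.time()
    report: dict = {"config": asdict(cfg), "config_hash": cfg.hash(),
                    "seed": cfg.seed}

    surveys = dataset.surveys
    pooled = pool_surveys(surveys)
    incidence = to_incidence(pooled)
    richness = incidence.richness()

    _log("correspondence analysis")
    ords = correspondence_analysis(incidence, n_axes=2, anchor=richness)
    report["ordination"] = {
        "axis1_inertia_pct": float(100 * ords.inertia_fraction[0]),
        "axis2_inertia_pct": float(100 * ords.inertia_fraction[1]),
    }
    corr = axis_environment_correlation(
        ords, dataset.environment[min(cfg.grains)], richness=richness
    )
    # correlation with the generating tree-cover gradient, when known
    tc = dataset.tree_cover.data
    ax1 = ords.site_scores["axis1"]
    common = ax1.index.intersection(tc.index)
    r_tc = float(np.corrcoef(ax1.loc[common], tc.loc[common])[0, 1])
    report["axis1_tree_cover_r"] = r_tc
    report["axis_correlations"] = corr.to_dict(orient="records")

    _log("global EMS")
    report["ems"] = {"global": _ems_unit(incidence, cfg)}

    _log("global variation partitioning")
    report["varpart"] = {"global": []}
    for gi, grain in enumerate(cfg.grains):
        unit = _varpart_unit(dataset, surveys, grain, cfg, seed_offset=gi)
        if unit is not None:
            report["varpart"]["global"].append(unit)

    if cfg.deconstruction:
        _log("deconstruction")
        sp_classes = cluster_species(ords, k=3)
        ls_classes = classify_landscape(dataset.tree_cover)
        report["species_classes"] = sp_classes.data["class"].to_dict()
        report["landscape_classes"] = ls_classes.data["class"].to_dict()
        report["ems"]["by_species_class"] = {}
        report["ems"]["by_landscape_class"] = {}
        report["varpart"]["by_species_class"] = {}
        report["varpart"]["by_landscape_class"] = {}
        units = [("species", c, None, sp_classes.members(c))
                 for c in SPECIES_CLASS_LABELS] + \
                [("landscape", c, ls_classes.members(c), None)
                 for c in LANDSCAPE_CLASS_LABELS]
        for ui, (kind, cls, sites, species) in enumerate(units, start=1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub = subset_matrix(incidence, sites=sites, species=species)
            key = ("by_species_class" if kind == "species"
                   else "by_landscape_class")
            if sub is None:
                report["ems"][key][cls] = {"skipped": "class too small"}
                continue
            try:
                report["ems"][key][cls] = _ems_unit(sub, cfg, seed_offset=ui)
            except Exception as exc:  # recorded, run continues
                report["ems"][key][cls] = {"error": str(exc)}
            report["varpart"][key][cls] = []
            for gi, grain in enumerate(cfg.grains):
                try:
                    unit = _varpart_unit(
                        dataset, surveys, grain, cfg,
                        sites=sites, species=species,
                        seed_offset=100 * ui + gi,
                    )
                except Exception as exc:
                    unit = {"grain": grain, "error": str(exc)}
                if unit is not None:
                    report["varpart"][key][cls].append(unit)

    _log(f"done in {time.time() - t0:.1f}s")
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)

    rows = []
    for scope, block in report["ems"].items():
        if scope == "global":
            block = {"global": block}
        for cls, axes in block.items():
            for ax in ("axis1", "axis2"):
                if isinstance(axes, dict) and ax in axes:
                    rows.append({"scope": scope, "class": cls, **axes[ax]})
    pd.DataFrame(rows).to_csv(out_dir / "ems_labels.csv", index=False)

    curve = []
    for scope, block in report["varpart"].items():
        if scope == "global":
            block = {"global": block}
        for cls, units in block.items():
            for u in units:
                if "fractions" in u:
                    curve.append({"scope": scope, "class": cls,
                                  "grain": u["grain"],
                                  "total_explained": u["total_explained"],
                                  **u["fractions"]})
    pd.DataFrame(curve).to_csv(out_dir / "varpart_curves.csv", index=False)
    pd.DataFrame(report["axis_correlations"]).to_csv(
        out_dir / "axis_correlations.csv", index=False
    )
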