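"""Assembly of model-ready analysis tables from the four raw tables.

The analysis works on two frames:

* a **site frame** (one row per site) carrying geology, standardized climate
  (linear + quadratic) and the depth-averaged soil element concentrations,
  both raw and standardized — the soil tier of the model is fit at this level;
* a **tree frame** (one row per tree) with site covariates joined in and all
  continuous predictors standardized across trees — the foliage and herbivory
  tiers are fit at this level.

Standardization is done once here (and mirrored exactly by the synthetic
generator), so slopes throughout the model live on a per-standard-deviation
scale and the vague priors are comparably vague across predictors.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measures import ScalingRecord, depth_average, standardize, tree_damage

__all__ = [
    "SOIL_ELEMENTS",
    "CLIMATE_COLUMNS",
    "AnalysisData",
    "aggregate_leaves",
    "depth_average_soil",
    "build_analysis",
]

#: Soil elements carried through the analysis (CN is the carbon:nitrogen ratio).
SOIL_ELEMENTS = ("N", "P", "K", "Na", "CN")
CLIMATE_COLUMNS = ("mat", "map")
FOLIAGE_COLUMNS = ("total_n", "n_digest")


def aggregate_leaves(leaves: pd.DataFrame, *, min_leaves: int = 10) -> pd.DataFrame:
    """Collapse the leaf table to one damage value per tree.

    Each tree's herbivory response is the mean of its leaves' damage
    proportions (see :func:`herbscape.measures.tree_damage`).
    """
    rows = [
        {"tree_id": tid, "damage": tree_damage(grp["damage"], min_leaves=min_leaves),
         "n_leaves": len(grp)}
        for tid, grp in leaves.groupby("tree_id", sort=False)
    ]
    return pd.DataFrame(rows)


def depth_average_soil(
    cores: pd.DataFrame,
    *,
    site: str = "site_id",
    element: str = "element",
    value: str = "value",
) -> pd.DataFrame:
    """Collapse a long per-depth soil core table to one value per site.

    ``cores`` has one row per (site, element, depth) with possibly missing
    values; each site x element cell becomes the arithmetic mean over its
    non-missing depths (see :func:`herbscape.measures.depth_average`).
    Returns a wide table with one row per site and ``soil_<element>``
    columns, matching the soil table the generators emit.
    """
    rows: dict = {}
    for (sid, elem), grp in cores.groupby([site, element], sort=False):
        mean, _ = depth_average(grp[value])
        rows.setdefault(sid, {site: sid})[f"soil_{elem}"] = mean
    return pd.DataFrame(list(rows.values())).sort_values(site).reset_index(
        drop=True
    )


@dataclass
class AnalysisData:
    """Model-ready frames plus the scaling records needed to invert them."""

    site_frame: pd.DataFrame
    tree_frame: pd.DataFrame
    site_scaler: ScalingRecord
    tree_scaler: ScalingRecord
    site_ids: list = field(default_factory=list)
    species: list = field(default_factory=list)
    genera: list = field(default_factory=list)
    genus_map: dict = field(default_factory=dict)
    geology_classes: list = field(default_factory=list)
    soil_elements: tuple = SOIL_ELEMENTS

    @property
    def n_sites(self) -> int:
        return len(self.site_frame)

    @property
    def n_trees(self) -> int:
        return len(self.tree_frame)


def _ordered_unique(values) -> list:
    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


def standardize_site_frame(
    sites: pd.DataFrame, soil: pd.DataFrame, soil_elements=SOIL_ELEMENTS
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Join sites+soil and standardize climate (with quadratics) and soil."""
    frame = sites.sort_values("site_id").reset_index(drop=True)
    frame = frame.merge(soil, on="site_id", how="left", validate="one_to_one")
    soil_cols = [f"soil_{e}" for e in soil_elements]
    frame, rec = standardize(
        frame, list(CLIMATE_COLUMNS) + soil_cols, quadratic=CLIMATE_COLUMNS
    )
    return frame, rec


def standardize_tree_covariates(
    trees: pd.DataFrame,
    sites: pd.DataFrame,
    soil: pd.DataFrame,
    soil_elements=SOIL_ELEMENTS,
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Join site covariates onto trees and standardize them across trees.

    Site-level predictors are standardized *at the tree level* here (trees per
    site act as weights), which is the scale on which the foliage and
    herbivory tiers see them.
    """
    soil_cols = [f"soil_{e}" for e in soil_elements]
    covars = sites[["site_id", "geology", "mat", "map"]].merge(
        soil[["site_id", *soil_cols]], on="site_id", how="left"
    )
    frame = trees.merge(covars, on="site_id", how="left", validate="many_to_one")
    frame, rec = standardize(
        frame, list(CLIMATE_COLUMNS) + soil_cols, quadratic=CLIMATE_COLUMNS
    )
    return frame, rec


def build_analysis(
    sites: pd.DataFrame,
    soil: pd.DataFrame,
    trees: pd.DataFrame,
    leaves: pd.DataFrame | None = None,
    *,
    soil_elements=SOIL_ELEMENTS,
    min_leaves: int = 10,
) -> AnalysisData:
    """Build the standardized site and tree analysis frames.

    ``leaves`` may be omitted when only the soil/foliage tiers are needed; the
    tree frame then has no ``damage`` column.
    """
    site_frame, site_rec = standardize_site_frame(sites, soil, soil_elements)
    tree_frame, tree_rec = standardize_tree_covariates(
        trees, sites, soil, soil_elements
    )
    # standardize the foliar responses across trees (they are predictors of
    # the herbivory tier as well as responses of the foliage tier)
    tree_frame, fol_rec = standardize(tree_frame, list(FOLIAGE_COLUMNS))
    tree_rec.means.update(fol_rec.means)
    tree_rec.sds.update(fol_rec.sds)

    if leaves is not None:
        per_tree = aggregate_leaves(leaves, min_leaves=min_leaves)
        tree_frame = tree_frame.merge(
            per_tree, on="tree_id", how="left", validate="one_to_one"
        )
        if tree_frame["damage"].isna().any():
            missing = tree_frame.loc[tree_frame["damage"].isna(), "tree_id"]
            raise ValueError(f"trees without leaves: {list(missing[:5])} ...")

    species = _ordered_unique(trees["species"])
    genus_map = dict(zip(trees["species"], trees["genus"]))
    genera = _ordered_unique(genus_map[s] for s in species)
    return AnalysisData(
        site_frame=site_frame,
        tree_frame=tree_frame,
        site_scaler=site_rec,
        tree_scaler=tree_rec,
        site_ids=list(site_frame["site_id"]),
        species=species,
        genera=genera,
        genus_map=genus_map,
        geology_classes=_ordered_unique(site_frame["geology"]),
        soil_elements=tuple(soil_elements),
    )
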