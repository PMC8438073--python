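"""Deterministic dendrochronological transforms.

Ring widths (mm, radial, one averaged series per stem) and the diameter at
breast height measured at sampling are turned into a yearly DBH history, basal
area increments (BAI, cm^2 y^-1), within-tree standardized covariates, and the
growth-nitrogen-efficiency index GNE = BAI / (net N mineralization rate).

Conventions
-----------
* DBH series are end-of-year diameters in cm. ``reconstruct_dbh`` walks the
  recursion DBH_{y-1} = DBH_y - 2 * rw_y (ring width doubled because a radial
  increment widens the diameter on both sides), so a series of N rings yields
  N + 1 diameters, the first being the diameter before the first ring formed.
* BAI_y = BA_y - BA_{y-1} with BA = pi * (DBH/2)^2; the first diameter year
  carries no BAI.
* The size covariate attached to a growth year is the diameter *entering*
  that year (end of the previous year), so it is predetermined with respect
  to that year's growth.
* Standardization is the within-tree z-score with the sample (n-1) SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TreeRecord",
    "DataError",
    "reconstruct_dbh",
    "compute_bai",
    "standardize_within_tree",
    "compute_gne",
    "assemble_tree_year_table",
]

MM_PER_CM = 10.0


class DataError(ValueError):
    """Raised when input data violate a structural contract."""


@dataclass
class TreeRecord:
    """One tree: identity, location, sampled diameter and its ring series.

    rings maps calendar year -> ring width in mm (radial); years must be
    consecutive and widths non-negative.
    """

    tree_id: str
    site_id: str
    x: float
    y: float
    dbh_at_sampling: float  # cm
    rings: pd.Series = field(repr=False)  # year -> width (mm)

    def __post_init__(self) -> None:
        self.rings = pd.Series(self.rings, dtype=float).sort_index()
        years = self.rings.index.to_numpy()
        if len(years) and np.any(np.diff(years) != 1):
            raise DataError(f"tree {self.tree_id}: ring years are not consecutive")
        if (self.rings < 0).any():
            raise DataError(f"tree {self.tree_id}: negative ring width")
        if self.dbh_at_sampling <= 0:
            raise DataError(f"tree {self.tree_id}: non-positive DBH at sampling")

    @property
    def years(self) -> np.ndarray:
        return self.rings.index.to_numpy()


def reconstruct_dbh(
    rings: pd.Series,
    dbh_at_sampling: float,
    *,
    tree_id: str = "?",
) -> pd.Series:
    """Past end-of-year DBH (cm) from ring widths (mm) and the sampled DBH.

    Returns a series over years [first_ring_year - 1, ..., last_ring_year];
    the last value equals ``dbh_at_sampling`` and each step back removes twice
    the (mm -> cm converted) ring width.
    """
    if dbh_at_sampling <= 0:
        raise DataError(f"tree {tree_id}: dbh_at_sampling must be > 0")
    rings = pd.Series(rings, dtype=float).sort_index()
    years = rings.index.to_numpy()
    if len(years) == 0:
        raise DataError(f"tree {tree_id}: empty ring series")
    decrements = 2.0 * rings.to_numpy()[::-1] / MM_PER_CM  # diameter lost walking back
    dbh_back = dbh_at_sampling - np.concatenate([[0.0], np.cumsum(decrements)])
    dbh = dbh_back[::-1]
    if np.any(dbh <= 0):
        bad = int(np.concatenate([[years[0] - 1], years])[dbh <= 0][-1])
        raise DataError(
            f"tree {tree_id}: reconstructed DBH <= 0 at year {bad}; "
            "ring series inconsistent with sampled DBH"
        )
    index = np.concatenate([[years[0] - 1], years])
    return pd.Series(dbh, index=index, name="dbh_cm")


def compute_bai(dbh_series: pd.Series) -> pd.Series:
    """Basal area increment (cm^2 y^-1) from an end-of-year DBH series (cm).

    BAI_y = pi*(DBH_y/2)^2 - pi*(DBH_{y-1}/2)^2; the first year is dropped.
    A negative BAI (shrinking diameter) is legal but logged as a warning.
    """
    dbh_series = pd.Series(dbh_series, dtype=float).sort_index()
    if len(dbh_series) < 2:
        raise DataError("need at least 2 years of DBH to difference")
    ba = np.pi * (dbh_series.to_numpy() / 2.0) ** 2
    bai = pd.Series(np.diff(ba), index=dbh_series.index[1:], name="bai_cm2")
    n_neg = int((bai < 0).sum())
    if n_neg:
        logger.warning("%d negative BAI value(s) (diameter decrease)", n_neg)
    return bai


def standardize_within_tree(series: pd.Series | np.ndarray) -> pd.Series:
    """z-score a per-tree series (sample SD, n-1 denominator)."""
    s = pd.Series(np.asarray(series, dtype=float)) if not isinstance(
        series, pd.Series
    ) else series.astype(float)
    if len(s) < 2:
        raise DataError("standardization needs >= 2 values")
    sd = s.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DataError("cannot standardize a constant series")
    return (s - s.mean()) / sd


def compute_gne(bai: pd.Series | np.ndarray, nminer: float) -> pd.Series | np.ndarray:
    """Growth-nitrogen-efficiency index: GNE = BAI / Nminer.

    Units: cm^2 y^-1 per (ug N g^-1 d^-1). nminer must be strictly positive.
    """
    if nminer <= 0:
        raise ValueError(f"nminer must be > 0, got {nminer}")
    return bai / nminer


def assemble_tree_year_table(
    trees: list[TreeRecord],
    soils: pd.DataFrame,
    climate: pd.DataFrame,
    co2: pd.DataFrame,
    *,
    standardize_climate: bool = True,
) -> pd.DataFrame:
    """Join rings, soils and yearly covariates into the canonical analysis table.

    Returns one row per tree-year with columns:
    tree_id, site_id, year, bai, dbh (diameter entering the year), ln_dbh,
    bais_lag1 (previous year's within-tree z-scored log growth), may_tmin
    (z-scored over the full period when ``standardize_climate``), co2, nminer,
    gne, gnes (within-tree standardized GNE).

    Rows are restricted to years with a valid lag-1 BAIS. Missing climate or
    CO2 years raise a DataError listing the gaps.
    """
    soils = soils.set_index("tree_id") if "tree_id" in soils.columns else soils
    climate_s = climate.set_index("year")["may_tmin"].astype(float)
    co2_s = co2.set_index("year")["co2"].astype(float)
    if standardize_climate:
        climate_used = (climate_s - climate_s.mean()) / climate_s.std(ddof=1)
    else:
        climate_used = climate_s

    rows = []
    for tree in trees:
        if tree.tree_id not in soils.index:
            raise DataError(f"tree {tree.tree_id}: no soil record")
        nminer = float(soils.loc[tree.tree_id, "nminer"])
        dbh = reconstruct_dbh(tree.rings, tree.dbh_at_sampling, tree_id=tree.tree_id)
        bai = compute_bai(dbh)
        years = bai.index.to_numpy()
        missing_clim = sorted(set(years) - set(climate_used.index))
        missing_co2 = sorted(set(years) - set(co2_s.index))
        if missing_clim or missing_co2:
            raise DataError(
                f"tree {tree.tree_id}: missing climate years {missing_clim}, "
                f"missing CO2 years {missing_co2}"
            )
        # lag covariate: z-score of log growth (the scale the model lives on);
        # non-positive BAI years cannot enter the log and drop out of the lag
        ln_bai = pd.Series(
            np.where(bai > 0, np.log(np.where(bai > 0, bai, 1.0)), np.nan),
            index=bai.index,
        )
        valid = ln_bai.dropna()
        if len(valid) < 2:
            raise DataError(f"tree {tree.tree_id}: fewer than 2 positive BAI years")
        bais = (ln_bai - valid.mean()) / valid.std(ddof=1)
        gne = compute_gne(bai, nminer)
        gnes = standardize_within_tree(gne)
        # lag-1: the first BAI year has no standardized predecessor
        for y in years[1:]:
            if not np.isfinite(bais.loc[y - 1]):
                logger.warning(
                    "tree %s year %d: no valid lag growth, row dropped",
                    tree.tree_id, y,
                )
                continue
            rows.append(
                {
                    "tree_id": tree.tree_id,
                    "site_id": tree.site_id,
                    "year": int(y),
                    "bai": float(bai.loc[y]),
                    "dbh": float(dbh.loc[y - 1]),
                    "bais_lag1": float(bais.loc[y - 1]),
                    "may_tmin": float(climate_used.loc[y]),
                    "co2": float(co2_s.loc[y]),
                    "nminer": nminer,
                    "gne": float(gne.loc[y]),
                    "gnes": float(gnes.loc[y]),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise DataError("no usable tree-year rows")
    table["ln_dbh"] = np.log(table["dbh"])
    return table.sort_values(["tree_id", "year"]).reset_index(drop=True)
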