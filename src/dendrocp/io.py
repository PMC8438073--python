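"""Readers and writers for the canonical file formats.

Everything on disk is plain text: long-format ring CSVs or Tucson (decadal)
.rwl files for ring widths, and simple headered CSVs for soils, climate,
atmospheric CO2, gene-count tables, root tips and trait tables. Readers
validate schemas and raise :class:`~dendrocp.dendro.DataError` with a concrete
complaint; writers emit exactly what the readers accept, so simulated and
real studies flow through the same code path.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dendro import DataError, TreeRecord

__all__ = [
    "read_rings_csv",
    "write_rings_csv",
    "read_rwl",
    "write_rwl",
    "read_soils_csv",
    "read_climate_csv",
    "read_co2_csv",
    "build_tree_records",
    "read_gene_counts_csv",
    "read_root_tips_csv",
    "read_trait_table_csv",
    "read_tree_year_table",
    "write_tree_year_table",
]


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"{what}: missing column(s) {missing}")


# ---------------------------------------------------------------- ring series


def read_rings_csv(path: str | Path) -> pd.DataFrame:
    """Long-format ring widths: columns tree_id, year, width_mm."""
    df = pd.read_csv(path)
    _require_columns(df, ["tree_id", "year", "width_mm"], f"rings file {path}")
    if (df["width_mm"] < 0).any():
        raise DataError(f"rings file {path}: negative ring width")
    df["year"] = df["year"].astype(int)
    return df.sort_values(["tree_id", "year"]).reset_index(drop=True)


def write_rings_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[["tree_id", "year", "width_mm"]].to_csv(path, index=False)


def read_rwl(path: str | Path) -> pd.DataFrame:
    """Minimal Tucson decadal .rwl reader.

    Values are hundredths of mm with stop marker 999, or thousandths with
    stop marker -9999. Returns a long table (tree_id, year, width_mm).
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        series = line[:8].strip()
        rest = line[8:].split()
        if len(rest) < 2:
            continue
        try:
            decade = int(rest[0])
        except ValueError:
            continue  # header line
        for k, tok in enumerate(rest[1:]):
            v = int(tok)
            if v == 999:
                break
            if v == -9999:
                break
            divisor = 100.0
            rows.append({"tree_id": series, "year": decade + k, "width_mm": v / divisor})
    if not rows:
        raise DataError(f"rwl file {path}: no data lines parsed")
    return pd.DataFrame(rows).sort_values(["tree_id", "year"]).reset_index(drop=True)


def write_rwl(df: pd.DataFrame, path: str | Path) -> None:
    """Write long-format ring widths as Tucson decadal .rwl (0.01 mm units)."""
    _require_columns(df, ["tree_id", "year", "width_mm"], "rwl input")
    lines = []
    for tid, grp in df.groupby("tree_id", sort=True):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(dtype=int)
        vals = np.round(grp["width_mm"].to_numpy() * 100).astype(int)
        y = years[0]
        i = 0
        while i < len(years):
            decade_end = (y // 10) * 10 + 10
            n = min(decade_end - y, len(years) - i)
            toks = [f"{v:6d}" for v in vals[i : i + n]]
            if i + n == len(years):
                toks.append(f"{999:6d}")
            lines.append(f"{str(tid)[:8]:<8}{y:4d}" + "".join(toks))
            i += n
            y += n
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------ metadata


def read_soils_csv(path: str | Path) -> pd.DataFrame:
    """Per-tree soils: tree_id, site_id, x, y, nminer (+ optional chemistry)."""
    df = pd.read_csv(path)
    _require_columns(df, ["tree_id", "site_id", "x", "y", "nminer"], f"soils file {path}")
    if (df["nminer"] <= 0).any():
        raise DataError(f"soils file {path}: non-positive nminer")
    if df["tree_id"].duplicated().any():
        raise DataError(f"soils file {path}: duplicated tree_id")
    return df


def read_climate_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["year", "may_tmin"], f"climate file {path}")
    df["year"] = df["year"].astype(int)
    if df["year"].duplicated().any():
        raise DataError(f"climate file {path}: duplicated year")
    return df.sort_values("year").reset_index(drop=True)


def read_co2_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["year", "co2"], f"CO2 file {path}")
    df["year"] = df["year"].astype(int)
    if (df["co2"] <= 0).any():
        raise DataError(f"CO2 file {path}: non-positive CO2")
    return df.sort_values("year").reset_index(drop=True)


def build_tree_records(
    rings: pd.DataFrame, soils: pd.DataFrame, dbh: pd.DataFrame | None = None
) -> list[TreeRecord]:
    """Assemble TreeRecords from long rings + soils (+ optional dbh table).

    DBH at sampling is read from a ``dbh_cm`` column of soils unless a
    separate table (tree_id, dbh_cm) is given.
    """
    dbh_map = (dbh if dbh is not None else soils).set_index("tree_id")["dbh_cm"]
    soils_i = soils.set_index("tree_id")
    records = []
    for tid, grp in rings.groupby("tree_id", sort=True):
        if tid not in soils_i.index:
            raise DataError(f"tree {tid}: rings present but no soil record")
        records.append(
            TreeRecord(
                tree_id=str(tid),
                site_id=str(soils_i.loc[tid, "site_id"]),
                x=float(soils_i.loc[tid, "x"]),
                y=float(soils_i.loc[tid, "y"]),
                dbh_at_sampling=float(dbh_map.loc[tid]),
                rings=grp.set_index("year")["width_mm"],
            )
        )
    return records


# ---------------------------------------------------------------- gene tables


def read_gene_counts_csv(path: str | Path) -> pd.DataFrame:
    """Sample x gene-family counts; first column sample_id."""
    df = pd.read_csv(path, index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or (arr < 0).any():
        raise DataError(f"count table {path}: counts must be non-negative numbers")
    return df


def read_root_tips_csv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "root_tips"], f"root-tip file {path}")
    if (df["root_tips"] < 0).any():
        raise DataError(f"root-tip file {path}: negative counts")
    return df.set_index("sample_id")["root_tips"].astype(float)


def read_trait_table_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df, ["genus", "exploration_type", "rhizomorphs"], f"trait table {path}"
    )
    return df


# ----------------------------------------------------------- tree-year table

_TYT_COLUMNS = [
    "tree_id", "site_id", "year", "bai", "dbh", "ln_dbh", "bais_lag1",
    "may_tmin", "co2", "nminer", "gne", "gnes",
]


def write_tree_year_table(table: pd.DataFrame, path: str | Path) -> None:
    table[_TYT_COLUMNS].to_csv(path, index=False)


def read_tree_year_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, _TYT_COLUMNS, f"tree-year table {path}")
    df["year"] = df["year"].astype(int)
    return df
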