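"""Habitat occupancy from occurrence records via a fixed-margin null model.

The degree of habitat occupancy asks whether a species occurs in a habitat
more often than expected given how common the species and the habitat are
overall.  Occurrence records are filtered (collection year window, minimum
coordinate precision), assigned a habitat class from a categorical
land-cover grid, and tabulated into a species x habitat count matrix.  The
matrix is compared against randomized matrices with identical row and column
sums, drawn from the conditional distribution of independent counts given
the margins (the distribution targeted by Patefield's algorithm / r2dtable).
The score of a species-habitat cell is the percentage of simulated counts
strictly below the observed one; cells above the 80th percentile are "high"
occupancy, below the 20th "low", anything else intermediate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HABITATS",
    "HabitatGrid",
    "OccupancyResult",
    "load_records",
    "validate_records",
    "filter_records",
    "assign_habitat",
    "build_matrix",
    "apply_min_records",
    "patefield_sample",
    "occupancy_percentiles",
    "classify_occupancy",
]

HABITATS = ("natural", "agricultural", "urban")

#: default column mapping for GBIF "simple CSV" exports
GBIF_COLUMNS = {
    "decimalLatitude": "lat",
    "decimalLongitude": "lon",
    "year": "year",
    "species": "species",
}


# ---------------------------------------------------------------------------
# records


def load_records(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read an occurrence CSV, optionally renaming GBIF-style columns.

    The textual coordinate columns (``lat_text``/``lon_text``) are filled
    from the raw CSV fields so that trailing zeros survive for the
    decimal-precision filter.
    """
    df = pd.read_csv(path, dtype=str)
    mapping = dict(GBIF_COLUMNS)
    if column_map:
        mapping.update(column_map)
    df = df.rename(columns={k: v for k, v in mapping.items() if k in df.columns})
    required = ["species", "lat", "lon", "year"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"records file missing columns: {missing}")
    if "lat_text" not in df.columns:
        df["lat_text"] = df["lat"]
    if "lon_text" not in df.columns:
        df["lon_text"] = df["lon"]
    df["lat"] = pd.to_numeric(df["lat"], errors="raise")
    df["lon"] = pd.to_numeric(df["lon"], errors="raise")
    df["year"] = pd.to_numeric(df["year"], errors="raise").astype(int)
    return validate_records(df)


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check coordinate ranges and 4-digit years; returns the frame."""
    lat = records["lat"].astype(float)
    lon = records["lon"].astype(float)
    year = records["year"].astype(int)
    bad = records.index[(lat < -90) | (lat > 90) | (lon < -180) | (lon > 180)]
    if len(bad):
        raise ValueError(f"coordinates out of range in record(s) {list(bad[:5])}")
    bad = records.index[(year < 1000) | (year > 9999)]
    if len(bad):
        raise ValueError(f"year is not a 4-digit integer in record(s) {list(bad[:5])}")
    return records


def _decimals_of_text(text: str) -> int:
    s = str(text).strip().replace("−", "-")
    if "e" in s.lower():
        try:
            exp = Decimal(s).as_tuple().exponent
        except InvalidOperation:
            return 0
        return max(0, -int(exp))
    if "." not in s:
        return 0
    return len(s.split(".", 1)[1].rstrip())


def _decimals_of_float(value: float) -> int:
    # shortest round-trip rendering; trailing zeros are invisible here,
    # which is why the textual coordinate takes precedence when available
    return _decimals_of_text(repr(float(value)))


def _coord_decimals(records: pd.DataFrame, num_col: str, text_col: str) -> pd.Series:
    if text_col in records.columns:
        text = records[text_col]
        out = pd.Series(0, index=records.index, dtype=int)
        has_text = text.notna() & (text.astype(str).str.strip() != "")
        out[has_text] = text[has_text].map(_decimals_of_text)
        out[~has_text] = records.loc[~has_text, num_col].map(_decimals_of_float)
        return out
    return records[num_col].map(_decimals_of_float)


def filter_records(
    records: pd.DataFrame,
    *,
    min_year: int = 1990,
    max_year: int = 2022,
    min_decimals: int = 2,
) -> pd.DataFrame:
    """Keep records inside the year window with precise-enough coordinates.

    Bounds are inclusive.  Decimal places are counted on the original
    textual coordinates (``lat_text``/``lon_text``) when present, falling
    back to the shortest round-trip rendering of the float.  The input is
    never mutated.
    """
    year = records["year"].astype(int)
    keep = (year >= min_year) & (year <= max_year)
    keep &= _coord_decimals(records, "lat", "lat_text") >= min_decimals
    keep &= _coord_decimals(records, "lon", "lon_text") >= min_decimals
    return records.loc[keep].copy()


# ---------------------------------------------------------------------------
# habitat grid


@dataclass
class HabitatGrid:
    """Categorical land-cover grid plus its reclassification table.

    ``codes`` holds raw integer cover codes on a regular lat/lon grid; the
    reclassification maps every code present to one of the three habitat
    classes.  Row 0 is the minimum-latitude edge; cells are half-open
    ``[lower, upper)`` intervals in both axes, so a point on a shared edge
    belongs to the cell whose closed lower edge it sits on.
    """

    codes: np.ndarray
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    reclass: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.ndim != 2:
            raise ValueError("grid codes must be a 2-D array")
        if not (self.lat_max > self.lat_min and self.lon_max > self.lon_min):
            raise ValueError("degenerate bounding box")
        present = set(np.unique(self.codes).tolist())
        unmapped = present - set(self.reclass)
        if unmapped:
            raise ValueError(f"cover codes without reclassification: {sorted(unmapped)}")
        bad = {c: k for c, k in self.reclass.items() if k not in HABITATS}
        if bad:
            raise ValueError(f"reclassification to unknown habitat class: {bad}")

    @property
    def n_rows(self) -> int:
        return self.codes.shape[0]

    @property
    def n_cols(self) -> int:
        return self.codes.shape[1]

    @property
    def cell_height(self) -> float:
        return (self.lat_max - self.lat_min) / self.n_rows

    @property
    def cell_width(self) -> float:
        return (self.lon_max - self.lon_min) / self.n_cols

    def class_grid(self) -> np.ndarray:
        """Grid of habitat-class strings."""
        lut = np.vectorize(self.reclass.get)
        return lut(self.codes)

    def cell_index(self, lat: np.ndarray, lon: np.ndarray):
        """(row, col, inside) arrays for point coordinates."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        row = np.floor((lat - self.lat_min) / self.cell_height).astype(int)
        col = np.floor((lon - self.lon_min) / self.cell_width).astype(int)
        inside = (
            (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        )
        return row, col, inside

    # -- persistence (plain-text matrix + JSON sidecar + reclass CSV) ------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "grid_codes.txt", self.codes, fmt="%d")
        sidecar = {
            "lat_min": self.lat_min,
            "lat_max": self.lat_max,
            "lon_min": self.lon_min,
            "lon_max": self.lon_max,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
        }
        (directory / "grid_meta.json").write_text(json.dumps(sidecar, indent=2))
        pd.DataFrame(
            {"code": list(self.reclass), "habitat": list(self.reclass.values())}
        ).to_csv(directory / "grid_reclass.csv", index=False)

    @classmethod
    def load(cls, directory) -> "HabitatGrid":
        directory = Path(directory)
        codes = np.loadtxt(directory / "grid_codes.txt", dtype=int, ndmin=2)
        meta = json.loads((directory / "grid_meta.json").read_text())
        reclass_df = pd.read_csv(directory / "grid_reclass.csv")
        reclass = dict(zip(reclass_df["code"].astype(int), reclass_df["habitat"]))
        return cls(
            codes=codes,
            lat_min=meta["lat_min"],
            lat_max=meta["lat_max"],
            lon_min=meta["lon_min"],
            lon_max=meta["lon_max"],
            reclass=reclass,
        )


def assign_habitat(
    records: pd.DataFrame,
    grid: HabitatGrid,
    *,
    strict: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Attach the habitat class of the containing grid cell to each record.

    Points outside the grid are dropped and counted in the report by
    default; ``strict=True`` raises instead.  Returns ``(labelled, report)``.
    """
    row, col, inside = grid.cell_index(records["lat"], records["lon"])
    n_outside = int((~inside).sum())
    if n_outside and strict:
        raise ValueError(f"{n_outside} record(s) fall outside the habitat grid")
    kept = records.loc[inside].copy()
    classes = grid.class_grid()
    kept["habitat"] = classes[row[inside], col[inside]]
    report = {"n_input": len(records), "n_assigned": len(kept), "n_outside": n_outside}
    return kept, report


def build_matrix(labelled: pd.DataFrame) -> pd.DataFrame:
    """Species x habitat count matrix (columns exactly the three habitats)."""
    if len(labelled) == 0:
        return pd.DataFrame(columns=list(HABITATS), dtype=int)
    mat = pd.crosstab(labelled["species"], labelled["habitat"])
    mat = mat.reindex(columns=list(HABITATS), fill_value=0).fillna(0).astype(int)
    mat.index.name = "species"
    mat.columns.name = "habitat"
    return mat.sort_index()


def apply_min_records(matrix: pd.DataFrame, min_records: int = 50) -> pd.DataFrame:
    """Drop species whose total record count falls below ``min_records``."""
    keep = matrix.sum(axis=1) >= min_records
    out = matrix.loc[keep]
    if len(out) == 0:
        raise ValueError(
            f"no species retains >= {min_records} records; occupancy undefined"
        )
    return out.copy()


# ---------------------------------------------------------------------------
# null model


def patefield_sample(row_margins, col_margins, rng) -> np.ndarray:
    """One random contingency table with the given margins.

    Draws from the conditional distribution of independent counts given the
    margins (probability proportional to
    ``prod r_i! prod c_j! / (N! prod t_ij!)``), the distribution sampled by
    Patefield's AS 159 / R's ``r2dtable``.  Rows are filled sequentially by
    multivariate hypergeometric draws from the remaining column totals,
    which realizes exactly that distribution.

    ``rng`` may be a :class:`numpy.random.Generator` or an integer seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    r = np.asarray(row_margins, dtype=int)
    c = np.asarray(col_margins, dtype=int)
    if (r < 0).any() or (c < 0).any():
        raise ValueError("margins must be non-negative")
    if r.sum() != c.sum():
        raise ValueError(f"margin sums differ: rows {r.sum()} vs columns {c.sum()}")
    if r.sum() == 0:
        raise ValueError("total count must be positive")
    out = np.empty((len(r), len(c)), dtype=int)
    remaining = c.copy()
    for i in range(len(r) - 1):
        row = rng.multivariate_hypergeometric(remaining, int(r[i]))
        out[i] = row
        remaining -= row
    out[-1] = remaining
    return out


@dataclass
class OccupancyResult:
    """Null-model percentile scores and classes per species-habitat cell.

    ``table`` is a long-form frame (species, habitat, observed, percentile,
    klass); ``n_sim``, ``seed`` and ``ties`` record provenance.
    """

    table: pd.DataFrame
    n_sim: int
    seed: int | None
    ties: str = "strict"

    def matrix(self, column: str = "percentile") -> pd.DataFrame:
        return self.table.pivot(index="species", columns="habitat", values=column)[
            list(HABITATS)
        ]

    def class_counts(self) -> pd.DataFrame:
        counts = (
            self.table.groupby(["habitat", "klass"]).size().unstack(fill_value=0)
        )
        return counts.reindex(
            index=list(HABITATS), columns=["low", "intermediate", "high"], fill_value=0
        )

    def to_csv(self, path) -> None:
        out = self.table.assign(n_sim=self.n_sim, seed=self.seed)
        out.to_csv(path, index=False)


def classify_occupancy(
    percentiles: pd.Series | np.ndarray,
    *,
    high: float = 80.0,
    low: float = 20.0,
):
    """Map percentile scores to {low, intermediate, high}.

    Thresholds are strict: a score must *exceed* ``high`` or fall *below*
    ``low``; boundary values are intermediate.
    """
    if not 0 <= low < high <= 100:
        raise ValueError(f"invalid thresholds low={low}, high={high}")
    p = np.asarray(percentiles, dtype=float)
    klass = np.where(p > high, "high", np.where(p < low, "low", "intermediate"))
    if isinstance(percentiles, pd.Series):
        return pd.Series(klass, index=percentiles.index)
    return klass


def occupancy_percentiles(
    matrix: pd.DataFrame,
    *,
    n_sim: int = 10_000,
    seed: int | None = None,
    ties: str = "strict",
    high: float = 80.0,
    low: float = 20.0,
) -> OccupancyResult:
    """Score every species-habitat cell against the fixed-margin null model.

    The percentile of a cell is ``100 * (# simulations with a simulated
    count strictly below the observed) / n_sim``; with ``ties="half"`` each
    simulated count equal to the observed contributes one half.  The same
    generator stream drives all ``n_sim`` randomized matrices, so a fixed
    seed reproduces the result exactly.
    """
    if len(matrix) == 0:
        raise ValueError("occurrence matrix is empty")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if ties not in ("strict", "half"):
        raise ValueError(f"unknown tie policy {ties!r}")
    # canonical row/column order so permuting the input permutes the
    # percentiles exactly (same seed, same draws per cell)
    if set(matrix.columns) == set(HABITATS):
        matrix = matrix[list(HABITATS)]
    matrix = matrix.sort_index()
    obs = matrix.to_numpy(dtype=int)
    r = obs.sum(axis=1)
    c = obs.sum(axis=0)
    rng = np.random.default_rng(seed)
    below = np.zeros(obs.shape, dtype=float)
    for _ in range(n_sim):
        sim = patefield_sample(r, c, rng)
        below += sim < obs
        if ties == "half":
            below += 0.5 * (sim == obs)
    percentile = 100.0 * below / n_sim
    rows = []
    for i, sp in enumerate(matrix.index):
        for j, hab in enumerate(matrix.columns):
            rows.append((sp, hab, int(obs[i, j]), float(percentile[i, j])))
    table = pd.DataFrame(rows, columns=["species", "habitat", "observed", "percentile"])
    table["klass"] = classify_occupancy(table["percentile"], high=high, low=low)
    return OccupancyResult(table=table, n_sim=n_sim, seed=seed, ties=ties)
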