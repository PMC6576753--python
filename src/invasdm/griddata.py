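"""Grid data model, CSV I/O, spatial-domain constraints, and sampling-effort accounting.

The modelling domain is a regular grid of square cells in planar km
coordinates (cell centroids).  Predictor layers live in a
:class:`PredictorStack`, where every column carries one of three type tags:

``environmental``
    climate / topography / land-use style layers, available in both the
    native and the invaded region;
``anthropic``
    human-activity layers (distances to facilities, densities), meaningful
    only in the invaded region;
``distance_to_first_record``
    the per-species Euclidean distance to the earliest dated occurrence,
    a proxy for spatially correlated dispersal from the introduction point.

Occurrence records are rows of (species, cell_id, date, region); dates are
integers (simulation steps or day ordinals) so that only their ordering
matters.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from shapely import MultiPoint, Point

ENVIRONMENTAL = "environmental"
ANTHROPIC = "anthropic"
DIST_FIRST_RECORD = "distance_to_first_record"
VALID_TAGS = frozenset({ENVIRONMENTAL, ANTHROPIC, DIST_FIRST_RECORD})

REGIONS = ("native", "invaded")
GRID_COLUMNS = ("cell_id", "x_km", "y_km", "area_fraction")
MIN_AREA_FRACTION = 0.70


class GridDataError(ValueError):
    """Raised for malformed grid tables, occurrence files, or predictor stacks."""


# ---------------------------------------------------------------------------
# Predictor stack
# ---------------------------------------------------------------------------

class PredictorStack:
    """Per-cell predictor matrix with per-column type tags.

    Parameters
    ----------
    frame : DataFrame
        One row per cell, indexed by integer ``cell_id``; one column per
        predictor, all values finite.
    tags : mapping of column name -> tag
        Every column must be tagged with one of :data:`VALID_TAGS`.
    """

    def __init__(self, frame: pd.DataFrame, tags: Mapping[str, str]):
        frame = frame.copy()
        frame.index = frame.index.astype(int)
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].tolist()
            raise GridDataError(f"duplicate cell ids in predictor stack: {dups[:5]}")
        if frame.columns.has_duplicates:
            dups = frame.columns[frame.columns.duplicated()].tolist()
            raise GridDataError(f"duplicate predictor names: {dups}")
        tags = dict(tags)
        missing = set(frame.columns) - set(tags)
        if missing:
            raise GridDataError(f"columns without a tag: {sorted(missing)}")
        for name, tag in tags.items():
            if name not in frame.columns:
                raise GridDataError(f"tag given for unknown column {name!r}")
            if tag not in VALID_TAGS:
                raise GridDataError(
                    f"column {name!r} has unknown tag {tag!r}; "
                    f"allowed: {sorted(VALID_TAGS)}"
                )
        values = frame.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = frame.columns[~np.isfinite(values).all(axis=0)].tolist()
            raise GridDataError(f"non-finite values in columns {bad}")
        self.frame = frame.astype(float)
        self.tags = tags

    # -- basic introspection ------------------------------------------------
    @property
    def cell_ids(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_cells(self) -> int:
        return len(self.frame)

    def names_with_tags(self, tags: Iterable[str]) -> list[str]:
        wanted = set(tags)
        return [c for c in self.frame.columns if self.tags[c] in wanted]

    # -- construction / subsetting -----------------------------------------
    def with_column(self, name: str, values, tag: str) -> "PredictorStack":
        """Return a new stack with one extra column."""
        if name in self.frame.columns:
            raise GridDataError(f"column {name!r} already present")
        frame = self.frame.copy()
        frame[name] = np.asarray(values, dtype=float)
        return PredictorStack(frame, {**self.tags, name: tag})

    def select(self, names: Iterable[str]) -> "PredictorStack":
        names = list(names)
        return PredictorStack(self.frame[names], {n: self.tags[n] for n in names})

    def subset_cells(self, cell_ids: Iterable[int]) -> "PredictorStack":
        idx = np.asarray(list(cell_ids), dtype=int)
        return PredictorStack(self.frame.loc[idx], self.tags)

    def matrix_for(self, cell_ids: Iterable[int], names: Iterable[str]) -> pd.DataFrame:
        """Design-matrix rows for the given cells and columns."""
        idx = np.asarray(list(cell_ids), dtype=int)
        return self.frame.loc[idx, list(names)]

    def __eq__(self, other) -> bool:  # round-trip checks
        return (
            isinstance(other, PredictorStack)
            and self.tags == other.tags
            and self.frame.shape == other.frame.shape
            and list(self.frame.columns) == list(other.frame.columns)
            and (self.frame.index == other.frame.index).all()
            and np.allclose(self.frame.to_numpy(), other.frame.to_numpy())
        )


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class OccurrenceSet:
    """Dated presence records: columns species, cell_id, date, region."""

    records: pd.DataFrame

    COLUMNS = ("species", "cell_id", "date", "region")

    def __post_init__(self):
        df = self.records
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise GridDataError(f"occurrence records missing columns {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["cell_id"] = df["cell_id"].astype(int)
        df["date"] = df["date"].astype(int)
        df["region"] = df["region"].astype(str).str.strip().str.lower()
        bad = ~df["region"].isin(REGIONS)
        if bad.any():
            raise GridDataError(
                f"unknown region values: {sorted(df.loc[bad, 'region'].unique())}"
            )
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def deduplicate(self) -> tuple["OccurrenceSet", int]:
        """Keep the earliest record per (species, cell, region).

        Returns the deduplicated set and the number of dropped duplicates.
        """
        df = self.records.sort_values(["species", "region", "cell_id", "date"])
        kept = df.drop_duplicates(subset=["species", "cell_id", "region"], keep="first")
        return OccurrenceSet(kept.reset_index(drop=True)), len(df) - len(kept)

    def for_species(self, species: str, region: str | None = None) -> pd.DataFrame:
        df = self.records[self.records["species"] == species]
        if region is not None:
            df = df[df["region"] == region]
        return df.reset_index(drop=True)

    def species(self) -> list[str]:
        return sorted(self.records["species"].unique())

    @staticmethod
    def concat(parts: Iterable["OccurrenceSet"]) -> "OccurrenceSet":
        frames = [p.records for p in parts]
        if not frames:
            return OccurrenceSet(pd.DataFrame(columns=list(OccurrenceSet.COLUMNS)))
        return OccurrenceSet(pd.concat(frames, ignore_index=True))


@dataclasses.dataclass
class SpeciesProfile:
    """Invasion-history traits used as covariates in the performance analysis."""

    species: str
    time_since_introduction: float  # years
    economic_interest: bool
    n_presences: int
    ns_distance_km: float  # span between northernmost and southernmost records

    def __post_init__(self):
        for field in ("time_since_introduction", "n_presences", "ns_distance_km"):
            if getattr(self, field) < 0:
                raise GridDataError(f"{field} must be >= 0")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------
# predictors.csv: cell_id,x_km,y_km,area_fraction,region,<name>:<tag>,...
# occurrences.csv: species,cell_id,date,region
# profiles.csv:    species,time_since_introduction,economic_interest,
#                  n_presences,ns_distance_km

def write_predictors(path, grid: pd.DataFrame, stack: PredictorStack, region: str) -> None:
    if region not in REGIONS:
        raise GridDataError(f"region must be one of {REGIONS}, got {region!r}")
    grid = grid.set_index("cell_id") if "cell_id" in grid.columns else grid
    out = pd.DataFrame(index=stack.frame.index)
    for col in ("x_km", "y_km", "area_fraction"):
        out[col] = grid.loc[out.index, col]
    out["region"] = region
    for name in stack.names:
        out[f"{name}:{stack.tags[name]}"] = stack.frame[name]
    out.index.name = "cell_id"
    out.to_csv(path, float_format="%.10g")


def read_predictors(path) -> tuple[pd.DataFrame, PredictorStack, str]:
    """Read a predictor table; returns (grid, stack, region)."""
    df = pd.read_csv(path)
    for col in GRID_COLUMNS + ("region",):
        if col not in df.columns:
            raise GridDataError(f"{path}: missing required column {col!r}")
    regions = df["region"].astype(str).str.lower().unique()
    if len(regions) != 1 or regions[0] not in REGIONS:
        raise GridDataError(f"{path}: region column must be a single value in {REGIONS}")
    pred_cols = [c for c in df.columns if c not in GRID_COLUMNS + ("region",)]
    tags = {}
    names = []
    for col in pred_cols:
        if ":" not in col:
            raise GridDataError(f"{path}: predictor header {col!r} lacks a ':tag' suffix")
        name, tag = col.rsplit(":", 1)
        if tag not in VALID_TAGS:
            raise GridDataError(f"{path}: column {name!r} has unknown tag {tag!r}")
        if name in tags:
            raise GridDataError(f"{path}: duplicate predictor name {name!r}")
        tags[name] = tag
        names.append(name)
    body = df[pred_cols + ["x_km", "y_km", "area_fraction"]]
    nan_rows = body.isna().any(axis=1)
    if nan_rows.any():
        row = int(np.flatnonzero(nan_rows.to_numpy())[0])
        raise GridDataError(f"{path}: missing value in data row {row}")
    grid = df[list(GRID_COLUMNS)].copy()
    grid["cell_id"] = grid["cell_id"].astype(int)
    frame = df[pred_cols].copy()
    frame.columns = names
    frame.index = grid["cell_id"].to_numpy()
    stack = PredictorStack(frame, tags)
    return grid.reset_index(drop=True), stack, regions[0]


def _parse_dates(raw: pd.Series, path) -> pd.Series:
    """Integer steps pass through; anything else must be an ISO date (-> day ordinal)."""
    out = pd.to_numeric(raw, errors="coerce")
    as_int = out.dropna()
    if (as_int == as_int.astype(int)).all() and not out.isna().any():
        return out.astype(int)
    parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = parsed.isna() & out.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise GridDataError(f"{path}: unparseable date in data row {row}: {raw.iloc[row]!r}")
    ordinals = parsed.map(lambda d: d.toordinal() if pd.notna(d) else np.nan)
    merged = out.where(~out.isna(), ordinals)
    return merged.astype(int)


def read_occurrences(path, grid: pd.DataFrame | None = None) -> tuple[OccurrenceSet, int]:
    """Read occurrence records; returns (deduplicated set, duplicate count).

    ``cell_id`` may be replaced by ``x_km``/``y_km`` columns, resolved to the
    nearest cell centroid of ``grid``.
    """
    df = pd.read_csv(path)
    for col in ("species", "date", "region"):
        if col not in df.columns:
            raise GridDataError(f"{path}: missing required column {col!r}")
    if "cell_id" not in df.columns:
        if not {"x_km", "y_km"} <= set(df.columns):
            raise GridDataError(f"{path}: needs either cell_id or x_km/y_km columns")
        if grid is None:
            raise GridDataError(f"{path}: x/y records need a grid to resolve cells")
        coords = grid[["x_km", "y_km"]].to_numpy()
        pts = df[["x_km", "y_km"]].to_numpy(dtype=float)
        from scipy.spatial import cKDTree

        _, nearest = cKDTree(coords).query(pts)
        df["cell_id"] = grid["cell_id"].to_numpy()[nearest]
    df["date"] = _parse_dates(df["date"].astype(str).str.strip(), path)
    occ = OccurrenceSet(df[list(OccurrenceSet.COLUMNS)])
    return occ.deduplicate()


def write_occurrences(occ: OccurrenceSet, path) -> None:
    occ.records.to_csv(path, index=False)


def write_profiles(profiles: Iterable[SpeciesProfile], path) -> None:
    rows = [
        {
            "species": p.species,
            "time_since_introduction": p.time_since_introduction,
            "economic_interest": "yes" if p.economic_interest else "no",
            "n_presences": p.n_presences,
            "ns_distance_km": p.ns_distance_km,
        }
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_profiles(path) -> list[SpeciesProfile]:
    df = pd.read_csv(path)
    return [
        SpeciesProfile(
            species=str(r.species),
            time_since_introduction=float(r.time_since_introduction),
            economic_interest=str(r.economic_interest).strip().lower() in ("yes", "true", "1"),
            n_presences=int(r.n_presences),
            ns_distance_km=float(r.ns_distance_km),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Domain constraints
# ---------------------------------------------------------------------------

def filter_valid_cells(grid: pd.DataFrame, min_area_fraction: float = MIN_AREA_FRACTION) -> pd.DataFrame:
    """Drop cells with less than the minimum land-area fraction.

    The boundary is inclusive: a cell with exactly the threshold fraction is
    retained (cells with *less* than 70% of their area in the study region,
    typically coastal ones, are excluded).
    """
    if "area_fraction" not in grid.columns:
        raise GridDataError("grid lacks an area_fraction column")
    return grid[grid["area_fraction"] >= min_area_fraction].reset_index(drop=True)


def _presence_coords(grid: pd.DataFrame, presences: pd.DataFrame) -> np.ndarray:
    g = grid.set_index("cell_id")
    cells = presences["cell_id"].astype(int)
    missing = set(cells) - set(g.index)
    if missing:
        raise GridDataError(f"presence cells not in grid: {sorted(missing)[:5]}")
    return g.loc[cells, ["x_km", "y_km"]].to_numpy(dtype=float)


def constrain_invaded_domain(
    grid: pd.DataFrame, presences: pd.DataFrame, buffer_km: float = 200.0
) -> pd.DataFrame:
    """Clip the invaded-region grid to within ``buffer_km`` north of the
    northernmost presence ("north" = larger y in planar km)."""
    if len(presences) == 0:
        raise GridDataError("cannot constrain invaded domain with zero presences")
    y_max = _presence_coords(grid, presences)[:, 1].max()
    return grid[grid["y_km"] <= y_max + buffer_km].reset_index(drop=True)


def constrain_native_domain(grid: pd.DataFrame, native_presences: pd.DataFrame) -> pd.DataFrame:
    """Retain cells whose centroid lies inside or on the convex hull of the
    native presence coordinates."""
    coords = _presence_coords(grid, native_presences)
    if len(coords) < 3:
        raise GridDataError("convex hull needs at least 3 native presences")
    hull = MultiPoint([tuple(p) for p in coords]).convex_hull
    if hull.geom_type != "Polygon":  # collinear or coincident points
        raise GridDataError("native presences are collinear; convex hull is degenerate")
    keep = np.fromiter(
        (hull.covers(Point(x, y)) for x, y in grid[["x_km", "y_km"]].to_numpy()),
        dtype=bool,
        count=len(grid),
    )
    return grid[keep].reset_index(drop=True)


def distance_to_first_record(grid: pd.DataFrame, occurrences: pd.DataFrame) -> pd.Series:
    """Euclidean distance (km) from every cell to the earliest-dated record.

    Ties at the earliest date are broken by the lowest cell id.  The result
    is a Series indexed by cell_id, suitable for
    ``stack.with_column(name, values, DIST_FIRST_RECORD)``.
    """
    if len(occurrences) == 0:
        raise GridDataError("distance_to_first_record needs at least one dated record")
    first = occurrences.sort_values(["date", "cell_id"]).iloc[0]
    g = grid.set_index("cell_id")
    if int(first.cell_id) not in g.index:
        raise GridDataError(f"first-record cell {int(first.cell_id)} not in grid")
    x0, y0 = g.loc[int(first.cell_id), ["x_km", "y_km"]]
    d = np.hypot(g["x_km"] - x0, g["y_km"] - y0)
    d.name = "dist_first_record"
    return d


def sampling_coverage(grid: pd.DataFrame, related_records: pd.DataFrame) -> float:
    """Fraction of grid cells holding at least one related-native record.

    Used as the sampling-effort check that justifies treating uncovered cells
    with caution when drawing pseudo-absences.
    """
    if len(grid) == 0:
        return 0.0
    covered = set(related_records["cell_id"].astype(int)) & set(grid["cell_id"].astype(int))
    return len(covered) / len(grid)
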