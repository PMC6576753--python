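"""Synthetic landscapes, invasions, and biased observation records.

This module manufactures test-bed data with the statistical structure the
downstream analysis assumes, while retaining full generating truth:

* spatially autocorrelated environmental layers (Gaussian-smoothed white
  noise), standing in for climate / topography rasters;
* anthropic layers built as Euclidean distances to generated facility
  points (cities, pet stores, ports);
* a dated invasion front spreading from a known introduction cell through a
  mixture of environmentally driven short-range diffusion and
  human-mediated long-distance jumps;
* detection with configurable accessibility bias, and surrogate
  related-native records for sampling-effort accounting.

Every generator is a pure function of (configuration, seed).  The generating
coefficients, introduction cell, and per-cell colonization dates are kept in
a :class:`SimulationTruth` so recovery experiments can compare estimates
against truth; nothing downstream of this module reads the truth.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import expit

from .griddata import (
    ANTHROPIC,
    ENVIRONMENTAL,
    GridDataError,
    OccurrenceSet,
    PredictorStack,
)

INTERCEPT = "intercept"


@dataclasses.dataclass
class Landscape:
    """A pair of regional grids plus their predictor stacks.

    The native stack carries environmental columns only (anthropic layers
    have the opposite meaning in a species' native range and are never
    generated there), sharing names with the invaded environmental columns.
    """

    invaded_grid: pd.DataFrame
    native_grid: pd.DataFrame
    predictors_invaded: PredictorStack
    predictors_native: PredictorStack

    def __post_init__(self):
        anthro = self.predictors_native.names_with_tags([ANTHROPIC])
        if anthro:
            raise GridDataError(f"native stack must not contain anthropic columns: {anthro}")
        inv_env = set(self.predictors_invaded.names_with_tags([ENVIRONMENTAL]))
        nat_env = set(self.predictors_native.names_with_tags([ENVIRONMENTAL]))
        if not nat_env <= inv_env:
            raise GridDataError(
                f"native environmental columns {sorted(nat_env - inv_env)} "
                "missing from invaded stack"
            )


@dataclasses.dataclass
class SimulationTruth:
    """Generating model of one simulated invasion.

    ``beta`` maps predictor names (plus optional ``"intercept"``) to
    coefficients of the suitability logit; coefficients apply to per-grid
    z-scored predictor columns so that magnitudes near 1 are meaningful
    regardless of a layer's units.
    """

    beta: dict[str, float]
    intro_cell: int
    jump_rate: float
    dispersal_scale_km: float
    colonization_date: dict[int, int] = dataclasses.field(default_factory=dict)
    parent: dict[int, int] = dataclasses.field(default_factory=dict)

    def validate_forest(self) -> None:
        """Colonization dates must form a forest rooted at the intro cell."""
        dates = self.colonization_date
        if dates.get(self.intro_cell) != 0:
            raise ValueError("introduction cell must have colonization date 0")
        for cell, t in dates.items():
            if cell == self.intro_cell:
                continue
            p = self.parent.get(cell)
            if p is None or p not in dates:
                raise ValueError(f"colonized cell {cell} has no colonized parent")
            if dates[p] >= t:
                raise ValueError(f"parent of {cell} not colonized strictly earlier")


# ---------------------------------------------------------------------------
# Layer generators
# ---------------------------------------------------------------------------

def make_grid(nx: int = 40, ny: int = 50, cell_km: float = 5.0) -> pd.DataFrame:
    """Regular nx-by-ny grid of square cells; centroids in planar km."""
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return pd.DataFrame(
        {
            "cell_id": np.arange(nx * ny),
            "x_km": (ii.ravel() + 0.5) * cell_km,
            "y_km": (jj.ravel() + 0.5) * cell_km,
            "area_fraction": 1.0,
        }
    )


def _coords(grid: pd.DataFrame) -> np.ndarray:
    return grid[["x_km", "y_km"]].to_numpy(dtype=float)


def gen_env_field(grid: pd.DataFrame, correlation_range_km: float, seed: int) -> pd.Series:
    """Spatially autocorrelated field: Gaussian-kernel low-pass of white noise.

    The kernel bandwidth is the stated correlation range, so cell-to-cell
    correlation decays on that km scale.  Values are standardized to mean 0,
    sd 1 over the grid.
    """
    if len(grid) == 0:
        raise GridDataError("cannot generate a field on an empty grid")
    if correlation_range_km <= 0:
        raise ValueError("correlation_range_km must be > 0")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(len(grid))
    xy = _coords(grid)
    d2 = cdist(xy, xy, "sqeuclidean")
    w = np.exp(-d2 / (2.0 * correlation_range_km**2))
    field = w @ z
    sd = field.std()
    # infinite-range limit: the kernel is uniform and the raw field is
    # numerically constant; standardizing rounding noise would manufacture
    # spurious structure, so return the flat field instead
    if sd <= 1e-8 * (np.abs(field).max() + 1e-300):
        field = np.zeros_like(field)
    else:
        field = (field - field.mean()) / sd
    return pd.Series(field, index=grid["cell_id"].to_numpy(), name="env")


def gen_point_distance_layer(
    grid: pd.DataFrame, n_points: int, seed: int, return_points: bool = False
):
    """Distance (km) from each cell centroid to the nearest generated facility.

    Facilities are placed uniformly over the grid's bounding box — the
    pattern behind all anthropic distance layers (pet stores, ports, cities).
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    xy = _coords(grid)
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    pts = rng.uniform(lo, hi, size=(n_points, 2))
    dist = cdist(xy, pts).min(axis=1)
    series = pd.Series(dist, index=grid["cell_id"].to_numpy(), name="dist")
    return (series, pts) if return_points else series


def nearest_facility_distance(xy: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Distance from each coordinate to its nearest facility point."""
    return cdist(xy, points).min(axis=1)


# ---------------------------------------------------------------------------
# Invasion dynamics
# ---------------------------------------------------------------------------

def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    return (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)


def _linear_predictor(stack: PredictorStack, beta: Mapping[str, float], names) -> np.ndarray:
    eta = np.full(stack.n_cells, float(beta.get(INTERCEPT, 0.0)))
    for name in names:
        if name == INTERCEPT:
            continue
        if name not in stack.frame.columns:
            raise GridDataError(f"truth coefficient refers to unknown predictor {name!r}")
        eta += beta[name] * _zscore(stack.frame[name].to_numpy())
    return eta


def simulate_invasion(
    landscape: Landscape, truth: SimulationTruth, n_steps: int, seed: int
) -> tuple[dict[int, int], dict[int, int]]:
    """Spread an invasion over the invaded grid for ``n_steps`` steps.

    Two independent colonization channels act on every uncolonized cell at
    each step:

    * diffusion: probability ``logistic(beta . x) * exp(-d / dispersal_scale)``
      where ``d`` is the distance to the nearest colonized cell;
    * human-mediated jump: probability
      ``jump_rate * logistic(beta_anthropic . x_anthropic)`` (uniform
      ``jump_rate/2`` when the truth loads no anthropic layer).

    Returns (colonization_date, parent) maps; the parent of a newly
    colonized cell is its nearest already-colonized cell, so dates form a
    forest rooted at the introduction cell.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    grid = landscape.invaded_grid
    stack = landscape.predictors_invaded
    ids = grid["cell_id"].to_numpy()
    if truth.intro_cell not in set(ids):
        raise GridDataError(f"introduction cell {truth.intro_cell} not in grid")
    rng = np.random.default_rng(seed)
    xy = _coords(grid)
    n = len(ids)
    pos = {c: i for i, c in enumerate(ids)}

    suit = expit(_linear_predictor(stack, truth.beta, truth.beta.keys()))
    anthro_names = [
        c for c in stack.names_with_tags([ANTHROPIC]) if c in truth.beta
    ]
    jump_suit = expit(_linear_predictor(stack, truth.beta, anthro_names))

    colonized = np.zeros(n, dtype=bool)
    dates = np.full(n, -1, dtype=int)
    parents = np.full(n, -1, dtype=int)
    i0 = pos[truth.intro_cell]
    colonized[i0] = True
    dates[i0] = 0
    # nearest-colonized distance and its argmin, updated incrementally
    dmin = np.hypot(xy[:, 0] - xy[i0, 0], xy[:, 1] - xy[i0, 1])
    amin = np.full(n, i0, dtype=int)

    for t in range(1, n_steps + 1):
        open_idx = np.flatnonzero(~colonized)
        if len(open_idx) == 0:
            break
        d = dmin[open_idx]
        if truth.dispersal_scale_km > 0:
            kernel = np.exp(-d / truth.dispersal_scale_km)
        else:
            kernel = (d == 0).astype(float)
        p_loc = suit[open_idx] * kernel
        p_jump = truth.jump_rate * jump_suit[open_idx]
        p = 1.0 - (1.0 - p_loc) * (1.0 - p_jump)
        hit = open_idx[rng.random(len(open_idx)) < p]
        if len(hit) == 0:
            continue
        dates[hit] = t
        parents[hit] = amin[hit]
        colonized[hit] = True
        # update nearest-colonized distances with the newly colonized cells
        dnew = cdist(xy, xy[hit])
        j = dnew.argmin(axis=1)
        better = dnew[np.arange(n), j] < dmin
        dmin[better] = dnew[better, j[better]]
        amin[better] = hit[j[better]]

    col_dates = {int(ids[i]): int(dates[i]) for i in np.flatnonzero(colonized)}
    par = {
        int(ids[i]): int(ids[parents[i]])
        for i in np.flatnonzero(colonized)
        if i != i0
    }
    return col_dates, par


def simulate_observation(
    colonization_date: Mapping[int, int],
    detection_prob: float,
    bias_layer: pd.Series | None,
    seed: int,
    species: str = "species_1",
) -> OccurrenceSet:
    """Detect colonized cells with probability ``detection_prob * bias(cell)``.

    A detected cell yields one presence record dated at its colonization
    step; uncolonized cells never produce records.
    """
    if not 0 < detection_prob <= 1:
        raise ValueError("detection_prob must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for cell in sorted(colonization_date):
        bias = 1.0 if bias_layer is None else float(np.clip(bias_layer.loc[cell], 0.0, 1.0))
        if rng.random() < detection_prob * bias:
            rows.append(
                {
                    "species": species,
                    "cell_id": cell,
                    "date": colonization_date[cell],
                    "region": "invaded",
                }
            )
    return OccurrenceSet(pd.DataFrame(rows, columns=list(OccurrenceSet.COLUMNS)))


def accessibility_bias(
    grid: pd.DataFrame, dist_to_city: pd.Series, halfway_km: float = 40.0, scale_km: float = 15.0
) -> pd.Series:
    """Detection bias decaying with distance to the nearest city.

    A logistic accessibility curve: ~1 near cities, 0.5 at ``halfway_km``,
    approaching 0 in remote cells.
    """
    b = expit(-(dist_to_city.loc[grid["cell_id"].to_numpy()] - halfway_km) / scale_km)
    return pd.Series(b.to_numpy(), index=grid["cell_id"].to_numpy())


def gen_related_native_records(
    landscape: Landscape, coverage_fraction: float, seed: int, species: str = "related_native"
) -> OccurrenceSet:
    """Surrogate related-native records over the invaded grid.

    Each cell independently holds a record with the stated probability, so
    realized coverage concentrates tightly around the request on grids of a
    few thousand cells.
    """
    if not 0 <= coverage_fraction <= 1:
        raise ValueError("coverage_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = landscape.invaded_grid["cell_id"].to_numpy()
    keep = rng.random(len(ids)) < coverage_fraction if coverage_fraction < 1 else np.ones(len(ids), bool)
    rows = [
        {"species": species, "cell_id": int(c), "date": 0, "region": "invaded"}
        for c in ids[keep]
    ]
    return OccurrenceSet(pd.DataFrame(rows, columns=list(OccurrenceSet.COLUMNS)))


def simulate_native_presences(
    landscape: Landscape, truth: SimulationTruth, base_rate: float, seed: int, species: str = "species_1"
) -> OccurrenceSet:
    """Native-range presences drawn from the environmental part of the truth.

    Cell probability = ``base_rate * logistic(beta_env . x_native)``; dates
    are 0 (native records carry no invasion chronology).
    """
    rng = np.random.default_rng(seed)
    stack = landscape.predictors_native
    env_names = [c for c in stack.names if c in truth.beta]
    p = base_rate * expit(_linear_predictor(stack, truth.beta, env_names))
    ids = landscape.native_grid["cell_id"].to_numpy()
    keep = rng.random(len(ids)) < p[: len(ids)]
    rows = [
        {"species": species, "cell_id": int(c), "date": 0, "region": "native"}
        for c in ids[keep]
    ]
    return OccurrenceSet(pd.DataFrame(rows, columns=list(OccurrenceSet.COLUMNS)))


# ---------------------------------------------------------------------------
# Default study landscape
# ---------------------------------------------------------------------------

DEFAULT_ENV_RANGES = (15.0, 25.0, 35.0, 50.0, 70.0)
DEFAULT_FACILITIES = {"dist_cities": 10, "dist_pet_stores": 40, "dist_ports": 15}


def default_landscape(
    seed: int,
    nx: int = 40,
    ny: int = 50,
    cell_km: float = 5.0,
    env_ranges=DEFAULT_ENV_RANGES,
    facilities: Mapping[str, int] | None = None,
    coastal_band: int = 1,
) -> Landscape:
    """Build the default 40x50-cell (5 km) two-region study landscape.

    Environmental layers share names across regions but are independent
    realizations (two disjoint geographies).  Cells in the outermost
    ``coastal_band`` rows/columns get partial area fractions so that the
    land-area validity filter has work to do.
    """
    facilities = dict(DEFAULT_FACILITIES if facilities is None else facilities)
    rng = np.random.default_rng(seed)

    def one_grid(offset: int) -> pd.DataFrame:
        grid = make_grid(nx, ny, cell_km)
        if coastal_band > 0:
            xy = _coords(grid)
            lo, hi = xy.min(axis=0), xy.max(axis=0)
            edge = (
                (xy[:, 0] - lo[0] < coastal_band * cell_km)
                | (hi[0] - xy[:, 0] < coastal_band * cell_km)
                | (xy[:, 1] - lo[1] < coastal_band * cell_km)
                | (hi[1] - xy[:, 1] < coastal_band * cell_km)
            )
            frac = np.ones(len(grid))
            sub = np.random.default_rng(seed + 7 + offset)
            frac[edge] = sub.uniform(0.3, 1.0, edge.sum())
            grid["area_fraction"] = frac
        return grid

    inv_grid = one_grid(0)
    nat_grid = one_grid(1)

    env_names = [f"env_{i + 1}" for i in range(len(env_ranges))]
    inv_cols, nat_cols, tags_inv, tags_nat = {}, {}, {}, {}
    for i, (name, rng_km) in enumerate(zip(env_names, env_ranges)):
        inv_cols[name] = gen_env_field(inv_grid, rng_km, seed + 100 + i).to_numpy()
        nat_cols[name] = gen_env_field(nat_grid, rng_km, seed + 200 + i).to_numpy()
        tags_inv[name] = ENVIRONMENTAL
        tags_nat[name] = ENVIRONMENTAL
    for i, (name, n_points) in enumerate(sorted(facilities.items())):
        inv_cols[name] = gen_point_distance_layer(inv_grid, n_points, seed + 300 + i).to_numpy()
        tags_inv[name] = ANTHROPIC
    # population density: patchy at near-cell scale, unlike the smooth
    # facility-distance cones — propagule pressure varies cell to cell
    inv_cols["pop_density"] = gen_env_field(inv_grid, 8.0, seed + 400).to_numpy()
    tags_inv["pop_density"] = ANTHROPIC

    stack_inv = PredictorStack(
        pd.DataFrame(inv_cols, index=inv_grid["cell_id"].to_numpy()), tags_inv
    )
    stack_nat = PredictorStack(
        pd.DataFrame(nat_cols, index=nat_grid["cell_id"].to_numpy()), tags_nat
    )
    return Landscape(inv_grid, nat_grid, stack_inv, stack_nat)


def make_truth(
    landscape: Landscape,
    driver: str,
    seed: int,
    intercept: float | None = None,
    effect: float | None = None,
    jump_rate: float | None = None,
    dispersal_scale_km: float | None = None,
) -> SimulationTruth:
    """Generating truth for one species under a named driver regime.

    ``driver`` selects which predictor family carries the signal:

    * ``"environmental"`` — suitability loads on the environmental layers;
      diffusion-dominated spread (small uniform jump rate);
    * ``"anthropic"`` — suitability loads on the anthropic distance layers
      (negative coefficients: close to facilities = suitable); spread is
      jump-dominated, emulating propagule-pressure-driven invasion;
    * ``"mixed"`` — both families at half strength.
    """
    rng = np.random.default_rng(seed)
    stack = landscape.predictors_invaded
    env = stack.names_with_tags([ENVIRONMENTAL])
    anth = stack.names_with_tags([ANTHROPIC])
    if driver == "environmental":
        # diffusion-dominated: the front advances into climatically suitable cells
        intercept = -3.0 if intercept is None else intercept
        effect = 1.8 if effect is None else effect
        jr = 0.001 if jump_rate is None else jump_rate
        ds = 4.5 if dispersal_scale_km is None else dispersal_scale_km
    elif driver == "anthropic":
        # jump-dominated: propagule pressure, not climate, places colonists
        intercept = -2.5 if intercept is None else intercept
        effect = 2.5 if effect is None else effect
        jr = 0.03 if jump_rate is None else jump_rate
        ds = 1.0 if dispersal_scale_km is None else dispersal_scale_km
    elif driver == "mixed":
        intercept = -2.75 if intercept is None else intercept
        effect = 2.0 if effect is None else effect
        jr = 0.01 if jump_rate is None else jump_rate
        ds = 2.5 if dispersal_scale_km is None else dispersal_scale_km
    else:
        raise ValueError(f"unknown driver {driver!r}")
    beta: dict[str, float] = {INTERCEPT: intercept}
    if driver == "environmental":
        signs = rng.choice([-1.0, 1.0], size=len(env))
        for name, s in zip(env, signs):
            beta[name] = s * effect * rng.uniform(0.5, 1.0)
    elif driver == "anthropic":
        for name in anth:
            # distance layers: closer to facilities = more suitable; density
            # layers carry the propagule-pressure signal and dominate
            if name.startswith("dist"):
                beta[name] = -effect * rng.uniform(0.7, 1.0)
            else:
                beta[name] = effect * rng.uniform(1.2, 1.5)
    else:
        for name in env:
            beta[name] = rng.choice([-1.0, 1.0]) * 0.5 * effect * rng.uniform(0.5, 1.0)
        for name in anth:
            sign = -1.0 if name.startswith("dist") else 1.0
            beta[name] = sign * 0.5 * effect * rng.uniform(0.7, 1.0)
    # introduction succeeds where conditions allow: intro cell drawn from the
    # top decile of generating suitability
    suit = expit(_linear_predictor(stack, beta, beta.keys()))
    ids = landscape.invaded_grid["cell_id"].to_numpy()
    top = ids[suit >= np.quantile(suit, 0.9)]
    intro = int(rng.choice(top))
    return SimulationTruth(beta=beta, intro_cell=intro, jump_rate=jr, dispersal_scale_km=ds)


# ---------------------------------------------------------------------------
# Truth serialization (flat key=value text)
# ---------------------------------------------------------------------------

def write_truth(truth: SimulationTruth, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"intro_cell={truth.intro_cell}\n")
        fh.write(f"jump_rate={truth.jump_rate!r}\n")
        fh.write(f"dispersal_scale_km={truth.dispersal_scale_km!r}\n")
        for name in sorted(truth.beta):
            fh.write(f"beta.{name}={truth.beta[name]!r}\n")
        for cell in sorted(truth.colonization_date):
            fh.write(f"colonized.{cell}={truth.colonization_date[cell]}\n")
        for cell in sorted(truth.parent):
            fh.write(f"parent.{cell}={truth.parent[cell]}\n")


def read_truth(path) -> SimulationTruth:
    beta: dict[str, float] = {}
    dates: dict[int, int] = {}
    parent: dict[int, int] = {}
    scalars: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            if key.startswith("beta."):
                beta[key[5:]] = float(raw)
            elif key.startswith("colonized."):
                dates[int(key[10:])] = int(raw)
            elif key.startswith("parent."):
                parent[int(key[7:])] = int(raw)
            else:
                scalars[key] = float(raw)
    return SimulationTruth(
        beta=beta,
        intro_cell=int(scalars["intro_cell"]),
        jump_rate=scalars["jump_rate"],
        dispersal_scale_km=scalars["dispersal_scale_km"],
        colonization_date=dates,
        parent=parent,
    )
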