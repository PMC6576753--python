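"""Collinearity filtering, scenario assembly, temporal splitting,
pseudo-absence sampling, and spatial-sorting-bias correction.

The three modelling scenarios differ in which predictor families and which
regions' records enter the design matrix:

* ``INVADED`` — environmental layers plus distance-to-first-record, invaded
  region only;
* ``NATIVE`` — environmental layers only, trained on native presences plus
  the invaded training presences (anthropic layers are excluded: human
  activity tends to have the opposite association in a species' native
  range);
* ``MIXED`` — environmental plus anthropic layers plus
  distance-to-first-record, invaded region only.

Validation is temporally independent: the oldest 70% of dated invaded
records train the models, the newest 30% test them.  Because the test
presences of an expanding invasion sit close to the training presences,
test pseudo-absences are matched by pairwise distance sampling so that the
presence/absence distance-to-training distributions agree (spatial sorting
bias correction).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .griddata import (
    ANTHROPIC,
    DIST_FIRST_RECORD,
    ENVIRONMENTAL,
    GridDataError,
    PredictorStack,
)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """Which predictor tags and training regions a scenario uses."""

    name: str
    tags: frozenset
    use_native: bool

    def __post_init__(self):
        if self.use_native and ANTHROPIC in self.tags:
            raise GridDataError(
                f"scenario {self.name}: anthropic predictors cannot be combined "
                "with native-range records"
            )


SCENARIOS: dict[str, ScenarioSpec] = {
    "INVADED": ScenarioSpec("INVADED", frozenset({ENVIRONMENTAL, DIST_FIRST_RECORD}), False),
    "NATIVE": ScenarioSpec("NATIVE", frozenset({ENVIRONMENTAL}), True),
    "MIXED": ScenarioSpec(
        "MIXED", frozenset({ENVIRONMENTAL, ANTHROPIC, DIST_FIRST_RECORD}), False
    ),
}


# ---------------------------------------------------------------------------
# Collinearity: variance inflation factors
# ---------------------------------------------------------------------------

_R2_SINGULAR = 1.0 - 1e-10


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF_j = 1 / (1 - R^2_j), R^2 from OLS of column j on the others."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot <= 0:
        return np.inf
    r2 = 1.0 - resid @ resid / ss_tot
    if r2 >= _R2_SINGULAR:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_scores(X: pd.DataFrame) -> pd.Series:
    """VIF of every column against all the others."""
    arr = X.to_numpy(dtype=float)
    return pd.Series([_vif_one(arr, j) for j in range(arr.shape[1])], index=X.columns)


def vif_filter(
    X: pd.DataFrame, threshold: float = 10.0
) -> tuple[list[str], list[str]]:
    """Iteratively drop the worst-VIF column while any VIF exceeds the threshold.

    Zero-variance columns are dropped first (their VIF is undefined).
    Returns (retained column names in original order, log messages).
    """
    if X.shape[1] < 2:
        return list(X.columns), []
    log: list[str] = []
    cols = list(X.columns)
    for c in list(cols):
        if X[c].std() < 1e-12:
            cols.remove(c)
            log.append(f"dropped zero-variance column {c!r}")
    while len(cols) > 1:
        vifs = vif_scores(X[cols])
        worst = vifs.idxmax()
        if vifs[worst] <= threshold:
            break
        cols.remove(worst)
        log.append(f"dropped {worst!r} (VIF={vifs[worst]:.3g})")
    return cols, log


# ---------------------------------------------------------------------------
# Temporal split
# ---------------------------------------------------------------------------

def temporal_split(
    occurrences: pd.DataFrame, train_frac: float = 0.7
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Oldest ``round(train_frac * n)`` records train; the newest test.

    Records sharing the boundary date are ordered by cell id, so the split
    is deterministic and every training date <= every testing date.
    """
    n = len(occurrences)
    if n < 4:
        raise GridDataError(f"temporal split needs >= 4 records, got {n}")
    if occurrences["date"].nunique() < 2:
        raise GridDataError("all records share one date; no temporal signal to split on")
    ordered = occurrences.sort_values(["date", "cell_id"], kind="mergesort").reset_index(drop=True)
    n_train = int(math.floor(train_frac * n + 0.5))  # half-up rounding
    n_train = min(max(n_train, 1), n - 1)
    return ordered.iloc[:n_train].copy(), ordered.iloc[n_train:].copy()


# ---------------------------------------------------------------------------
# Pseudo-absences
# ---------------------------------------------------------------------------

def sample_pseudoabsences(
    grid: pd.DataFrame,
    focal_presence_cells: Iterable[int],
    n: int,
    seed: int,
    pool: str = "all",
    related_cells: Iterable[int] | None = None,
    exclude: Iterable[int] | None = None,
) -> np.ndarray:
    """Draw ``n`` distinct cells uniformly at random from cells without a
    focal presence.

    ``pool="sampled"`` restricts the pool to cells with related-native
    coverage (the sampling-effort check); ``exclude`` removes further cells,
    e.g. cells already used as training pseudo-absences.
    """
    presences = set(int(c) for c in focal_presence_cells)
    eligible = [int(c) for c in grid["cell_id"] if int(c) not in presences]
    if pool == "sampled":
        if related_cells is None:
            raise GridDataError('pool="sampled" needs related-native cells')
        covered = set(int(c) for c in related_cells)
        eligible = [c for c in eligible if c in covered]
    elif pool != "all":
        raise GridDataError(f'pool must be "all" or "sampled", got {pool!r}')
    if exclude is not None:
        banned = set(int(c) for c in exclude)
        eligible = [c for c in eligible if c not in banned]
    if len(eligible) < n:
        raise GridDataError(
            f"pseudo-absence pool too small: {len(eligible)} eligible cells for n={n}"
        )
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(np.array(sorted(eligible)), size=n, replace=False))


# ---------------------------------------------------------------------------
# Spatial sorting bias
# ---------------------------------------------------------------------------

def _nearest_distances(points: np.ndarray, reference: np.ndarray) -> np.ndarray:
    return cdist(points, reference).min(axis=1)


def calc_ssb(
    test_pres_xy: np.ndarray, test_abs_xy: np.ndarray, train_pres_xy: np.ndarray
) -> tuple[float, float, float]:
    """Spatial sorting bias diagnostic.

    Returns ``(d_p, d_a, ratio)``: the mean nearest-training-presence
    distance of the test presences, the same for the test absences, and
    their ratio.  A ratio near 1 indicates no sorting bias; a ratio well
    below 1 means the test presences hug the training presences and model
    accuracy will be inflated.
    """
    for name, arr in (("test presences", test_pres_xy), ("test absences", test_abs_xy),
                      ("training presences", train_pres_xy)):
        if len(arr) == 0:
            raise GridDataError(f"calc_ssb: empty {name}")
    d_p = float(_nearest_distances(np.asarray(test_pres_xy, float), np.asarray(train_pres_xy, float)).mean())
    d_a = float(_nearest_distances(np.asarray(test_abs_xy, float), np.asarray(train_pres_xy, float)).mean())
    ratio = d_p / d_a if d_a > 0 else np.inf
    return d_p, d_a, ratio


@dataclasses.dataclass
class PwdResult:
    """Outcome of pairwise distance sampling."""

    matched_pres: np.ndarray  # indices into test presences
    matched_abs: np.ndarray  # indices into the candidate pool
    unmatched_pres: np.ndarray


def pwd_sample(
    test_pres_xy: np.ndarray,
    candidate_abs_xy: np.ndarray,
    train_pres_xy: np.ndarray,
    tr: float = 0.33,
    seed: int | None = None,
) -> PwdResult:
    """Pairwise distance sampling of test absences.

    For each test presence with nearest-training distance ``d_f``, greedily
    (in order of increasing ``d_f``) pick an unused candidate absence whose
    nearest-training distance ``d_s`` satisfies ``|d_s - d_f| <= tr * d_f``;
    among admissible candidates the closest in distance is taken, ties by
    lowest index.  Presences with no admissible candidate stay unmatched.
    The procedure is deterministic; ``seed`` is accepted for interface
    symmetry with the samplers but unused.
    """
    if len(candidate_abs_xy) == 0:
        raise GridDataError("pwd_sample: empty candidate pool")
    d_f = _nearest_distances(np.asarray(test_pres_xy, float), np.asarray(train_pres_xy, float))
    d_s = _nearest_distances(np.asarray(candidate_abs_xy, float), np.asarray(train_pres_xy, float))
    order = np.argsort(d_f, kind="stable")
    used = np.zeros(len(d_s), dtype=bool)
    pairs: list[tuple[int, int]] = []
    unmatched: list[int] = []
    for i in order:
        gap = np.abs(d_s - d_f[i])
        ok = (~used) & (gap <= tr * d_f[i])
        if not ok.any():
            unmatched.append(int(i))
            continue
        cand = np.flatnonzero(ok)
        j = int(cand[np.argmin(gap[cand])])
        used[j] = True
        pairs.append((int(i), j))
    if not pairs:
        raise GridDataError(
            "pwd_sample: no admissible pairs; enlarge the candidate pool or tolerance"
        )
    mp = np.array([p for p, _ in pairs], dtype=int)
    ma = np.array([a for _, a in pairs], dtype=int)
    return PwdResult(mp, ma, np.array(unmatched, dtype=int))


# ---------------------------------------------------------------------------
# Dataset split bookkeeping and scenario assembly
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DatasetSplit:
    """Cells entering training and (bias-corrected) testing for one species."""

    train_pres: np.ndarray
    train_abs: np.ndarray
    test_pres: np.ndarray  # matched subset after pairwise distance sampling
    test_abs: np.ndarray
    test_pres_all: np.ndarray = dataclasses.field(default=None)
    ssb_before: float = np.nan
    ssb_after: float = np.nan
    n_unmatched: int = 0

    def __post_init__(self):
        if self.test_pres_all is None:
            self.test_pres_all = self.test_pres
        if set(self.train_pres) & set(self.test_pres_all):
            raise GridDataError("train and test presence cells overlap")
        if len(self.train_abs) != len(self.train_pres):
            raise GridDataError("training pseudo-absences must match presence count")
        if set(self.train_abs) & set(self.train_pres):
            raise GridDataError("a training pseudo-absence cell carries a presence")

    def provenance_frame(self) -> pd.DataFrame:
        rows = []
        for role, cells in (
            ("train_presence", self.train_pres),
            ("train_pseudoabsence", self.train_abs),
            ("test_presence", self.test_pres),
            ("test_pseudoabsence", self.test_abs),
        ):
            for c in cells:
                rows.append({"cell_id": int(c), "role": role})
        return pd.DataFrame(rows)


def build_split(
    grid: pd.DataFrame,
    presences: pd.DataFrame,
    seed: int,
    train_frac: float = 0.7,
    pwd_tr: float = 0.33,
    test_abs_pool_factor: int = 10,
    pool: str = "all",
    related_cells: Iterable[int] | None = None,
) -> DatasetSplit:
    """Temporal split plus pseudo-absence sampling and sorting-bias correction.

    Training pseudo-absences: as many as training presences, uniform over
    cells without a focal presence.  Test pseudo-absences: a candidate pool
    of ``test_abs_pool_factor x n_test`` cells (excluding presence cells and
    training pseudo-absence cells) matched to the test presences by pairwise
    distance sampling.
    """
    train, test = temporal_split(presences, train_frac)
    all_pres = presences["cell_id"].astype(int).to_numpy()
    train_pres = train["cell_id"].astype(int).to_numpy()
    test_pres = test["cell_id"].astype(int).to_numpy()

    train_abs = sample_pseudoabsences(
        grid, all_pres, len(train_pres), seed, pool=pool, related_cells=related_cells
    )
    pool_n = min(
        test_abs_pool_factor * len(test_pres),
        len(grid) - len(set(all_pres)) - len(train_abs),
    )
    cand = sample_pseudoabsences(
        grid, all_pres, pool_n, seed + 1, pool=pool,
        related_cells=related_cells, exclude=train_abs,
    )
    g = grid.set_index("cell_id")
    xy = lambda cells: g.loc[np.asarray(cells, int), ["x_km", "y_km"]].to_numpy(float)

    _, _, ssb_before = calc_ssb(xy(test_pres), xy(cand), xy(train_pres))
    matched = pwd_sample(xy(test_pres), xy(cand), xy(train_pres), tr=pwd_tr)
    test_pres_m = test_pres[matched.matched_pres]
    test_abs_m = cand[matched.matched_abs]
    _, _, ssb_after = calc_ssb(xy(test_pres_m), xy(test_abs_m), xy(train_pres))

    return DatasetSplit(
        train_pres=train_pres,
        train_abs=train_abs,
        test_pres=test_pres_m,
        test_abs=test_abs_m,
        test_pres_all=test_pres,
        ssb_before=ssb_before,
        ssb_after=ssb_after,
        n_unmatched=len(matched.unmatched_pres),
    )


@dataclasses.dataclass
class ScenarioData:
    """Assembled design matrices for one scenario."""

    name: str
    columns: list[str]
    X_train: pd.DataFrame
    y_train: np.ndarray
    X_test: pd.DataFrame
    y_test: np.ndarray
    vif_log: list[str]


def assemble_scenario(
    spec: ScenarioSpec | str,
    invaded_stack: PredictorStack,
    split: DatasetSplit,
    native_stack: PredictorStack | None = None,
    native_pres: Sequence[int] | None = None,
    native_abs: Sequence[int] | None = None,
    vif_threshold: float = 10.0,
) -> ScenarioData:
    """Build training and testing design matrices for one scenario.

    Rows: presences (1) and pseudo-absences (0).  The NATIVE scenario
    prepends all native presences (and matching native pseudo-absences) to
    the invaded training rows; evaluation always uses the invaded test
    split.  Columns: the VIF-retained predictors among the scenario's
    permitted tags.
    """
    if isinstance(spec, str):
        spec = SCENARIOS[spec]
    names = invaded_stack.names_with_tags(spec.tags)
    if not names:
        raise GridDataError(f"scenario {spec.name}: no predictors with tags {sorted(spec.tags)}")
    if spec.use_native:
        if native_stack is None or native_pres is None or native_abs is None:
            raise GridDataError(f"scenario {spec.name} needs the native stack and records")
        bad = [n for n in names if n not in native_stack.frame.columns]
        if bad:
            raise GridDataError(
                f"scenario {spec.name}: columns {bad} unavailable in native stack"
            )

    blocks_X = []
    blocks_y = []
    if spec.use_native:
        blocks_X.append(native_stack.matrix_for(native_pres, names))
        blocks_y.append(np.ones(len(native_pres)))
        blocks_X.append(native_stack.matrix_for(native_abs, names))
        blocks_y.append(np.zeros(len(native_abs)))
    blocks_X.append(invaded_stack.matrix_for(split.train_pres, names))
    blocks_y.append(np.ones(len(split.train_pres)))
    blocks_X.append(invaded_stack.matrix_for(split.train_abs, names))
    blocks_y.append(np.zeros(len(split.train_abs)))
    X_train = pd.concat(blocks_X, ignore_index=True)
    y_train = np.concatenate(blocks_y)

    retained, log = vif_filter(X_train, threshold=vif_threshold)
    X_train = X_train[retained]

    test_cells = np.concatenate([split.test_pres, split.test_abs])
    X_test = invaded_stack.matrix_for(test_cells, retained).reset_index(drop=True)
    y_test = np.concatenate([np.ones(len(split.test_pres)), np.zeros(len(split.test_abs))])
    return ScenarioData(spec.name, retained, X_train, y_train, X_test, y_test, log)
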