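"""Calibration and recovery experiments built on the simulator.

These are the package's statistical self-checks, each an explicit
simulation study:

* :func:`null_calibration` — type-I control of the permutation null test:
  with pure-noise suitability and an unbiased test set, the real model
  should exceed its null 97.5th percentile in about 2.5% of replicates;
* :func:`driver_recovery` — attribution: invasions driven by anthropic
  layers (human-mediated jumps) should hand the MIXED scenario the largest
  TSS effect size, while environmentally driven diffusion should erase any
  MIXED advantage over INVADED/NATIVE.

Only this module and the pipeline's acceptance checks ever join model
results back to :class:`~invasdm.synthio.SimulationTruth`.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import evaluate as _evaluate
from . import models as _models
from . import preprocess as _pre
from . import synthio as _syn
from .griddata import DIST_FIRST_RECORD, constrain_invaded_domain, filter_valid_cells, distance_to_first_record


# ---------------------------------------------------------------------------
# Null-model type-I calibration
# ---------------------------------------------------------------------------

def _random_dated_presences(grid, n_pres: int, rng) -> pd.DataFrame:
    """Presences of a 'pure noise' species: uniform cells, random dates.

    No predictor or spatial structure, so the test set carries no sorting
    bias and the real model is exchangeable with its permutation nulls.
    """
    cells = rng.choice(grid["cell_id"].to_numpy(), size=n_pres, replace=False)
    dates = rng.integers(0, 30, size=n_pres)
    return pd.DataFrame(
        {"species": "noise", "cell_id": cells, "date": dates, "region": "invaded"}
    )


def null_calibration(
    n_replicates: int = 200,
    n_null: int = 199,
    seed: int = 0,
    n_pres: int = 60,
    algorithm: str = "GLM",
    landscape: _syn.Landscape | None = None,
) -> pd.DataFrame:
    """Replicate the null test under a noise-only generating model.

    One fixed landscape; per replicate a fresh random presence set, a
    temporal split, equal-n training pseudo-absences and random test
    absences, a real model fit, and a permutation null distribution.
    Returns one row per replicate with the real statistics, the null 97.5th
    percentiles, and exceedance flags.
    """
    if landscape is None:
        landscape = _syn.default_landscape(seed + 1)
    grid = filter_valid_cells(landscape.invaded_grid)
    stack = landscape.predictors_invaded
    env_names = stack.names_with_tags(["environmental"])[:3]
    rows = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + 10_000 + r)
        pres = _random_dated_presences(grid, n_pres, rng)
        train, test = _pre.temporal_split(pres)
        train_pres = train["cell_id"].to_numpy()
        test_pres = test["cell_id"].to_numpy()
        all_pres = pres["cell_id"].to_numpy()
        train_abs = _pre.sample_pseudoabsences(grid, all_pres, len(train_pres), seed + 20_000 + r)
        test_abs = _pre.sample_pseudoabsences(
            grid, all_pres, len(test_pres), seed + 30_000 + r, exclude=train_abs
        )
        X_train = pd.concat(
            [stack.matrix_for(train_pres, env_names), stack.matrix_for(train_abs, env_names)],
            ignore_index=True,
        )
        y_train = np.r_[np.ones(len(train_pres)), np.zeros(len(train_abs))]
        X_test = pd.concat(
            [stack.matrix_for(test_pres, env_names), stack.matrix_for(test_abs, env_names)],
            ignore_index=True,
        )
        y_test = np.r_[np.ones(len(test_pres)), np.zeros(len(test_abs))]
        spec = _models.ModelSpec(algorithm, seed=seed + r)
        fm = _models.fit(spec, X_train, y_train)
        if fm.status != "ok":
            continue
        real = _evaluate.evaluate_scores(
            y_train, _models.predict(fm, X_train), y_test, _models.predict(fm, X_test)
        )
        nulls = _evaluate.null_distribution(
            spec, X_train, y_train, X_test, y_test, n_null=n_null, seed=seed + 40_000 + r
        )
        es = _evaluate.effect_sizes(real, nulls)
        rows.append(
            {
                "replicate": r,
                "TSS_real": real.tss,
                "AUC_real": real.auc,
                "TSSnull_97_5": es.tss_null_97_5,
                "AUCnull_97_5": es.auc_null_97_5,
                "TSS_exceeds": es.tss_better_than_null,
                "AUC_exceeds": es.auc_better_than_null,
                "null_auc_mean": float(np.mean(nulls["AUC"].values)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Driver recovery
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DriverRecoveryResult:
    per_replicate: pd.DataFrame  # replicate x scenario TSSes (wide)
    winner_shares: pd.Series  # fraction of replicates each scenario wins
    best_labels: pd.Series  # best_scenario_table-style label per replicate


def _one_recovery_replicate(driver: str, seed: int, n_null: int, n_steps: int) -> dict | None:
    landscape = _syn.default_landscape(seed)
    truth = _syn.make_truth(landscape, driver, seed + 1)
    dates, parents = _syn.simulate_invasion(landscape, truth, n_steps, seed + 2)
    truth.colonization_date = dates
    occ = _syn.simulate_observation(dates, 0.8, None, seed + 3)
    native = _syn.simulate_native_presences(landscape, truth, 0.15, seed + 4)

    grid = filter_valid_cells(landscape.invaded_grid)
    pres = occ.records[occ.records["cell_id"].isin(grid["cell_id"])]
    if len(pres) < 20:
        return None
    domain = constrain_invaded_domain(grid, pres)
    try:
        split = _pre.build_split(domain, pres, seed=seed + 5)
    except Exception:
        return None
    dist = distance_to_first_record(landscape.invaded_grid, pres)
    stack = landscape.predictors_invaded.with_column(
        "dist_first_record", dist.to_numpy(), DIST_FIRST_RECORD
    )
    nat_grid = filter_valid_cells(landscape.native_grid)
    native_pres = native.records["cell_id"].to_numpy()
    native_pres = native_pres[np.isin(native_pres, nat_grid["cell_id"].to_numpy())]
    if len(native_pres) < 3:
        return None
    native_abs = _pre.sample_pseudoabsences(nat_grid, native_pres, len(native_pres), seed + 6)

    out = {"replicate": seed}
    for scen in ("INVADED", "NATIVE", "MIXED"):
        sd = _pre.assemble_scenario(
            scen, stack, split,
            native_stack=landscape.predictors_native,
            native_pres=native_pres, native_abs=native_abs,
        )
        spec = _models.ModelSpec("GLM", seed=seed)
        fm = _models.fit(spec, sd.X_train, sd.y_train)
        if fm.status != "ok":
            return None
        real = _evaluate.evaluate_scores(
            sd.y_train, _models.predict(fm, sd.X_train), sd.y_test, _models.predict(fm, sd.X_test)
        )
        nulls = _evaluate.null_distribution(
            spec, sd.X_train, sd.y_train, sd.X_test, sd.y_test, n_null=n_null, seed=seed + 7
        )
        es = _evaluate.effect_sizes(real, nulls)
        out[scen] = es.tss_es
    return out


def driver_recovery(
    driver: str,
    n_replicates: int = 50,
    seed: int = 0,
    n_null: int = 59,
    n_steps: int = 25,
) -> DriverRecoveryResult:
    """Which scenario wins the TSS effect size under a known spread driver.

    Each replicate simulates a fresh landscape and invasion, runs the full
    preprocessing (temporal split, pseudo-absences, pairwise distance
    sampling), fits a GLM per scenario, and records the TSS effect sizes.
    """
    rows = []
    r = 0
    attempts = 0
    while len(rows) < n_replicates and attempts < 3 * n_replicates:
        res = _one_recovery_replicate(driver, seed + 101 * attempts, n_null, n_steps)
        attempts += 1
        if res is not None:
            rows.append(res)
    per = pd.DataFrame(rows)
    scen_cols = ["INVADED", "NATIVE", "MIXED"]
    winners = per[scen_cols].idxmax(axis=1)
    shares = winners.value_counts(normalize=True).reindex(scen_cols).fillna(0.0)
    labels = per[scen_cols].apply(
        lambda row: "Null" if row.max() <= 0 else row.idxmax(), axis=1
    )
    return DriverRecoveryResult(per, shares, labels)
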