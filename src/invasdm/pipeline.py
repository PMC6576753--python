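"""End-to-end pipeline: simulate -> constrain -> split -> fit -> null-test -> compare.

A single YAML config (or dict) drives the run; one master seed fans out to
per-stage, per-species seeds by fixed offsets, so reruns with the same
config and master seed produce byte-identical result CSVs.

Outputs written to the run directory:

``predictors_invaded.csv`` / ``predictors_native.csv``
    the generated landscape in the standard predictor-table dialect;
``occurrences.csv``, ``profiles.csv``, ``truth_<species>.txt``
    records, invasion-history traits, and retained generating truth;
``split_<species>.csv``
    train/test membership with provenance flags;
``results.csv``
    per species x scenario x algorithm: real TSS/AUC, null 97.5th
    percentiles, effect sizes, better-than-null flags, null failure counts;
``best_scenarios.csv``, ``best_scenario_shares.csv``
    the winning-scenario tabulation and its category shares;
``lmm_<response>.csv``, ``lmm_wald_<response>.csv``, ``lsmeans_<response>.csv``
    the mixed-model analysis (when enough better-than-null rows exist);
``config.yaml``, ``run.log``, ``summary.json``.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare as _compare
from . import evaluate as _evaluate
from . import models as _models
from . import preprocess as _pre
from . import synthio as _syn
from .griddata import (
    DIST_FIRST_RECORD,
    GridDataError,
    OccurrenceSet,
    SpeciesProfile,
    distance_to_first_record,
    filter_valid_cells,
    sampling_coverage,
    write_occurrences,
    write_predictors,
    write_profiles,
)

STAGES = ("simulate", "preprocess", "fit", "evaluate", "compare")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "synthio": {
        "nx": 40,
        "ny": 50,
        "cell_km": 5.0,
        "detection_prob": 0.8,
        "use_accessibility_bias": True,
        "related_coverage": 0.72,
        "native_base_rate": 0.15,
        "species": [
            {"name": "species_1", "driver": "anthropic", "n_steps": 25},
            {"name": "species_2", "driver": "environmental", "n_steps": 25},
            {"name": "species_3", "driver": "mixed", "n_steps": 25},
        ],
    },
    "scenarios": ["INVADED", "NATIVE", "MIXED"],
    "algorithms": ["GLM", "MAXENT"],
    "ensemble": True,
    "n_null": 99,
    "vif_threshold": 10.0,
    "train_frac": 0.7,
    "pwd_tr": 0.33,
    "test_abs_pool_factor": 10,
    "pseudoabsence_pool": "all",
    "buffer_km": 200.0,
    "null_mode": "joint",
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return _merge(DEFAULT_CONFIG, yaml.safe_load(fh) or {})


# seed fan-out offsets (kept < 2**31 overall)
_OFF_LANDSCAPE = 11
_OFF_SPECIES = 1000
_OFF_SPLIT = 23
_OFF_NULL = 47
_OFF_MODEL = 83


def _species_seed(master: int, i: int) -> int:
    return (master + _OFF_SPECIES * (i + 1)) % (2**31 - 1)


@dataclasses.dataclass
class RunLog:
    lines: list[str] = dataclasses.field(default_factory=list)

    def add(self, msg: str) -> None:
        self.lines.append(msg)

    def write(self, path) -> None:
        Path(path).write_text("\n".join(self.lines) + "\n", encoding="utf-8")


def run_pipeline(config: dict, out_dir, master_seed: int | None = None, upto: str = "compare") -> Path:
    """Execute the pipeline through stage ``upto``; returns the run directory."""
    if upto not in STAGES:
        raise GridDataError(f"unknown stage {upto!r}; choose from {STAGES}")
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if master_seed is not None:
        cfg["seed"] = int(master_seed)
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    log = RunLog()
    t0 = time.time()
    stage_limit = STAGES.index(upto)

    # ------------------------------------------------------------------ simulate
    syn = cfg["synthio"]
    landscape = _syn.default_landscape(
        seed + _OFF_LANDSCAPE, nx=syn["nx"], ny=syn["ny"], cell_km=syn["cell_km"]
    )
    bias = None
    if syn.get("use_accessibility_bias") and "dist_cities" in landscape.predictors_invaded.names:
        bias = _syn.accessibility_bias(
            landscape.invaded_grid, landscape.predictors_invaded.frame["dist_cities"]
        )
    related = _syn.gen_related_native_records(
        landscape, syn.get("related_coverage", 0.72), seed + 5
    )

    species_data: dict[str, dict] = {}
    occ_parts = [related]
    profiles: list[SpeciesProfile] = []
    for i, sp in enumerate(syn["species"]):
        sseed = _species_seed(seed, i)
        truth = _syn.make_truth(
            landscape,
            sp.get("driver", "mixed"),
            sseed,
            jump_rate=sp.get("jump_rate"),
            dispersal_scale_km=sp.get("dispersal_scale_km"),
        )
        dates, parents = _syn.simulate_invasion(landscape, truth, sp.get("n_steps", 25), sseed + 1)
        truth.colonization_date = dates
        truth.parent = parents
        occ = _syn.simulate_observation(
            dates, syn.get("detection_prob", 0.8), bias, sseed + 2, species=sp["name"]
        )
        native = _syn.simulate_native_presences(
            landscape, truth, syn.get("native_base_rate", 0.15), sseed + 3, species=sp["name"]
        )
        rng = np.random.default_rng(sseed + 4)
        inv = occ.records
        profiles.append(
            SpeciesProfile(
                species=sp["name"],
                time_since_introduction=float(sp.get("n_steps", 25)),
                economic_interest=bool(rng.random() < 0.5),
                n_presences=len(inv),
                ns_distance_km=float(inv_span(landscape.invaded_grid, inv)),
            )
        )
        species_data[sp["name"]] = {"truth": truth, "occ": occ, "native": native}
        occ_parts += [occ, native]
        _syn.write_truth(truth, out / f"truth_{sp['name']}.txt")
        log.add(
            f"simulate {sp['name']}: {len(dates)} colonized, {len(inv)} detected, "
            f"{len(native)} native presences"
        )

    occurrences = OccurrenceSet.concat(occ_parts)
    write_occurrences(occurrences, out / "occurrences.csv")
    write_profiles(profiles, out / "profiles.csv")
    write_predictors(out / "predictors_invaded.csv", landscape.invaded_grid,
                     landscape.predictors_invaded, "invaded")
    write_predictors(out / "predictors_native.csv", landscape.native_grid,
                     landscape.predictors_native, "native")
    log.add(f"simulate: done in {time.time() - t0:.1f}s")
    if stage_limit < 1:
        log.write(out / "run.log")
        return out

    # ---------------------------------------------------------------- preprocess
    valid_inv = filter_valid_cells(landscape.invaded_grid)
    valid_nat = filter_valid_cells(landscape.native_grid)
    log.add(
        f"preprocess: {len(valid_inv)}/{len(landscape.invaded_grid)} invaded and "
        f"{len(valid_nat)}/{len(landscape.native_grid)} native cells pass the "
        "area-fraction filter"
    )
    coverage = sampling_coverage(valid_inv, related.records)
    log.add(f"preprocess: related-native sampling coverage {coverage:.3f}")

    profile_by_name = {p.species: p for p in profiles}
    prepped: dict[str, dict] = {}
    for i, (name, data) in enumerate(species_data.items()):
        sseed = _species_seed(seed, i)
        occ = data["occ"]
        pres = occ.records[occ.records["cell_id"].isin(valid_inv["cell_id"])]
        if len(pres) < 8:
            log.add(f"preprocess {name}: only {len(pres)} presences; species skipped")
            continue
        try:
            domain = filter_valid_cells(landscape.invaded_grid)
            from .griddata import constrain_invaded_domain

            domain = constrain_invaded_domain(domain, pres, buffer_km=cfg["buffer_km"])
            split = _pre.build_split(
                domain,
                pres,
                seed=sseed + _OFF_SPLIT,
                train_frac=cfg["train_frac"],
                pwd_tr=cfg["pwd_tr"],
                test_abs_pool_factor=cfg["test_abs_pool_factor"],
                pool=cfg["pseudoabsence_pool"],
                related_cells=related.records["cell_id"].to_numpy(),
            )
        except GridDataError as exc:
            log.add(f"preprocess {name}: skipped ({exc})")
            continue
        split.provenance_frame().to_csv(out / f"split_{name}.csv", index=False)
        # distance to first record, computed from the training chronology
        dist = distance_to_first_record(landscape.invaded_grid, pres)
        stack = landscape.predictors_invaded.with_column(
            "dist_first_record", dist.to_numpy(), DIST_FIRST_RECORD
        )
        native_pres = data["native"].records["cell_id"].to_numpy()
        native_pres = native_pres[np.isin(native_pres, valid_nat["cell_id"].to_numpy())]
        native_abs = (
            _pre.sample_pseudoabsences(
                valid_nat, native_pres, len(native_pres), sseed + _OFF_SPLIT + 1
            )
            if len(native_pres)
            else np.array([], dtype=int)
        )
        prepped[name] = {
            "split": split,
            "stack": stack,
            "native_pres": native_pres,
            "native_abs": native_abs,
        }
        log.add(
            f"preprocess {name}: {len(split.train_pres)} train presences, "
            f"{len(split.test_pres)} matched test presences "
            f"(SSB ratio {split.ssb_before:.2f} -> {split.ssb_after:.2f}, "
            f"{split.n_unmatched} unmatched)"
        )
    if stage_limit < 2:
        log.write(out / "run.log")
        return out

    # ------------------------------------------------------------- fit + evaluate
    algos = [a.upper() for a in cfg["algorithms"]]
    rows: list[dict] = []
    for i, (name, prep) in enumerate(prepped.items()):
        sseed = _species_seed(seed, i)
        for scen in cfg["scenarios"]:
            try:
                sd = _pre.assemble_scenario(
                    scen,
                    prep["stack"],
                    prep["split"],
                    native_stack=landscape.predictors_native,
                    native_pres=prep["native_pres"],
                    native_abs=prep["native_abs"],
                    vif_threshold=cfg["vif_threshold"],
                )
            except GridDataError as exc:
                log.add(f"fit {name}/{scen}: skipped ({exc})")
                continue
            for msg in sd.vif_log:
                log.add(f"fit {name}/{scen}: {msg}")
            specs = [_models.ModelSpec(a, seed=sseed + _OFF_MODEL) for a in algos]
            if cfg.get("ensemble"):
                specs.append(
                    _models.ModelSpec(
                        "ENSEMBLE", (("members", tuple(specs)),), seed=sseed + _OFF_MODEL
                    )
                )
            for spec in specs:
                row = {
                    "species": name, "scenario": scen, "algorithm": spec.algorithm,
                }
                fm = _models.fit(spec, sd.X_train, sd.y_train)
                row["status"] = fm.status
                if fm.status != "ok":
                    log.add(f"fit {name}/{scen}/{spec.algorithm}: failed ({fm.failure_reason})")
                    rows.append(row)
                    continue
                s_tr = _models.predict(fm, sd.X_train)
                s_te = _models.predict(fm, sd.X_test)
                real = _evaluate.evaluate_scores(sd.y_train, s_tr, sd.y_test, s_te)
                row.update(
                    TSS_real=real.tss, AUC_real=real.auc, threshold=real.threshold
                )
                if stage_limit >= 3:
                    try:
                        nulls = _evaluate.null_distribution(
                            spec, sd.X_train, sd.y_train, sd.X_test, sd.y_test,
                            n_null=int(cfg["n_null"]),
                            seed=sseed + _OFF_NULL,
                            mode=cfg["null_mode"],
                        )
                        es = _evaluate.effect_sizes(real, nulls)
                        row.update(
                            TSSnull_97_5=es.tss_null_97_5,
                            AUCnull_97_5=es.auc_null_97_5,
                            TSSes=es.tss_es,
                            AUCes=es.auc_es,
                            TSS_better_than_null=es.tss_better_than_null,
                            AUC_better_than_null=es.auc_better_than_null,
                            n_null_failed=nulls["TSS"].n_failed,
                        )
                    except _evaluate.EvaluationError as exc:
                        log.add(f"evaluate {name}/{scen}/{spec.algorithm}: null models void ({exc})")
                        row["status"] = "null_failed"
                rows.append(row)
    results = _evaluate.results_frame(rows)
    results.to_csv(out / "results.csv", index=False, float_format="%.10g")
    log.add(f"evaluate: {len(results)} model rows in {time.time() - t0:.1f}s")
    if stage_limit < 4:
        log.write(out / "run.log")
        return out

    # -------------------------------------------------------------------- compare
    summary: dict = {"n_models": int((results["status"] == "ok").sum())}
    ok = results[results["status"] == "ok"].copy()
    if len(ok):
        table, shares = _compare.best_scenario_table(ok)
        table.to_csv(out / "best_scenarios.csv", index=False, float_format="%.10g")
        shares.rename("share").to_csv(out / "best_scenario_shares.csv", float_format="%.10g")
        summary["best_scenario_shares"] = {k: float(v) for k, v in shares.items()}
        if len(shares):
            summary["modal_best_scenario"] = shares.idxmax()
        both = ok["TSS_better_than_null"].astype(bool) & ok["AUC_better_than_null"].astype(bool)
        summary["frac_better_than_null_both"] = float(both.mean())
        summary["TSS_real_mean"] = float(ok["TSS_real"].mean())
        summary["AUC_real_mean"] = float(ok["AUC_real"].mean())
        prof_df = pd.DataFrame(
            [
                {
                    "species": p.species,
                    "time_since_introduction": p.time_since_introduction,
                    "economic_interest": p.economic_interest,
                    "n_presences": p.n_presences,
                    "ns_distance_km": p.ns_distance_km,
                }
                for p in profiles
            ]
        )
        perf = ok.merge(prof_df, on="species", how="left")
        for response in ("TSSes", "AUCes"):
            try:
                lmm = _compare.fit_performance_lmm(perf, response=response)
            except Exception as exc:
                log.add(f"compare: LMM for {response} not fit ({exc})")
                continue
            lmm.coefficients.to_csv(out / f"lmm_{response}.csv", index=False, float_format="%.10g")
            lmm.wald.to_csv(out / f"lmm_wald_{response}.csv", index=False, float_format="%.10g")
            lmm.lsmeans.to_csv(out / f"lsmeans_{response}.csv", index=False, float_format="%.10g")
            log.add(f"compare: LMM for {response} fit on {lmm.n_obs} rows")
    log.add(f"compare: done in {time.time() - t0:.1f}s total")
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.write(out / "run.log")
    return out


def inv_span(grid: pd.DataFrame, records: pd.DataFrame) -> float:
    """North-south span (km) of a record set."""
    if len(records) == 0:
        return 0.0
    g = grid.set_index("cell_id")
    ys = g.loc[records["cell_id"].astype(int), "y_km"]
    return float(ys.max() - ys.min())
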