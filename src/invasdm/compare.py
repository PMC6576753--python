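"""Best-scenario tabulation and mixed-model analysis of performance drivers.

Two summaries sit on top of the per-model effect sizes:

* :func:`best_scenario_table` labels, for every species x algorithm x
  statistic, the scenario with the largest positive effect size ("Null"
  when no scenario beats chance; exact ties joined with "=", e.g.
  ``"Mixed=Native"``) and reports the category shares.
* :func:`fit_performance_lmm` models the effect sizes of the
  better-than-null models as a function of scenario, algorithm, their
  interaction, and invasion-history traits (N-S range span, number of
  presences, economic interest, time since introduction), with a random
  intercept per species.  It reports coefficient estimates, joint Wald
  chi-square tests per term, and least-square means per
  scenario x algorithm cell.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats

SCENARIO_LABELS = {"INVADED": "Invaded", "NATIVE": "Native", "MIXED": "Mixed"}
_COVARIATES = ("ns_distance_km", "n_presences", "time_since_introduction")


class CompareError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Best-scenario table
# ---------------------------------------------------------------------------

def best_scenario_table(perf: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Label the winning scenario per species x algorithm x statistic.

    ``perf`` needs columns species, scenario, algorithm, TSSes, AUCes.
    Returns (table, shares); shares is the fraction of labels per category
    over all species x algorithm x statistic combinations.
    """
    rows = []
    for (species, algorithm), grp in sorted(
        perf.groupby(["species", "algorithm"], sort=True), key=lambda kv: kv[0]
    ):
        for statistic in ("TSSes", "AUCes"):
            sub = grp.dropna(subset=[statistic])
            if len(sub) == 0:
                continue
            vmax = sub[statistic].max()
            if vmax <= 0:
                label = "Null"
            else:
                winners = sorted(
                    SCENARIO_LABELS.get(s, s.title())
                    for s in sub.loc[sub[statistic] == vmax, "scenario"]
                )
                label = "=".join(winners)
            rows.append(
                {
                    "species": species,
                    "algorithm": algorithm,
                    "statistic": statistic,
                    "best_scenario": label,
                    "effect_size": vmax,
                }
            )
    table = pd.DataFrame(rows, columns=["species", "algorithm", "statistic", "best_scenario", "effect_size"])
    shares = (
        table["best_scenario"].value_counts(normalize=True).sort_index()
        if len(table)
        else pd.Series(dtype=float)
    )
    return table, shares


# ---------------------------------------------------------------------------
# Linear mixed model of performance
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LmmResult:
    response: str
    coefficients: pd.DataFrame  # term, estimate, se, z, p (standardized covariates)
    wald: pd.DataFrame  # term, chisq, df, p
    lsmeans: pd.DataFrame  # scenario, algorithm, mean, se, ci_low, ci_high
    random_intercept_var: float
    dropped_terms: list[str]
    n_obs: int
    covariate_scaling: pd.DataFrame  # covariate, mean, sd (for back-transformation)


def _term_blocks(design_info) -> dict[str, slice]:
    return {t.name(): design_info.term_name_slices[t.name()] for t in design_info.terms}


def fit_performance_lmm(
    perf: pd.DataFrame,
    response: str = "TSSes",
    only_better_than_null: bool = True,
) -> LmmResult:
    """Mixed model of effect sizes with a random intercept per species.

    ``perf`` is the performance table joined with the species profiles
    (columns: species, scenario, algorithm, TSSes/AUCes and their
    better-than-null flags, ns_distance_km, n_presences, economic_interest,
    time_since_introduction).  Only rows better than null on the analysed
    statistic enter the fit.  Numeric covariates are z-scored before
    fitting (their units differ by orders of magnitude); the scaling is
    returned so estimates can be mapped back to raw units.
    """
    if response not in ("TSSes", "AUCes"):
        raise CompareError("response must be TSSes or AUCes")
    df = perf.copy()
    flag_col = f"{response[:3]}_better_than_null"
    if only_better_than_null and flag_col in df.columns:
        df = df[df[flag_col].astype(bool)]
    df = df.dropna(subset=[response]).reset_index(drop=True)
    if df["scenario"].nunique() < 2:
        raise CompareError("need at least 2 scenario levels after filtering")

    dropped: list[str] = []
    scaling_rows = []
    terms = ["C(scenario, Treatment('INVADED'))"]
    if df["algorithm"].nunique() >= 2:
        terms.append("C(algorithm)")
        terms.append("C(scenario, Treatment('INVADED')):C(algorithm)")
    else:
        dropped += ["algorithm", "scenario:algorithm"]
    for cov in _COVARIATES:
        if cov not in df.columns:
            dropped.append(cov)
            continue
        sd = df[cov].std()
        if not np.isfinite(sd) or sd < 1e-12:
            dropped.append(cov)
            continue
        scaling_rows.append({"covariate": cov, "mean": df[cov].mean(), "sd": sd})
        df[f"z_{cov}"] = (df[cov] - df[cov].mean()) / sd
        terms.append(f"z_{cov}")
    if "economic_interest" in df.columns and df["economic_interest"].nunique() >= 2:
        df["economic_interest"] = (
            df["economic_interest"].astype(str).str.lower().isin(("yes", "true", "1"))
        )
        terms.append("C(economic_interest)")
    else:
        dropped.append("economic_interest")

    formula = f"{response} ~ " + " + ".join(terms)
    n_species = df["species"].nunique()

    if n_species >= 2:
        import warnings as _warnings

        model = smf.mixedlm(formula, data=df, groups=df["species"])
        with _warnings.catch_warnings():
            # boundary variance estimates are expected and handled; the Wald
            # machinery below only needs the fixed-effect covariance
            _warnings.simplefilter("ignore")
            try:
                fitted = model.fit(reml=True)
            except np.linalg.LinAlgError:
                fitted = model.fit(reml=True, method="powell")
        fe = fitted.fe_params
        cov_fe = fitted.cov_params().iloc[: len(fe), : len(fe)]
        design_info = model.data.design_info
        re_var = float(fitted.cov_re.iloc[0, 0])
    else:
        # degenerate single-species limit: zero random variance, plain OLS
        model = smf.ols(formula, data=df)
        fitted = model.fit()
        fe = fitted.params
        cov_fe = fitted.cov_params()
        design_info = model.data.design_info
        re_var = 0.0

    names = list(fe.index)
    V = cov_fe.to_numpy()
    se = np.sqrt(np.diag(V))
    z = fe.to_numpy() / se
    coefficients = pd.DataFrame(
        {
            "term": names,
            "estimate": fe.to_numpy(),
            "se": se,
            "z": z,
            "p": 2 * stats.norm.sf(np.abs(z)),
        }
    )

    wald_rows = []
    for term_name, sl in _term_blocks(design_info).items():
        if term_name == "Intercept":
            continue
        b = fe.to_numpy()[sl]
        Vb = V[sl, sl]
        dfree = np.linalg.matrix_rank(Vb)
        if dfree == 0:
            raise CompareError(f"aliased (non-estimable) term: {term_name}")
        chisq = float(b @ np.linalg.pinv(Vb) @ b)
        wald_rows.append(
            {
                "term": _pretty_term(term_name),
                "chisq": chisq,
                "df": int(dfree),
                "p": float(stats.chi2.sf(chisq, dfree)),
            }
        )
    wald = pd.DataFrame(wald_rows, columns=["term", "chisq", "df", "p"])

    lsmeans = _lsmeans(df, design_info, fe.to_numpy(), V)
    return LmmResult(
        response=response,
        coefficients=coefficients,
        wald=wald,
        lsmeans=lsmeans,
        random_intercept_var=re_var,
        dropped_terms=dropped,
        n_obs=len(df),
        covariate_scaling=pd.DataFrame(scaling_rows, columns=["covariate", "mean", "sd"]),
    )


def _pretty_term(name: str) -> str:
    return (
        name.replace("C(scenario, Treatment('INVADED'))", "scenario")
        .replace("C(algorithm)", "algorithm")
        .replace("C(economic_interest)", "economic_interest")
        .replace("z_", "")
    )


def _lsmeans(df: pd.DataFrame, design_info, fe: np.ndarray, V: np.ndarray) -> pd.DataFrame:
    """Model-adjusted cell means: covariates at their (standardized) mean,
    factor covariates averaged over their observed levels."""
    scenarios = sorted(df["scenario"].unique())
    algorithms = sorted(df["algorithm"].unique())
    eco_levels = (
        sorted(df["economic_interest"].unique()) if "economic_interest" in df.columns else [False]
    )
    rows = []
    for sc in scenarios:
        for alg in algorithms:
            grid = pd.DataFrame(
                {
                    "scenario": sc,
                    "algorithm": alg,
                    "economic_interest": eco_levels,
                }
            )
            for col in df.columns:
                if col.startswith("z_"):
                    grid[col] = 0.0
            try:
                (mat,) = build_design_matrices([design_info], grid)
            except Exception:
                continue  # level combination absent from the fit
            L = np.asarray(mat).mean(axis=0)
            mean = float(L @ fe)
            se = float(np.sqrt(max(L @ V @ L, 0.0)))
            rows.append(
                {
                    "scenario": sc,
                    "algorithm": alg,
                    "mean": mean,
                    "se": se,
                    "ci_low": mean - 1.96 * se,
                    "ci_high": mean + 1.96 * se,
                }
            )
    return pd.DataFrame(rows, columns=["scenario", "algorithm", "mean", "se", "ci_low", "ci_high"])
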