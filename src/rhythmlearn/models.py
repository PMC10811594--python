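"""Longitudinal linear mixed models of game performance.

Three models mirror the study design, all fit by REML on one record per
game played:

* progress:     score ~ time + (1 | player / game / level)
* diagnosis:    score ~ age + 6 diagnosis indicators + (1 | game / level)
* interaction:  score ~ time * diagnosis + (1 | game / level)

``time`` counts levels played (starting at 1), ``game`` is the task and
``level`` the task-chapter unit within it.  Nesting is expressed through
variance components on the indicator expansion of the inner grouping
factors.  The default backend is statsmodels' MixedLM; an R/lme4 backend
(run through Rscript) is available as an independent cross-check.

The module also provides the engagement filter (players with at least a
minimum number of games) and parameter-recovery experiments that
regenerate cohorts from known coefficients and verify the fits retrieve
them — the validation strategy for a pipeline whose real data are not
public.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .cohort import DIAGNOSES, CohortConfig, FixedEffects, simulate_longitudinal

__all__ = [
    "ModelFit",
    "engagement_filter",
    "fit_progress_model",
    "fit_diagnosis_model",
    "fit_interaction_model",
    "predicted_change",
    "diagnosis_recovery",
    "progress_recovery",
    "interaction_recovery",
]

DEFAULT_MIN_GAMES = 15  # inclusive: "at least 15 games"

#: the six diagnosis terms of the published diagnosis model (dyspraxia is
#: a pathway trigger, not a model term)
MODEL_DIAGNOSES = (
    "dyscalculia",
    "dysgraphia",
    "dyslexia",
    "dysphasia",
    "adhd",
    "executive_impairment",
)


@dataclass(frozen=True)
class ModelFit:
    """Fixed-effect table and random-effect variances of one fit.

    ``fixed_effects`` is indexed by term with columns estimate, se,
    tvalue, df, pvalue, ci_low, ci_high.  Degrees of freedom are the
    backend's: residual-based for statsmodels, Satterthwaite for lme4.
    """

    formula: str
    fixed_effects: pd.DataFrame
    re_var: dict
    n_obs: int
    converged: bool
    backend: str = "statsmodels"

    def term(self, name: str) -> pd.Series:
        if name not in self.fixed_effects.index:
            raise KeyError(
                f"no fixed-effect term {name!r}; terms: "
                f"{list(self.fixed_effects.index)}"
            )
        return self.fixed_effects.loc[name]

    def ci_covers(self, name: str, value: float) -> bool:
        t = self.term(name)
        return bool(t["ci_low"] <= value <= t["ci_high"])


def engagement_filter(
    records: pd.DataFrame, min_games: int = DEFAULT_MIN_GAMES
) -> pd.DataFrame:
    """Keep all records of players with at least ``min_games`` games."""
    if min_games < 1:
        raise ValueError("min_games must be >= 1")
    counts = records.groupby("player_id")["time_index"].size()
    keep = counts.index[counts >= min_games]
    return records[records["player_id"].isin(keep)].reset_index(drop=True)


def _zcrit() -> float:
    return float(stats.norm.ppf(0.975))


def _fit_statsmodels(
    formula: str,
    data: pd.DataFrame,
    groups: str,
    vc_formula: dict,
    re_formula: Optional[str],
) -> tuple[pd.DataFrame, dict, bool]:
    model = smf.mixedlm(
        formula, data, groups=groups, re_formula=re_formula, vc_formula=vc_formula
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True, method="lbfgs")
    fe_names = model.exog_names
    df_resid = len(data) - len(fe_names)
    z = _zcrit()
    table = pd.DataFrame(
        {
            "estimate": [res.params[n] for n in fe_names],
            "se": [res.bse[n] for n in fe_names],
            "tvalue": [res.tvalues[n] for n in fe_names],
            "df": float(df_resid),
            "pvalue": [res.pvalues[n] for n in fe_names],
        },
        index=fe_names,
    )
    table["ci_low"] = table["estimate"] - z * table["se"]
    table["ci_high"] = table["estimate"] + z * table["se"]
    re_var = {"residual": float(res.scale)}
    if re_formula is not None:
        re_var[groups] = float(np.asarray(res.cov_re)[0, 0])
    for i, name in enumerate(model.exog_vc.names):
        re_var[name] = float(res.vcomp[i])
    return table, re_var, bool(res.converged)


_R_TEMPLATE = """
suppressMessages(library(lmerTest))
d <- read.csv("{csv}")
m <- lmer({formula}, data = d, REML = TRUE)
s <- summary(m)
co <- as.data.frame(s$coefficients)
vc <- as.data.frame(VarCorr(m))
out <- list(
  terms = rownames(co),
  estimate = co[["Estimate"]],
  se = co[["Std. Error"]],
  df = co[["df"]],
  tvalue = co[["t value"]],
  pvalue = co[["Pr(>|t|)"]],
  re_groups = vc$grp,
  re_var = vc$vcov,
  converged = length(m@optinfo$conv$lme4$messages) == 0
)
cat(jsonlite::toJSON(out, auto_unbox = TRUE, digits = 12))
"""


def _fit_lme4(
    r_formula: str, data: pd.DataFrame
) -> tuple[pd.DataFrame, dict, bool]:
    """Cross-check backend: fit with lme4/lmerTest through Rscript."""
    with tempfile.TemporaryDirectory() as tmp:
        csv = Path(tmp) / "records.csv"
        data.to_csv(csv, index=False)
        script = Path(tmp) / "fit.R"
        script.write_text(_R_TEMPLATE.format(csv=csv, formula=r_formula))
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True,
            text=True,
            check=False,
        )
    if proc.returncode != 0:
        raise RuntimeError(f"lme4 backend failed:\n{proc.stderr}")
    out = json.loads(proc.stdout)
    terms = ["Intercept" if t == "(Intercept)" else t for t in out["terms"]]
    table = pd.DataFrame(
        {
            "estimate": out["estimate"],
            "se": out["se"],
            "tvalue": out["tvalue"],
            "df": out["df"],
            "pvalue": out["pvalue"],
        },
        index=terms,
    )
    z = _zcrit()
    table["ci_low"] = table["estimate"] - z * table["se"]
    table["ci_high"] = table["estimate"] + z * table["se"]
    re_var = {
        ("residual" if g == "Residual" else g): float(v)
        for g, v in zip(out["re_groups"], out["re_var"])
    }
    return table, re_var, bool(out["converged"])


def _require_columns(records: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ValueError(f"records are missing columns: {missing}")


def _rename_interaction_terms(index: pd.Index, diagnosis: str) -> pd.Index:
    return pd.Index(
        [
            t.replace("time_index:" + diagnosis, f"time_index:{diagnosis}").replace(
                diagnosis + ":time_index", f"time_index:{diagnosis}"
            )
            for t in index
        ]
    )


def fit_progress_model(records: pd.DataFrame, backend: str = "statsmodels") -> ModelFit:
    """Progress over time: score ~ time + (1 | player / game / level)."""
    _require_columns(records, ["player_id", "game_id", "level_name", "time_index", "score"])
    if records["player_id"].nunique() < 2:
        raise ValueError("progress model needs at least 2 players")
    if records["time_index"].nunique() < 2:
        raise ValueError("progress model needs at least 2 distinct time values")
    formula_desc = "score ~ time_index + (1|player_id/game_id/level_name)"
    if backend == "lme4":
        table, re_var, conv = _fit_lme4(formula_desc, records)
    else:
        table, re_var, conv = _fit_statsmodels(
            "score ~ time_index",
            records,
            groups="player_id",
            re_formula="1",
            vc_formula={
                "game_id": "0 + C(game_id)",
                "level_name": "0 + C(level_name)",
            },
        )
    return ModelFit(formula_desc, table, re_var, len(records), conv, backend)


def _merged(records: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    _require_columns(records, ["player_id", "game_id", "level_name", "score"])
    missing = set(records["player_id"]) - set(profiles["player_id"])
    if missing:
        raise ValueError(
            f"profiles do not cover all players in records: {sorted(missing)[:5]}..."
        )
    return records.merge(profiles, on="player_id", how="left")


def fit_diagnosis_model(
    records: pd.DataFrame, profiles: pd.DataFrame, backend: str = "statsmodels"
) -> ModelFit:
    """Diagnosis and age effects on average performance:
    score ~ age + six diagnosis indicators + (1 | game / level).

    Diagnosis columns with no variation are dropped with a warning (the
    model would otherwise be rank deficient).
    """
    data = _merged(records, profiles)
    terms = ["age"]
    for d in MODEL_DIAGNOSES:
        if data[d].nunique() > 1:
            terms.append(d)
        else:
            warnings.warn(
                f"diagnosis column {d!r} has no variation and was dropped",
                UserWarning,
                stacklevel=2,
            )
    formula = "score ~ " + " + ".join(terms)
    formula_desc = formula + " + (1|game_id/level_name)"
    if backend == "lme4":
        table, re_var, conv = _fit_lme4(formula_desc, data)
    else:
        table, re_var, conv = _fit_statsmodels(
            formula,
            data,
            groups="game_id",
            re_formula="1",
            vc_formula={"level_name": "0 + C(level_name)"},
        )
    return ModelFit(formula_desc, table, re_var, len(data), conv, backend)


def fit_interaction_model(
    records: pd.DataFrame,
    profiles: pd.DataFrame,
    diagnosis: str,
    backend: str = "statsmodels",
) -> ModelFit:
    """Diagnosis-moderated progress:
    score ~ time + diagnosis + time x diagnosis + (1 | game / level)."""
    if diagnosis not in MODEL_DIAGNOSES:
        raise ValueError(
            f"diagnosis must be one of {MODEL_DIAGNOSES}, got {diagnosis!r}"
        )
    data = _merged(records, profiles)
    if data[diagnosis].nunique() < 2:
        raise ValueError(
            f"both {diagnosis} groups must be present to fit the interaction"
        )
    formula = f"score ~ time_index * {diagnosis}"
    formula_desc = (
        f"score ~ time_index + {diagnosis} + time_index:{diagnosis}"
        " + (1|game_id/level_name)"
    )
    if backend == "lme4":
        table, re_var, conv = _fit_lme4(formula_desc, data)
        table.index = _rename_interaction_terms(table.index, diagnosis)
    else:
        table, re_var, conv = _fit_statsmodels(
            formula,
            data,
            groups="game_id",
            re_formula="1",
            vc_formula={"level_name": "0 + C(level_name)"},
        )
    return ModelFit(formula_desc, table, re_var, len(data), conv, backend)


def predicted_change(fit: ModelFit, n_levels: int) -> float:
    """Model-predicted score change after ``n_levels`` levels:
    time coefficient x n_levels."""
    if "time_index" not in fit.fixed_effects.index:
        raise ValueError("fit has no time term; cannot predict change over levels")
    return float(fit.term("time_index")["estimate"] * n_levels)


# ---------------------------------------------------------------------------
# parameter-recovery experiments
# ---------------------------------------------------------------------------

def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _no_interactions(coef: FixedEffects) -> FixedEffects:
    return replace(coef, time_x={d: 0.0 for d in coef.time_x})


def diagnosis_recovery(
    n_reps: int = 50, seed: int = 0, config: Optional[CohortConfig] = None
) -> pd.DataFrame:
    """Recover the diagnosis-model coefficients from cohorts generated
    with the published coefficient set.

    The generator matches the fitted model: game and level random
    intercepts shared across players, no player intercept, no time trend.
    Returns one row per replicate and term with the estimate, SE, the
    generating value and whether the 95% CI covered it.
    """
    base = config or CohortConfig(
        re_structure="game_level",
        player_sd=0.0,
        coefficients=_no_interactions(FixedEffects(time=0.0)),
    )
    gen = {
        "age": base.coefficients.age,
        **{d: getattr(base.coefficients, d) for d in MODEL_DIAGNOSES},
    }
    rows = []
    for rep, s in enumerate(_child_seeds(seed, n_reps)):
        records, profiles = simulate_longitudinal(base, s)
        records = engagement_filter(records)
        profiles = profiles[profiles["player_id"].isin(records["player_id"])]
        fit = fit_diagnosis_model(records, profiles)
        for term, true_val in gen.items():
            if term not in fit.fixed_effects.index:
                continue
            t = fit.term(term)
            rows.append(
                {
                    "rep": rep,
                    "term": term,
                    "estimate": t["estimate"],
                    "se": t["se"],
                    "generating": true_val,
                    "covered": fit.ci_covers(term, true_val),
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)


def progress_recovery(
    n_reps: int = 20,
    seed: int = 0,
    n_levels: int = 250,
    config: Optional[CohortConfig] = None,
) -> pd.DataFrame:
    """Recover the per-level time slope with the nested progress model
    and convert it to the predicted change after ``n_levels`` levels.

    The generator uses the published slope (0.02/level) with nested
    player/game/level intercepts; a common slope is generated (no
    diagnosis interactions) since the fitted model estimates one."""
    base = config or CohortConfig(coefficients=_no_interactions(FixedEffects()))
    slope = base.coefficients.time
    rows = []
    for rep, s in enumerate(_child_seeds(seed, n_reps)):
        records, _ = simulate_longitudinal(base, s)
        records = engagement_filter(records)
        fit = fit_progress_model(records)
        t = fit.term("time_index")
        rows.append(
            {
                "rep": rep,
                "slope": t["estimate"],
                "se": t["se"],
                "generating": slope,
                "covered": fit.ci_covers("time_index", slope),
                "pred_change": predicted_change(fit, n_levels),
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def interaction_recovery(
    diagnosis: str,
    n_reps: int = 50,
    seed: int = 0,
    config: Optional[CohortConfig] = None,
) -> pd.DataFrame:
    """Recover one time x diagnosis interaction.

    The generator matches the fitted model: intercept, common time slope,
    the diagnosis main effect and its published interaction, game/level
    intercepts shared across players and residual noise; other fixed
    effects are zero so the generating process is exactly the estimated
    one."""
    defaults = FixedEffects()
    if config is None:
        coef = FixedEffects(
            age=0.0,
            dyscalculia=0.0,
            dysgraphia=0.0,
            dyslexia=0.0,
            dysphasia=0.0,
            adhd=0.0,
            executive_impairment=0.0,
            time_x={d: 0.0 for d in defaults.time_x},
        )
        coef = replace(
            coef,
            **{diagnosis: getattr(defaults, diagnosis)},
            time_x={**coef.time_x, diagnosis: defaults.time_x[diagnosis]},
        )
        config = CohortConfig(
            re_structure="game_level", player_sd=0.0, coefficients=coef
        )
    gen_value = config.coefficients.time_x[diagnosis]
    term = f"time_index:{diagnosis}"
    rows = []
    for rep, s in enumerate(_child_seeds(seed, n_reps)):
        records, profiles = simulate_longitudinal(config, s)
        records = engagement_filter(records)
        profiles = profiles[profiles["player_id"].isin(records["player_id"])]
        fit = fit_interaction_model(records, profiles, diagnosis)
        t = fit.term(term)
        rows.append(
            {
                "rep": rep,
                "term": term,
                "estimate": t["estimate"],
                "se": t["se"],
                "generating": gen_value,
                "covered": fit.ci_covers(term, gen_value),
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
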