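"""Covariate-adjusted case/control plasma analysis.

The human cohort confounds disease with age and BMI (HFrEF patients are on
average older and heavier), so class totals are residualized on age and BMI
(pooled over both groups, grand mean added back) before the nonparametric
group comparison, and species-level log2 mole percent is modeled by robust
(Huber) regression::

    log2(mole%) ~ 1 + group + age + bmi,   group = 1[HFrEF]

The group coefficient is the estimated log2 fold change (HFrEF vs control)
with its regression standard error; the "estimated control mean mole
percent" is the back-transformed model prediction for a control subject at
cohort-mean age and BMI.  BH adjustment runs across species and the dual
threshold (adjusted p < 0.1 and |log2FC| >= 0.5) flags discoveries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .class_stats import FDR_THRESHOLD, StatsError, bh_adjust
from .ingest import AbundanceTable
from .species_differential import MIN_ABS_LOG2FC, classify_significant

HUBER_TUNING = 1.345  # 95% efficiency under Gaussian errors


def correct_class_totals(totals: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Residualize each class total on age and BMI (pooled least squares).

    Returns residual + grand mean per class; corrected values have zero
    sample correlation with age and BMI, while group differences survive
    (the group indicator is deliberately not in the model).
    """
    ann = annotation.loc[totals.index]
    for col in ("age", "bmi"):
        if np.ptp(ann[col].to_numpy(dtype=float)) == 0:
            raise StatsError(f"covariate {col!r} is constant; correction undefined")
    X = sm.add_constant(ann[["age", "bmi"]].to_numpy(dtype=float))
    corrected = {}
    for cls in totals.columns:
        y = totals[cls].to_numpy(dtype=float)
        res = sm.OLS(y, X, missing="drop").fit()
        corrected[cls] = y - X @ res.params + np.nanmean(y)
    return pd.DataFrame(corrected, index=totals.index)[totals.columns]


@dataclass
class HumanSpeciesResult:
    species: str
    log2fc: float  # group coefficient (HFrEF vs control) on log2 scale
    se: float  # regression standard error of the group coefficient
    p: float
    control_mean_molepct: float  # prediction at group=control, cohort-mean age/BMI
    n_obs: int
    estimable: bool
    note: str = ""


def fit_species_robust_model(
    y, annotation: pd.DataFrame, method: str = "huber"
) -> HumanSpeciesResult:
    """Fit one species' log2 values on group, age and BMI.

    ``huber`` (default): M-estimation with Huber loss (tuning constant
    1.345), which coincides with ordinary least squares when every residual
    falls inside the Huber threshold; ``ols`` substitutes the plain fit.
    Needs >= 6 non-missing observations spanning both groups.
    """
    y = np.asarray(y, dtype=float)
    ann = annotation
    group = (ann["group"] == "HFrEF").astype(float).to_numpy()
    X = np.column_stack([np.ones_like(group), group,
                         ann["age"].to_numpy(dtype=float),
                         ann["bmi"].to_numpy(dtype=float)])
    obs = np.isfinite(y)
    nah = HumanSpeciesResult("", np.nan, np.nan, np.nan, np.nan, int(obs.sum()), False)
    if obs.sum() < 6 or len(np.unique(group[obs])) < 2:
        nah.note = "too few observations or a group all-missing"
        return nah
    Xo, yo = X[obs], y[obs]
    if np.linalg.matrix_rank(Xo) < Xo.shape[1]:
        nah.note = "rank-deficient design"
        return nah
    if method == "huber":
        fit = sm.RLM(yo, Xo, M=sm.robust.norms.HuberT(t=HUBER_TUNING)).fit()
        # Student-t reference with the fit's residual df instead of the
        # default normal approximation, which is anti-conservative at
        # cohort-scale n.
        df_resid = len(yo) - Xo.shape[1]
        pvalues = 2.0 * stats.t.sf(np.abs(fit.params / fit.bse), df=df_resid)
    elif method == "ols":
        fit = sm.OLS(yo, Xo).fit()
        pvalues = fit.pvalues
    else:
        raise StatsError(f"unknown method {method!r}")
    params, bse = fit.params, fit.bse
    mean_age = float(np.mean(ann["age"].to_numpy(dtype=float)[obs]))
    mean_bmi = float(np.mean(ann["bmi"].to_numpy(dtype=float)[obs]))
    control_log2 = params[0] + params[2] * mean_age + params[3] * mean_bmi
    return HumanSpeciesResult(
        species="",
        log2fc=float(params[1]),
        se=float(bse[1]),
        p=float(pvalues[1]),
        control_mean_molepct=float(2.0 ** control_log2),
        n_obs=int(obs.sum()),
        estimable=True,
    )


def run_human_species_analysis(
    table: AbundanceTable, annotation: pd.DataFrame, method: str = "huber"
) -> pd.DataFrame:
    """Fit all species, BH across species, dual-threshold classification.

    Output mirrors the case/control species scatter: estimated log2FC and
    its standard error vs estimated control-group mean mole percent, with
    the significance flag.
    """
    if table.unit_state != "log2_mole_percent":
        raise StatsError("human species analysis runs on the log2 table")
    ann = annotation.loc[table.samples]
    rows = []
    for name in table.species:
        r = fit_species_robust_model(table.data[name].to_numpy(), ann, method=method)
        r.species = name
        rows.append(r)
    df = pd.DataFrame(
        {
            "species": [r.species for r in rows],
            "log2fc": [r.log2fc for r in rows],
            "se": [r.se for r in rows],
            "p": [r.p for r in rows],
            "control_mean_molepct": [r.control_mean_molepct for r in rows],
            "n_obs": [r.n_obs for r in rows],
            "estimable": [r.estimable for r in rows],
        }
    ).set_index("species")
    df["linear_fc"] = 2.0 ** df["log2fc"]
    ok = df["estimable"] & np.isfinite(df["p"])
    df["adj_p"] = np.nan
    if ok.any():
        df.loc[ok, "adj_p"] = bh_adjust(df.loc[ok, "p"].to_numpy())
    df["significant"] = [
        classify_significant(q, f, FDR_THRESHOLD, MIN_ABS_LOG2FC)
        for q, f in zip(df["adj_p"], df["log2fc"])
    ]
    return df
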