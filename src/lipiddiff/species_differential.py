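"""Per-species 2x2 factorial modeling, FDR filtering, regulation-group
clustering and fold-change classification.

Each species' log2 mole percent is modeled by ordinary least squares with
treatment (dummy) coding, reference levels wt and sham::

    y ~ 1 + G + I + G:I,   G = 1[genotype == atATGL-KO], I = 1[intervention == TAC]

Three hypotheses are tested per species: the genotype coefficient (t), the
intervention coefficient (t), and the joint F of the full model against
intercept-only ("genotype + intervention + their interaction").  BH
adjustment runs separately within each test family across species; a species
is retained when any adjusted p < 0.1.  Retained species are grouped by Ward
hierarchical clustering of their standardized (t_genotype, t_intervention,
signed sqrt F) vectors, and displayed as row z-scores of the four cell means.
Per-genotype TAC-vs-sham fold changes feed the dual-threshold rule
(adjusted p < 0.1 and |log2FC| >= 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .class_stats import FDR_THRESHOLD, StatsError, bh_adjust, mann_whitney_two_sided
from .ingest import AbundanceTable

CELLS = ("wt:sham", "wt:TAC", "atATGL-KO:sham", "atATGL-KO:TAC")
MIN_ABS_LOG2FC = 0.5


def design_2x2(annotation: pd.DataFrame) -> pd.DataFrame:
    """Treatment-coded design matrix (const, G, I, G:I); wt/sham reference."""
    G = (annotation["genotype"] == "atATGL-KO").astype(float)
    I = (annotation["intervention"] == "TAC").astype(float)
    X = pd.DataFrame(
        {"const": 1.0, "genotype": G, "intervention": I, "interaction": G * I},
        index=annotation.index,
    )
    return X


@dataclass
class SpeciesModelResult:
    species: str
    beta: np.ndarray  # (const, genotype, intervention, interaction)
    t_genotype: float
    p_genotype: float
    t_intervention: float
    p_intervention: float
    F: float
    p_F: float
    df_resid: int
    estimable: bool
    note: str = ""


def fit_species_linear_model(y, X: pd.DataFrame, species: str = "") -> SpeciesModelResult:
    """OLS fit of one species with casewise deletion of missing values.

    Requires >= 5 non-missing observations spanning >= 3 of the 4 cells and a
    full-rank design after deletion; otherwise the species is flagged
    inestimable.  Zero residual variance yields NaN statistics (inestimable
    p, reported, not 0).
    """
    y = np.asarray(y, dtype=float)
    obs = np.isfinite(y)
    Xo = X.to_numpy(dtype=float)[obs]
    yo = y[obs]
    nan4 = np.full(4, np.nan)
    cells_present = len(
        {(g, i) for g, i in Xo[:, 1:3].astype(int).tolist()}
    )
    if obs.sum() < 5 or cells_present < 3 or np.linalg.matrix_rank(Xo) < Xo.shape[1]:
        return SpeciesModelResult(species, nan4, *[np.nan] * 6, df_resid=0,
                                  estimable=False, note="rank-deficient or too few observations")
    res = sm.OLS(yo, Xo).fit()
    if res.ssr <= max(1e-12 * max(res.centered_tss, 1.0), 0.0) or not np.isfinite(res.ssr):
        return SpeciesModelResult(species, res.params, np.nan, np.nan, np.nan,
                                  np.nan, np.nan, np.nan,
                                  df_resid=int(res.df_resid), estimable=False,
                                  note="zero residual variance")
    return SpeciesModelResult(
        species=species,
        beta=res.params,
        t_genotype=float(res.tvalues[1]),
        p_genotype=float(res.pvalues[1]),
        t_intervention=float(res.tvalues[2]),
        p_intervention=float(res.pvalues[2]),
        F=float(res.fvalue),
        p_F=float(res.f_pvalue),
        df_resid=int(res.df_resid),
        estimable=True,
    )


def run_three_test_families(table: AbundanceTable, annotation: pd.DataFrame) -> pd.DataFrame:
    """Fit every species; BH within each of the three test families.

    Returns one row per species with coefficients, t/F statistics, raw and
    adjusted p-values per family, and the retained flag (any adjusted p <
    0.1).  Inestimable species are excluded from the BH families but kept in
    the output.
    """
    if table.unit_state != "log2_mole_percent":
        raise StatsError("factorial models run on log2_mole_percent tables")
    X = design_2x2(annotation.loc[table.samples])
    fits = [
        fit_species_linear_model(table.data[colname].to_numpy(), X, species=colname)
        for colname in table.species
    ]
    df = pd.DataFrame(
        {
            "species": [f.species for f in fits],
            "beta_const": [f.beta[0] for f in fits],
            "beta_genotype": [f.beta[1] for f in fits],
            "beta_intervention": [f.beta[2] for f in fits],
            "beta_interaction": [f.beta[3] for f in fits],
            "t_genotype": [f.t_genotype for f in fits],
            "p_genotype": [f.p_genotype for f in fits],
            "t_intervention": [f.t_intervention for f in fits],
            "p_intervention": [f.p_intervention for f in fits],
            "F": [f.F for f in fits],
            "p_F": [f.p_F for f in fits],
            "df_resid": [f.df_resid for f in fits],
            "estimable": [f.estimable for f in fits],
        }
    ).set_index("species")
    for family in ("genotype", "intervention", "F"):
        raw_col = f"p_{family}"
        adj_col = f"adj_p_{family}"
        ok = df["estimable"] & np.isfinite(df[raw_col])
        df[adj_col] = np.nan
        if ok.any():
            df.loc[ok, adj_col] = bh_adjust(df.loc[ok, raw_col].to_numpy())
    adj = df[["adj_p_genotype", "adj_p_intervention", "adj_p_F"]]
    df["retained"] = (adj < FDR_THRESHOLD).any(axis=1)
    return df


@dataclass
class RegulationGroups:
    """Cluster labels, display z-score matrix and linkage for retained species."""

    labels: pd.Series  # species -> 1..k
    zscores: pd.DataFrame  # species x 4 cell means, row-standardized, display order
    linkage_matrix: np.ndarray
    statistic_matrix: pd.DataFrame  # standardized columns used for clustering


def _signed_sqrt_F(row: pd.Series) -> float:
    betas = row[["beta_genotype", "beta_intervention", "beta_interaction"]].to_numpy()
    dominant = betas[np.argmax(np.abs(betas))]
    return float(np.sign(dominant) if dominant else 1.0) * np.sqrt(row["F"])


def cell_means(table: AbundanceTable, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-species mean log2 value in each of the four design cells."""
    groups = annotation.loc[table.samples, "genotype"].str.cat(
        annotation.loc[table.samples, "intervention"], sep=":")
    means = table.data.groupby(groups, observed=True).mean().T
    return means[[c for c in CELLS if c in means.columns]]


def row_zscores(means: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize cell means (population SD over the row); an all-equal
    row becomes zeros."""
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=0)
    z = means.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def cluster_regulation_groups(
    results: pd.DataFrame,
    table: AbundanceTable,
    annotation: pd.DataFrame,
    k: int = 4,
    method: str = "ward",
    metric: str = "euclidean",
) -> RegulationGroups:
    """Ward-cluster retained species on standardized test statistics.

    The per-species vector is (t_genotype, t_intervention, signed sqrt F)
    with the sign of the F component taken from the dominant coefficient;
    columns are z-scored across species before clustering and species are
    processed in canonical-name order, making labels independent of input
    order.  The tree is cut at ``k`` clusters (default 4), relabeled in
    display (dendrogram leaf) order; the display matrix holds row z-scores
    of the four cell means ordered by cluster then leaf order.
    """
    retained = results[results["retained"] & results["estimable"]]
    if len(retained) < k:
        raise StatsError(f"need >= k={k} retained species, have {len(retained)}")
    retained = retained.sort_index()  # deterministic: canonical-name order
    M = pd.DataFrame(
        {
            "t_genotype": retained["t_genotype"],
            "t_intervention": retained["t_intervention"],
            "signed_sqrt_F": retained.apply(_signed_sqrt_F, axis=1),
        }
    )
    sd = M.std(axis=0, ddof=0).replace(0.0, 1.0)
    Mz = (M - M.mean(axis=0)) / sd
    Z = linkage(Mz.to_numpy(), method=method, metric=metric)
    raw_labels = fcluster(Z, t=k, criterion="maxclust")
    leaf_order = leaves_list(Z)
    # Relabel clusters 1..k in order of first appearance along the dendrogram.
    relabel: dict[int, int] = {}
    for leaf in leaf_order:
        relabel.setdefault(raw_labels[leaf], len(relabel) + 1)
    labels = pd.Series([relabel[l] for l in raw_labels], index=Mz.index, name="cluster")
    means = cell_means(table, annotation).loc[Mz.index]
    z = row_zscores(means)
    display_idx = [Mz.index[i] for i in leaf_order]
    z = z.loc[sorted(display_idx, key=lambda s: (labels[s], display_idx.index(s)))]
    return RegulationGroups(labels=labels, zscores=z, linkage_matrix=Z,
                            statistic_matrix=Mz)


def classify_significant(adj_p: float, log2fc: float,
                         fdr: float = FDR_THRESHOLD,
                         min_abs_log2fc: float = MIN_ABS_LOG2FC) -> bool:
    """Dual-threshold rule: adjusted p < 0.1 and |log2FC| >= 0.5."""
    return bool(np.isfinite(adj_p) and np.isfinite(log2fc)
                and adj_p < fdr and abs(log2fc) >= min_abs_log2fc)


def per_genotype_fold_changes(
    log2_table: AbundanceTable,
    molepct_table: AbundanceTable,
    annotation: pd.DataFrame,
    test: str = "t",
) -> pd.DataFrame:
    """TAC-vs-sham fold changes per species, computed separately per genotype.

    log2FC = mean(log2 TAC) - mean(log2 sham); mean mole percent is the
    arithmetic mean over that genotype's samples.  p-values come from an
    equal-variance two-sample t-test on log2 values (``test="t"``, default)
    or a Mann-Whitney U test (``test="mannwhitney"``); BH across species
    within each genotype; the dual-threshold flag uses the adjusted p.
    """
    if log2_table.unit_state != "log2_mole_percent":
        raise StatsError("fold changes require the log2 table")
    ann = annotation.loc[log2_table.samples]
    out = []
    for geno in ann["genotype"].unique():
        sham = ann.index[(ann["genotype"] == geno) & (ann["intervention"] == "sham")]
        tac = ann.index[(ann["genotype"] == geno) & (ann["intervention"] == "TAC")]
        if len(sham) == 0 or len(tac) == 0:
            raise StatsError(f"genotype {geno!r} lacks a sham or TAC group")
        ls = log2_table.data.loc[sham]
        lt = log2_table.data.loc[tac]
        log2fc = lt.mean(axis=0, skipna=True) - ls.mean(axis=0, skipna=True)
        mean_pct = molepct_table.data.loc[list(sham) + list(tac)].mean(axis=0, skipna=True)
        if test == "t":
            with warnings.catch_warnings():
                # species with < 2 observations per group yield NaN p-values,
                # which the BH family simply drops
                warnings.simplefilter("ignore")
                tt = stats.ttest_ind(lt.to_numpy(), ls.to_numpy(), axis=0,
                                     equal_var=True, nan_policy="omit")
            p = pd.Series(np.asarray(tt.pvalue, dtype=float), index=ls.columns)
        elif test == "mannwhitney":
            p = pd.Series(
                {
                    spname: mann_whitney_two_sided(
                        lt[spname].dropna(), ls[spname].dropna())[1]
                    if lt[spname].notna().sum() >= 2 and ls[spname].notna().sum() >= 2
                    else np.nan
                    for spname in ls.columns
                }
            )
        else:
            raise StatsError(f"unknown test {test!r}")
        df = pd.DataFrame(
            {"genotype": geno, "mean_mole_percent": mean_pct,
             "log2fc": log2fc, "p": p}
        )
        ok = np.isfinite(df["p"])
        df["adj_p"] = np.nan
        if ok.any():
            df.loc[ok, "adj_p"] = bh_adjust(df.loc[ok, "p"].to_numpy())
        df["significant"] = [
            classify_significant(q, f) for q, f in zip(df["adj_p"], df["log2fc"])
        ]
        df.index.name = "species"
        out.append(df.reset_index())
    return pd.concat(out, ignore_index=True)
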