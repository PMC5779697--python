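"""Class-level aggregation and nonparametric group comparisons.

Species are summed into lipid-class totals (mole percent, after imputation)
and each class is compared between interventions or cohorts with a two-sided
Mann-Whitney U test.  p-values are Benjamini-Hochberg adjusted *within one
comparison family* (e.g. all classes for wt sham-vs-TAC), and flagged at
display tiers 0.05/0.01/0.001 alongside the pipeline-wide adjusted p < 0.1
discovery rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ingest import AbundanceTable, IngestError

FDR_THRESHOLD = 0.1  # pipeline-wide discovery rule on adjusted p
DISPLAY_TIERS = (0.05, 0.01, 0.001)


class StatsError(ValueError):
    pass


def class_totals(table: AbundanceTable, catalog=None) -> pd.DataFrame:
    """Sum species mole percent into per-class totals.

    Expects an imputed mole-percent table; returns samples x classes with
    classes ordered by mean abundance descending.
    """
    if table.unit_state != "mole_percent":
        raise StatsError("class totals are computed on mole_percent tables")
    catalog = catalog if catalog is not None else table.catalog
    unknown = [c for c in table.species if c not in catalog]
    if unknown:
        raise StatsError(f"species with unknown class: {unknown[:5]}")
    classes = pd.Series({name: catalog[name].class_code for name in table.species})
    totals = table.data.T.groupby(classes).sum(min_count=1).T
    order = totals.mean(axis=0).sort_values(ascending=False).index
    return totals[order]


def mann_whitney_two_sided(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    ``auto`` uses the exact null distribution when n1+n2 <= 20 and the data
    are tie-free, otherwise the normal approximation with tie and continuity
    corrections.  Returns (U of the first sample, p in (0, 1]).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise StatsError("Mann-Whitney requires >= 2 observations per group")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if mode == "auto":
        method = "exact" if (len(a) + len(b) <= 20 and not ties) else "asymptotic"
    elif mode == "exact":
        if ties:
            raise StatsError("exact Mann-Whitney is undefined with ties")
        method = "exact"
    elif mode == "normal_approx":
        method = "asymptotic"
    else:
        raise StatsError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    p = float(min(res.pvalue, 1.0))
    return float(res.statistic), max(p, np.finfo(float).tiny)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise StatsError("bh_adjust expects a non-empty 1-D p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise StatsError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significance_tier(adj_p: float) -> str:
    """Display stars for an adjusted p-value (tiers 0.05/0.01/0.001)."""
    if not np.isfinite(adj_p):
        return ""
    return "*" * sum(adj_p < t for t in DISPLAY_TIERS)


def _sem(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan


def compare_classes(
    totals: pd.DataFrame,
    annotation: pd.DataFrame,
    design: str = "mouse_within_genotype",
    mode: str = "auto",
) -> pd.DataFrame:
    """Per-class two-group Mann-Whitney comparisons with BH per family.

    ``mouse_within_genotype``: sham vs TAC separately within each genotype
    (two families).  ``human_two_group``: control vs HFrEF (one family, on
    covariate-corrected totals supplied by the caller).
    """
    if design == "mouse_within_genotype":
        families = [
            (geno, annotation.index[(annotation["genotype"] == geno)
                                    & (annotation["intervention"] == "sham")],
             annotation.index[(annotation["genotype"] == geno)
                              & (annotation["intervention"] == "TAC")])
            for geno in annotation["genotype"].unique()
        ]
    elif design == "human_two_group":
        families = [
            ("human", annotation.index[annotation["group"] == "control"],
             annotation.index[annotation["group"] == "HFrEF"])
        ]
    else:
        raise StatsError(f"unknown design {design!r}")

    rows = []
    for family, idx1, idx2 in families:
        if len(idx1) < 2 or len(idx2) < 2:
            raise StatsError(f"family {family!r} has < 2 samples in a group")
        fam_rows = []
        for cls in totals.columns:
            a = totals.loc[idx1, cls].to_numpy(dtype=float)
            b = totals.loc[idx2, cls].to_numpy(dtype=float)
            U, p = mann_whitney_two_sided(a, b, mode=mode)
            fam_rows.append({
                "family": family, "class": cls,
                "n1": int(np.isfinite(a).sum()), "n2": int(np.isfinite(b).sum()),
                "mean1": float(np.nanmean(a)), "sem1": _sem(a),
                "mean2": float(np.nanmean(b)), "sem2": _sem(b),
                "U": U, "p": p,
                "direction": "up" if np.nanmean(b) > np.nanmean(a) else "down",
            })
        fam = pd.DataFrame(fam_rows)
        fam["adj_p"] = bh_adjust(fam["p"].to_numpy())
        fam["tier"] = [significance_tier(q) for q in fam["adj_p"]]
        fam["significant"] = fam["adj_p"] < FDR_THRESHOLD
        rows.append(fam)
    return pd.concat(rows, ignore_index=True)
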