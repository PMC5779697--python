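"""PC/PE ratios of acyl-chain-matched species pairs.

A falling PC/PE ratio is read as a membrane-integrity signal, so for every
PC and PE species carrying the identical multiset of acyl chains the
per-sample ratio mole%(PC) / mole%(PE) is computed (diacyl pairs by default;
ether pairs optionally matched among themselves) and its TAC response is
tested per genotype with a Mann-Whitney U test, BH-adjusted across pairs
within the genotype.  Ratios are never imputed: a sample missing either
member has a missing ratio, and pairs observed in fewer than half of a
family's samples are flagged untestable and excluded from the BH family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .class_stats import FDR_THRESHOLD, StatsError, bh_adjust, mann_whitney_two_sided
from .ingest import AbundanceTable
from .nomenclature import LipidSpecies, find_matched_pairs


def matched_pc_pe_pairs(table: AbundanceTable, include_ether: bool = False):
    """Chain-matched (PC, PE) pairs among the table's retained species."""
    pcs = table.species_of_class("PC") + (table.species_of_class("PC O-") if include_ether else [])
    pes = table.species_of_class("PE") + (table.species_of_class("PE O-") if include_ether else [])
    return find_matched_pairs(pcs, pes, include_ether=include_ether)


def pair_label(pc: LipidSpecies, pe: LipidSpecies) -> str:
    return f"{pc.canonical_name} / {pe.canonical_name}"


def compute_matched_ratios(
    table: AbundanceTable,
    pairs: list[tuple[LipidSpecies, LipidSpecies]],
) -> pd.DataFrame:
    """Per-sample PC/PE mole-percent ratios, one column per matched pair.

    Missing whenever either member is missing; identity
    log2(ratio) = log2(PC) - log2(PE) holds exactly.
    """
    if table.unit_state != "mole_percent":
        raise StatsError("ratios are computed on mole_percent tables")
    cols = {}
    for pc, pe in pairs:
        for member in (pc, pe):
            if member.canonical_name not in table.data.columns:
                raise StatsError(
                    f"pair member {member.canonical_name!r} absent from table "
                    "(filtered out?)"
                )
        cols[pair_label(pc, pe)] = table.data[pc.canonical_name] / table.data[pe.canonical_name]
    return pd.DataFrame(cols, index=table.data.index)


def _sem(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan


def test_ratios(
    ratios: pd.DataFrame,
    annotation: pd.DataFrame,
    design: str = "mouse_within_genotype",
    min_observed_fraction: float = 0.5,
) -> pd.DataFrame:
    """Sham-vs-TAC Mann-Whitney per pair within each genotype.

    BH runs across testable pairs within a genotype family.  A pair is
    testable when >= ``min_observed_fraction`` of the family's ratios are
    observed and each group retains >= 2 observations.
    """
    if design != "mouse_within_genotype":
        raise StatsError(f"unknown design {design!r}")
    ann = annotation.loc[ratios.index]
    out = []
    for geno in ann["genotype"].unique():
        sham = ann.index[(ann["genotype"] == geno) & (ann["intervention"] == "sham")]
        tac = ann.index[(ann["genotype"] == geno) & (ann["intervention"] == "TAC")]
        fam_rows = []
        for pair in ratios.columns:
            a = ratios.loc[sham, pair].to_numpy(dtype=float)
            b = ratios.loc[tac, pair].to_numpy(dtype=float)
            n_obs = np.isfinite(a).sum() + np.isfinite(b).sum()
            testable = (
                n_obs >= min_observed_fraction * (len(a) + len(b))
                and np.isfinite(a).sum() >= 2
                and np.isfinite(b).sum() >= 2
            )
            U = p = np.nan
            if testable:
                U, p = mann_whitney_two_sided(a, b)
            fam_rows.append({
                "genotype": geno, "pair": pair,
                "mean_sham": float(np.nanmean(a)) if np.isfinite(a).any() else np.nan,
                "sem_sham": _sem(a),
                "mean_tac": float(np.nanmean(b)) if np.isfinite(b).any() else np.nan,
                "sem_tac": _sem(b),
                "log2_mean_ratio_sham": float(np.log2(np.nanmean(a))) if np.isfinite(a).any() else np.nan,
                "log2_mean_ratio_tac": float(np.log2(np.nanmean(b))) if np.isfinite(b).any() else np.nan,
                "U": U, "p": p, "testable": testable,
            })
        fam = pd.DataFrame(fam_rows)
        fam["adj_p"] = np.nan
        ok = fam["testable"] & np.isfinite(fam["p"])
        if ok.any():
            fam.loc[ok, "adj_p"] = bh_adjust(fam.loc[ok, "p"].to_numpy())
        fam["significant"] = fam["adj_p"] < FDR_THRESHOLD
        fam["direction"] = np.where(fam["mean_tac"] > fam["mean_sham"], "up", "down")
        out.append(fam)
    return pd.concat(out, ignore_index=True)
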