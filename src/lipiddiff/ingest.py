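"""Ingestion and normalization of raw pmol lipidomics tables.

The pipeline consumes wide or long CSV tables of lipid amounts (pmol) per
sample per species, together with a sample-annotation CSV.  Raw zeros and
empty cells are both treated as *missing* (below the instrument's detection
threshold), because the downstream analysis log-transforms and imputes rather
than adding pseudocounts.  Species are filtered by within-group missingness,
converted to mole percent of the per-sample total of retained species, and
log2-transformed.  Group-median or regression imputation is provided for the
class-level analyses only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .nomenclature import LipidSpecies, parse_species_name

MOUSE_GENOTYPES = ("wt", "atATGL-KO")
MOUSE_INTERVENTIONS = ("sham", "TAC")
HUMAN_GROUPS = ("control", "HFrEF")


class IngestError(ValueError):
    pass


@dataclass
class AbundanceTable:
    """Samples x species matrix with explicit missingness (NaN).

    ``data`` columns are canonical species names; ``catalog`` maps each
    column to its parsed :class:`LipidSpecies`.  ``unit_state`` is one of
    ``pmol``, ``mole_percent``, ``log2_mole_percent``.
    """

    data: pd.DataFrame
    unit_state: str = "pmol"
    catalog: dict[str, LipidSpecies] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    def species_of_class(self, class_code: str) -> list[LipidSpecies]:
        return [s for s in self.catalog.values() if s.class_code == class_code]


def _catalog_from_names(names) -> tuple[dict[str, LipidSpecies], dict[str, str]]:
    """Parse raw header names; return (canonical catalog, raw->canonical map).

    Collects all unparseable names into a single error; raises on two raw
    spellings that collapse onto the same canonical species.
    """
    catalog: dict[str, LipidSpecies] = {}
    rename: dict[str, str] = {}
    bad: list[str] = []
    for raw in names:
        try:
            sp = parse_species_name(str(raw))
        except ValueError as exc:
            bad.append(f"{raw!r} ({exc})")
            continue
        if sp.canonical_name in catalog:
            raise IngestError(
                f"species name collision: {raw!r} parses to {sp.canonical_name!r}, "
                "already present under another spelling"
            )
        catalog[sp.canonical_name] = sp
        rename[str(raw)] = sp.canonical_name
    if bad:
        raise IngestError("unparseable species names: " + "; ".join(bad))
    return catalog, rename


def read_abundance_csv(path, orientation: str = "wide") -> AbundanceTable:
    """Read a raw pmol CSV into an :class:`AbundanceTable`.

    ``wide``: first column sample id, remaining columns species names.
    ``long``: columns (sample, species, pmol).  Zeros and blanks become NaN.
    """
    if orientation == "wide":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise IngestError(f"duplicate sample ids: {dups}")
        if pd.Index(df.columns).duplicated().any():
            raise IngestError("duplicate species columns in wide CSV")
    elif orientation == "long":
        raw = pd.read_csv(path)
        if raw.shape[1] < 3:
            raise IngestError("long CSV requires columns (sample, species, pmol)")
        raw = raw.iloc[:, :3]
        raw.columns = ["sample", "species", "pmol"]
        dup = raw.duplicated(subset=["sample", "species"])
        if dup.any():
            pairs = raw.loc[dup, ["sample", "species"]].to_records(index=False).tolist()
            raise IngestError(f"duplicate (sample, species) rows: {pairs[:5]}")
        df = raw.pivot(index="sample", columns="species", values="pmol")
        df.index = df.index.astype(str)
    else:
        raise IngestError(f"unknown orientation {orientation!r}")

    catalog, rename = _catalog_from_names(df.columns)
    df = df.rename(columns=rename)
    values = df.apply(pd.to_numeric, errors="coerce").astype(float)
    if (values < 0).any().any():
        raise IngestError("negative pmol values encountered")
    values = values.mask(values == 0.0)  # zeros are below-detection, not true zeros
    return AbundanceTable(data=values, unit_state="pmol", catalog=catalog)


def read_annotation_csv(path, mode: str = "mouse") -> pd.DataFrame:
    """Read sample annotations.

    mouse: columns (sample, genotype, intervention); human: columns
    (sample, group, age, bmi).  Returns a DataFrame indexed by sample id.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["sample", "genotype", "intervention"] if mode == "mouse" else [
        "sample", "group", "age", "bmi"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IngestError(f"annotation CSV lacks column(s): {missing}")
    df = df.set_index(df["sample"].astype(str))[required[1:]]
    if mode == "mouse":
        for col, levels in (("genotype", MOUSE_GENOTYPES), ("intervention", MOUSE_INTERVENTIONS)):
            bad = set(df[col]) - set(levels)
            if bad:
                raise IngestError(f"unknown {col} level(s) {bad}; expected {levels}")
    else:
        bad = set(df["group"]) - set(HUMAN_GROUPS)
        if bad:
            raise IngestError(f"unknown group level(s) {bad}; expected {HUMAN_GROUPS}")
        for col in ("age", "bmi"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
            if not np.isfinite(df[col]).all():
                raise IngestError(f"non-finite {col} values in annotation")
    return df


def check_annotation(table: AbundanceTable, annotation: pd.DataFrame) -> None:
    missing = set(table.samples) - set(annotation.index)
    if missing:
        raise IngestError(f"samples without annotation: {sorted(missing)}")


def mouse_groups(annotation: pd.DataFrame) -> pd.Series:
    """Cell label per sample, e.g. ``wt:TAC``."""
    return annotation["genotype"].str.cat(annotation["intervention"], sep=":")


def filter_species_by_missingness(
    table: AbundanceTable,
    grouping: pd.Series,
    max_missing_fraction: float = 0.5,
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Retain species observed often enough in at least one experimental group.

    A species is retained iff in >= 1 group its fraction of non-missing
    samples is >= 1 - ``max_missing_fraction``.  Returns the filtered table
    and a report of removed species with their per-group observed fractions.
    """
    if table.unit_state != "pmol":
        raise IngestError("missingness filtering applies to raw pmol tables")
    if not 0 <= max_missing_fraction <= 1:
        raise IngestError("max_missing_fraction must be in [0, 1]")
    grouping = grouping.reindex(table.samples)
    if grouping.isna().any():
        raise IngestError("grouping lacks entries for some samples")
    observed = table.data.notna()
    frac = observed.groupby(grouping, observed=True).mean()  # groups x species
    keep = frac.max(axis=0) >= 1.0 - max_missing_fraction
    removed = frac.T[~keep.values]
    removed.index.name = "species"
    kept_cols = [c for c in table.species if keep[c]]
    if not kept_cols:
        raise IngestError("all species removed by missingness filter")
    filtered = replace(
        table,
        data=table.data[kept_cols].copy(),
        catalog={c: table.catalog[c] for c in kept_cols},
    )
    return filtered, removed.reset_index()


def to_mole_percent(table: AbundanceTable) -> AbundanceTable:
    """Per sample: 100 * pmol / sum of non-missing pmol of retained species."""
    if table.unit_state != "pmol":
        raise IngestError("to_mole_percent expects a pmol table")
    totals = table.data.sum(axis=1, skipna=True)
    empty = totals <= 0
    if empty.any():
        raise IngestError(
            f"sample(s) with no observed values: {list(table.data.index[empty])}"
        )
    data = table.data.div(totals, axis=0) * 100.0
    return replace(table, data=data, unit_state="mole_percent")


def log2_transform(table: AbundanceTable) -> AbundanceTable:
    """Elementwise log2; missing preserved; zeros must already be missing."""
    if table.unit_state != "mole_percent":
        raise IngestError("log2_transform expects a mole_percent table")
    vals = table.data.to_numpy()
    if np.any(vals[np.isfinite(vals)] <= 0):
        raise IngestError("non-missing zero or negative mole-percent value; "
                          "zeros must be declared missing at ingest")
    return replace(table, data=np.log2(table.data), unit_state="log2_mole_percent")


def impute_for_class_totals(
    table: AbundanceTable,
    grouping: pd.Series,
    method: str = "group_median",
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Impute missing mole-percent values for class-level comparisons only.

    ``group_median``: within-group median per species, falling back to the
    overall species median when a group has no observations.  ``regression``:
    fitted value of an ordinary least-squares fit of the species on group
    indicator variables (equals group means on balanced designs), same
    fallback.  Returns the imputed table and the boolean mask of imputed
    cells.
    """
    if table.unit_state != "mole_percent":
        raise IngestError("imputation operates on mole_percent tables")
    grouping = grouping.reindex(table.samples)
    if grouping.isna().any():
        raise IngestError("grouping lacks entries for some samples")
    data = table.data.copy()
    all_missing = data.isna().all(axis=0)
    if all_missing.any():
        raise IngestError(
            f"species missing in all samples (should have been filtered): "
            f"{list(data.columns[all_missing])}"
        )
    mask = data.isna()
    if method == "group_median":
        fill = data.groupby(grouping, observed=True).transform("median")
    elif method == "regression":
        fill = pd.DataFrame(index=data.index, columns=data.columns, dtype=float)
        dummies = pd.get_dummies(grouping).astype(float)
        X = dummies.to_numpy()  # cell-means coding: fitted values = group means
        for col in data.columns:
            y = data[col].to_numpy()
            obs = np.isfinite(y)
            Xo = X[obs]
            ok = Xo.sum(axis=0) > 0
            beta = np.linalg.lstsq(Xo[:, ok], y[obs], rcond=None)[0]
            full = np.full(X.shape[1], np.nan)
            full[ok] = beta
            fill[col] = X @ np.nan_to_num(full) + np.where(
                (X[:, ~ok].sum(axis=1) > 0), np.nan, 0.0
            )
    else:
        raise IngestError(f"unknown imputation method {method!r}")
    fill = fill.fillna(data.median(axis=0))  # overall species median fallback
    data = data.where(~mask, fill)
    return replace(table, data=data), mask


def write_table(table: AbundanceTable, path, sidecar: dict | None = None) -> None:
    """Write the table as CSV plus a JSON sidecar recording the unit state."""
    table.data.to_csv(path, index_label="sample")
    meta = {"unit_state": table.unit_state, "n_samples": len(table.samples),
            "n_species": len(table.species)}
    if sidecar:
        meta.update(sidecar)
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
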