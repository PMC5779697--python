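import numpy as np
import pandas as pd
import pytest

from lipiddiff.ingest import (
    AbundanceTable,
    filter_species_by_missingness,
    log2_transform,
    mouse_groups,
    to_mole_percent,
)
from lipiddiff.nomenclature import parse_species_name
from lipiddiff.synthetic import default_recovery_config, simulate_study


def make_table(values: pd.DataFrame, unit_state: str = "pmol") -> AbundanceTable:
    """Wrap a samples x species DataFrame; columns must be parseable names."""
    catalog = {}
    rename = {}
    for col in values.columns:
        sp = parse_species_name(col)
        catalog[sp.canonical_name] = sp
        rename[col] = sp.canonical_name
    return AbundanceTable(data=values.rename(columns=rename).astype(float),
                          unit_state=unit_state, catalog=catalog)


@pytest.fixture(scope="session")
def mouse_study():
    """One simulated 2x2 mouse study with 10 planted wt-TAC effects."""
    table, annotation, truth = simulate_study(default_recovery_config(), seed=7)
    return table, annotation, truth


@pytest.fixture(scope="session")
def mouse_prepared(mouse_study):
    """Filtered / mole-percent / log2 stages of the mouse study."""
    table, annotation, truth = mouse_study
    grouping = mouse_groups(annotation)
    filtered, _ = filter_species_by_missingness(table, grouping)
    molepct = to_mole_percent(filtered)
    log2t = log2_transform(molepct)
    return filtered, molepct, log2t, annotation, grouping, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
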