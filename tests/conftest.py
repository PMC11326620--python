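import numpy as np
import pandas as pd
import pytest

from medaqua import ProductionPanel, SyntheticConfig, generate_panel


@pytest.fixture
def tiny_panel() -> ProductionPanel:
    """Two species, two countries, three years; hand-checkable volumes."""
    rows = [
        # year, country, species, environment, group, quantity_t, value_kusd
        (2000, "A", "carp", "freshwater", "fish", 100.0, 50.0),
        (2000, "B", "carp", "freshwater", "fish", 50.0, 25.0),
        (2000, "A", "mussel", "marine", "bivalve", 30.0, 10.0),
        (2001, "A", "carp", "freshwater", "fish", 110.0, 55.0),
        (2001, "B", "mussel", "marine", "bivalve", 40.0, 12.0),
        (2002, "B", "mussel", "marine", "bivalve", 60.0, 20.0),
    ]
    df = pd.DataFrame(rows, columns=[
        "year", "country", "species", "environment", "group",
        "quantity_t", "value_kusd"])
    return ProductionPanel(df, provenance="fixture")


@pytest.fixture
def noiseless_config() -> SyntheticConfig:
    return SyntheticConfig(n_species=5, n_countries=4, years=(1950, 2000),
                           noise_cv=0.0, seed=42)


@pytest.fixture
def noiseless_panel(noiseless_config) -> ProductionPanel:
    return generate_panel(noiseless_config)


def write_csv(path, text):
    path.write_text(text.strip() + "\n")
    return path
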