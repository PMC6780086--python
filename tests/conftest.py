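import numpy as np
import pandas as pd
import pytest

import phosremodel as pr


@pytest.fixture(scope="session")
def default_transcriptome():
    """One default-scale simulated transcriptome shared across tests."""
    return pr.generate_transcriptome(pr.TranscriptomeSimConfig(seed=11))


@pytest.fixture(scope="session")
def default_lipidome():
    return pr.generate_lipidome(pr.LipidomeSimConfig(seed=11))


@pytest.fixture
def design():
    return pr.default_design(3)


@pytest.fixture
def toy_matrix(design):
    """Deterministic 4-gene matrix: one depletion-induced gene, one
    depletion-repressed gene, one flat gene, one low-level gene."""
    rows = {
        "g_up": [100, 110, 90, 420, 400, 380, 95, 105, 100],
        "g_down": [400, 380, 420, 95, 105, 100, 410, 390, 400],
        "g_flat": [50, 55, 45, 52, 48, 50, 49, 51, 50],
        "g_low": [2, 3, 2, 2, 3, 2, 3, 2, 2],
    }
    df = pd.DataFrame(rows, index=[s.sample_id for s in design]).T
    return pr.ExpressionMatrix(df.astype(float), design)


@pytest.fixture
def toy_lipid_table(design):
    """Three-species table with exactly doubled/halved PD levels."""
    def sp(name, levels):
        s = pr.parse_species(name)
        s.levels = np.array(levels, dtype=float)
        return s

    species = [
        sp("DGTS(16:0/18:1)", [10, 11, 9, 31, 29, 30, 10, 10, 10]),
        sp("DGTS(16:0/16:1)", [5, 5, 5, 15, 16, 14, 5, 5, 5]),
        sp("PC(16:0/20:5)", [40, 42, 38, 12, 13, 11, 41, 39, 40]),
    ]
    return pr.LipidTable(species=species, samples=design)
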