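import numpy as np
import pandas as pd
import pytest

from circaphos import quantio


@pytest.fixture
def tiny_proteome():
    return {
        "P1": "MKSLGLLPGPTKAA",
        "P2": "AAADDDSAAAAKRT",
    }


def make_measurement(
    peptide="SLGLLPGPTK",
    mods="S1",
    protein="P1",
    charge=2,
    missed_cleavages=0,
    group="parent",
    replicate=1,
    abundance=100.0,
):
    return quantio.PeptideMeasurement(
        peptide=peptide,
        mods=tuple(quantio.parse_mods(mods, peptide)),
        protein_id=protein,
        charge=charge,
        missed_cleavages=missed_cleavages,
        group=group,
        replicate=replicate,
        abundance=abundance,
    )


@pytest.fixture
def quant_csv(tmp_path):
    """A well-formed 3-row peptide quant file."""
    df = pd.DataFrame(
        {
            "peptide": ["SLGLLPGPTK"] * 3,
            "mods": ["S1"] * 3,
            "protein": ["P1"] * 3,
            "charge": [2, 3, 2],
            "missed_cleavages": [0, 0, 1],
            "group": ["parent"] * 3,
            "replicate": [1, 1, 1],
            "abundance": [100.0, 200.0, 50.0],
        }
    )
    path = tmp_path / "quant.csv"
    df.to_csv(path, index=False)
    return path


def site_table_from_values(values_by_site):
    """Build a SiteQuantTable directly from {key: {(group, rep): value}}."""
    cells = sorted({c for d in values_by_site.values() for c in d})
    columns = pd.MultiIndex.from_tuples(cells, names=["group", "replicate"])
    keys = sorted(values_by_site)
    mat = np.full((len(keys), len(cells)), np.nan)
    for i, k in enumerate(keys):
        for j, c in enumerate(cells):
            if c in values_by_site[k]:
                mat[i, j] = values_by_site[k][c]
    data = pd.DataFrame(mat, index=pd.Index(keys), columns=columns)
    counts = pd.Series(1, index=data.index)
    return quantio.SiteQuantTable(data, counts)
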