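import pandas as pd
import pytest

from deltascan import io as dio


@pytest.fixture(scope="session")
def preknown_db():
    return dio.read_modification_db(dio.preknown_db_path())


@pytest.fixture(scope="session")
def unimod_db():
    return dio.read_modification_db(dio.unimod_db_path())


@pytest.fixture(scope="session")
def peak_table():
    """The packaged 25-peak published summary (classification, delta mass,
    frequency, annotation, formula, printed mass/error)."""
    return pd.read_csv(dio.peak_summary_path(), sep="\t")


@pytest.fixture()
def tiny_psms():
    """Six hand-written PSMs covering both groups and two sites."""
    return pd.DataFrame({
        "spectrum_id": [f"s{i}" for i in range(6)],
        "peptide": ["AAAAWAAAA"] * 6,
        "protein": ["P1", "P1", "P1", "P2", "P2", "P2"],
        "site": [10, 10, 10, 3, 3, 3],
        "residue": ["W"] * 6,
        "delta_mass": [15.995, 15.994, 15.996, 3.995, 3.994, 3.996],
        "score": [350.0, 400.0, 300.0, 500.0, 310.0, 320.0],
        "delta_mod_score": [15.0, 12.0, 10.0, 20.0, 11.0, 13.0],
        "fdr_2d": [0.001, 0.005, 0.01, 0.0, 0.002, 0.003],
        "sample_id": ["T01", "N01", "T01", "N01", "T01", "N01"],
        "group": ["tumor", "NAT", "tumor", "NAT", "tumor", "NAT"],
    })
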