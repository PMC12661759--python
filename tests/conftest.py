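import numpy as np
import pytest

from csfbench.io import PeptideRecord, PeptideTable, SampleSheet


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250921)


@pytest.fixture()
def toy_sheet():
    return SampleSheet(
        samples={
            "A.P1": {"method": "A", "patient": "P1"},
            "A.P2": {"method": "A", "patient": "P2"},
            "B.P1": {"method": "B", "patient": "P1"},
            "B.P2": {"method": "B", "patient": "P2"},
        }
    )


def make_table(rows, workflow=None):
    """rows: list of (sequence, accessions, {sample: intensity})."""
    return PeptideTable(
        records=[
            PeptideRecord(sequence=s, accessions=tuple(a), intensities=dict(i))
            for s, a, i in rows
        ],
        workflow=workflow,
    )


@pytest.fixture()
def make_peptide_table():
    return make_table
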