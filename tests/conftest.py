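import numpy as np
import pytest

from acetylink.genomic_io import CountMatrix, SampleRecord, SampleSheet


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_sheet(n_per_group: int, assay: str = "rna", library_size: int = 10**6) -> SampleSheet:
    records = []
    for cond in ("control", "case"):
        for k in range(n_per_group):
            records.append(SampleRecord(f"{cond}{k + 1}", cond, assay, library_size))
    return SampleSheet(records)


def make_counts(array, sheet: SampleSheet, feature_kind: str = "gene") -> CountMatrix:
    array = np.asarray(array)
    ids = [f"f{i}" for i in range(array.shape[0])]
    samples = [s.sample_id for s in sheet.samples]
    return CountMatrix(ids, samples, array, feature_kind)


@pytest.fixture
def sheet6() -> SampleSheet:
    return make_sheet(3)
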