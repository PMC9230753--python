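import numpy as np
import pytest

import bfpcnet as b


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 20-patient synthetic dataset on disk, shared across tests."""
    out = tmp_path_factory.mktemp("data")
    spec = b.SyntheticSpec(n_patients=20, image_size=48, seed=7)
    manifest = b.generate_dataset(spec, out)
    return spec, manifest


@pytest.fixture(scope="session")
def small_records(small_dataset):
    _, manifest = small_dataset
    data = b.read_manifest(manifest)
    assert not data.errors
    return data.records


def make_records(labels_per_record):
    """Metadata-only records (paths never resolved) for split/balance tests."""
    records = []
    for i, labels in enumerate(labels_per_record):
        records.append(b.PatientRecord(f"r{i}", f"l{i}.png", f"r{i}.png",
                                       np.asarray(labels, dtype=int)))
    return records


def single_label_records(cls_index, n, start=0):
    labels = np.zeros(8, dtype=int)
    labels[cls_index] = 1
    return make_records([labels] * n)
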