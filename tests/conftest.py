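from __future__ import annotations

import pytest
from hypothesis import settings

from cislnc.paired_de import call_deregulated

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from cislnc.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset (seed 1) shared across tests."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_de(default_dataset):
    """Deregulation calls for both cohorts of the default dataset."""
    ds = default_dataset
    return call_deregulated(ds.cohort_a), call_deregulated(ds.cohort_b)


@pytest.fixture()
def gtf_file(tmp_path):
    """Factory writing GTF text to a temp file."""

    def _write(text: str):
        path = tmp_path / "genes.gtf"
        path.write_text(text)
        return path

    return _write
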