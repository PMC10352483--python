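import numpy as np
import pandas as pd
import pytest

from evscope import decode, simulate
from evscope.panel import PanelSpec, default_panel


@pytest.fixture(scope="session")
def small_panel() -> PanelSpec:
    """Ten-protein panel with well-separated tags."""
    return default_panel(n_proteins=10, tag_length=8, seed=11)


@pytest.fixture(scope="session")
def full_panel() -> PanelSpec:
    return default_panel()


@pytest.fixture(scope="session")
def clean_sim_config() -> simulate.SimConfig:
    """Small error-free cohort configuration (2 vs 2 samples)."""
    return simulate.SimConfig(
        samples_per_group={"OVCA": 3, "Con": 3}, evs_per_sample=1200,
        base_error_rate=0.0, low_quality_fraction=0.0,
        reads_per_molecule=1.0, seed=7)


@pytest.fixture(scope="session")
def clean_truth(full_panel, clean_sim_config) -> simulate.SimulationTruth:
    panel, subclusters = simulate.default_scenario(panel=full_panel)
    return simulate.simulate_population(clean_sim_config, full_panel,
                                        subclusters)


@pytest.fixture(scope="session")
def decoded_cohort(clean_truth, full_panel, tmp_path_factory):
    """FASTQ round trip of the clean cohort: decoded matrices + groups."""
    outdir = tmp_path_factory.mktemp("reads")
    paths = simulate.emit_reads(clean_truth, outdir)
    matrices = {}
    for sid, path in paths.items():
        matrices[sid], _ = decode.decode_sample(path, full_panel)
    return matrices, clean_truth.sample_groups


def write_fastq(path, records):
    """records: iterable of (name, seq, qual_string)."""
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    return path
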