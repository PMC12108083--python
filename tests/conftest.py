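import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from panscreen.data_io import AbundanceMatrix, SampleMetadata
from panscreen.synthetic import (
    default_scenario,
    lineages_for,
    pangenome_map_for,
    simulate_community,
    simulate_gene_reads,
)


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic scenario (seed 42) simulated once per session."""
    scenario = default_scenario(seed=42)
    relabund, metadata = simulate_community(scenario)
    reads, copynum, presence, truth = simulate_gene_reads(relabund, scenario)
    return {
        "scenario": scenario,
        "relabund": relabund,
        "metadata": metadata,
        "reads": reads,
        "copynum": copynum,
        "presence": presence,
        "truth": truth,
        "lineages": lineages_for(scenario),
        "pangenome_map": pangenome_map_for(truth),
    }


@pytest.fixture
def tiny_presence():
    """2 genes x 4 samples presence matrix."""
    return AbundanceMatrix(
        ["g1", "g2"],
        ["s1", "s2", "s3", "s4"],
        np.array([[1.0, 1.0, 0.0, 1.0], [1.0, 0.0, 0.0, 1.0]]),
        "gene_presence",
    )


@pytest.fixture
def tiny_metadata():
    return SampleMetadata(
        groups={"s1": "case", "s2": "case", "s3": "control", "s4": "control"}
    )
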