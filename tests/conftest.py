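import numpy as np
import pandas as pd
import pytest

from hybridgs import simdata
from hybridgs.genotype_io import MARKER_COLUMNS, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_markers(n, chrom="chr01", alleles=("A", "G")):
    return pd.DataFrame(
        [(f"m{j+1}", chrom, (j + 1) * 100, alleles[0], alleles[1]) for j in range(n)],
        columns=MARKER_COLUMNS,
    )


@pytest.fixture
def small_panel(rng):
    """10 homozygous samples x 20 encoded markers."""
    calls = rng.choice([-1.0, 1.0], size=(10, 20))
    return GenotypeMatrix([f"s{i}" for i in range(10)], make_markers(20), calls)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small but structurally complete NC II bundle (reused across tests)."""
    cfg = simdata.SimulationConfig(
        n_females=20, n_males=3, n_candidates=15, n_markers=300, seed=7
    )
    archs = [
        simdata.TraitArchitecture("HI", 0.85, n_qtl=30, mean=50.0),
        simdata.TraitArchitecture("LO", 0.30, n_qtl=30, mean=20.0),
    ]
    return simdata.make_study_bundle(cfg, archs)
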