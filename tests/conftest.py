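import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cpgdm import simulate
from cpgdm.methylome import MethylomeTable


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(
        seed=11,
        n_chromosomes=1,
        chrom_length=80_000,
        n_genes=10,
        emt_set_size=5,
        n_de_genes=4,
        n_planted_dmrs=3,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate.simulate_annotation_bundle(small_config)


def make_table(records, samples, conditions):
    """records: list of (chrom, pos, strand, meth list, unmeth list)."""
    sites = pd.DataFrame(
        [(r[0], r[1], r[2]) for r in records], columns=["chrom", "pos", "strand"]
    )
    meth = np.array([r[3] for r in records], dtype=float)
    unmeth = np.array([r[4] for r in records], dtype=float)
    if meth.size == 0:
        meth = np.empty((0, len(samples)))
        unmeth = np.empty((0, len(samples)))
    return MethylomeTable(
        sites=sites, meth=meth, unmeth=unmeth, samples=list(samples),
        conditions=dict(conditions),
    )


@pytest.fixture
def toy_table():
    """Two dyads, 1 uncut + 1 cut sample."""
    return make_table(
        [
            ("chr1", 100, "+", [3, 1], [1, 3]),
            ("chr1", 101, "-", [2, 1], [2, 3]),
            ("chr1", 200, "+", [5, 0], [0, 5]),
            ("chr1", 201, "-", [4, 1], [1, 4]),
        ],
        ["u1", "c1"],
        {"u1": "uncut", "c1": "cut"},
    )
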