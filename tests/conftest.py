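import pandas as pd
import pytest

from mistseq import simulate as sim
from mistseq.model import CountTable, RunConfig


@pytest.fixture(scope="session")
def config():
    return RunConfig(seed=7)


@pytest.fixture(scope="session")
def world():
    """A mid-sized synthetic world shared by read-only tests."""
    return sim.simulate_genome_and_annotation(n_genes=80, seed=7)


@pytest.fixture(scope="session")
def decay_run(world, config):
    table, s_true, alpha_map = sim.simulate_decay_counts(
        world, config, conditions=("WT", "mutant")
    )
    return table, s_true, alpha_map


def make_table(counts: dict, species=None) -> CountTable:
    """Build a CountTable from {(cond, tp, rep): list-of-counts}."""
    n = len(next(iter(counts.values())))
    index = pd.MultiIndex.from_arrays(
        [["chr1"] * n, list(range(10, 10 + n)), ["+"] * n],
        names=["chrom", "pos", "strand"],
    )
    df = pd.DataFrame(counts, index=index)
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    if species is None:
        species = pd.Series("sample", index=index)
    else:
        species = pd.Series(species, index=index)
    return CountTable(df, species)
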