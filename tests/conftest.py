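import pandas as pd
import pytest

from astra.genome_io import ProbeSignalTable
from astra.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def sim():
    """One shared default-condition simulation for read-only tests."""
    return simulate(SimConfig(seed=7))


@pytest.fixture(scope="session")
def sim_features(sim):
    from astra.feature_builder import assemble_features

    strand_of = {g.gene_id: g.strand for g in sim.genes}
    strand_of.update(
        {hp.hairpin_id: hp.genomic_placement[3] for hp in sim.hairpins})
    X, y = assemble_features(sim.gold, sim.probes, sim.smrnas, strand_of)
    groups = pd.Series([p.group for p in sim.gold], index=X.index)
    return X, y, groups


def make_probe_table(rows, samples=("s1",), signal_cutoff=0.73):
    """Build a ProbeSignalTable from (probe_id, chrom, start, end, strand,
    sequence, *signals) tuples."""
    cols = ProbeSignalTable.META_COLUMNS + list(samples)
    frame = pd.DataFrame(list(rows), columns=cols)
    return ProbeSignalTable(frame, list(samples), signal_cutoff)
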