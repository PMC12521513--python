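import numpy as np
import pandas as pd
import pytest

from panelfrag import synthetic as syn
from panelfrag.fragments import SampleFragments
from panelfrag.regions import ExonRegion, PanelDefinition


@pytest.fixture(scope="session")
def small_config():
    return syn.SimulationConfig(seed=7, n_samples_per_phenotype=3, reads_per_sample=2000)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return syn.generate_panel(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_panel):
    samples, labels = syn.simulate_cohort(small_config, small_panel)
    return samples, labels


@pytest.fixture()
def toy_panel():
    """Hand-built 3-gene panel: A has exons 1-2, B exons 2-3 (no rank 1 on
    panel), C a single exon."""
    return PanelDefinition(
        (
            ExonRegion("chr1", 100, 200, "A", 1, True),
            ExonRegion("chr1", 300, 450, "A", 2, True),
            ExonRegion("chr1", 1000, 1100, "B", 2, True),
            ExonRegion("chr1", 1300, 1500, "B", 3, True),
            ExonRegion("chr1", 2000, 2120, "C", 1, True),
        )
    )


def make_fragments(sample_id, triples):
    """SampleFragments from (chrom, start, end[, motif5, motif3]) tuples."""
    rows = []
    for t in triples:
        chrom, start, end = t[:3]
        m5 = t[3] if len(t) > 3 else None
        m3 = t[4] if len(t) > 4 else None
        rows.append(
            {"chrom": chrom, "start": start, "end": end, "motif5": m5, "motif3": m3}
        )
    return SampleFragments(sample_id, pd.DataFrame(rows))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
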