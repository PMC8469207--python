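import numpy as np
import pandas as pd
import pytest

from littoral.core import CommunityTable, HabitatPartition, Sample, TaxonInfo


def make_table(biomass, taxa=None, samples=None, abundance=None, habitats=None):
    """Build a CommunityTable from a plain 2-D array.

    ``habitats`` maps each sample column index to a habitat id;
    default: every sample its own habitat.
    """
    arr = np.asarray(biomass, dtype=float)
    n_t, n_s = arr.shape
    tids = taxa or [f"tax{i}" for i in range(n_t)]
    sids = samples or [f"s{j}" for j in range(n_s)]
    habs = habitats or {j: sids[j] for j in range(n_s)}
    taxa_info = [t if isinstance(t, TaxonInfo) else TaxonInfo(taxon_id=t) for t in tids]
    tids = [t.taxon_id for t in taxa_info]
    samp = [Sample(sample_id=sids[j], habitat_id=habs[j]) for j in range(n_s)]
    return CommunityTable(
        taxa=taxa_info,
        samples=samp,
        biomass=pd.DataFrame(arr, index=tids, columns=sids),
        abundance=(
            None
            if abundance is None
            else pd.DataFrame(np.asarray(abundance, float), index=tids, columns=sids)
        ),
    )


@pytest.fixture
def two_habitat_table():
    """Four taxa over two habitats with two samples each."""
    biomass = [
        [10.0, 12.0, 0.0, 0.0],   # exclusive to habitat A
        [0.0, 0.0, 6.0, 8.0],     # exclusive to habitat B
        [5.0, 5.0, 5.0, 5.0],     # ubiquitous
        [1.0, 3.0, 2.0, 2.0],
    ]
    table = make_table(
        biomass,
        taxa=["excA", "excB", "ubiq", "mix"],
        samples=["a1", "a2", "b1", "b2"],
        habitats={0: "A", 1: "A", 2: "B", 3: "B"},
    )
    partition = HabitatPartition.from_samples(table.samples)
    return table, partition
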