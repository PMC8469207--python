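"""Bundled reference data.

Two small CSVs ship with the package:

* ``baikal_richness.csv`` -- the taxon richness bookkeeping of a
  Lake Baikal coastal survey: counts of recorded taxa per higher
  group, split into the plankton and the benthic flora.  Summing the
  printed group counts gives 92 plankton taxa, 88 benthic-flora taxa
  and 180 in total.
* ``baikal_dominants_registry.csv`` -- a starter taxon registry for
  the survey's dominant taxa.  Guild flags and the uniform saprobic
  valences are **placeholders, not authoritative**: real valences
  come from the published saprobic-organism lists and must be
  supplied by the user for any real assessment.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import TaxonRegistry
from .io import read_registry

__all__ = ["load_baikal_richness", "richness_totals", "load_dominants_registry"]


def _data_path(name: str):
    return resources.files("littoral.data").joinpath(name)


def load_baikal_richness() -> pd.DataFrame:
    """Per-group taxon counts (columns: community, higher_group, n_taxa)."""
    with resources.as_file(_data_path("baikal_richness.csv")) as p:
        return pd.read_csv(p)


def richness_totals() -> dict[str, int]:
    """Summed taxon counts: plankton, benthic flora, and the grand total."""
    df = load_baikal_richness()
    by = df.groupby("community")["n_taxa"].sum()
    plankton = int(by.get("plankton", 0))
    benthic = int(
        by.get("benthic_macroalgae", 0)
        + by.get("benthic_microalgae", 0)
        + by.get("benthic_macrophytes", 0)
    )
    return {
        "plankton": plankton,
        "benthic_flora": benthic,
        "total": plankton + benthic,
    }


def load_dominants_registry() -> TaxonRegistry:
    """Starter registry for the survey's dominant taxa (placeholder valences)."""
    with resources.as_file(_data_path("baikal_dominants_registry.csv")) as p:
        return read_registry(p)
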