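"""Delimited-text readers and writers for community data.

Three CSV/TSV artefacts are supported, all UTF-8 with ``.`` decimal
separator:

* community table -- **wide** (rows = taxa, first column ``taxon_id``,
  remaining columns one per sample) or **long** (columns ``taxon_id``,
  ``sample_id``, ``value``).  Wide is the canonical output dialect.
  In long form an absent (taxon, sample) pair means zero (absence),
  not missing data.
* taxon registry -- columns ``taxon_id``, ``name``, ``higher_group``,
  ``eutrophic``, ``oligotrophic``, ``mesosaprobiont``, ``endemic``,
  ``saprobic_valence``.
* sample sheet -- columns ``sample_id``, ``habitat_id``,
  ``station_id``, ``stratum``, ``replicate``.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CommunityTable,
    Sample,
    TaxonInfo,
    TaxonRegistry,
    ValidationError,
)

__all__ = [
    "read_community_table",
    "write_community_table",
    "read_registry",
    "write_registry",
    "read_sample_sheet",
    "write_sample_sheet",
]

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}


def _as_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, np.integer, float, np.floating)):
        if pd.isna(v):
            return False
        return bool(int(v))
    s = str(v).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"cannot interpret {v!r} as a boolean flag")


def read_registry(path: str | Path, sep: str = ",") -> TaxonRegistry:
    df = pd.read_csv(path, sep=sep, dtype={"taxon_id": str})
    required = {"taxon_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"registry {path}: missing columns {sorted(missing)}")
    taxa = []
    for _, row in df.iterrows():
        val = row.get("saprobic_valence", np.nan)
        taxa.append(
            TaxonInfo(
                taxon_id=str(row["taxon_id"]),
                name=str(row.get("name", "") or row["taxon_id"]),
                higher_group=str(row.get("higher_group", "") or ""),
                guild_eutrophic=_as_bool(row.get("eutrophic", False)),
                guild_oligotrophic=_as_bool(row.get("oligotrophic", False)),
                guild_mesosaprobiont=_as_bool(row.get("mesosaprobiont", False)),
                guild_endemic=_as_bool(row.get("endemic", False)),
                saprobic_valence=None if pd.isna(val) else float(val),
            )
        )
    return TaxonRegistry(taxa)


def write_registry(registry: TaxonRegistry, path: str | Path, sep: str = ",") -> None:
    registry.to_frame().to_csv(path, sep=sep, index=False)


def read_sample_sheet(path: str | Path, sep: str = ",") -> list[Sample]:
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"sample_id", "habitat_id"} - set(df.columns)
    if missing:
        raise ValidationError(f"sample sheet {path}: missing columns {sorted(missing)}")
    samples = []
    for _, row in df.iterrows():
        rep = row.get("replicate")
        samples.append(
            Sample(
                sample_id=str(row["sample_id"]),
                habitat_id=str(row["habitat_id"]),
                station_id=(None if pd.isna(row.get("station_id")) else str(row["station_id"])),
                stratum=(None if pd.isna(row.get("stratum")) else str(row["stratum"])),
                replicate=(None if rep is None or pd.isna(rep) else int(rep)),
            )
        )
    return samples


def write_sample_sheet(samples: Sequence[Sample], path: str | Path, sep: str = ",") -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "habitat_id": s.habitat_id,
                "station_id": s.station_id,
                "stratum": s.stratum,
                "replicate": s.replicate,
            }
            for s in samples
        ]
    ).to_csv(path, sep=sep, index=False)


def _read_matrix(path: str | Path, dialect: str, sep: str, what: str) -> pd.DataFrame:
    if dialect == "wide":
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"{what} {path}: duplicate taxon row {dup!r}")
        return df.astype(float)
    if dialect == "long":
        df = pd.read_csv(
            path, sep=sep, dtype={"taxon_id": str, "sample_id": str},
            float_precision="round_trip",
        )
        missing = {"taxon_id", "sample_id", "value"} - set(df.columns)
        if missing:
            raise ValidationError(
                f"{what} {path}: long dialect missing columns {sorted(missing)}"
            )
        dup = df.duplicated(subset=["taxon_id", "sample_id"])
        if dup.any():
            r = df[dup].iloc[0]
            raise ValidationError(
                f"{what} {path}: duplicate (taxon, sample) pair "
                f"({r['taxon_id']!r}, {r['sample_id']!r})"
            )
        # absent pairs are absences (zero), not missing data
        return (
            df.pivot(index="taxon_id", columns="sample_id", values="value")
            .fillna(0.0)
            .astype(float)
        )
    raise ValidationError(f"unknown table dialect {dialect!r}")


def read_community_table(
    path: str | Path,
    *,
    dialect: str = "wide",
    sample_sheet: str | Path | None = None,
    registry: TaxonRegistry | None = None,
    abundance_path: str | Path | None = None,
    unit_kind: str = "per_volume",
    sep: str = ",",
) -> CommunityTable:
    """Read and validate a community table.

    With no sample sheet each column becomes its own habitat (sample id
    doubles as habitat id).  Taxa absent from ``registry`` warn and fall
    back to bare placeholder attributes.
    """
    biomass = _read_matrix(path, dialect, sep, "community table")

    if sample_sheet is not None:
        samples = read_sample_sheet(sample_sheet, sep=sep)
        by_id = {s.sample_id: s for s in samples}
        missing = [c for c in biomass.columns if c not in by_id]
        if missing:
            raise ValidationError(
                f"samples {missing} in table but not in sample sheet"
            )
        samples = [by_id[c] for c in biomass.columns]
    else:
        samples = [Sample(sample_id=c, habitat_id=c) for c in biomass.columns]

    if registry is not None:
        unknown = [t for t in biomass.index if t not in registry]
        if unknown:
            warnings.warn(
                f"{len(unknown)} taxa not in registry (e.g. {unknown[:3]}); "
                "using placeholder attributes",
                stacklevel=2,
            )
        taxa = [registry.get(t) for t in biomass.index]
    else:
        taxa = [TaxonInfo(taxon_id=t, name=t) for t in biomass.index]

    abundance = None
    if abundance_path is not None:
        abundance = _read_matrix(abundance_path, dialect, sep, "abundance table")
        abundance = abundance.reindex(index=biomass.index, columns=biomass.columns)
        if abundance.isna().any().any():
            raise ValidationError(
                "abundance table does not cover every (taxon, sample) cell "
                "of the biomass table"
            )

    return CommunityTable(
        taxa=taxa,
        samples=samples,
        biomass=biomass,
        abundance=abundance,
        unit_kind=unit_kind,
    )


def write_community_table(
    table: CommunityTable,
    path: str | Path,
    *,
    dialect: str = "wide",
    what: str = "biomass",
    sep: str = ",",
) -> None:
    """Write the biomass (or abundance) matrix.

    Values are written with shortest round-tripping float repr, so a
    write -> read cycle reproduces the matrix bit-for-bit.
    """
    mat = table.biomass if what == "biomass" else table.abundance
    if mat is None:
        raise ValidationError(f"table has no {what} matrix")
    if dialect == "wide":
        out = mat.copy()
        out.index.name = "taxon_id"
        out.to_csv(path, sep=sep)
    elif dialect == "long":
        long = mat.stack().rename("value").reset_index()
        long.columns = ["taxon_id", "sample_id", "value"]
        long.to_csv(path, sep=sep, index=False)
    else:
        raise ValidationError(f"unknown table dialect {dialect!r}")
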