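"""Core data model for taxon x sample community tables.

The universal input of every analysis stage is a quantitative community
table: a taxon x sample matrix of biomass (optionally paired with an
abundance matrix of identical shape), a list of per-sample metadata
records (habitat, station, depth stratum, replicate), and per-taxon
attributes (higher taxonomic group, indicator-guild flags, saprobic
valence).  Samples are grouped into habitats -- e.g. a reference data
set, a background site and an impacted site -- by a
:class:`HabitatPartition`.

Units are metadata only: plankton biomass is conventionally mg m^-3
(per unit volume), benthos mg m^-2 (per unit area).  No conversion is
ever performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ValidationError",
    "Sample",
    "TaxonInfo",
    "TaxonRegistry",
    "CommunityTable",
    "HabitatPartition",
    "integrate_strata",
    "total_biomass",
]

SAPROBIC_VALENCE_RANGE = (0.0, 4.5)


class ValidationError(ValueError):
    """A table, registry or partition violates its contract."""


@dataclass(frozen=True)
class Sample:
    """Metadata for one quantitative sample.

    ``habitat_id`` is the reporting unit (e.g. ``"RD"``, ``"Site1"``,
    ``"Site2"``); ``stratum`` labels a depth layer prior to vertical
    integration; ``replicate`` numbers repeated casts at one station.
    """

    sample_id: str
    habitat_id: str
    station_id: str | None = None
    stratum: str | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not self.habitat_id:
            raise ValidationError(
                f"sample {self.sample_id!r}: habitat_id must be non-empty"
            )


@dataclass(frozen=True)
class TaxonInfo:
    """Per-taxon attributes driving the indicator computations.

    Guild flags mark membership in the eutrophic (E) and oligotrophic
    (O) indicator lists, the mesosaprobiont (M) list and the set of
    lake endemics; ``saprobic_valence`` is the published tolerance
    score s_i on the 0--4.5 saprobity scale.  A taxon is an indicator
    species iff it has a valence.
    """

    taxon_id: str
    name: str = ""
    higher_group: str = ""
    guild_eutrophic: bool = False
    guild_oligotrophic: bool = False
    guild_mesosaprobiont: bool = False
    guild_endemic: bool = False
    saprobic_valence: float | None = None

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise ValidationError("taxon_id must be non-empty")
        if self.guild_eutrophic and self.guild_oligotrophic:
            raise ValidationError(
                f"taxon {self.taxon_id!r}: cannot be both eutrophic and oligotrophic"
            )
        if self.saprobic_valence is not None:
            lo, hi = SAPROBIC_VALENCE_RANGE
            if not (lo <= float(self.saprobic_valence) <= hi):
                raise ValidationError(
                    f"taxon {self.taxon_id!r}: saprobic valence "
                    f"{self.saprobic_valence} outside [{lo}, {hi}]"
                )

    @property
    def is_indicator(self) -> bool:
        return self.saprobic_valence is not None


class TaxonRegistry:
    """Lookup of :class:`TaxonInfo` by taxon id.

    Unknown taxa resolve to a bare placeholder (name = id, no guild
    membership, no valence) so that a registry covering only the
    indicator taxa of interest is sufficient.
    """

    def __init__(self, taxa: Iterable[TaxonInfo] = ()) -> None:
        self._taxa: dict[str, TaxonInfo] = {}
        for t in taxa:
            if t.taxon_id in self._taxa:
                raise ValidationError(f"duplicate taxon_id {t.taxon_id!r} in registry")
            self._taxa[t.taxon_id] = t

    def get(self, taxon_id: str) -> TaxonInfo:
        try:
            return self._taxa[taxon_id]
        except KeyError:
            return TaxonInfo(taxon_id=taxon_id, name=taxon_id)

    def add(self, info: TaxonInfo) -> None:
        if info.taxon_id in self._taxa:
            raise ValidationError(f"duplicate taxon_id {info.taxon_id!r} in registry")
        self._taxa[info.taxon_id] = info

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._taxa

    def __len__(self) -> int:
        return len(self._taxa)

    def __iter__(self) -> Iterator[TaxonInfo]:
        return iter(self._taxa.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "taxon_id": t.taxon_id,
                "name": t.name,
                "higher_group": t.higher_group,
                "eutrophic": int(t.guild_eutrophic),
                "oligotrophic": int(t.guild_oligotrophic),
                "mesosaprobiont": int(t.guild_mesosaprobiont),
                "endemic": int(t.guild_endemic),
                "saprobic_valence": (
                    np.nan if t.saprobic_valence is None else float(t.saprobic_valence)
                ),
            }
            for t in self
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "taxon_id",
                "name",
                "higher_group",
                "eutrophic",
                "oligotrophic",
                "mesosaprobiont",
                "endemic",
                "saprobic_valence",
            ],
        )


@dataclass
class CommunityTable:
    """A validated taxon x sample quantitative matrix.

    ``biomass`` (and optionally ``abundance``) are DataFrames indexed
    by taxon id with sample ids as columns; rows and columns align
    with ``taxa`` and ``samples``.
    """

    taxa: list[TaxonInfo]
    samples: list[Sample]
    biomass: pd.DataFrame
    abundance: pd.DataFrame | None = None
    unit_kind: str = "per_volume"

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return [t.taxon_id for t in self.taxa]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    # -- validation ------------------------------------------------
    def validate(self) -> None:
        if self.unit_kind not in ("per_volume", "per_area"):
            raise ValidationError(f"unknown unit_kind {self.unit_kind!r}")
        tids = self.taxon_ids
        sids = self.sample_ids
        if len(set(tids)) != len(tids):
            raise ValidationError("duplicate taxon ids in table")
        if len(set(sids)) != len(sids):
            raise ValidationError("duplicate sample ids in table")
        for name, mat in (("biomass", self.biomass), ("abundance", self.abundance)):
            if mat is None:
                continue
            if list(mat.index) != tids or list(mat.columns) != sids:
                raise ValidationError(
                    f"{name} matrix index/columns do not match taxa/samples"
                )
            vals = mat.to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                r, c = np.argwhere(~np.isfinite(vals))[0]
                raise ValidationError(
                    f"non-finite {name} at ({tids[r]!r}, {sids[c]!r})"
                )
            if np.any(vals < 0):
                r, c = np.argwhere(vals < 0)[0]
                raise ValidationError(
                    f"negative {name} at ({tids[r]!r}, {sids[c]!r}): {vals[r, c]}"
                )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CommunityTable":
        keep = list(sample_ids)
        samples = [s for s in self.samples if s.sample_id in set(keep)]
        return CommunityTable(
            taxa=list(self.taxa),
            samples=samples,
            biomass=self.biomass[[s.sample_id for s in samples]].copy(),
            abundance=(
                None
                if self.abundance is None
                else self.abundance[[s.sample_id for s in samples]].copy()
            ),
            unit_kind=self.unit_kind,
        )


@dataclass
class HabitatPartition:
    """Disjoint grouping of sample ids into habitats.

    Insertion order of ``groups`` is the reporting order.
    """

    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for hab, sids in self.groups.items():
            if not hab:
                raise ValidationError("habitat_id must be non-empty")
            dup = seen.intersection(sids)
            if dup:
                raise ValidationError(
                    f"samples {sorted(dup)} assigned to more than one habitat"
                )
            if len(set(sids)) != len(sids):
                raise ValidationError(f"duplicate sample ids in habitat {hab!r}")
            seen.update(sids)

    @classmethod
    def from_samples(cls, samples: Iterable[Sample]) -> "HabitatPartition":
        groups: dict[str, list[str]] = {}
        for s in samples:
            groups.setdefault(s.habitat_id, []).append(s.sample_id)
        return cls(groups)

    @property
    def order(self) -> list[str]:
        return list(self.groups)

    def all_sample_ids(self) -> list[str]:
        out: list[str] = []
        for sids in self.groups.values():
            out.extend(sids)
        return out

    def covers(self, table: CommunityTable) -> bool:
        return set(self.all_sample_ids()) == set(table.sample_ids)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

_VALID_KEYS = ("station_id", "habitat_id")


def integrate_strata(
    table: CommunityTable,
    by: Sequence[str] = ("station_id", "habitat_id"),
) -> CommunityTable:
    """Pool depth strata (and replicates) into one integral sample per group.

    Samples sharing the grouping keys are averaged taxon-wise
    (arithmetic mean), emulating the merge of casts from several water
    layers into a single integral 0--15 m sample per station.  The
    operation is idempotent: re-integrating an integrated table with
    the same keys is the identity.
    """
    bad = [k for k in by if k not in _VALID_KEYS]
    if bad:
        raise ValidationError(f"grouping keys {bad} not in {_VALID_KEYS}")
    if not by:
        raise ValidationError("at least one grouping key required")

    groups: dict[tuple, list[Sample]] = {}
    for s in table.samples:
        key = tuple(getattr(s, k) or "" for k in by)
        groups.setdefault(key, []).append(s)

    new_samples: list[Sample] = []
    bio_cols: dict[str, pd.Series] = {}
    abu_cols: dict[str, pd.Series] = {}
    for key, members in groups.items():
        habitats = sorted({m.habitat_id for m in members})
        if len(habitats) > 1:
            raise ValidationError(
                f"group {key} mixes habitats {habitats}; include 'habitat_id' "
                "in the grouping keys or fix the sample sheet"
            )
        stations = {m.station_id for m in members}
        sid = "|".join(str(p) for p in key if p != "") or habitats[0]
        new_samples.append(
            Sample(
                sample_id=sid,
                habitat_id=habitats[0],
                station_id=stations.pop() if len(stations) == 1 else None,
                stratum=None,
                replicate=None,
            )
        )
        cols = [m.sample_id for m in members]
        bio_cols[sid] = table.biomass[cols].mean(axis=1)
        if table.abundance is not None:
            abu_cols[sid] = table.abundance[cols].mean(axis=1)

    sids = [s.sample_id for s in new_samples]
    if len(set(sids)) != len(sids):
        raise ValidationError("integration produced non-unique sample ids")
    biomass = pd.DataFrame(bio_cols)[sids]
    abundance = pd.DataFrame(abu_cols)[sids] if abu_cols else None
    return CommunityTable(
        taxa=list(table.taxa),
        samples=new_samples,
        biomass=biomass,
        abundance=abundance,
        unit_kind=table.unit_kind,
    )


def total_biomass(
    table: CommunityTable, partition: HabitatPartition
) -> dict[str, tuple[float, float | None]]:
    """Per-habitat mean and standard error of per-sample total biomass.

    Per-sample totals (sum over taxa) are averaged within each
    habitat; SE = sample standard deviation / sqrt(n), reported as
    ``None`` for single-sample habitats.
    """
    out: dict[str, tuple[float, float | None]] = {}
    for hab, sids in partition.groups.items():
        if not sids:
            raise ValidationError(f"habitat {hab!r} has no samples")
        totals = table.biomass[list(sids)].sum(axis=0).to_numpy(dtype=float)
        mean = float(np.mean(totals))
        se = float(stats.sem(totals, ddof=1)) if len(totals) > 1 else None
        out[hab] = (mean, se)
    return out
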