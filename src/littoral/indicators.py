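"""Diversity, saprobity and guild-ratio indicators per habitat.

Four indicator families summarise the trophic condition of each
habitat:

* Shannon diversity H on biomass proportions (natural log by default);
* the Pantle-Buck saprobity index, ``S = sum(s_i h_i) / sum(h_i)``,
  a frequency-weighted mean of the saprobic valences s_i of the
  indicator species present, mapped to the classical saprobic zones
  (oligosaprobic 0.50-1.50, beta-mesosaprobic 1.51-2.50,
  alpha-mesosaprobic 2.51-3.50, polysaprobic 3.51-4.50);
* E/O -- the count of eutrophic indicator species over the count of
  oligotrophic indicator species present (presence/absence only);
* M/E -- the biomass of mesosaprobiont taxa over the biomass of lake
  endemics, an early-warning eutrophication signal: values above 1
  mean tolerant widespread taxa outweigh the endemic assemblage.

Ratios are additionally formatted in the compact ``x:1`` / ``1:x``
field style (rounding half away from zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import (
    CommunityTable,
    HabitatPartition,
    TaxonInfo,
    TaxonRegistry,
    ValidationError,
    total_biomass,
)

__all__ = [
    "SaprobicZone",
    "RatioResult",
    "shannon_diversity",
    "saprobity_index",
    "classify_saprobic_zone",
    "format_ratio",
    "eo_ratio",
    "me_ratio",
    "TrophicRow",
    "TrophicReport",
    "build_trophic_report",
]


class SaprobicZone(str, Enum):
    OLIGOSAPROBIC = "oligosaprobic"
    BETA_MESOSAPROBIC = "beta_mesosaprobic"
    ALPHA_MESOSAPROBIC = "alpha_mesosaprobic"
    POLYSAPROBIC = "polysaprobic"
    OUT_OF_RANGE = "out_of_range"


# Zone limits are printed to two decimals (e.g. oligosaprobic up to
# 1.50, beta-mesosaprobic from 1.51), leaving (1.50, 1.51) formally
# uncovered; interior boundaries split the gap at the midpoint so that
# every S in [0.50, 4.50] classifies.
ZONE_BOUNDS: tuple[float, float, float, float, float] = (0.50, 1.505, 2.505, 3.505, 4.50)
_ZONES = (
    SaprobicZone.OLIGOSAPROBIC,
    SaprobicZone.BETA_MESOSAPROBIC,
    SaprobicZone.ALPHA_MESOSAPROBIC,
    SaprobicZone.POLYSAPROBIC,
)


def shannon_diversity(values: Sequence[float], base: float | None = None) -> float:
    """Shannon index H = -sum(p_k log p_k) over positive entries.

    ``values`` are raw quantities (biomass shares are formed
    internally); ``base`` defaults to the natural logarithm.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("expected a 1-D vector of quantities")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValidationError("quantities must be finite and non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValidationError("Shannon index undefined for an all-zero vector")
    p = arr[arr > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def saprobity_index(valences: Sequence[float], weights: Sequence[float]) -> float:
    """Frequency-weighted mean valence S = sum(s_i h_i) / sum(h_i).

    Invariant to uniform rescaling of the weights; bounded by the
    extreme valences of the contributing indicators.
    """
    s = np.asarray(valences, dtype=float)
    h = np.asarray(weights, dtype=float)
    if s.size == 0:
        raise ValidationError("no indicator species: saprobity index undefined")
    if s.shape != h.shape:
        raise ValidationError("valences and weights must have the same length")
    if np.any(h <= 0) or not np.all(np.isfinite(h)):
        raise ValidationError("all occurrence weights h_i must be positive")
    return float((s * h).sum() / h.sum())


def classify_saprobic_zone(S: float) -> SaprobicZone:
    """Map a saprobity index to its zone; outside [0.50, 4.50] -> out_of_range."""
    if not math.isfinite(S):
        raise ValidationError("saprobity index must be finite")
    lo, b1, b2, b3, hi = ZONE_BOUNDS
    if S < lo or S > hi:
        return SaprobicZone.OUT_OF_RANGE
    for bound, zone in zip((b1, b2, b3), _ZONES[:3]):
        if S < bound:
            return zone
    return SaprobicZone.POLYSAPROBIC


class RatioResult(NamedTuple):
    raw: float  # may be inf (zero denominator) or nan (undefined)
    text: str


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def format_ratio(raw: float) -> str:
    """Compact ``x:1`` / ``1:x`` rendering of a positive ratio."""
    if not math.isfinite(raw) or raw <= 0:
        raise ValidationError(f"cannot format ratio {raw!r}")
    if raw >= 1:
        return f"{_round_half_away(raw)}:1"
    return f"1:{_round_half_away(1.0 / raw)}"


def eo_ratio(taxa: Iterable[TaxonInfo]) -> RatioResult:
    """Eutrophic over oligotrophic species count among the taxa present."""
    taxa = list(taxa)
    e = sum(t.guild_eutrophic for t in taxa)
    o = sum(t.guild_oligotrophic for t in taxa)
    if e == 0 and o == 0:
        return RatioResult(float("nan"), "NA")
    if o == 0:
        return RatioResult(float("inf"), f"{e}:0")
    if e == 0:
        return RatioResult(0.0, f"0:{o}")
    return RatioResult(e / o, format_ratio(e / o))


def me_ratio(
    table: CommunityTable,
    sample_ids: Sequence[str],
    registry: TaxonRegistry | None = None,
) -> RatioResult:
    """Mesosaprobiont biomass over endemic biomass within a habitat.

    Zero endemic biomass with positive mesosaprobiont biomass yields an
    infinite raw value and the sentinel text ``"M:0"``.
    """
    infos = _resolve_taxa(table, registry)
    sub = table.biomass[list(sample_ids)].sum(axis=1)
    m = float(sum(sub[t.taxon_id] for t in infos if t.guild_mesosaprobiont))
    e = float(sum(sub[t.taxon_id] for t in infos if t.guild_endemic))
    if m == 0 and e == 0:
        return RatioResult(float("nan"), "NA")
    if e == 0:
        return RatioResult(float("inf"), "M:0")
    if m == 0:
        return RatioResult(0.0, "0:E")
    return RatioResult(m / e, format_ratio(m / e))


def _resolve_taxa(
    table: CommunityTable, registry: TaxonRegistry | None
) -> list[TaxonInfo]:
    """Taxon attributes from the registry where available, else from the table."""
    if registry is None:
        return list(table.taxa)
    return [registry.get(t.taxon_id) if t.taxon_id in registry else t for t in table.taxa]


@dataclass
class TrophicRow:
    habitat_id: str
    n_taxa: int
    shannon_H: float
    n_indicator_species: int
    saprobity_S: float | None
    saprobic_zone: SaprobicZone | None
    eo: RatioResult
    me: RatioResult
    total_biomass_mean: float
    total_biomass_se: float | None


@dataclass
class TrophicReport:
    rows: list[TrophicRow]

    def row(self, habitat_id: str) -> TrophicRow:
        for r in self.rows:
            if r.habitat_id == habitat_id:
                return r
        raise KeyError(habitat_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "habitat_id": r.habitat_id,
                    "n_taxa": r.n_taxa,
                    "shannon_H": r.shannon_H,
                    "n_indicator_species": r.n_indicator_species,
                    "saprobity_S": np.nan if r.saprobity_S is None else r.saprobity_S,
                    "saprobic_zone": "" if r.saprobic_zone is None else r.saprobic_zone.value,
                    "EO_raw": r.eo.raw,
                    "EO": r.eo.text,
                    "ME_raw": r.me.raw,
                    "ME": r.me.text,
                    "total_biomass_mean": r.total_biomass_mean,
                    "total_biomass_se": (
                        np.nan if r.total_biomass_se is None else r.total_biomass_se
                    ),
                }
                for r in self.rows
            ]
        )


def build_trophic_report(
    table: CommunityTable,
    registry: TaxonRegistry | None,
    partition: HabitatPartition,
    *,
    shannon_base: float | None = None,
    h_weight: str | Callable[[pd.Series], float] = "occurrence",
) -> TrophicReport:
    """Assemble the per-habitat indicator block.

    ``h_weight`` controls the saprobity frequency weights: the default
    ``"occurrence"`` counts the habitat samples in which an indicator
    occurs; a callable receives the indicator's per-sample biomass
    within the habitat and returns a positive weight.  Habitats without
    indicator species get ``None`` for S and the zone.
    """
    infos = _resolve_taxa(table, registry)
    by_id = {t.taxon_id: t for t in infos}
    totals = total_biomass(table, partition)
    rows: list[TrophicRow] = []
    for hab, sids in partition.groups.items():
        sub = table.biomass[list(sids)]
        pooled = sub.sum(axis=1)
        present = pooled[pooled > 0]
        if present.empty:
            raise ValidationError(f"habitat {hab!r} has no biomass at all")
        present_infos = [by_id[t] for t in present.index]
        ind = [t for t in present_infos if t.is_indicator]
        S = zone = None
        if ind:
            valences = [float(t.saprobic_valence) for t in ind]
            if callable(h_weight):
                weights = [float(h_weight(sub.loc[t.taxon_id])) for t in ind]
            elif h_weight == "occurrence":
                weights = [float((sub.loc[t.taxon_id] > 0).sum()) for t in ind]
            else:
                raise ValidationError(f"unknown h_weight {h_weight!r}")
            S = saprobity_index(valences, weights)
            zone = classify_saprobic_zone(S)
        mean, se = totals[hab]
        rows.append(
            TrophicRow(
                habitat_id=hab,
                n_taxa=len(present),
                shannon_H=shannon_diversity(present.to_numpy(), base=shannon_base),
                n_indicator_species=len(ind),
                saprobity_S=S,
                saprobic_zone=zone,
                eo=eo_ratio(present_infos),
                me=me_ratio(table, sids, registry),
                total_biomass_mean=mean,
                total_biomass_se=se,
            )
        )
    return TrophicReport(rows)
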