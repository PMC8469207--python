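"""Index of relative biotope confinement and key-species selection.

The confinement index F_ij measures the fidelity of taxon *i* to
habitat *j* on a scale from -1 (absent from the habitat) to +1 (found
nowhere else).  With

* ``n_ij`` -- quantity (here: biomass) of taxon *i* in habitat *j*,
* ``n_i``  -- its quantity summed over all habitats,
* ``N_j``  -- total quantity of all taxa in habitat *j*,
* ``N``    -- the grand total,

the index is::

    F_ij = (n_ij * N - n_i * N_j) / (n_ij * N + n_i * N_j - 2 * n_ij * N_j)

F_ij = 0 exactly when the taxon's share of habitat *j* equals the
habitat's share of the grand total (n_ij / N_j = n_i / N), i.e. the
taxon is indifferent to the habitat.  Given n_i > 0 and N_j < N the
denominator is strictly positive (it equals
``n_ij * (N - N_j) + N_j * (n_i - n_ij)``), so the index is always
defined for a proper habitat subset.

A habitat's *key species* are its dominant taxa attaining the maximum
positive F_ij there.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CommunityTable, HabitatPartition, ValidationError

__all__ = [
    "confinement_index",
    "confinement_table",
    "select_key_species",
    "ConfinementResult",
    "confinement_report",
]

_REL_TOL = 1e-9


def confinement_index(n_ij: float, n_i: float, N_j: float, N: float) -> float:
    """Biotope-confinement index for a single taxon x habitat pair.

    Preconditions: ``0 <= n_ij <= n_i <= N``, ``n_ij <= N_j < N`` and
    ``n_i, N_j, N > 0``.
    """
    vals = (n_ij, n_i, N_j, N)
    if not all(math.isfinite(v) for v in vals):
        raise ValidationError(f"non-finite input {vals}")
    if n_ij < 0 or n_i <= 0 or N_j <= 0 or N <= 0:
        raise ValidationError(
            f"require n_ij >= 0 and n_i, N_j, N > 0; got {vals}"
        )
    slack = _REL_TOL * N
    if n_ij > n_i + slack or n_ij > N_j + slack or n_i > N + slack or N_j > N + slack:
        raise ValidationError(
            f"inconsistent totals: need n_ij <= n_i <= N and n_ij <= N_j <= N; got {vals}"
        )
    if N_j >= N:
        raise ValidationError(
            "habitat must be a proper subset of all collections (N_j < N)"
        )
    # the endpoints are algebraically forced (given N_j < N) and are
    # returned exactly, immune to rounding in the products
    if n_ij == 0.0:
        return -1.0
    if n_ij == n_i:
        return 1.0
    num = n_ij * N - n_i * N_j
    den = n_ij * N + n_i * N_j - 2.0 * n_ij * N_j
    if den == 0.0:
        raise ValidationError(
            f"degenerate partition: zero denominator for inputs {vals}"
        )
    return num / den


@dataclass
class ConfinementResult:
    """Per-taxon, per-habitat confinement values with the inputs echoed.

    ``fij`` is a taxa x habitats DataFrame; ``key_taxa`` is filled by
    :func:`select_key_species`.
    """

    fij: pd.DataFrame
    n_ij: pd.DataFrame
    n_i: pd.Series
    N_j: pd.Series
    N: float
    key_taxa: dict[str, set[str]] = field(default_factory=dict)

    @property
    def habitats(self) -> list[str]:
        return list(self.fij.columns)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.fij.index)


def confinement_table(
    table: CommunityTable, partition: HabitatPartition
) -> ConfinementResult:
    """Compute F_ij for every taxon over a habitat partition.

    Biomass is pooled (summed) per habitat before applying the index;
    taxa with zero total biomass are omitted.  Habitats with zero total
    biomass are dropped with a warning (the index is undefined there).
    """
    habitats = partition.order
    if len(habitats) < 2:
        raise ValidationError(
            "confinement index requires at least two habitats (otherwise N_j = N)"
        )
    n_ij = pd.DataFrame(
        {hab: table.biomass[list(sids)].sum(axis=1) for hab, sids in partition.groups.items()}
    )[habitats]
    N_j = n_ij.sum(axis=0)
    N = float(N_j.sum())
    if N <= 0:
        raise ValidationError("grand total biomass must be positive")

    empty = [h for h in habitats if N_j[h] <= 0]
    if empty:
        warnings.warn(
            f"habitats {empty} have zero total biomass; confinement undefined there",
            stacklevel=2,
        )
        n_ij = n_ij.drop(columns=empty)
        N_j = N_j.drop(index=empty)
        if n_ij.shape[1] < 2:
            raise ValidationError(
                "fewer than two habitats with positive biomass"
            )

    n_i = n_ij.sum(axis=1)
    keep = n_i > 0
    n_ij = n_ij.loc[keep]
    n_i = n_i.loc[keep]

    nij = n_ij.to_numpy(dtype=float)
    ni = n_i.to_numpy(dtype=float)[:, None]
    Nj = N_j.to_numpy(dtype=float)[None, :]
    num = nij * N - ni * Nj
    den = nij * N + ni * Nj - 2.0 * nij * Nj
    f = num / den
    f[nij == 0.0] = -1.0  # exact endpoints, forced given N_j < N
    f[nij == np.broadcast_to(ni, f.shape)] = 1.0
    fij = pd.DataFrame(f, index=n_ij.index, columns=n_ij.columns)
    return ConfinementResult(fij=fij, n_ij=n_ij, n_i=n_i, N_j=N_j, N=N)


def select_key_species(
    conf: ConfinementResult, dominants: Mapping[str, set[str] | Sequence[str]]
) -> dict[str, set[str]]:
    """Key species per habitat: dominants attaining the maximum positive F_ij.

    Exact ties at the maximum all qualify; if no dominant has a
    positive index the habitat's key set is empty.  The selection is
    stored on ``conf.key_taxa`` and returned.
    """
    keys: dict[str, set[str]] = {}
    for hab in conf.habitats:
        cand = [t for t in dominants.get(hab, ()) if t in conf.fij.index]
        if not cand:
            keys[hab] = set()
            continue
        vals = conf.fij.loc[cand, hab]
        fmax = vals.max()
        keys[hab] = set(vals.index[vals == fmax]) if fmax > 0 else set()
    conf.key_taxa = keys
    return keys


def confinement_report(
    conf: ConfinementResult,
    dominants: Mapping[str, set[str]] | None = None,
    decimals: int = 3,
) -> pd.DataFrame:
    """Tabular export: one row per taxon, one F column per habitat.

    F values are rounded to ``decimals`` (default 3, the conventional
    reporting precision); when ``dominants`` is given, rows are
    restricted to taxa dominant somewhere and an ``is_key`` column
    flags each habitat's key species.
    """
    df = conf.fij.round(decimals).copy()
    df.index.name = "taxon_id"
    if dominants is not None:
        keys = conf.key_taxa or select_key_species(conf, dominants)
        dom_all = sorted(set().union(*dominants.values()) & set(df.index))
        df = df.loc[[t for t in conf.taxon_ids if t in dom_all]]
        for hab in conf.habitats:
            df[f"is_key_{hab}"] = [t in keys.get(hab, set()) for t in df.index]
    return df.reset_index()
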