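"""Dominant-taxon filtering, Ward clustering and PCA ordination.

Community structure is characterised by the dominant taxa only: a
taxon qualifies when its habitat-mean biomass reaches a group-specific
threshold in at least one habitat (10 mg m^-3 for plankton, 10 x 10^3
mg m^-2 for benthic macroalgae, 1 mg m^-2 for benthic microalgae).
The retained taxon x habitat matrix of mean biomass is
log10(x + 1)-transformed, taxa are clustered with Ward linkage on
Euclidean distances into communities (labelled a, b, c, ...), and the
same matrix is ordinated by PCA with habitats as variables, so that
each community's position along the first two components shows which
habitat its taxa are confined to.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .core import CommunityTable, HabitatPartition, ValidationError

__all__ = [
    "DEFAULT_THRESHOLDS",
    "DominanceFilterSpec",
    "DominantSelection",
    "habitat_mean_matrix",
    "filter_dominants",
    "log_transform",
    "CommunityAssignment",
    "ward_communities",
    "OrdinationResult",
    "pca_ordination",
]

# Biomass thresholds below which a taxon is not considered dominant,
# in the group's native units (mg m^-3 for plankton, mg m^-2 for benthos).
DEFAULT_THRESHOLDS: dict[str, float] = {
    "plankton": 10.0,
    "benthic_macroalgae": 10_000.0,
    "benthic_microalgae": 1.0,
}


@dataclass(frozen=True)
class DominanceFilterSpec:
    organism_group: str
    threshold: float

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("dominance threshold must be positive")

    @classmethod
    def for_group(cls, organism_group: str) -> "DominanceFilterSpec":
        try:
            return cls(organism_group, DEFAULT_THRESHOLDS[organism_group])
        except KeyError:
            raise ValidationError(
                f"unknown organism group {organism_group!r}; "
                f"known: {sorted(DEFAULT_THRESHOLDS)}"
            ) from None


def habitat_mean_matrix(
    table: CommunityTable, partition: HabitatPartition
) -> pd.DataFrame:
    """Taxon x habitat matrix of mean biomass over each habitat's samples."""
    return pd.DataFrame(
        {
            hab: table.biomass[list(sids)].mean(axis=1)
            for hab, sids in partition.groups.items()
        }
    )[partition.order]


@dataclass
class DominantSelection:
    """Dominant taxa per habitat plus the reduced mean-biomass matrix."""

    per_habitat: dict[str, set[str]]
    matrix: pd.DataFrame  # retained taxa x habitats, untransformed means

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.matrix.index)


def filter_dominants(
    table: CommunityTable,
    spec: DominanceFilterSpec,
    partition: HabitatPartition,
) -> DominantSelection:
    """Retain taxa whose habitat-mean biomass reaches the threshold somewhere.

    Rows that qualify in one habitat keep their (possibly zero) values
    in all habitats -- those zeros carry the confinement signal.
    """
    means = habitat_mean_matrix(table, partition)
    mask = means >= spec.threshold
    retained = means.index[mask.any(axis=1)]
    if retained.empty:
        raise ValidationError(
            f"no taxon reaches the {spec.organism_group} dominance threshold "
            f"{spec.threshold}; review the threshold or the units"
        )
    per_habitat = {
        hab: set(means.index[mask[hab]]) for hab in means.columns
    }
    return DominantSelection(per_habitat=per_habitat, matrix=means.loc[retained])


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log10(x + 1); requires non-negative entries."""
    vals = matrix.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValidationError("log10(x + 1) transform requires non-negative entries")
    return pd.DataFrame(
        np.log10(vals + 1.0), index=matrix.index, columns=matrix.columns
    )


@dataclass
class CommunityAssignment:
    labels: dict[str, str]  # taxon_id -> community label ('a', 'b', ...)
    linkage: np.ndarray  # scipy condensed linkage record
    n_communities: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"taxon_id": list(self.labels), "community": list(self.labels.values())}
        )


def _letter(i: int) -> str:
    letters = string.ascii_lowercase
    return letters[i] if i < len(letters) else f"c{i + 1}"


def ward_communities(matrix: pd.DataFrame, k: int = 3) -> CommunityAssignment:
    """Agglomerative Ward/Euclidean clustering of taxon rows into k communities.

    Labels are assigned in order of first appearance down the taxon
    list.  Ward linkage on Euclidean distances is monotone, so merge
    heights never decrease.
    """
    n = matrix.shape[0]
    if n < 2:
        raise ValidationError("clustering requires at least two taxa")
    if k > n:
        raise ValidationError(f"cannot cut {n} taxa into k={k} communities")
    if k < 1:
        raise ValidationError("k must be at least 1")
    d = pdist(matrix.to_numpy(dtype=float), metric="euclidean")
    if k > 1 and d.max() == 0.0:
        raise ValidationError(
            "all taxon profiles are identical (zero distances); "
            "only k=1 is meaningful"
        )
    Z = linkage(d, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, str] = {}
    labels: dict[str, str] = {}
    for tid, c in zip(matrix.index, raw):
        if c not in relabel:
            relabel[c] = _letter(len(relabel))
        labels[tid] = relabel[c]
    return CommunityAssignment(labels=labels, linkage=Z, n_communities=k)


@dataclass
class OrdinationResult:
    scores: pd.DataFrame  # taxa x components
    loadings: pd.DataFrame  # habitat variables x components
    explained: np.ndarray  # variance fractions, one per component (sums to 1)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        s = self.scores.copy()
        s.index.name = "taxon_id"
        l = self.loadings.copy()
        l.index.name = "habitat_id"
        l.loc["explained_fraction"] = self.explained
        return s.reset_index(), l.reset_index()


def pca_ordination(matrix: pd.DataFrame) -> OrdinationResult:
    """PCA of taxa over habitat variables (covariance matrix, full rank).

    Columns (habitats) are centred; components are sign-fixed so the
    largest-magnitude loading of each component is positive, making
    the ordination deterministic.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("ordination requires at least two habitat variables")
    if matrix.shape[0] < 3:
        raise ValidationError("ordination requires at least three taxa")
    X = matrix.to_numpy(dtype=float)
    if np.allclose(X - X.mean(axis=0), 0.0):
        raise ValidationError("matrix has no variance (rank 0 after centring)")
    pca = PCA(n_components=min(X.shape), svd_solver="full")
    scores = pca.fit_transform(X)
    comps = pca.components_  # components x variables
    for c in range(comps.shape[0]):
        i = int(np.argmax(np.abs(comps[c])))
        if comps[c, i] < 0:
            comps[c] *= -1.0
            scores[:, c] *= -1.0
    names = [f"PC{i + 1}" for i in range(comps.shape[0])]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=names),
        loadings=pd.DataFrame(comps.T, index=matrix.columns, columns=names),
        explained=pca.explained_variance_ratio_.copy(),
    )
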