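"""End-to-end orchestration: load -> integrate -> filter -> cluster /
ordinate -> confinement -> indicators -> dominance curves -> report.

The pipeline writes deterministic CSV outputs plus a machine-readable
run manifest; identical configs (and seeds) produce byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .confinement import confinement_report, confinement_table, select_key_species
from .core import (
    CommunityTable,
    HabitatPartition,
    TaxonRegistry,
    ValidationError,
    integrate_strata,
)
from .dominance import abc_analysis
from .indicators import build_trophic_report
from .io import read_community_table, read_registry
from .structure import (
    DominanceFilterSpec,
    filter_dominants,
    log_transform,
    pca_ordination,
    ward_communities,
)
from .synthetic import SyntheticScenario, generate_community

__all__ = ["RunConfig", "StageError", "run_pipeline", "summarize_higher_taxa"]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs and knobs of one pipeline run.

    Either the three file paths (``table``, ``registry``, ``samples``)
    or a :class:`SyntheticScenario` must be given.
    """

    out_dir: str | Path
    table: str | Path | None = None
    registry: str | Path | None = None
    samples: str | Path | None = None
    abundance: str | Path | None = None
    scenario: SyntheticScenario | None = None
    organism_group: str = "plankton"
    threshold: float | None = None
    k: int = 3
    shannon_base: float | None = None
    h_weight: str = "occurrence"
    dialect: str = "wide"
    unit_kind: str = "per_volume"
    seed: int = 0

    def to_jsonable(self) -> dict:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, Path):
                v = str(v)
            elif isinstance(v, SyntheticScenario):
                v = dataclasses.asdict(v)
            d[f.name] = v
        return d


def summarize_higher_taxa(
    table: CommunityTable,
    registry: TaxonRegistry | None,
    partition: HabitatPartition,
) -> pd.DataFrame:
    """Percentage of total biomass per higher group, per habitat.

    Rows are higher groups, columns habitats; each column sums to 100.
    """
    groups = []
    for t in table.taxa:
        info = registry.get(t.taxon_id) if registry is not None and t.taxon_id in registry else t
        groups.append(info.higher_group or "unassigned")
    out = {}
    for hab, sids in partition.groups.items():
        pooled = table.biomass[list(sids)].sum(axis=1)
        total = float(pooled.sum())
        if total <= 0:
            raise ValidationError(f"habitat {hab!r} has zero total biomass")
        out[hab] = pooled.groupby(pd.Index(groups, name="higher_group")).sum() / total * 100.0
    return pd.DataFrame(out)[partition.order].fillna(0.0)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise StageError(name, exc) from exc

        return wrapped

    return deco


def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        table, registry, partition, _truth = generate_community(
            config.scenario, seed=config.seed
        )
        return table, registry, partition
    if config.table is None:
        raise ValidationError("config needs either input paths or a scenario")
    registry = read_registry(config.registry) if config.registry else None
    table = read_community_table(
        config.table,
        dialect=config.dialect,
        sample_sheet=config.samples,
        registry=registry,
        abundance_path=config.abundance,
        unit_kind=config.unit_kind,
    )
    return table, registry, HabitatPartition.from_samples(table.samples)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    stages: list[str] = []

    def write_csv(df: pd.DataFrame, name: str, **kw) -> None:
        df.to_csv(out_dir / name, **kw)
        written.append(name)

    table, registry, partition = _stage("load")(_load_inputs)(config)
    stages.append("load")

    if any(s.stratum is not None for s in table.samples):
        table = _stage("integrate_strata")(integrate_strata)(table)
        partition = HabitatPartition.from_samples(table.samples)
        stages.append("integrate_strata")

    fspec = (
        DominanceFilterSpec(config.organism_group, config.threshold)
        if config.threshold is not None
        else DominanceFilterSpec.for_group(config.organism_group)
    )
    selection = _stage("filter_dominants")(filter_dominants)(table, fspec, partition)
    stages.append("filter_dominants")

    transformed = log_transform(selection.matrix)
    assignment = _stage("ward_communities")(ward_communities)(transformed, k=config.k)
    stages.append("ward_communities")
    comm = assignment.to_frame()
    comm["habitat_of_max_biomass"] = [
        selection.matrix.loc[t].idxmax() for t in comm["taxon_id"]
    ]
    write_csv(comm, "communities.csv", index=False)

    ordination = _stage("pca_ordination")(pca_ordination)(transformed)
    stages.append("pca_ordination")
    scores, loadings = ordination.to_frames()
    write_csv(scores, "ordination_scores.csv", index=False)
    write_csv(loadings, "ordination_loadings.csv", index=False)

    conf = _stage("confinement")(confinement_table)(table, partition)
    select_key_species(conf, selection.per_habitat)
    stages.append("confinement")
    write_csv(
        confinement_report(conf, selection.per_habitat), "confinement.csv", index=False
    )
    write_csv(conf.fij.rename_axis("taxon_id").reset_index(), "confinement_raw.csv", index=False)

    report = _stage("indicators")(build_trophic_report)(
        table,
        registry,
        partition,
        shannon_base=config.shannon_base,
        h_weight=config.h_weight,
    )
    stages.append("indicators")
    write_csv(report.to_frame(), "indicators.csv", index=False)

    if table.abundance is not None:
        curves = _stage("dominance_curves")(abc_analysis)(table, partition)
        stages.append("dominance_curves")
        frames = []
        summary = []
        for hab, cs in curves.items():
            df = cs.to_frame()
            df.insert(0, "habitat_id", hab)
            frames.append(df)
            summary.append(
                {
                    "habitat_id": hab,
                    "classification": cs.classification.value,
                    "crossing_ranks": ";".join(map(str, cs.crossing_ranks)),
                }
            )
        write_csv(pd.concat(frames, ignore_index=True), "dominance_curves.csv", index=False)
        write_csv(pd.DataFrame(summary), "dominance_summary.csv", index=False)

    ht = _stage("higher_taxa")(summarize_higher_taxa)(table, registry, partition)
    stages.append("higher_taxa")
    write_csv(ht.rename_axis("higher_group").reset_index(), "higher_taxa.csv", index=False)

    cfg = config.to_jsonable()
    manifest = {
        "package": "littoral",
        "version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "stages_completed": stages,
        "outputs": sorted(written),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
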