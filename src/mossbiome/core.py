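"""Prevalence-threshold core microbiomes and their intersections.

A core set at threshold t over a sample scope contains every OTU present
(nonzero count) in at least ``floor(t * n_scope)`` scoped samples,
optionally required to be present in at least one sample of every group
of a partition (e.g. both peatland systems). Presets wire the standard
profiles: a total core at 66% with the both-systems constraint, per-system
cores at 66%, and per-moss-species cores at the stricter 75%.

At 66% of 122 samples the minimum prevalence count is floor(0.66*122)=80.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community_data import OtuTable, relative_abundance

__all__ = [
    "CoreResult",
    "prevalence",
    "min_prevalence_count",
    "core_set",
    "core_intersection",
    "core_profiles",
]


@dataclass
class CoreResult:
    """A core OTU set with threshold provenance and abundance contributions.

    ``contribution`` maps group label -> (min%, max%) of the per-sample
    summed relative abundance of the core OTUs within that group.
    """

    name: str
    core_otu_ids: tuple[str, ...]
    threshold: float
    min_count: int
    n_scope_samples: int
    sample_scope: tuple[str, ...]
    group_constraint: str | None = None
    contribution: dict[str, tuple[float, float]] = field(default_factory=dict)
    otu_universe: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.core_otu_ids)


def prevalence(table: OtuTable, scope=None) -> pd.Series:
    """Per-OTU presence count (nonzero samples) over a sample scope."""
    if scope is None:
        scope = table.sample_ids
    scope = list(scope)
    if not scope:
        raise ValueError("empty sample scope")
    idx = [table.sample_index(s) for s in scope]
    counts = (table.counts[:, idx] > 0).sum(axis=1)
    return pd.Series(counts, index=list(table.otu_ids), name="prevalence")


def min_prevalence_count(n_samples: int, threshold: float) -> int:
    """Samples an OTU must occupy to meet a prevalence threshold.

    ``floor(threshold * n_samples)``, so 66% of 122 samples requires
    presence in 80 of them.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    return math.floor(threshold * n_samples)


def core_set(
    table: OtuTable,
    scope=None,
    threshold: float = 0.66,
    require_presence_in_groups: dict[str, list[str]] | None = None,
    name: str = "core",
) -> CoreResult:
    """Core OTU set over a sample scope at a prevalence threshold.

    ``require_presence_in_groups`` maps group label -> sample ids; a core
    OTU must additionally be present in at least one sample of every
    group. Contributions (min-max % of per-sample summed relative
    abundance of core OTUs) are computed per constraint group, or over the
    whole scope when no grouping is given.
    """
    if scope is None:
        scope = list(table.sample_ids)
    scope = list(scope)
    if not scope:
        raise ValueError("empty sample scope")
    prev = prevalence(table, scope)
    need = min_prevalence_count(len(scope), threshold)
    member = prev >= need
    if require_presence_in_groups:
        for gname, gsamples in require_presence_in_groups.items():
            if not gsamples:
                raise ValueError(f"group {gname!r} has no samples")
            gprev = prevalence(table, gsamples)
            member &= gprev >= 1
    core_ids = tuple(o for o in table.otu_ids if member[o])
    groups = require_presence_in_groups or {"scope": scope}
    contribution = {}
    if core_ids:
        pos = {o: i for i, o in enumerate(table.otu_ids)}
        core_idx = [pos[o] for o in core_ids]
        for gname, gsamples in groups.items():
            sub = table.select_samples(gsamples)
            rel = relative_abundance(sub).values
            sums = rel[core_idx, :].sum(axis=0) * 100.0
            contribution[gname] = (float(sums.min()), float(sums.max()))
    return CoreResult(
        name=name,
        core_otu_ids=core_ids,
        threshold=threshold,
        min_count=need,
        n_scope_samples=len(scope),
        sample_scope=tuple(scope),
        group_constraint=(
            ",".join(require_presence_in_groups) if require_presence_in_groups else None
        ),
        contribution=contribution,
        otu_universe=frozenset(table.otu_ids),
    )


def core_intersection(a: CoreResult, b: CoreResult) -> dict:
    """Shared OTUs between two core sets built on the same OTU universe."""
    if a.otu_universe and b.otu_universe and not (a.otu_universe & b.otu_universe):
        raise ValueError(
            f"cores {a.name!r} and {b.name!r} come from disjoint OTU universes"
        )
    sa, sb = set(a.core_otu_ids), set(b.core_otu_ids)
    shared = tuple(sorted(sa & sb))
    return {
        "a": a.name,
        "b": b.name,
        "n_a": len(sa),
        "n_b": len(sb),
        "n_shared": len(shared),
        "shared_otu_ids": shared,
    }


def core_profiles(
    preset: str,
    table: OtuTable,
    metadata: pd.DataFrame,
    total_threshold: float = 0.66,
    species_threshold: float = 0.75,
    moss_only: bool = False,
) -> list[CoreResult]:
    """Standard core-microbiome profiles.

    ``total``: one core over all samples (or moss samples only with
    ``moss_only=True``) at 66%, constrained to presence in both systems.
    ``per_system``: a 66% core over each system's samples.
    ``per_species``: a 75% core over each moss species' samples (species
    with fewer than 2 samples are skipped with a warning).
    """
    md = metadata.loc[list(table.sample_ids)]
    if preset == "total":
        scope = (
            list(md.index[md["sample_class"] == "moss"]) if moss_only else list(md.index)
        )
        groups = {
            sys: list(md.index[(md["system"] == sys) & md.index.isin(scope)])
            for sys in sorted(md["system"].unique())
        }
        return [
            core_set(
                table,
                scope,
                total_threshold,
                require_presence_in_groups=groups,
                name="total_core",
            )
        ]
    if preset == "per_system":
        out = []
        for sys in sorted(md["system"].unique()):
            scope = list(md.index[md["system"] == sys])
            out.append(core_set(table, scope, total_threshold, name=f"{sys}_core"))
        return out
    if preset == "per_species":
        out = []
        moss = md[md["sample_class"] == "moss"]
        for sp in sorted(moss["plant_label"].unique()):
            scope = list(moss.index[moss["plant_label"] == sp])
            if len(scope) < 2:
                warnings.warn(f"species {sp!r} has <2 samples; skipped")
                continue
            out.append(core_set(table, scope, species_threshold, name=f"{sp}_core"))
        return out
    raise ValueError(f"unknown preset: {preset!r}")
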