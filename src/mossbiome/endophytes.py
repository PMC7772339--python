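"""Paired endophyte-vs-epiphyte OTU screening with Monte-Carlo chi-square.

Every moss plant contributes two endophyte technical-replicate libraries
(pooled by summation) and one epiphyte library. For each OTU and plant
unit a 2x2 contingency table — rows endo/epi, columns this-OTU/all-other
OTUs — is tested with the Pearson chi-square statistic whose p-value is
estimated by Monte-Carlo sampling of tables with both margins fixed
(conditional null). An OTU qualifies for reporting when it is
significantly *more* abundant in the endophyte fraction (p below alpha
and endo relative abundance above epi) in at least one plant unit, and
its endo-mean relative abundance exceeds a floor (default 0.5%) in at
least a minimum number of plant units (default 4).

For a 2x2 table the fixed-margins null is the central hypergeometric
distribution, which is what the sampler draws from; larger tables fall
back to Patefield sampling via scipy. The test-suite checks the
Monte-Carlo p against exact conditional enumeration on small tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import agnes, cor_to_dissimilarity, correlation_matrix

__all__ = [
    "EndophyteCall",
    "UnitTest",
    "build_contingency",
    "monte_carlo_chisq",
    "classify_endophytes",
    "heatmap_matrix",
]


@dataclass
class UnitTest:
    """One OTU x plant-unit contingency test."""

    plant_unit: str
    p_value: float
    direction: str  # endo_higher | epi_higher | tie
    endo_mean_relabund: float
    epi_relabund: float
    testable: bool = True


@dataclass
class EndophyteCall:
    """Screening record for one OTU across all plant units."""

    otu_id: str
    unit_tests: list[UnitTest] = field(default_factory=list)
    n_significant_endo_higher: int = 0
    n_samples_above_abundance: int = 0
    qualifies: bool = False


def _pair_units(metadata: pd.DataFrame) -> dict[str, tuple[list[str], list[str]]]:
    """plant_unit -> (endo sample ids, epi sample ids)."""
    md = metadata[metadata["fraction"].isin(["endophyte", "epiphyte"])]
    units: dict[str, tuple[list[str], list[str]]] = {}
    for unit, grp in md.groupby("plant_unit"):
        if not unit:
            continue
        endo = list(grp.index[grp["fraction"] == "endophyte"])
        epi = list(grp.index[grp["fraction"] == "epiphyte"])
        if endo and epi:
            units[unit] = (endo, epi)
    return units


def build_contingency(table, metadata: pd.DataFrame, plant_unit: str, otu_id: str) -> np.ndarray:
    """2x2 table [[endo_otu, endo_rest], [epi_otu, epi_rest]] for one unit.

    The endophyte technical replicates are summed; the epiphyte row is the
    single wash-off library.
    """
    units = _pair_units(metadata.loc[list(table.sample_ids)])
    if plant_unit not in units:
        raise ValueError(f"plant unit {plant_unit!r} lacks paired endo/epi libraries")
    endo, epi = units[plant_unit]
    oi = list(table.otu_ids).index(otu_id)
    e_idx = [table.sample_index(s) for s in endo]
    p_idx = [table.sample_index(s) for s in epi]
    endo_otu = int(table.counts[oi, e_idx].sum())
    endo_tot = int(table.counts[:, e_idx].sum())
    epi_otu = int(table.counts[oi, p_idx].sum())
    epi_tot = int(table.counts[:, p_idx].sum())
    return np.array(
        [[endo_otu, endo_tot - endo_otu], [epi_otu, epi_tot - epi_otu]], dtype=np.int64
    )


def _pearson_x2(obs: np.ndarray) -> float:
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (obs - expected) ** 2 / expected
    return float(np.nansum(terms))


def monte_carlo_chisq(
    table2x2, n_rep: int = 5000, seed=None, rng: np.random.Generator | None = None
) -> tuple[float, float]:
    """Pearson X^2 with a Monte-Carlo conditional p-value.

    Null replicates fix both margins; ``p = (1 + #{X2* >= X2}) / (n_rep + 1)``.
    A zero row or column margin leaves X^2 undefined: such tables are
    untestable and return ``(0.0, 1.0)`` by convention.
    """
    obs = np.asarray(table2x2, dtype=np.int64)
    if (obs < 0).any():
        raise ValueError("contingency counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return 0.0, 1.0
    x2 = _pearson_x2(obs)
    if rng is None:
        rng = np.random.default_rng(seed)
    if obs.shape == (2, 2):
        # both-margins-fixed null for a 2x2 table == central hypergeometric
        n_total = int(obs.sum())
        a = rng.hypergeometric(cols[0], cols[1], rows[0], size=n_rep)
        sim = np.column_stack([a, rows[0] - a, cols[0] - a, cols[1] - rows[0] + a])
        expected = np.outer(rows, cols).ravel() / n_total
        x2_sim = ((sim - expected) ** 2 / expected).sum(axis=1)
    else:
        rt = stats.random_table(rows, cols)
        sims = rt.rvs(n_rep, random_state=rng)
        expected = np.outer(rows, cols) / obs.sum()
        x2_sim = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
    hits = int(np.sum(x2_sim >= x2 - 1e-12))
    p = (1 + hits) / (n_rep + 1)
    return x2, p


def classify_endophytes(
    table,
    metadata: pd.DataFrame,
    alpha: float = 0.001,
    min_relabund: float = 0.005,
    min_samples: int = 4,
    n_rep: int = 5000,
    seed=None,
    min_significant_units: int = 1,
    test_all: bool = False,
    pooled: bool = False,
) -> list[EndophyteCall]:
    """Screen every OTU for endophyte enrichment across paired plant units.

    Direction compares the endo-mean relative abundance (average of the
    technical replicates' per-library proportions) with the epiphyte
    library's proportion. Qualification requires ``endo_higher`` with
    ``p < alpha`` in at least ``min_significant_units`` units AND
    endo-mean relative abundance above ``min_relabund`` in at least
    ``min_samples`` units. Only OTUs that can meet the abundance filter
    are tested unless ``test_all=True`` (the skipped OTUs cannot qualify
    regardless of their p-values). With ``pooled=True`` a single 2x2 table
    summed over all units is tested per OTU instead.
    """
    md = metadata.loc[list(table.sample_ids)]
    units = _pair_units(md)
    if not units:
        raise ValueError("no plant units with paired endo/epi libraries")
    rng = np.random.default_rng(seed)
    unit_names = sorted(units)
    counts = table.counts
    totals = counts.sum(axis=0).astype(float)
    sidx = {s: j for j, s in enumerate(table.sample_ids)}

    # per-unit index arrays and per-unit relative abundances
    endo_rel = np.zeros((table.n_otus, len(unit_names)))
    epi_rel = np.zeros_like(endo_rel)
    unit_endo_idx, unit_epi_idx = [], []
    for u, unit in enumerate(unit_names):
        endo, epi = units[unit]
        ei = [sidx[s] for s in endo]
        pi = [sidx[s] for s in epi]
        unit_endo_idx.append(ei)
        unit_epi_idx.append(pi)
        endo_rel[:, u] = (counts[:, ei] / totals[ei]).mean(axis=1)
        epi_rel[:, u] = (counts[:, pi] / totals[pi]).mean(axis=1)

    n_above = (endo_rel > min_relabund).sum(axis=1)
    candidates = np.arange(table.n_otus)
    if not test_all:
        candidates = candidates[n_above >= min_samples]

    calls: list[EndophyteCall] = []
    for oi in candidates:
        otu = table.otu_ids[oi]
        call = EndophyteCall(otu_id=otu, n_samples_above_abundance=int(n_above[oi]))
        if pooled:
            tables = [
                sum(
                    (
                        _unit_table(counts, oi, unit_endo_idx[u], unit_epi_idx[u])
                        for u in range(len(unit_names))
                    ),
                    start=np.zeros((2, 2), dtype=np.int64),
                )
            ]
            tested_units = ["pooled"]
            e_rel = [float(endo_rel[oi].mean())]
            p_rel = [float(epi_rel[oi].mean())]
        else:
            tables = [
                _unit_table(counts, oi, unit_endo_idx[u], unit_epi_idx[u])
                for u in range(len(unit_names))
            ]
            tested_units = unit_names
            e_rel = endo_rel[oi]
            p_rel = epi_rel[oi]
        for u, tab in enumerate(tables):
            testable = tab[0].sum() > 0 and tab[1].sum() > 0 and tab[:, 0].sum() > 0 and tab[:, 1].sum() > 0
            x2, p = monte_carlo_chisq(tab, n_rep=n_rep, rng=rng)
            if e_rel[u] > p_rel[u]:
                direction = "endo_higher"
            elif e_rel[u] < p_rel[u]:
                direction = "epi_higher"
            else:
                direction = "tie"
            call.unit_tests.append(
                UnitTest(
                    plant_unit=tested_units[u],
                    p_value=p,
                    direction=direction,
                    endo_mean_relabund=float(e_rel[u]),
                    epi_relabund=float(p_rel[u]),
                    testable=bool(testable),
                )
            )
        call.n_significant_endo_higher = sum(
            1
            for t in call.unit_tests
            if t.testable and t.direction == "endo_higher" and t.p_value < alpha
        )
        call.qualifies = (
            call.n_significant_endo_higher >= min_significant_units
            and call.n_samples_above_abundance >= min_samples
        )
        calls.append(call)
    return calls


def _unit_table(counts, oi, e_idx, p_idx) -> np.ndarray:
    endo_otu = int(counts[oi, e_idx].sum())
    endo_tot = int(counts[:, e_idx].sum())
    epi_otu = int(counts[oi, p_idx].sum())
    epi_tot = int(counts[:, p_idx].sum())
    return np.array(
        [[endo_otu, endo_tot - endo_otu], [epi_otu, epi_tot - epi_otu]], dtype=np.int64
    )


def heatmap_matrix(
    calls: list[EndophyteCall],
    floor: float | None = None,
) -> dict:
    """log2(endo-mean relabund x 100000) matrix of qualifying OTUs with
    Pearson-correlation dendrograms over rows (OTUs) and columns (units).

    Zero abundances are floored (default: half the smallest nonzero
    relative abundance) before the log.
    """
    qual = [c for c in calls if c.qualifies]
    if not qual:
        raise ValueError("no qualifying OTUs to plot")
    unit_names = [t.plant_unit for t in qual[0].unit_tests]
    M = np.array([[t.endo_mean_relabund for t in c.unit_tests] for c in qual])
    nz = M[M > 0]
    if floor is None:
        floor = float(nz.min()) / 2.0 if nz.size else 1e-6
    vals = np.log2(np.maximum(M, floor) * 100_000.0)
    frame = pd.DataFrame(vals, index=[c.otu_id for c in qual], columns=unit_names)
    row_dend = col_dend = None
    if frame.shape[0] >= 2 and frame.shape[1] >= 2:
        try:
            rc = correlation_matrix(
                frame.to_numpy().T, method="pearson", sample_ids=list(frame.index)
            )
            row_dend = agnes(cor_to_dissimilarity(rc), leaf_labels=list(frame.index))
        except ValueError:  # a constant profile leaves no defined correlation
            row_dend = None
        try:
            cc = correlation_matrix(frame.to_numpy(), method="pearson", sample_ids=unit_names)
            col_dend = agnes(cor_to_dissimilarity(cc), leaf_labels=unit_names)
        except ValueError:
            col_dend = None
    return {"matrix": frame, "row_dendrogram": row_dend, "col_dendrogram": col_dend, "floor": floor}
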