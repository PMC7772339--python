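import numpy as np
import pandas as pd
import pytest

from mossbiome.community_data import OtuTable, filter_rare
from mossbiome.synthetic import StudyConfig, generate_study


@pytest.fixture
def small_table() -> OtuTable:
    """5 OTUs x 4 samples, hand-checkable counts."""
    counts = np.array(
        [
            [10, 0, 3, 1],
            [5, 5, 5, 5],
            [0, 20, 1, 0],
            [2, 2, 6, 0],
            [1, 1, 1, 14],
        ]
    )
    tax = [
        "k__Bacteria; p__Proteobacteria; f__Acetobacteraceae",
        "k__Bacteria; p__Acidobacteria; f__Acidobacteriaceae",
        "k__Bacteria; p__Cyanobacteria; c__Chloroplast; f__",
        "k__Archaea; p__Euryarchaeota; f__Methanobacteriaceae",
        "k__Bacteria; p__Proteobacteria; f__Methylocystaceae",
    ]
    return OtuTable(
        otu_ids=tuple(f"OTU{i}" for i in range(5)),
        sample_ids=("s1", "s2", "s3", "s4"),
        counts=counts,
        taxonomy=tuple(tax),
    )


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study, rare-filtered, shared across tests."""
    table, metadata, truth = generate_study(StudyConfig(seed=11))
    filtered, _ = filter_rare(table)
    return filtered, metadata.loc[list(filtered.sample_ids)], truth


@pytest.fixture(scope="session")
def small_study():
    """A reduced-size study for expensive end-to-end checks."""
    cfg = StudyConfig(
        seed=7,
        n_otus_total=300,
        n_core_shared=20,
        n_system_specific_per_system=50,
        n_endophyte_enriched=10,
        n_subsites_per_area=2,
        n_plants_per_subsite=2,
    )
    table, metadata, truth = generate_study(cfg)
    return table, metadata, truth, cfg


def random_count_table(rng, n_otus, n_samples, high=50):
    """Random dense count matrix with positive row/column sums."""
    while True:
        Y = rng.integers(0, high, size=(n_otus, n_samples))
        if (Y.sum(axis=0) > 0).all() and (Y.sum(axis=1) > 0).all():
            return Y
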