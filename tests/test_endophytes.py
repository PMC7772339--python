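import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from mossbiome.community_data import OtuTable
from mossbiome.endophytes import (
    _pearson_x2,
    build_contingency,
    classify_endophytes,
    heatmap_matrix,
    monte_carlo_chisq,
)


def _paired_table():
    """Two plant units; OTU 'enriched' is pushed up in endo libraries."""
    counts = np.array(
        [
            [30, 32, 4, 28, 30, 3],   # enriched
            [40, 38, 48, 40, 42, 50],
            [30, 30, 48, 32, 28, 47],
        ]
    )
    sample_ids = ("u1_e1", "u1_e2", "u1_epi", "u2_e1", "u2_e2", "u2_epi")
    table = OtuTable(
        ("enriched", "bg1", "bg2"), sample_ids, counts, ("k",) * 3
    )
    md = pd.DataFrame(
        {
            "fraction": ["endophyte", "endophyte", "epiphyte"] * 2,
            "plant_unit": ["u1"] * 3 + ["u2"] * 3,
            "sample_class": ["moss"] * 6,
            "system": ["sph"] * 6,
        },
        index=list(sample_ids),
    )
    return table, md


def test_build_contingency_bookkeeping():
    counts = np.zeros((2, 3), dtype=int)
    counts[0] = [3, 2, 1]       # OTU of interest
    counts[1] = [97, 98, 99]    # everything else
    t = OtuTable(("otu", "rest"), ("e1", "e2", "epi"), counts, ("k", "k"))
    md = pd.DataFrame(
        {
            "fraction": ["endophyte", "endophyte", "epiphyte"],
            "plant_unit": ["u"] * 3,
            "sample_class": ["moss"] * 3,
        },
        index=["e1", "e2", "epi"],
    )
    tab = build_contingency(t, md, "u", "otu")
    np.testing.assert_array_equal(tab, [[5, 195], [1, 99]])
    # marginals conserve the library totals
    assert tab[0].sum() == 200 and tab[1].sum() == 100


def test_build_contingency_unknown_unit():
    t, md = _paired_table()
    with pytest.raises(ValueError, match="nope"):
        build_contingency(t, md, "nope", "enriched")


def test_monte_carlo_chisq_identical_rows():
    x2, p = monte_carlo_chisq(np.array([[10, 90], [10, 90]]), n_rep=500, seed=0)
    assert x2 == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_monte_carlo_chisq_matches_exact_conditional():
    """For [[3,0],[0,3]] the exact conditional p is P(X2 >= 6) = 2/20."""
    obs = np.array([[3, 0], [0, 3]])
    x2, p = monte_carlo_chisq(obs, n_rep=5000, seed=1)
    p_exact = 2 / 20
    se = np.sqrt(p_exact * (1 - p_exact) / 5000)
    assert abs(p - p_exact) <= 3 * se + 2 / 5001


def test_monte_carlo_chisq_p_floor_and_zero_margin():
    x2, p = monte_carlo_chisq(np.array([[50, 0], [0, 50]]), n_rep=200, seed=0)
    assert p >= 1 / 201
    x2, p = monte_carlo_chisq(np.array([[0, 5], [0, 7]]), n_rep=100, seed=0)
    assert (x2, p) == (0.0, 1.0)


def test_monte_carlo_chisq_rxc_path():
    obs = np.array([[10, 2, 3], [2, 11, 4]])
    x2, p = monte_carlo_chisq(obs, n_rep=2000, seed=3)
    from scipy.stats import chi2_contingency

    ref = chi2_contingency(obs, correction=False)
    assert x2 == pytest.approx(ref.statistic)
    assert abs(p - ref.pvalue) < 0.05  # asymptotic vs conditional MC


def test_classify_detects_planted_enrichment():
    t, md = _paired_table()
    calls = classify_endophytes(
        t, md, alpha=0.05, min_relabund=0.005, min_samples=2, n_rep=999, seed=0
    )
    by_id = {c.otu_id: c for c in calls}
    assert by_id["enriched"].qualifies
    assert by_id["enriched"].n_significant_endo_higher >= 1
    for bg in ("bg1", "bg2"):
        assert not by_id[bg].qualifies


def test_classify_abundance_filter_blocks_reporting():
    t, md = _paired_table()
    # min_samples=3 cannot be met with only 2 plant units
    calls = classify_endophytes(
        t, md, alpha=0.05, min_relabund=0.005, min_samples=3, n_rep=499, seed=0
    )
    assert all(not c.qualifies for c in calls)


def test_classify_deterministic_under_seed():
    t, md = _paired_table()
    kw = dict(alpha=0.05, min_relabund=0.005, min_samples=2, n_rep=499, seed=42)
    a = classify_endophytes(t, md, **kw)
    b = classify_endophytes(t, md, **kw)
    assert [(c.otu_id, c.qualifies) for c in a] == [(c.otu_id, c.qualifies) for c in b]
    pa = [t_.p_value for c in a for t_ in c.unit_tests]
    pb = [t_.p_value for c in b for t_ in c.unit_tests]
    assert pa == pb


def test_classify_requires_paired_units():
    t, md = _paired_table()
    md2 = md.copy()
    md2["fraction"] = "reference"
    md2["plant_unit"] = ""
    with pytest.raises(ValueError):
        classify_endophytes(t, md2, seed=0)


def test_heatmap_matrix_values_and_shape():
    t, md = _paired_table()
    calls = classify_endophytes(
        t, md, alpha=0.05, min_relabund=0.005, min_samples=2, n_rep=999, seed=0
    )
    hm = heatmap_matrix(calls)
    qual = [c for c in calls if c.qualifies]
    assert hm["matrix"].shape == (len(qual), 2)
    # entries are log2(relabund * 1e5)
    c0 = qual[0]
    expect = np.log2(max(c0.unit_tests[0].endo_mean_relabund, hm["floor"]) * 1e5)
    assert hm["matrix"].iloc[0, 0] == pytest.approx(expect)


def test_heatmap_log_scale_reference_points():
    assert np.log2(0.001 * 1e5) == pytest.approx(6.6439, abs=1e-4)
    assert np.log2((1 / 100000) * 1e5) == pytest.approx(0.0)


def test_heatmap_empty_calls_rejected():
    with pytest.raises(ValueError):
        heatmap_matrix([])


def test_pooled_replicates_preserve_direction():
    """Summing consistent technical replicates never flips the endo/epi
    direction."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        e1, e2 = rng.integers(1, 50, size=2)
        tot1, tot2 = rng.integers(500, 1000, size=2)
        # replicate-consistent: both replicates on the same side of epi
        epi, epitot = rng.integers(1, 50), rng.integers(500, 1000)
        r1, r2, re = e1 / tot1, e2 / tot2, epi / epitot
        if (r1 - re) * (r2 - re) <= 0:
            continue
        pooled_side = np.sign((e1 + e2) / (tot1 + tot2) - re)
        mean_side = np.sign((r1 + r2) / 2 - re)
        assert pooled_side == mean_side
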