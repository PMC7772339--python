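import numpy as np
import pandas as pd
import pytest
from scipy.linalg import eigh

from mossbiome.ordination import (
    CollinearityError,
    ca,
    cca,
    permutation_test,
    prepare_constraints,
    variance_partition,
    vif,
)
from .conftest import random_count_table


# ---------------------------------------------------------------------------
# CA
# ---------------------------------------------------------------------------

def test_ca_diagonal_two_by_two():
    # chi-square of [[10,0],[0,10]] is 20; total inertia = 20/20 = 1
    r = ca(np.array([[10, 0], [0, 10]]))
    assert r.total_inertia == pytest.approx(1.0)


def test_ca_rank_one_table_zero_inertia():
    rows = np.array([1.0, 2.0, 3.0])
    cols = np.array([4.0, 5.0])
    Y = np.outer(rows, cols)
    assert ca(Y).total_inertia == pytest.approx(0.0, abs=1e-12)


def test_ca_inertia_equals_chisq_over_n():
    rng = np.random.default_rng(21)
    for _ in range(5):
        Y = random_count_table(rng, 5, 4).astype(float)
        N = Y.sum()
        exp = np.outer(Y.sum(axis=1), Y.sum(axis=0)) / N
        chi2 = ((Y - exp) ** 2 / exp).sum()
        assert ca(Y).total_inertia == pytest.approx(chi2 / N, rel=1e-10)


def test_ca_rejects_empty_row():
    with pytest.raises(ValueError):
        ca(np.array([[0, 0], [1, 2]]))


# ---------------------------------------------------------------------------
# CCA and the generalized-eigenproblem oracle
# ---------------------------------------------------------------------------

def _cca_eigs_oracle(Y_sites_by_species, X):
    """Constrained eigenvalues from the generalized eigenproblem
    eig(Xw' Q Q' Xw, Xw' Xw) — an independent formulation of the same fit."""
    Y = np.asarray(Y_sites_by_species, dtype=float)
    N = Y.sum()
    P = Y / N
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    Xc = X - r @ X
    Xw = Xc * np.sqrt(r)[:, None]
    G = Xw.T @ Q @ Q.T @ Xw
    S = Xw.T @ Xw
    vals = eigh(G, S, eigvals_only=True)
    vals = np.sort(vals)[::-1]
    return vals[vals > 1e-10]


def test_cca_matches_generalized_eigen_oracle():
    rng = np.random.default_rng(3)
    for _ in range(8):
        Y = random_count_table(rng, 6, 10)  # OTUs x samples
        X = rng.normal(size=(10, 2))
        fit = cca(Y, X)
        oracle = _cca_eigs_oracle(Y.T, X)
        np.testing.assert_allclose(fit.constrained_eigenvalues, oracle, atol=1e-8)
        assert fit.constrained_inertia == pytest.approx(oracle.sum(), abs=1e-8)


def test_cca_binary_constraint_matches_oracle():
    rng = np.random.default_rng(8)
    Y = random_count_table(rng, 6, 10)
    x = (rng.random(10) < 0.5).astype(float).reshape(-1, 1)
    if x.std() == 0:
        x[0, 0] = 1 - x[0, 0]
    fit = cca(Y, x)
    oracle = _cca_eigs_oracle(Y.T, x)
    np.testing.assert_allclose(fit.constrained_eigenvalues, oracle, atol=1e-8)


def test_cca_agrees_with_vegan_on_fixture():
    """Cross-check against the reference constrained-ordination
    implementation in R (vegan) on a small fixed table."""
    import json
    import subprocess
    import tempfile
    from pathlib import Path

    rng = np.random.default_rng(42)
    Y = random_count_table(rng, 5, 8)  # OTUs x samples
    X = rng.normal(size=(8, 2))
    with tempfile.TemporaryDirectory() as td:
        td = Path(td)
        np.savetxt(td / "Y.csv", Y.T, delimiter=",", fmt="%d")
        np.savetxt(td / "X.csv", X, delimiter=",")
        script = (
            'suppressMessages(library(vegan));'
            f'Y <- as.matrix(read.csv("{td}/Y.csv", header=FALSE));'
            f'X <- as.matrix(read.csv("{td}/X.csv", header=FALSE));'
            "m <- cca(Y ~ X);"
            "cat(jsonlite::toJSON(list(tot=m$tot.chi, eig=as.numeric(m$CCA$eig)), digits=12))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ref = json.loads(out.stdout)
    fit = cca(Y, X)
    assert fit.total_inertia == pytest.approx(ref["tot"][0], rel=1e-4)
    np.testing.assert_allclose(fit.constrained_eigenvalues, ref["eig"], rtol=1e-4)


def test_saturated_constraints_recover_ca():
    rng = np.random.default_rng(13)
    Y = random_count_table(rng, 7, 5)
    X = np.eye(5)  # sample identity indicators
    with pytest.raises(CollinearityError):
        cca(Y, X)  # one indicator is redundant after centering
    fit = cca(Y, X, drop_aliased=True)
    assert fit.constrained_inertia == pytest.approx(fit.total_inertia, abs=1e-10)
    assert fit.residual_inertia == pytest.approx(0.0, abs=1e-10)
    np.testing.assert_allclose(
        fit.constrained_eigenvalues, ca(Y).unconstrained_eigenvalues, atol=1e-8
    )


def test_constant_constraint_rejected():
    rng = np.random.default_rng(1)
    Y = random_count_table(rng, 5, 6)
    with pytest.raises((CollinearityError, ValueError)):
        cca(Y, np.ones((6, 1)))


def test_inertia_decomposition_identity_partial_cca():
    rng = np.random.default_rng(77)
    Y = random_count_table(rng, 8, 12)
    X = rng.normal(size=(12, 2))
    Z = rng.normal(size=(12, 1))
    fit = cca(Y, X, Z)
    total = fit.conditioned_inertia + fit.constrained_inertia + fit.residual_inertia
    assert total == pytest.approx(fit.total_inertia, rel=1e-10)
    assert fit.constrained_inertia == pytest.approx(
        fit.constrained_eigenvalues.sum(), rel=1e-10
    )
    assert (np.diff(fit.constrained_eigenvalues) <= 1e-12).all()
    assert (np.diff(fit.unconstrained_eigenvalues) <= 1e-12).all()


# ---------------------------------------------------------------------------
# constraint preparation / VIF
# ---------------------------------------------------------------------------

def _toy_metadata():
    return pd.DataFrame(
        {
            "ph": [4.0, 5.0, 6.0, 7.0, 5.5, np.nan],
            "mostly_missing": [1.0, np.nan, np.nan, 2.0, np.nan, np.nan],
            "habitat": ["bog", "fen", "bog", "fen", "fen", "bog"],
        },
        index=[f"s{i}" for i in range(6)],
    )


def test_prepare_constraints_drops_heavily_missing_variable():
    cm = prepare_constraints(_toy_metadata(), ["ph", "mostly_missing", "habitat"])
    assert "mostly_missing" in cm.dropped_variables
    assert cm.dropped_variables["mostly_missing"] == pytest.approx(4 / 6)
    # s5 dropped complete-case (ph missing)
    assert cm.dropped_samples == ["s5"]


def test_prepare_constraints_centering_and_treatment_coding():
    cm = prepare_constraints(_toy_metadata(), ["ph", "habitat"])
    assert cm.frame["ph"].mean() == pytest.approx(0.0)
    assert cm.variable_columns["habitat"] == ["habitat[fen]"]
    assert set(cm.frame["habitat[fen]"]) == {0.0, 1.0}


def test_prepare_constraints_k_level_factor():
    md = pd.DataFrame({"f": list("aabbcc")}, index=[f"s{i}" for i in range(6)])
    cm = prepare_constraints(md, ["f"])
    assert len(cm.variable_columns["f"]) == 2


def test_vif_orthogonal_columns_unity():
    X = np.array([[1, 0], [1, 0], [-1, 1], [-1, -1]], dtype=float)
    X[:, 1] = [1, -1, 1, -1]
    v = vif(X)
    np.testing.assert_allclose(v.to_numpy(), 1.0, atol=1e-12)


def test_vif_correlated_pair_closed_form():
    # two columns with correlation 0.8 -> VIF = 1/(1-0.64)
    rng = np.random.default_rng(2)
    a = rng.normal(size=4000)
    b = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(size=4000)
    v = vif(np.column_stack([a, b]))
    rho2 = np.corrcoef(a, b)[0, 1] ** 2
    np.testing.assert_allclose(v.to_numpy(), 1 / (1 - rho2), rtol=1e-9)
    assert v.iloc[0] == pytest.approx(1 / (1 - 0.64), rel=0.05)


def test_vif_duplicate_column_infinite():
    a = np.arange(5.0)
    v = vif(np.column_stack([a, a, np.ones(5)]))
    assert np.isinf(v.iloc[0]) or np.isinf(v.iloc[1])


# ---------------------------------------------------------------------------
# permutation inference and variance partitioning
# ---------------------------------------------------------------------------

def test_permutation_p_lower_bound_and_extreme_case():
    rng = np.random.default_rng(10)
    # two-block table: constraint perfectly separates the blocks
    block = np.zeros((10, 12), dtype=int)
    block[:5, :6] = rng.integers(20, 40, size=(5, 6))
    block[5:, 6:] = rng.integers(20, 40, size=(5, 6))
    block += 1  # keep margins positive
    x = np.repeat([0.0, 1.0], 6).reshape(-1, 1)
    f, p = permutation_test(block, x, n_perm=99, seed=0)
    assert p == pytest.approx(1 / 100)
    assert p >= 1 / (99 + 1)


def test_permutation_nperm_floor():
    with pytest.raises(ValueError):
        permutation_test(np.ones((3, 4), dtype=int), np.arange(4.0), n_perm=5)


def test_variance_partition_recovers_planted_factor():
    """Factor A drives a two-block composition; factor B is noise. A's
    marginal share dominates and only A is significant."""
    rng = np.random.default_rng(1)
    n = 24
    a = np.repeat(["u", "v"], n // 2)
    b = rng.permutation(np.repeat(["x", "y"], n // 2))
    base = rng.integers(5, 15, size=(30, n))
    bump = np.zeros((30, n), dtype=int)
    bump[:15, a == "u"] = 40
    bump[15:, a == "v"] = 40
    Y = base + bump
    md = pd.DataFrame({"A": a, "B": b}, index=[f"s{i}" for i in range(n)])
    from mossbiome.community_data import OtuTable

    table = OtuTable(
        tuple(f"o{i}" for i in range(30)),
        tuple(md.index),
        Y,
        ("k",) * 30,
    )
    cm = prepare_constraints(md, ["A", "B"])
    vp = variance_partition(table, cm, n_perm=199, seed=4)
    t = vp.table.set_index("variable")
    assert t.loc["A", "share_pct"] >= 5 * t.loc["B", "share_pct"]
    assert t.loc["A", "p_value"] <= 0.005
    assert t.loc["B", "p_value"] > 0.05


def test_variance_partition_orthogonal_shares_additive():
    """For orthogonal constraints the marginal shares sum to the joint
    constrained inertia."""
    rng = np.random.default_rng(44)
    Y = random_count_table(rng, 11, 8)
    # equal library sizes make the balanced A/B design exactly orthogonal
    # under the row-mass weighting
    target = int(Y.sum(axis=0).max()) + 10
    filler = target - Y.sum(axis=0)
    Y = np.vstack([Y, filler])
    a = np.tile([0.0, 1.0], 4)
    b = np.repeat([0.0, 1.0], 4)
    md = pd.DataFrame({"A": a, "B": b}, index=[f"s{i}" for i in range(8)])
    from mossbiome.community_data import OtuTable

    table = OtuTable(
        tuple(f"o{i}" for i in range(12)), tuple(md.index), Y, ("k",) * 12
    )
    cm = prepare_constraints(md, ["A", "B"])
    vp = variance_partition(table, cm, n_perm=19, seed=0)
    joint = cca(table, cm)
    share_sum = vp.table["share_pct"].sum() / 100 * joint.total_inertia
    assert share_sum == pytest.approx(joint.constrained_inertia, abs=1e-8)


def test_variance_partition_duplicate_variable_aliases():
    rng = np.random.default_rng(12)
    Y = random_count_table(rng, 10, 8)
    md = pd.DataFrame(
        {"A": np.repeat([0.0, 1.0], 4), "Adup": np.repeat([0.0, 1.0], 4)},
        index=[f"s{i}" for i in range(8)],
    )
    from mossbiome.community_data import OtuTable

    table = OtuTable(tuple(f"o{i}" for i in range(10)), tuple(md.index), Y, ("k",) * 10)
    cm = prepare_constraints(md, ["A", "Adup"])
    with pytest.raises((CollinearityError, ValueError)):
        variance_partition(table, cm, n_perm=19, seed=0)
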