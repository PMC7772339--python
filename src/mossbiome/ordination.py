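"""Correspondence analysis, (partial) canonical correspondence analysis,
permutation inference, VIF diagnostics and per-variable variance
partitioning.

The community table is treated as a contingency table. With ``P`` the
table divided by its grand total and ``r``, ``c`` the row (sample) and
column (OTU) mass vectors, the analysis decomposes

    Q = D_r^{-1/2} (P - r c') D_c^{-1/2}

whose squared Frobenius norm is the total inertia (the table's Pearson
chi-square over its grand total). CA is the SVD of ``Q``. CCA projects the
rows of ``Q`` onto the span of row-mass-weighted, centered constraint
variables before the SVD; partial CCA first removes the span of
conditioning variables from both ``Q`` and the constraints, so total
inertia splits exactly into conditioned + constrained + residual parts.
Significance uses a pseudo-F statistic with free row permutation (no
conditions) or permutation of the reduced-model residuals (with
conditions). Per-variable shares are marginal by default: each variable is
constrained with all others as conditions.

The eigen-decomposition is implemented here from the linear algebra; the
test-suite checks it against an independent generalized-eigenproblem
formulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConstraintMatrix",
    "OrdinationResult",
    "VariancePartition",
    "prepare_constraints",
    "ca",
    "cca",
    "vif",
    "permutation_test",
    "variance_partition",
]

_EIG_TOL = 1e-12


class CollinearityError(ValueError):
    """Constraint columns are collinear to working precision."""

    def __init__(self, aliased: list[str]):
        self.aliased = aliased
        super().__init__(f"aliased (collinear) constraint columns: {aliased}")


@dataclass
class ConstraintMatrix:
    """Sample-aligned design matrix for (partial) CCA.

    ``frame`` holds encoded columns (treatment-coded indicators for
    factors, centered continuous variables) indexed by sample id;
    ``variable_columns`` maps each original variable to its encoded
    columns. Variables dropped for excessive missingness and samples
    dropped for residual missing values are reported.
    """

    frame: pd.DataFrame
    variable_columns: dict[str, list[str]]
    dropped_variables: dict[str, float] = field(default_factory=dict)
    dropped_samples: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def columns_for(self, variables) -> list[str]:
        cols: list[str] = []
        for v in variables:
            cols.extend(self.variable_columns[v])
        return cols

    def subset(self, variables) -> "ConstraintMatrix":
        cols = self.columns_for(variables)
        return ConstraintMatrix(
            frame=self.frame[cols],
            variable_columns={v: list(self.variable_columns[v]) for v in variables},
            dropped_variables=dict(self.dropped_variables),
            dropped_samples=list(self.dropped_samples),
        )


@dataclass
class OrdinationResult:
    """Inertia decomposition and scores of a CA/CCA fit."""

    total_inertia: float
    conditioned_inertia: float
    constrained_inertia: float
    residual_inertia: float
    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame | None
    n_samples: int
    n_otus: int

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.concatenate(
            [self.constrained_eigenvalues, self.unconstrained_eigenvalues]
        )

    def proportions(self) -> dict[str, float]:
        t = self.total_inertia
        return {
            "conditioned": self.conditioned_inertia / t,
            "constrained": self.constrained_inertia / t,
            "residual": self.residual_inertia / t,
        }


@dataclass
class VariancePartition:
    """Per-variable marginal (or sequential) inertia shares."""

    table: pd.DataFrame  # variable, share_pct, pseudo_F, p_value, n_perm
    scheme: str
    total_inertia: float
    joint_constrained_pct: float


# ---------------------------------------------------------------------------
# constraint preparation
# ---------------------------------------------------------------------------

def prepare_constraints(
    metadata: pd.DataFrame,
    variables: list[str],
    max_missing_fraction: float = 0.2,
) -> ConstraintMatrix:
    """Encode metadata variables into a design matrix.

    Variables missing in more than ``max_missing_fraction`` of samples are
    dropped (and reported); remaining samples with any missing value are
    dropped complete-case. Categorical variables become k-1 treatment-coded
    indicators (first level, sorted, is the reference); continuous
    variables are centered.
    """
    unknown = [v for v in variables if v not in metadata.columns]
    if unknown:
        raise KeyError(f"variables not in metadata: {unknown}")
    md = metadata[variables].copy()
    for col in md.columns:
        if md[col].dtype == object:
            md[col] = md[col].replace("", np.nan)
    miss = md.isna().mean()
    dropped_vars = {v: float(miss[v]) for v in variables if miss[v] > max_missing_fraction}
    kept = [v for v in variables if v not in dropped_vars]
    if not kept:
        raise ValueError(
            f"no variables survive the missingness filter: {dropped_vars}"
        )
    md = md[kept]
    complete = md.dropna()
    dropped_samples = [s for s in md.index if s not in complete.index]
    cols: dict[str, np.ndarray] = {}
    varcols: dict[str, list[str]] = {}
    for v in kept:
        series = complete[v]
        if pd.api.types.is_numeric_dtype(series):
            name = v
            cols[name] = series.to_numpy(dtype=float) - float(series.mean())
            varcols[v] = [name]
        else:
            levels = sorted(series.astype(str).unique())
            if len(levels) < 2:
                # constant factor carries no contrast; encode as empty
                varcols[v] = []
                continue
            names = []
            for lev in levels[1:]:
                name = f"{v}[{lev}]"
                cols[name] = (series.astype(str) == lev).to_numpy(dtype=float)
                names.append(name)
            varcols[v] = names
    frame = pd.DataFrame(cols, index=complete.index)
    if frame.shape[1] == 0:
        raise ValueError("no informative constraint columns after encoding")
    return ConstraintMatrix(
        frame=frame,
        variable_columns=varcols,
        dropped_variables=dropped_vars,
        dropped_samples=dropped_samples,
    )


# ---------------------------------------------------------------------------
# core decomposition
# ---------------------------------------------------------------------------

def _community_matrix(table) -> tuple[np.ndarray, list[str], list[str]]:
    """Return (samples x OTUs) float matrix + sample/OTU ids.

    Accepts an OtuTable, a RelAbundTable, or a plain (OTUs x samples)
    matrix as produced by :func:`mossbiome.community_data.hellinger`.
    """
    counts = getattr(table, "counts", None)
    if counts is None:
        counts = getattr(table, "values", None)
    if counts is not None and hasattr(table, "sample_ids"):
        return (
            np.asarray(counts, dtype=float).T,
            list(table.sample_ids),
            list(table.otu_ids),
        )
    mat = np.asarray(table, dtype=float).T
    return (
        mat,
        [f"S{j}" for j in range(mat.shape[0])],
        [f"OTU{i}" for i in range(mat.shape[1])],
    )


def _chi_square_setup(Y: np.ndarray, sample_ids, otu_ids):
    if (Y < 0).any():
        raise ValueError("community matrix must be non-negative")
    grand = Y.sum()
    if grand <= 0:
        raise ValueError("community matrix has zero grand total")
    rsum = Y.sum(axis=1)
    csum = Y.sum(axis=0)
    if (rsum == 0).any():
        raise ValueError(f"all-zero sample: {sample_ids[int(np.argmax(rsum == 0))]!r}")
    if (csum == 0).any():
        raise ValueError(f"all-zero OTU: {otu_ids[int(np.argmax(csum == 0))]!r}")
    P = Y / grand
    r = rsum / grand
    c = csum / grand
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return Q, r, c


def _center_weight(X: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Center columns by row-mass-weighted means and weight rows by sqrt(r)."""
    return (X - r @ X) * np.sqrt(r)[:, None]


def _svd_axes(M: np.ndarray):
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    keep = s**2 > _EIG_TOL * max(1.0, s[0] ** 2 if len(s) else 1.0)
    return U[:, keep], s[keep], Vt[keep]


def ca(table) -> OrdinationResult:
    """Correspondence analysis of a community table.

    Total inertia equals the table's Pearson chi-square divided by its
    grand total; axes are the singular vectors of the standardized
    residual matrix, scaled by the masses.
    """
    Y, sample_ids, otu_ids = _community_matrix(table)
    Q, r, c = _chi_square_setup(Y, sample_ids, otu_ids)
    total = float(np.sum(Q**2))
    U, s, Vt = _svd_axes(Q)
    axes = [f"CA{k + 1}" for k in range(len(s))]
    site = (U * s) / np.sqrt(r)[:, None]
    species = Vt.T / np.sqrt(c)[:, None]
    return OrdinationResult(
        total_inertia=total,
        conditioned_inertia=0.0,
        constrained_inertia=0.0,
        residual_inertia=total,
        constrained_eigenvalues=np.array([]),
        unconstrained_eigenvalues=s**2,
        site_scores=pd.DataFrame(site, index=sample_ids, columns=axes),
        species_scores=pd.DataFrame(species, index=otu_ids, columns=axes),
        biplot_scores=None,
        n_samples=len(sample_ids),
        n_otus=len(otu_ids),
    )


def _align(table, constraints, conditions):
    Y, sample_ids, otu_ids = _community_matrix(table)
    if isinstance(constraints, ConstraintMatrix):
        keep = [s for s in sample_ids if s in set(constraints.frame.index)]
        if conditions is not None and isinstance(conditions, ConstraintMatrix):
            cond_idx = set(conditions.frame.index)
            keep = [s for s in keep if s in cond_idx]
        if len(keep) < len(sample_ids):
            pos = {s: i for i, s in enumerate(sample_ids)}
            Y = Y[[pos[s] for s in keep], :]
            nz = Y.sum(axis=0) > 0
            Y = Y[:, nz]
            otu_ids = [o for o, k in zip(otu_ids, nz) if k]
            sample_ids = keep
        X = constraints.frame.loc[sample_ids].to_numpy(dtype=float)
        xnames = list(constraints.frame.columns)
    else:
        X = np.asarray(constraints, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        xnames = [f"X{j}" for j in range(X.shape[1])]
        if X.shape[0] != Y.shape[0]:
            raise ValueError("constraints rows must match samples")
    if conditions is None:
        Z, znames = None, []
    elif isinstance(conditions, ConstraintMatrix):
        Z = conditions.frame.loc[sample_ids].to_numpy(dtype=float)
        znames = list(conditions.frame.columns)
    else:
        Z = np.asarray(conditions, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        znames = [f"Z{j}" for j in range(Z.shape[1])]
        if Z.shape[0] != Y.shape[0]:
            raise ValueError("conditions rows must match samples")
    return Y, sample_ids, otu_ids, X, xnames, Z, znames


def cca(table, constraints, conditions=None, drop_aliased: bool = False) -> OrdinationResult:
    """(Partial) canonical correspondence analysis.

    ``constraints`` / ``conditions`` are ConstraintMatrix objects (sample
    alignment by id; samples missing from either are dropped from the
    table) or plain sample-aligned arrays. The inertia decomposition
    ``conditioned + constrained + residual = total`` holds exactly.

    Collinear constraint columns raise :class:`CollinearityError` naming
    the aliased columns; with ``drop_aliased=True`` they are dropped
    instead (redundant conditioning columns are always harmless and are
    dropped silently, since only the conditioning span matters).
    """
    Y, sample_ids, otu_ids, X, xnames, Z, znames = _align(table, constraints, conditions)
    Q, r, c = _chi_square_setup(Y, sample_ids, otu_ids)
    total = float(np.sum(Q**2))

    conditioned = 0.0
    Bz = None
    if Z is not None:
        Bz = _orthonormal(_center_weight(Z, r), znames, drop_aliased=True)
        Qz = Bz @ (Bz.T @ Q)
        conditioned = float(np.sum(Qz**2))
        Q1 = Q - Qz
    else:
        Q1 = Q
    Xw = _center_weight(X, r)
    if Bz is not None:
        Xw = Xw - Bz @ (Bz.T @ Xw)
    Bx = _orthonormal(Xw, xnames, drop_aliased=drop_aliased)
    Qfit = Bx @ (Bx.T @ Q1)
    constrained = float(np.sum(Qfit**2))
    Qres = Q1 - Qfit
    residual = float(np.sum(Qres**2))

    Uc, sc, Vct = _svd_axes(Qfit)
    Ur, sr, Vrt = _svd_axes(Qres)
    cca_axes = [f"CCA{k + 1}" for k in range(len(sc))]
    ca_axes = [f"CA{k + 1}" for k in range(len(sr))]
    with np.errstate(divide="ignore", invalid="ignore"):
        site = np.column_stack([Uc * sc, Ur * sr]) / np.sqrt(r)[:, None]
        species = np.column_stack([Vct.T, Vrt.T]) / np.sqrt(c)[:, None]
    axes = cca_axes + ca_axes
    # biplot scores: correlation of weighted constraint columns with the
    # constrained axes' linear-combination scores
    if len(sc):
        lc = Uc  # unit-norm weighted site scores
        Xn = Xw / np.maximum(np.linalg.norm(Xw, axis=0), 1e-300)
        biplot = pd.DataFrame(Xn.T @ lc, index=xnames, columns=cca_axes)
    else:
        biplot = pd.DataFrame(index=xnames, columns=[])
    return OrdinationResult(
        total_inertia=total,
        conditioned_inertia=conditioned,
        constrained_inertia=constrained,
        residual_inertia=residual,
        constrained_eigenvalues=sc**2,
        unconstrained_eigenvalues=sr**2,
        site_scores=pd.DataFrame(site, index=sample_ids, columns=axes),
        species_scores=pd.DataFrame(species, index=otu_ids, columns=axes),
        biplot_scores=biplot,
        n_samples=len(sample_ids),
        n_otus=len(otu_ids),
    )


def _orthonormal(Xw: np.ndarray, names: list[str], drop_aliased: bool = False) -> np.ndarray:
    """Orthonormal basis of col(Xw) by modified Gram-Schmidt.

    Raises :class:`CollinearityError` naming aliased columns unless
    ``drop_aliased`` is set, in which case they are simply skipped.
    """
    basis: list[np.ndarray] = []
    aliased: list[str] = []
    scale = max(np.linalg.norm(Xw), 1.0)
    for j in range(Xw.shape[1]):
        v = Xw[:, j].copy()
        for b in basis:
            v -= b * (b @ v)
        nv = np.linalg.norm(v)
        if nv > 1e-9 * scale:
            basis.append(v / nv)
        else:
            aliased.append(names[j] if j < len(names) else str(j))
    if aliased and not drop_aliased:
        raise CollinearityError(aliased)
    if not basis:
        raise ValueError("constraints have zero rank after centering/conditioning")
    return np.column_stack(basis)


def vif(constraints, weights=None) -> pd.Series:
    """Variance inflation factors of constraint columns.

    ``VIF_j = 1/(1 - R^2_j)`` from the weighted regression (with
    intercept) of column j on all other columns. Exactly collinear columns
    are reported as ``inf``.
    """
    if isinstance(constraints, ConstraintMatrix):
        X = constraints.frame.to_numpy(dtype=float)
        names = list(constraints.frame.columns)
    else:
        X = np.asarray(constraints, dtype=float)
        names = [f"X{j}" for j in range(X.shape[1])]
    n, q = X.shape
    if q < 2:
        raise ValueError("need at least 2 constraint columns for VIF")
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    sw = np.sqrt(w)
    Xc = (X - w @ X) * sw[:, None]
    out = {}
    for j in range(q):
        y = Xc[:, j]
        others = np.delete(Xc, j, axis=1)
        sst = float(y @ y)
        if sst <= 0:
            out[names[j]] = np.inf
            continue
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        r2 = 1.0 - float(resid @ resid) / sst
        out[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

def _fit_matrices(table, constraints, conditions, drop_aliased=False):
    """Shared setup for permutation tests: returns reduced-model residual
    matrix Q1, constraint basis Bx, ranks, and observed inertias."""
    Y, sample_ids, otu_ids, X, xnames, Z, znames = _align(table, constraints, conditions)
    Q, r, c = _chi_square_setup(Y, sample_ids, otu_ids)
    total = float(np.sum(Q**2))
    Xw = _center_weight(X, r)
    if Z is not None:
        Bz = _orthonormal(_center_weight(Z, r), znames, drop_aliased=True)
        Q1 = Q - Bz @ (Bz.T @ Q)
        Xw = Xw - Bz @ (Bz.T @ Xw)
        p_cond = Bz.shape[1]
    else:
        Q1 = Q
        p_cond = 0
    Bx = _orthonormal(Xw, xnames, drop_aliased=drop_aliased)
    return Q1, Bx, p_cond, total, len(sample_ids)


def _pseudo_f(ci: float, ri: float, q: int, n: int, p_cond: int) -> float:
    df_res = n - q - p_cond - 1
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    return (ci / q) / (ri / df_res)


def permutation_test(
    table,
    constraints,
    conditions=None,
    n_perm: int = 999,
    seed: int | None = None,
    drop_aliased: bool = False,
) -> tuple[float, float]:
    """Pseudo-F permutation test of the constraints.

    Null distributions are built by freely permuting the rows of the
    chi-square standardized community matrix when there are no conditions,
    and by permuting the rows of the reduced-model residuals otherwise;
    ``p = (1 + #{F* >= F}) / (n_perm + 1)``.
    """
    if n_perm < 19:
        raise ValueError("n_perm < 19 gives uselessly coarse p-values")
    Q1, Bx, p_cond, _total, n = _fit_matrices(table, constraints, conditions, drop_aliased)
    q = Bx.shape[1]
    t1 = float(np.sum(Q1**2))
    ci = float(np.sum((Bx.T @ Q1) ** 2))
    ri = t1 - ci
    f_obs = _pseudo_f(ci, ri, q, n, p_cond)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Qp = Q1[perm]
        ci_p = float(np.sum((Bx.T @ Qp) ** 2))
        ri_p = t1 - ci_p
        f_p = _pseudo_f(ci_p, max(ri_p, 1e-300), q, n, p_cond)
        if f_p >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return f_obs, p


def variance_partition(
    table,
    constraints: ConstraintMatrix,
    variables: list[str] | None = None,
    scope_conditions: list[str] | None = None,
    n_perm: int = 199,
    seed: int | None = None,
    scheme: str = "marginal",
    drop_aliased: bool = False,
) -> VariancePartition:
    """Per-variable inertia shares with permutation p-values.

    ``marginal`` (default): each variable's share is the constrained
    inertia of the partial CCA constraining that variable alone and
    conditioning on every other variable (plus ``scope_conditions``),
    as a percentage of total inertia. ``sequential`` adds variables in
    the given order, conditioning each on its predecessors.
    """
    if variables is None:
        variables = [v for v in constraints.variable_columns if constraints.variable_columns[v]]
    scope_conditions = scope_conditions or []
    rng = np.random.default_rng(seed)
    rows = []
    joint = cca(table, constraints.subset(variables + scope_conditions), drop_aliased=drop_aliased)
    for i, v in enumerate(variables):
        if scheme == "marginal":
            others = [u for u in variables if u != v] + scope_conditions
        elif scheme == "sequential":
            others = variables[:i] + scope_conditions
        else:
            raise ValueError(f"unknown scheme: {scheme!r}")
        cond = constraints.subset(others) if others else None
        fit = cca(table, constraints.subset([v]), cond, drop_aliased=drop_aliased)
        f_obs, p = permutation_test(
            table,
            constraints.subset([v]),
            cond,
            n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)),
            drop_aliased=drop_aliased,
        )
        rows.append(
            dict(
                variable=v,
                share_pct=100.0 * fit.constrained_inertia / fit.total_inertia,
                pseudo_F=f_obs,
                p_value=p,
                n_perm=n_perm,
            )
        )
    df = pd.DataFrame(rows).sort_values("share_pct", ascending=False, ignore_index=True)
    return VariancePartition(
        table=df,
        scheme=scheme,
        total_inertia=joint.total_inertia,
        joint_constrained_pct=100.0 * joint.constrained_inertia / joint.total_inertia,
    )
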