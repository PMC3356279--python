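"""Matrix permutation regression (MRQAP) with double semi-partialing.

Multiple regression quadratic assignment procedure: a dyadic dependent
matrix is regressed on several dyadic predictor matrices by OLS over the
off-diagonal cells, and inference comes from node permutations rather than
from parametric theory, because dyads sharing a node are not independent.

The double-semi-partialing (DSP) scheme of Dekker and colleagues builds
the null distribution of each coefficient separately: predictor X_i is
regressed on the remaining predictors, its residual matrix E_i is
node-permuted (rows and columns relabelled together, preserving network
structure), the permuted residuals replace X_i in the full model, and the
refitted coefficient is recorded.  The two-tailed p-value uses the add-one
rule, counting the observed statistic as one member of its own null
sample, so p is never 0.

The permutation refits are computed through the Frisch–Waugh–Lovell
identity: the coefficient on the permuted column equals the simple slope
between that column and the dependent variable after both are projected
off the other predictors, which lets all permutations be evaluated as
vectorised array operations with results identical to refitting the full
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import DyadicMatrix, InvariantError, UndefinedDyadError, derive_rng

__all__ = [
    "MRQAPResult",
    "PredictorResult",
    "vectorize_dyads",
    "ols_matrix_regression",
    "node_permute",
    "mrqap_dsp",
]


# ---------------------------------------------------------------------------
# Dyad vectorisation
# ---------------------------------------------------------------------------

def _dyad_cells(matrix: DyadicMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the cells a regression uses, in canonical order.

    Directed matrices contribute both (i, j) and (j, i); undirected
    matrices contribute each unordered dyad once (upper triangle).
    """
    n = matrix.n
    if matrix.directed:
        i_idx, j_idx = np.nonzero(~np.eye(n, dtype=bool))
    else:
        i_idx, j_idx = np.triu_indices(n, k=1)
    return i_idx, j_idx


def vectorize_dyads(matrix: DyadicMatrix) -> np.ndarray:
    """Off-diagonal cells as a flat vector in canonical order.

    Raises :class:`UndefinedDyadError` listing the offending dyads if any
    used cell is undefined; callers that tolerate missing dyads drop them
    listwise first (see :func:`mrqap_dsp`).
    """
    if matrix.n < 3:
        raise InvariantError("dyadic regression needs at least 3 nodes")
    i_idx, j_idx = _dyad_cells(matrix)
    bad = ~matrix.defined[i_idx, j_idx]
    if bad.any():
        dyads = [
            (matrix.ids[i], matrix.ids[j])
            for i, j in zip(i_idx[bad][:10], j_idx[bad][:10])
        ]
        raise UndefinedDyadError(f"undefined dyads in matrix: {dyads}")
    return matrix.values[i_idx, j_idx].astype(float)


def _check_conformable(dep: DyadicMatrix, predictors: Mapping[str, DyadicMatrix]):
    for name, m in predictors.items():
        if m.ids != dep.ids:
            raise InvariantError(
                f"predictor {name!r} ids differ from dependent matrix; "
                "reorder matrices to a shared id order first"
            )
        if m.directed != dep.directed:
            raise InvariantError(
                f"predictor {name!r} directedness differs from dependent matrix"
            )


# ---------------------------------------------------------------------------
# OLS on dyads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Fit:
    intercept: float
    slopes: np.ndarray
    r_squared: float


def _ols(y: np.ndarray, X: np.ndarray, names: Sequence[str]) -> _Fit:
    design = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise InvariantError(
            f"predictors are collinear (design rank {rank} < {design.shape[1]}); "
            f"predictors: {list(names)}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    return _Fit(intercept=float(beta[0]), slopes=beta[1:], r_squared=r2)


def ols_matrix_regression(
    dep: DyadicMatrix, predictors: Mapping[str, DyadicMatrix]
) -> tuple[dict[str, float], float, float]:
    """OLS of the dependent matrix on predictor matrices over dyad cells.

    Returns (slopes by predictor name, intercept, R^2).  Undefined dyads
    must already have been dropped or must be absent.
    """
    _check_conformable(dep, predictors)
    y = vectorize_dyads(dep)
    names = list(predictors)
    X = np.column_stack([vectorize_dyads(predictors[n]) for n in names])
    fit = _ols(y, X, names)
    return dict(zip(names, map(float, fit.slopes))), fit.intercept, fit.r_squared


# ---------------------------------------------------------------------------
# Node permutation
# ---------------------------------------------------------------------------

def node_permute(matrix: DyadicMatrix, relabeling: Sequence[int]) -> DyadicMatrix:
    """Apply one node relabelling: rows and columns permuted together.

    ``relabeling`` is a permutation of 0..n-1; output cell (i, j) takes the
    value of input cell (relabeling[i], relabeling[j]), so network
    structure is preserved and only node identities move.
    """
    p = np.asarray(relabeling)
    n = matrix.n
    if sorted(p.tolist()) != list(range(n)):
        raise InvariantError("relabeling must be a bijection of 0..n-1")
    return DyadicMatrix(
        ids=matrix.ids,
        values=matrix.values[np.ix_(p, p)],
        directed=matrix.directed,
        defined=matrix.defined[np.ix_(p, p)],
    )


# ---------------------------------------------------------------------------
# Double semi-partialing MRQAP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictorResult:
    """Per-predictor MRQAP output.

    ``null_mean`` and ``null_se`` summarise the DSP permutation slope
    distribution; under exchangeability the null mean should sit within a
    few standard errors of 0.
    """

    name: str
    slope: float
    slope_standardized: float
    p_value: float
    null_mean: float = float("nan")
    null_se: float = float("nan")


@dataclass
class MRQAPResult:
    """Fit summary for one MRQAP run.

    ``predictors`` preserves input order; p-values use the add-one rule
    (observed statistic counted as one permutation), so the smallest
    attainable p is 1/(n_permutations + 1).
    """

    predictors: list[PredictorResult]
    intercept: float
    r_squared: float
    n_permutations: int
    seed: int
    n_dyads: int
    tail: str = "two-sided"
    n_dropped_dyads: int = 0

    def p_value(self, name: str) -> float:
        for p in self.predictors:
            if p.name == name:
                return p.p_value
        raise KeyError(name)

    def slope(self, name: str) -> float:
        for p in self.predictors:
            if p.name == name:
                return p.slope
        raise KeyError(name)

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            [
                {"predictor": p.name, "slope": p.slope,
                 "slope_std": p.slope_standardized, "P": p.p_value}
                for p in self.predictors
            ]
        )


def _restrict(dep: DyadicMatrix, predictors: Mapping[str, DyadicMatrix]):
    """Listwise-drop dyads undefined in any matrix: returns copies whose
    shared mask marks only fully observed dyads, plus the dropped count."""
    mask = dep.defined.copy()
    for m in predictors.values():
        mask &= m.defined
    n_all = int((~np.eye(dep.n, dtype=bool)).sum())
    dropped = n_all - int(mask.sum())
    if dropped == 0:
        return dep, dict(predictors), 0

    def with_mask(m: DyadicMatrix) -> DyadicMatrix:
        vals = np.where(mask, m.values, 0.0)
        return DyadicMatrix(ids=m.ids, values=vals, directed=m.directed,
                            defined=mask)

    return with_mask(dep), {k: with_mask(v) for k, v in predictors.items()}, dropped


def mrqap_dsp(
    dep: DyadicMatrix,
    predictors: Mapping[str, DyadicMatrix],
    n_permutations: int = 2000,
    seed: int = 0,
    tail: str = "two-sided",
) -> MRQAPResult:
    """MRQAP with double-semi-partialing permutation inference.

    Parameters
    ----------
    dep
        Dependent dyadic matrix.
    predictors
        Ordered mapping name -> predictor matrix, conformable with ``dep``.
    n_permutations
        Node permutations per predictor (default 2000).
    seed
        Seed for the permutation stream; identical inputs and seed give
        identical results.
    tail
        'two-sided' (default), 'greater' or 'less'.

    Dyads undefined in any matrix are dropped listwise (their cells are
    zeroed and masked before residualising); the count is recorded on the
    result.  For undirected data the residual matrix is symmetric by
    construction, so node permutation preserves its exchangeability
    structure.
    """
    if tail not in ("two-sided", "greater", "less"):
        raise InvariantError(f"unknown tail {tail!r}")
    if n_permutations < 1:
        raise InvariantError("n_permutations must be positive")
    _check_conformable(dep, predictors)
    dep, predictors, n_dropped = _restrict(dep, predictors)

    names = list(predictors)
    i_idx, j_idx = _dyad_cells(dep)
    used = dep.defined[i_idx, j_idx]
    i_idx, j_idx = i_idx[used], j_idx[used]
    if len(i_idx) < len(names) + 2:
        raise InvariantError("too few defined dyads for regression")

    y = dep.values[i_idx, j_idx]
    X = np.column_stack([predictors[n].values[i_idx, j_idx] for n in names])
    fit = _ols(y, X, names)

    sd_y = y.std()
    rng = derive_rng(seed, "mrqap-dsp")
    n_nodes = dep.n
    perms = np.array(
        [rng.permutation(n_nodes) for _ in range(n_permutations)]
    )

    results: list[PredictorResult] = []
    for k, name in enumerate(names):
        others = np.delete(X, k, axis=1)
        Z = np.column_stack([np.ones(len(y)), others])
        Q, _ = np.linalg.qr(Z)
        e = X[:, k] - Q @ (Q.T @ X[:, k])  # semi-partialed predictor
        y_t = y - Q @ (Q.T @ y)

        # residuals back in matrix form for structure-preserving permutation
        E = np.zeros((n_nodes, n_nodes))
        E[i_idx, j_idx] = e
        if not dep.directed:
            E[j_idx, i_idx] = e

        # all permuted residual columns at once; FWL gives the full-model slope
        cols = E[perms[:, i_idx], perms[:, j_idx]].T  # (n_cells, n_perm)
        cols_t = cols - Q @ (Q.T @ cols)
        denom = np.einsum("ij,ij->j", cols_t, cols_t)
        denom[denom == 0] = np.inf  # degenerate permutation: slope 0
        b_perm = (cols_t.T @ y_t) / denom

        b_obs = float(fit.slopes[k])
        if tail == "two-sided":
            count = int(np.sum(np.abs(b_perm) >= abs(b_obs)))
        elif tail == "greater":
            count = int(np.sum(b_perm >= b_obs))
        else:
            count = int(np.sum(b_perm <= b_obs))
        p = (1 + count) / (n_permutations + 1)

        sd_x = X[:, k].std()
        b_std = b_obs * sd_x / sd_y if sd_y > 0 else np.nan
        results.append(
            PredictorResult(
                name=name, slope=b_obs, slope_standardized=float(b_std),
                p_value=float(p),
                null_mean=float(b_perm.mean()),
                null_se=float(b_perm.std(ddof=1) / np.sqrt(len(b_perm))),
            )
        )

    return MRQAPResult(
        predictors=results,
        intercept=fit.intercept,
        r_squared=fit.r_squared,
        n_permutations=n_permutations,
        seed=seed,
        n_dyads=int(len(y)),
        tail=tail,
        n_dropped_dyads=n_dropped,
    )
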