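"""Fuzzy K-means (Bezdek), cluster-count diagnostics, and group ratios.

Clinical subgroups overlap, so subjects are clustered softly: each subject j
holds a graded membership u_ij in every cluster i, and the Bezdek alternating
iteration minimizes

    J = sum_i sum_j u_ij^m * d^2(x_j, c_i),    m > 1,

where d is the Euclidean distance in the reduced (significant-PC) space and m
is the fuzzifier (m -> 1 recovers hard K-means).  Cluster-count diagnostics
follow the usual validity indices: inertia (elbow method), the partition
coefficient (1/N) sum u^2 and the partition entropy -(1/N) sum u ln u.
Cluster quality against the diagnostic grouping is summarized by the
group-in-cluster ratio: the fraction of each diagnostic group assigned to each
cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FuzzyResult",
    "ValidityIndices",
    "RatioMatrix",
    "fuzzy_kmeans",
    "hard_assign",
    "sweep_k",
    "group_cluster_ratio",
    "render_percent",
]


@dataclass
class FuzzyResult:
    centers: np.ndarray  # k x d
    membership: np.ndarray  # n x k, rows sum to 1
    fuzzifier: float
    objective_trace: list[float]
    n_iter: int
    converged: bool
    seed: int
    labels: np.ndarray = field(init=False)
    tie_rows: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.labels, self.tie_rows = _argmax_with_ties(self.membership)


@dataclass
class ValidityIndices:
    inertia_by_k: dict[int, float]
    pc_by_k: dict[int, float]
    pe_by_k: dict[int, float]
    elbow_k: int | None


@dataclass
class RatioMatrix:
    """Group × cluster composition: proportions, counts and group totals."""

    ratio: pd.DataFrame
    counts: pd.DataFrame
    group_totals: pd.Series

    def percent(self) -> pd.DataFrame:
        """Integer-percent rendering (half rounds away from zero)."""
        return self.ratio.map(lambda r: render_percent(r))


def render_percent(ratio: float) -> int:
    """Render a proportion as integer percent, rounding half away from zero."""
    pct = 100.0 * ratio
    return int(np.floor(pct + 0.5)) if pct >= 0 else -int(np.floor(-pct + 0.5))


def _argmax_with_ties(U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.argmax(U, axis=1)  # argmax takes the lowest index on ties
    row_max = U[np.arange(U.shape[0]), labels]
    ties = (np.isclose(U, row_max[:, None]).sum(axis=1)) > 1
    return labels, np.flatnonzero(ties)


# ---------------------------------------------------------------------------
# Bezdek iteration
# ---------------------------------------------------------------------------

def _update_membership(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances (n x k).

    u_ij = 1 / sum_l (d_ij / d_lj)^(2/(m-1)); points coinciding with one or
    more centers get their membership shared equally among those centers.
    """
    n, k = d2.shape
    U = np.zeros((n, k))
    zero = d2 <= 1e-300
    any_zero = zero.any(axis=1)
    if any_zero.any():
        z = zero[any_zero]
        U[any_zero] = z / z.sum(axis=1, keepdims=True)
    ok = ~any_zero
    if ok.any():
        power = 1.0 / (m - 1.0)
        inv = d2[ok] ** -power  # (1/d^2)^(1/(m-1))
        U[ok] = inv / inv.sum(axis=1, keepdims=True)
    return U


def _objective(X: np.ndarray, centers: np.ndarray, U: np.ndarray, m: float) -> float:
    d2 = _sq_distances(X, centers)
    return float(np.sum((U**m) * d2))


def _sq_distances(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - centers[None, :, :]
    return np.einsum("nkd,nkd->nk", diff, diff)


def fuzzy_kmeans(
    X,
    k: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    n_restarts: int = 10,
    seed: int = 0,
) -> FuzzyResult:
    """Fuzzy K-means on a complete subject × dimension matrix.

    Starts from ``n_restarts`` random row-stochastic membership matrices and
    keeps the run with the lowest final objective J.  Convergence is declared
    when the maximum absolute membership change drops below ``tol``.
    """
    arr = np.asarray(X, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if not np.isfinite(arr).all():
        raise ValueError("input contains non-finite entries")
    if m <= 1.0:
        raise ValueError(f"fuzzifier m must exceed 1, got {m}")
    n_distinct = np.unique(arr, axis=0).shape[0]
    if not (1 <= k <= n_distinct):
        raise ValueError(f"k={k} outside [1, {n_distinct} distinct rows]")

    rng = np.random.default_rng(seed)
    best: FuzzyResult | None = None
    for _ in range(max(1, n_restarts)):
        U = rng.random((arr.shape[0], k))
        U /= U.sum(axis=1, keepdims=True)
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            Um = U**m
            centers = (Um.T @ arr) / Um.sum(axis=0)[:, None]
            d2 = _sq_distances(arr, centers)
            U_new = _update_membership(d2, m)
            trace.append(float(np.sum((U_new**m) * d2)))
            delta = float(np.max(np.abs(U_new - U)))
            U = U_new
            if delta < tol:
                converged = True
                break
        result = FuzzyResult(
            centers=centers,
            membership=U,
            fuzzifier=m,
            objective_trace=trace,
            n_iter=it,
            converged=converged,
            seed=seed,
        )
        if best is None or trace[-1] < best.objective_trace[-1]:
            best = result
    assert best is not None
    return best


def hard_assign(result: FuzzyResult) -> np.ndarray:
    """Crisp labels: argmax membership, ties to the lowest cluster index."""
    return result.labels.copy()


# ---------------------------------------------------------------------------
# Cluster-count diagnostics
# ---------------------------------------------------------------------------

def partition_coefficient(U: np.ndarray) -> float:
    """PC = (1/N) sum u^2; 1 for crisp partitions, 1/k for uniform ones."""
    return float(np.sum(U**2) / U.shape[0])


def partition_entropy(U: np.ndarray) -> float:
    """PE = -(1/N) sum u ln u; 0 for crisp partitions, ln k for uniform ones."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(U > 0, U * np.log(U), 0.0)
    return float(-np.sum(term) / U.shape[0])


def sweep_k(X, k_range, m: float = 2.0, seed: int = 0, **fit_kwargs) -> ValidityIndices:
    """Fit every k in ``k_range`` and record inertia, PC and PE.

    Inertia is the within-cluster sum of squared distances of hard-assigned
    points to their cluster center.  The elbow is operationalized as the k
    maximizing the second difference of inertia over ``k_range`` (the point
    after which improvement levels off); it is undefined for fewer than three
    k values.
    """
    ks = sorted(k_range)
    inertia, pc, pe = {}, {}, {}
    arr = np.asarray(X, float)
    for k in ks:
        res = fuzzy_kmeans(arr, k, m=m, seed=seed, **fit_kwargs)
        labels = res.labels
        a = arr if arr.ndim == 2 else arr[:, None]
        d2 = _sq_distances(a, res.centers)
        inertia[k] = float(d2[np.arange(a.shape[0]), labels].sum())
        pc[k] = partition_coefficient(res.membership)
        pe[k] = partition_entropy(res.membership)

    elbow: int | None = None
    if len(ks) >= 3:
        second_diff = {
            ks[i]: inertia[ks[i - 1]] - 2 * inertia[ks[i]] + inertia[ks[i + 1]]
            for i in range(1, len(ks) - 1)
        }
        elbow = max(second_diff, key=second_diff.get)
    else:
        warnings.warn("k_range shorter than 3: elbow undefined", stacklevel=2)
    for i in range(1, len(ks)):
        if inertia[ks[i]] > inertia[ks[i - 1]] + 1e-9:
            warnings.warn(
                f"inertia increased from k={ks[i-1]} to k={ks[i]}; "
                "consider more restarts",
                stacklevel=2,
            )
    return ValidityIndices(inertia_by_k=inertia, pc_by_k=pc, pe_by_k=pe, elbow_k=elbow)


# ---------------------------------------------------------------------------
# Group-in-cluster ratio
# ---------------------------------------------------------------------------

def group_cluster_ratio(labels, groups) -> RatioMatrix:
    """Fraction of each diagnostic group falling in each cluster.

    ratio[i, j] = (# subjects of group i in cluster j) / (# subjects of
    group i).  Rows therefore sum to 1.
    """
    labels = np.asarray(labels)
    groups = pd.Series(np.asarray(groups), name="group")
    if len(labels) != len(groups):
        raise ValueError("labels and groups lengths differ")
    counts = pd.crosstab(groups, pd.Series(labels, name="cluster"))
    counts = counts.reindex(
        columns=sorted(np.unique(labels)), fill_value=0
    )
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("empty diagnostic group")
    ratio = counts.div(totals, axis=0)
    return RatioMatrix(ratio=ratio, counts=counts, group_totals=totals)
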