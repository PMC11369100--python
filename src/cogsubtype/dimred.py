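"""PCA with permutation-based component significance and feature ranking.

Cognitive batteries are strongly intercorrelated, so the pipeline reduces the
normalized feature/covariate matrix with principal component analysis before
clustering.  Which components carry signal rather than noise is decided by a
permutation test: each column of the input is independently shuffled across
subjects (destroying between-variable covariance while preserving marginals),
the PCA is refit, and a component is declared significant when its observed
explained-variance ratio exceeds the upper (1 - alpha) quantile of its own
permutation null.  Features are then ranked by how much of the significant
variance they carry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["PCAResult", "fit_pca", "permute_significance", "rank_feature_contributions"]


@dataclass
class PCAResult:
    """Loadings, scores, explained variance and permutation significance."""

    loadings: pd.DataFrame  # variable x component
    scores: pd.DataFrame  # subject x component
    evr: np.ndarray  # explained-variance ratio per component
    n_significant: int = 0
    significant: np.ndarray | None = None  # boolean flags per component
    null_evr: np.ndarray | None = None  # n_perm x component
    alpha: float | None = None
    n_perm: int | None = None
    seed: int | None = None

    @property
    def significant_scores(self) -> pd.DataFrame:
        """Subject coordinates on the significant components only."""
        if self.significant is None:
            raise ValueError("run permute_significance first")
        return self.scores.loc[:, self.significant]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, float)
    return pd.DataFrame(
        X,
        index=[f"s{i}" for i in range(X.shape[0])],
        columns=[f"v{j}" for j in range(X.shape[1])],
    )


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Force each component's largest-magnitude loading to be positive."""
    out = components.copy()
    for k in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[k])))
        if out[k, j] < 0:
            out[k] = -out[k]
    return out


def fit_pca(X) -> PCAResult:
    """Full PCA of a complete subject × variable matrix.

    Components are ordered by decreasing explained variance; the sign of each
    loading vector is fixed so its largest-magnitude entry is positive, making
    results invariant (up to that convention) to subject order.
    """
    df = _as_frame(X)
    arr = df.to_numpy(float)
    if not np.isfinite(arr).all():
        raise ValueError("input matrix contains non-finite entries")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 variables")

    model = PCA(svd_solver="full")
    model.fit(arr)
    comps = _fix_signs(model.components_)
    centered = arr - arr.mean(axis=0)
    scores = centered @ comps.T
    pc_names = [f"PC{k + 1}" for k in range(comps.shape[0])]
    return PCAResult(
        loadings=pd.DataFrame(comps.T, index=df.columns, columns=pc_names),
        scores=pd.DataFrame(scores, index=df.index, columns=pc_names),
        evr=model.explained_variance_ratio_.copy(),
    )


def _null_evr(arr: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Explained-variance ratios of column-wise permuted copies of ``arr``."""
    n, p = arr.shape
    k = min(n - 1 if n > 1 else 1, p)
    null = np.empty((n_perm, k))
    shuffled = arr.copy()
    for b in range(n_perm):
        for j in range(p):
            rng.shuffle(shuffled[:, j])
        centered = shuffled - shuffled.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        var = s**2
        null[b] = (var / var.sum())[:k]
    return null


def permute_significance(
    X,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PCAResult:
    """Flag components whose explained variance beats a permutation null.

    For each of ``n_perm`` permutations every column of ``X`` is shuffled
    independently across subjects and the PCA refit; component k is significant
    when its observed explained-variance ratio exceeds the empirical
    (1 - alpha) quantile of the permutation distribution for component k.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    if n_perm < 100:
        import warnings

        warnings.warn(
            f"n_perm={n_perm} < 100 yields unstable null quantiles",
            stacklevel=2,
        )
    result = fit_pca(X)
    arr = _as_frame(X).to_numpy(float)
    rng = np.random.default_rng(seed)
    null = _null_evr(arr, n_perm, rng)
    k = min(len(result.evr), null.shape[1])
    thresholds = np.quantile(null[:, :k], 1.0 - alpha, axis=0)
    flags = np.zeros(len(result.evr), dtype=bool)
    flags[:k] = result.evr[:k] > thresholds
    result.significant = flags
    result.n_significant = int(flags.sum())
    result.null_evr = null
    result.alpha = alpha
    result.n_perm = n_perm
    result.seed = seed
    return result


def rank_feature_contributions(result: PCAResult, top_k: int = 10) -> pd.Series:
    """Rank features by variance carried through the significant components.

    The contribution of feature f is sum_k evr[k] * loading[f, k]^2 over
    significant components k; with orthonormal loadings these contributions
    sum (over all features) to the total significant explained-variance ratio.
    Ties are broken lexicographically by variable name.
    """
    if result.significant is None or result.n_significant == 0:
        raise ValueError(
            "no significant components; run permute_significance and check "
            "that the data carry structure before ranking features"
        )
    sig = np.flatnonzero(result.significant)
    load = result.loadings.to_numpy()[:, sig]
    weights = result.evr[sig]
    contrib = pd.Series(
        (load**2) @ weights, index=result.loadings.index, name="contribution"
    )
    contrib = contrib.sort_index()  # lexicographic tie-break baseline
    contrib = contrib.sort_values(ascending=False, kind="stable")
    return contrib.head(top_k)
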