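"""Post-clustering statistics: homogeneity, rank tests, and partial correlations.

Everything downstream of the clustering lives here:

* subject-by-subject Pearson correlation of raw (non-standardized) cognitive
  profiles, compared between diagnostic groups block-wise (pooled t-tests on
  flattened correlation blocks, Levene tests on per-subject homogeneity
  summaries);
* Kruskal-Wallis omnibus tests with Dunn's rank-based post-hoc comparisons
  (Bonferroni corrected) for cognitive/clinical/medication scores across the
  cluster-derived groups;
* Pearson chi-square tests of independence for categorical demographics;
* a two-way ranked ANOVA (group × brain network) for covariate-corrected
  grey-matter volumes, with per-network Welch ANOVA post-hocs on ranks;
* partial Pearson correlations controlling for medication dose, with
  multiple-comparison correction.

The rank statistics are computed from their defining formulas (tie-corrected)
rather than delegated, so they can be validated against independent library
implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrBlockResult",
    "StatReport",
    "PartialCorrResult",
    "subject_correlation_blocks",
    "kruskal_dunn",
    "chi2_independence",
    "ranked_anova_interaction",
    "welch_anova",
    "partial_correlation_matrix",
    "levene_homogeneity",
    "adjust_pvalues",
]


@dataclass
class StatReport:
    test_name: str
    statistic: float
    df: float
    p_value: float
    df2: float | None = None
    posthoc: dict = field(default_factory=dict)  # key -> dict with statistic/p
    correction: str | None = None
    group_sizes: dict = field(default_factory=dict)


@dataclass
class CorrBlockResult:
    corr: pd.DataFrame  # subject x subject
    block_means: dict  # (group_a, group_b) -> mean of flattened block
    block_t: dict  # (group_a, group_b) -> StatReport (pooled t on within-blocks)
    levene: dict  # (group_a, group_b) -> StatReport (on per-subject summaries)
    subject_homogeneity: pd.Series  # per-subject mean within-group correlation


@dataclass
class PartialCorrResult:
    pairs: pd.DataFrame  # columns: var_a, var_b, partial_r, p_raw, p_corrected
    covariates: list[str]
    n_effective: int
    correction: str

    def matrix(self) -> pd.DataFrame:
        """Symmetric partial-correlation matrix (unit diagonal)."""
        names = sorted(set(self.pairs["var_a"]) | set(self.pairs["var_b"]))
        mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for _, row in self.pairs.iterrows():
            mat.loc[row["var_a"], row["var_b"]] = row["partial_r"]
            mat.loc[row["var_b"], row["var_a"]] = row["partial_r"]
        return mat


# ---------------------------------------------------------------------------
# Multiple-comparison corrections
# ---------------------------------------------------------------------------

def adjust_pvalues(p: np.ndarray, method: str = "holm") -> np.ndarray:
    """Bonferroni, Holm step-down, or Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, float)
    k = p.size
    if k == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * k, 1.0)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(k)
    if method == "holm":
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (k - rank) * p[idx])
            adjusted[idx] = min(running, 1.0)
        return adjusted
    if method == "fdr_bh":
        running = 1.0
        for rank in range(k - 1, -1, -1):
            idx = order[rank]
            running = min(running, p[idx] * k / (rank + 1))
            adjusted[idx] = min(running, 1.0)
        return adjusted
    raise ValueError(f"unknown correction method {method!r}")


# ---------------------------------------------------------------------------
# Subject correlation blocks and homogeneity
# ---------------------------------------------------------------------------

def _pooled_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Two-sided pooled-variance (Student) t-test; returns (t, df, p)."""
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    if se == 0.0:  # both blocks constant
        t = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
    else:
        t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def subject_correlation_blocks(X, groups) -> CorrBlockResult:
    """Group-blocked subject-by-subject Pearson correlation analysis.

    Correlates every pair of subjects' raw feature profiles, then compares the
    within-group correlation blocks between group pairs with pooled t-tests on
    the flattened full square blocks (diagonal and both triangles included, so
    a pair of groups sized n_a and n_b yields df = n_a^2 + n_b^2 - 2), and
    compares per-subject homogeneity summaries (each subject's mean
    correlation with the other members of its own group) with Levene tests,
    Bonferroni corrected over group pairs.
    """
    X = pd.DataFrame(X)
    groups = pd.Series(np.asarray(groups), index=X.index, name="group")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 variables to correlate profiles")
    arr = X.to_numpy(float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = X.index[sd == 0].tolist()
        raise ValueError(f"constant subject profile(s): {bad}")
    corr = pd.DataFrame(np.corrcoef(arr), index=X.index, columns=X.index)

    levels = list(dict.fromkeys(groups))
    idx = {g: np.flatnonzero(groups.to_numpy() == g) for g in levels}

    block_means: dict = {}
    for ga, gb in combinations(levels, 2):
        block_means[(ga, gb)] = float(
            corr.to_numpy()[np.ix_(idx[ga], idx[gb])].mean()
        )
    within_flat = {}
    for g in levels:
        block = corr.to_numpy()[np.ix_(idx[g], idx[g])]
        block_means[(g, g)] = float(block.mean())
        within_flat[g] = block.ravel()

    block_t: dict = {}
    for ga, gb in combinations(levels, 2):
        t, df, p = _pooled_ttest(within_flat[ga], within_flat[gb])
        block_t[(ga, gb)] = StatReport(
            test_name="pooled_t_block_means", statistic=t, df=df, p_value=p,
            group_sizes={ga: int(idx[ga].size), gb: int(idx[gb].size)},
        )

    # per-subject homogeneity: mean correlation with own-group peers
    homog = np.empty(len(groups))
    cmat = corr.to_numpy()
    for g in levels:
        ii = idx[g]
        block = cmat[np.ix_(ii, ii)]
        homog[ii] = (block.sum(axis=1) - 1.0) / (ii.size - 1)
    homog = pd.Series(homog, index=X.index, name="mean_within_group_r")

    pairs = list(combinations(levels, 2))
    raw_reports = []
    for ga, gb in pairs:
        rep = levene_homogeneity({ga: homog.iloc[idx[ga]].to_numpy(),
                                  gb: homog.iloc[idx[gb]].to_numpy()})
        raw_reports.append(rep)
    corrected = adjust_pvalues(
        np.array([r.p_value for r in raw_reports]), "bonferroni"
    )
    levene: dict = {}
    for (ga, gb), rep, pc in zip(pairs, raw_reports, corrected):
        rep.correction = "bonferroni"
        rep.posthoc = {"p_corrected": float(pc)}
        levene[(ga, gb)] = rep

    return CorrBlockResult(
        corr=corr, block_means=block_means, block_t=block_t,
        levene=levene, subject_homogeneity=homog,
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def _tie_term(ranks: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_dunn(values, group_labels, correction: str = "bonferroni") -> StatReport:
    """Kruskal-Wallis H (tie corrected) with Dunn's post-hoc z tests.

    Dunn's pairwise z statistics compare mean ranks using the tie-corrected
    pooled rank variance; two-sided normal p-values are corrected over all
    C(g, 2) pairs (Bonferroni by default).
    """
    values = np.asarray(values, float)
    group_labels = np.asarray(group_labels)
    levels = list(dict.fromkeys(group_labels))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    n_i = {g: int((group_labels == g).sum()) for g in levels}
    if min(n_i.values()) < 1:
        raise ValueError("every group needs at least one observation")

    N = values.size
    ranks = stats.rankdata(values)
    tie = _tie_term(values)

    h = 0.0
    for g in levels:
        r = ranks[group_labels == g]
        h += r.sum() ** 2 / r.size
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    denom = 1.0 - tie / (N**3 - N)
    if denom <= 0:  # all values identical
        h, p = 0.0, 1.0
    else:
        h /= denom
        p = float(stats.chi2.sf(h, len(levels) - 1))

    mean_rank = {g: float(ranks[group_labels == g].mean()) for g in levels}
    pooled_var = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))
    pairs = list(combinations(levels, 2))
    raw = []
    zstats = []
    for ga, gb in pairs:
        se = np.sqrt(pooled_var * (1.0 / n_i[ga] + 1.0 / n_i[gb]))
        z = (mean_rank[ga] - mean_rank[gb]) / se if se > 0 else 0.0
        zstats.append(float(z))
        raw.append(2.0 * stats.norm.sf(abs(z)))
    corrected = adjust_pvalues(np.array(raw), correction)
    posthoc = {
        (ga, gb): {"statistic": z, "p_raw": float(pr), "p_corrected": float(pc)}
        for (ga, gb), z, pr, pc in zip(pairs, zstats, raw, corrected)
    }
    return StatReport(
        test_name="kruskal_wallis", statistic=float(h), df=len(levels) - 1,
        p_value=float(p), posthoc=posthoc, correction=correction,
        group_sizes=n_i,
    )


# ---------------------------------------------------------------------------
# Chi-square test of independence
# ---------------------------------------------------------------------------

def chi2_independence(contingency) -> StatReport:
    """Pearson chi-square of independence (no continuity correction)."""
    obs = np.asarray(contingency, float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal in contingency table")
    expected = np.outer(row, col) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return StatReport(
        test_name="chi2_independence", statistic=chi2, df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
    )


# ---------------------------------------------------------------------------
# Ranked two-way ANOVA (group x network) + Welch post-hocs
# ---------------------------------------------------------------------------

def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Treatment-coded dummy columns (reference level dropped)."""
    return (codes[:, None] == np.arange(1, n_levels)[None, :]).astype(float)


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def welch_anova(values_by_group: dict) -> StatReport:
    """Welch's heteroscedastic one-way ANOVA; returns F, df1, df2, p."""
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n = np.array([len(values_by_group[g]) for g in groups], float)
    if (n < 2).any():
        raise ValueError("every group needs at least 2 observations")
    mean = np.array([np.mean(values_by_group[g]) for g in groups])
    var = np.array([np.var(values_by_group[g], ddof=1) for g in groups])
    w = n / var
    W = w.sum()
    grand = (w * mean).sum() / W
    g = len(groups)
    a = ((w * (mean - grand) ** 2).sum()) / (g - 1)
    tail = (((1 - w / W) ** 2) / (n - 1)).sum()
    b = 1.0 + 2.0 * (g - 2) / (g**2 - 1) * tail
    f = a / b
    df2 = (g**2 - 1) / (3.0 * tail)
    return StatReport(
        test_name="welch_anova", statistic=float(f), df=g - 1, df2=float(df2),
        p_value=float(stats.f.sf(f, g - 1, df2)),
        group_sizes={g_: int(len(values_by_group[g_])) for g_ in groups},
    )


def ranked_anova_interaction(
    volumes, group4_labels, alpha: float = 0.05
) -> StatReport:
    """Two-way ANOVA on jointly ranked volumes: group x network interaction.

    All volume values (subject × network, typically covariate-corrected
    residuals) are rank-transformed jointly, cast to long format, and the
    group × network interaction is tested by comparing the residual sum of
    squares of the full two-way model against the main-effects-only model.
    When the interaction is significant at ``alpha``, per-network Welch ANOVAs
    on the same ranks locate which networks differ between groups (Bonferroni
    corrected over networks).
    """
    volumes = pd.DataFrame(volumes)
    labels = pd.Series(np.asarray(group4_labels), index=volumes.index)
    levels = list(dict.fromkeys(labels))
    if any((labels == g).sum() == 0 for g in levels):
        raise ValueError("empty group")
    if volumes.shape[1] < 2:
        raise ValueError("need at least 2 networks")

    n, p = volumes.shape
    ranks = stats.rankdata(volumes.to_numpy(float).ravel()).reshape(n, p)

    g_codes = labels.map({g: i for i, g in enumerate(levels)}).to_numpy()
    long_rank = ranks.ravel()
    long_group = np.repeat(g_codes, p)
    long_net = np.tile(np.arange(p), n)

    G = _dummies(long_group, len(levels))
    V = _dummies(long_net, p)
    inter = np.einsum("ij,ik->ijk", G, V).reshape(len(long_rank), -1)
    ones = np.ones((len(long_rank), 1))

    X_full = np.hstack([ones, G, V, inter])
    X_main = np.hstack([ones, G, V])
    rss_full, rank_full = _ols_rss(X_full, long_rank)
    rss_main, rank_main = _ols_rss(X_main, long_rank)
    df_inter = rank_full - rank_main
    df_resid = len(long_rank) - rank_full
    f = ((rss_main - rss_full) / df_inter) / (rss_full / df_resid)
    p_val = float(stats.f.sf(f, df_inter, df_resid))

    report = StatReport(
        test_name="ranked_anova_interaction", statistic=float(f),
        df=df_inter, df2=float(df_resid), p_value=p_val,
        correction="bonferroni",
        group_sizes={g: int((labels == g).sum()) for g in levels},
    )
    if p_val < alpha:
        raw_reports = []
        for j, net in enumerate(volumes.columns):
            by_group = {g: ranks[g_codes == i, j] for i, g in enumerate(levels)}
            raw_reports.append(welch_anova(by_group))
        corrected = adjust_pvalues(
            np.array([r.p_value for r in raw_reports]), "bonferroni"
        )
        for net, rep, pc in zip(volumes.columns, raw_reports, corrected):
            report.posthoc[net] = {
                "statistic": rep.statistic, "df1": rep.df, "df2": rep.df2,
                "p_raw": rep.p_value, "p_corrected": float(pc),
                "significant": bool(pc < alpha),
            }
    return report


# ---------------------------------------------------------------------------
# Partial correlations
# ---------------------------------------------------------------------------

def partial_correlation_matrix(
    variables, covariates=None, correction: str = "holm"
) -> PartialCorrResult:
    """Pairwise partial Pearson correlations controlling for covariates.

    Each variable is regressed (OLS with intercept) on the covariate set; the
    partial correlation of a pair is the Pearson correlation of their
    residuals.  With an empty covariate set this reduces exactly to plain
    Pearson correlation.  P-values use the t transform with
    df = n - 2 - n_covariates and are adjusted over all pairs.
    """
    variables = pd.DataFrame(variables)
    n = variables.shape[0]
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        covariates = pd.DataFrame(index=variables.index)
    else:
        covariates = pd.DataFrame(covariates)
        if covariates.isna().any().any():
            raise ValueError("covariates contain missing values")
    k = covariates.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > n_covariates + 2 (n={n}, covariates={k})")

    design = np.column_stack([np.ones(n)] + [covariates[c].to_numpy(float)
                                             for c in covariates.columns])
    Y = variables.to_numpy(float)
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta

    names = list(variables.columns)
    pairs = list(combinations(range(len(names)), 2))
    rows = []
    df = n - 2 - k
    for a, b in pairs:
        ra, rb = resid[:, a], resid[:, b]
        va, vb = ra @ ra, rb @ rb
        if va <= 0 or vb <= 0:
            rows.append((names[a], names[b], np.nan, np.nan))
            continue
        r = float((ra @ rb) / np.sqrt(va * vb))
        r = float(np.clip(r, -1.0, 1.0))
        if abs(r) >= 1.0:
            p_raw = 0.0
        else:
            t = r * np.sqrt(df / (1.0 - r * r))
            p_raw = float(2.0 * stats.t.sf(abs(t), df))
        rows.append((names[a], names[b], r, p_raw))
    table = pd.DataFrame(rows, columns=["var_a", "var_b", "partial_r", "p_raw"])
    valid = table["p_raw"].notna()
    table["p_corrected"] = np.nan
    table.loc[valid, "p_corrected"] = adjust_pvalues(
        table.loc[valid, "p_raw"].to_numpy(), correction
    )
    return PartialCorrResult(
        pairs=table, covariates=list(covariates.columns),
        n_effective=n, correction=correction,
    )


# ---------------------------------------------------------------------------
# Levene's test
# ---------------------------------------------------------------------------

def levene_homogeneity(values_by_group: dict) -> StatReport:
    """Classic Levene W (deviations from group means) for equal variances."""
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(values_by_group[g], float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    g = len(arrays)
    N = sum(a.size for a in arrays)
    z = [np.abs(a - a.mean()) for a in arrays]
    zbar_i = np.array([zi.mean() for zi in z])
    zbar = sum(zi.sum() for zi in z) / N
    num = sum(a.size * (zb - zbar) ** 2 for a, zb in zip(arrays, zbar_i))
    den = sum(((zi - zb) ** 2).sum() for zi, zb in zip(z, zbar_i))
    if den == 0:
        w, p = 0.0, 1.0
    else:
        w = (N - g) / (g - 1) * num / den
        p = float(stats.f.sf(w, g - 1, N - g))
    return StatReport(
        test_name="levene", statistic=float(w), df=g - 1, df2=float(N - g),
        p_value=float(p),
        group_sizes={gr: int(a.size) for gr, a in zip(groups, arrays)},
    )
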