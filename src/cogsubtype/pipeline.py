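"""End-to-end orchestration: cohort -> preprocess -> PCA -> clustering -> stats.

A single :class:`RunConfig` drives the whole analysis.  All randomness flows
from one global seed, from which per-stage seeds are derived, so a rerun with
the same configuration reproduces every output byte for byte.  Each stage
writes plain-text artifacts (CSV/TSV/JSON) into the run directory together
with a manifest recording the configuration, derived seeds and per-stage
shapes; ``write_report`` renders a human-readable markdown summary from those
artifacts alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dimred import permute_significance, rank_feature_contributions
from .fuzzycluster import fuzzy_kmeans, group_cluster_ratio
from .groupstats import (
    kruskal_dunn,
    partial_correlation_matrix,
    ranked_anova_interaction,
    subject_correlation_blocks,
)
from .preprocess import (
    CohortTable,
    filter_missing,
    impute_stratified,
    normalize_features,
    residualize_volumes,
)
from .synthetic import (
    CLINICAL_COLUMNS,
    MEDICATION_COLUMNS,
    CohortConfig,
    generate_cohort,
    inject_missingness,
    read_cohort,
    write_cohort,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "write_report"]


class PipelineError(RuntimeError):
    """A stage failed; message carries the stage name and context."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``synthetic`` (a :class:`CohortConfig`) or ``input_dir``
    (a directory produced by :func:`cogsubtype.synthetic.write_cohort`) must
    be set.  The global ``seed`` drives every stochastic stage, including the
    synthetic generator (whose own seed field is overridden by a derived
    seed so one number controls the run).
    """

    outdir: str | Path = "run"
    seed: int = 0
    synthetic: CohortConfig | None = None
    input_dir: str | Path | None = None
    # preprocess
    var_thresh: float = 0.10
    subj_thresh: float = 0.20
    # dimensionality reduction
    n_perm: int = 5000
    alpha: float = 0.05
    include_covariates: bool = True
    # clustering
    k: int = 3
    fuzzifier: float = 2.0
    tol: float = 1e-6
    max_iter: int = 300
    n_restarts: int = 10
    rows: str = "all"  # or "patients_only"
    top_k_features: int = 10
    # statistics
    stats_alpha: float = 0.05
    correction: str = "holm"

    def validate(self) -> None:
        if (self.synthetic is None) == (self.input_dir is None):
            raise PipelineError(
                "config: exactly one of synthetic / input_dir must be set"
            )
        if self.rows not in ("all", "patients_only"):
            raise PipelineError(f"config: unknown rows mode {self.rows!r}")

    def derived_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        states = ss.generate_state(3) & 0x7FFFFFFF  # keep below 2**31
        return {
            "synthetic": int(states[0]),
            "dimred": int(states[1]),
            "cluster": int(states[2]),
        }

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        if self.input_dir is not None:
            d["input_dir"] = str(self.input_dir)
        if self.synthetic is not None:
            syn = d["synthetic"]
            syn["affected_networks"] = {
                str(kk): list(v) for kk, v in syn["affected_networks"].items()
            }
        return d


@dataclass
class PipelineResult:
    """In-memory handles on every stage output of a completed run."""

    config: RunConfig
    table: CohortTable  # normalized analysis table
    raw_table: CohortTable  # imputed but not normalized
    pca: object
    top_features: pd.Series
    fuzzy: object
    ratio: object
    group4: pd.Series
    reports: dict = field(default_factory=dict)
    run_dir: Path | None = None


def _df_to_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, lineterminator="\n")


_LOG_COLUMNS = {
    "exclusions": ["event", "name", "missing_fraction", "threshold"],
    "imputations": ["event", "name", "stratum", "kind", "fill", "n_cells"],
}


def _log_to_tsv(log: list[dict], path: Path, events: tuple[str, ...]) -> None:
    rows = [e for e in log if e.get("event") in events]
    df = pd.DataFrame(rows, columns=_LOG_COLUMNS.get(path.stem))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage in order and write all artifacts to ``outdir``."""
    config.validate()
    seeds = config.derived_seeds()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_jsonable(),
        "derived_seeds": seeds,
        "stages": {},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()

    def fail(stage: str, exc: Exception) -> PipelineError:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        return PipelineError(f"stage {stage!r} failed: {exc}")

    # -- stage 1: cohort ---------------------------------------------------
    try:
        if config.synthetic is not None:
            syn = dataclasses.replace(config.synthetic, seed=seeds["synthetic"])
            table, truth = generate_cohort(syn)
            table = inject_missingness(table, syn)
            write_cohort(table, outdir / "cohort", truth=truth, config=syn)
        else:
            table = read_cohort(config.input_dir)
            truth = None
    except Exception as exc:  # noqa: BLE001
        raise fail("cohort", exc) from exc
    manifest["stages"]["cohort"] = {"shape": list(table.values.shape)}

    # -- stage 2: preprocess ----------------------------------------------
    try:
        filtered = filter_missing(table, config.var_thresh, config.subj_thresh)
        imputed = impute_stratified(filtered)
        normalized = normalize_features(imputed)
    except Exception as exc:  # noqa: BLE001
        raise fail("preprocess", exc) from exc
    pre_dir = outdir / "preprocess"
    pre_dir.mkdir(exist_ok=True)
    _log_to_tsv(filtered.log, pre_dir / "exclusions.tsv",
                ("drop_variable", "drop_subject"))
    _log_to_tsv(imputed.log, pre_dir / "imputations.tsv", ("impute",))
    _df_to_csv(normalized.values, pre_dir / "normalized.csv")
    manifest["stages"]["preprocess"] = {
        "n_subjects": normalized.n_subjects,
        "n_variables": len(normalized.columns_by_role("feature", "covariate")),
        "n_dropped_variables": sum(
            1 for e in filtered.log if e["event"] == "drop_variable"
        ),
        "n_dropped_subjects": sum(
            1 for e in filtered.log if e["event"] == "drop_subject"
        ),
    }

    # -- stage 3: PCA + permutation test ----------------------------------
    pca_cols = normalized.columns_by_role("feature")
    if config.include_covariates:
        # demographic covariates join the PCA input; TIV is a brain nuisance
        # regressor, not a cognitive covariate, and stays out
        pca_cols += [c for c in normalized.columns_by_role("covariate")
                     if c != "tiv"]
    try:
        pca = permute_significance(
            normalized.values[pca_cols],
            n_perm=config.n_perm, alpha=config.alpha, seed=seeds["dimred"],
        )
        top = rank_feature_contributions(pca, top_k=config.top_k_features)
    except Exception as exc:  # noqa: BLE001
        raise fail("dimred", exc) from exc
    dim_dir = outdir / "dimred"
    dim_dir.mkdir(exist_ok=True)
    _df_to_csv(pca.loadings, dim_dir / "loadings.csv")
    _df_to_csv(pca.scores, dim_dir / "scores.csv")
    evr = pd.DataFrame(
        {"evr": pca.evr, "significant": pca.significant},
        index=pca.scores.columns,
    )
    _df_to_csv(evr, dim_dir / "evr.csv")
    _df_to_csv(top.to_frame(), dim_dir / "top_features.csv")
    manifest["stages"]["dimred"] = {
        "n_components": int(len(pca.evr)),
        "n_significant": int(pca.n_significant),
        "significant_evr_sum": float(pca.evr[pca.significant].sum()),
    }

    # -- stage 4: fuzzy clustering on significant PC scores ---------------
    scores = pca.significant_scores
    groups = normalized.group
    if config.rows == "patients_only":
        keep = groups != "control"
        scores = scores.loc[keep]
        groups = groups.loc[keep]
    try:
        fuzzy = fuzzy_kmeans(
            scores.to_numpy(), k=config.k, m=config.fuzzifier,
            tol=config.tol, max_iter=config.max_iter,
            n_restarts=config.n_restarts, seed=seeds["cluster"],
        )
        ratio = group_cluster_ratio(fuzzy.labels, groups.to_numpy())
    except Exception as exc:  # noqa: BLE001
        raise fail("cluster", exc) from exc
    clu_dir = outdir / "cluster"
    clu_dir.mkdir(exist_ok=True)
    membership = pd.DataFrame(
        fuzzy.membership, index=scores.index,
        columns=[f"cluster{j}" for j in range(config.k)],
    )
    _df_to_csv(membership, clu_dir / "membership.csv")
    labels = pd.Series(fuzzy.labels, index=scores.index, name="cluster")
    _df_to_csv(labels.to_frame(), clu_dir / "labels.csv")
    _df_to_csv(pd.DataFrame(fuzzy.centers, columns=scores.columns),
               clu_dir / "centers.csv")
    _df_to_csv(ratio.counts, clu_dir / "ratio_counts.csv")
    _df_to_csv(ratio.percent(), clu_dir / "ratio_percent.csv")
    manifest["stages"]["cluster"] = {
        "k": config.k, "converged": bool(fuzzy.converged),
        "n_iter": int(fuzzy.n_iter),
        "objective": float(fuzzy.objective_trace[-1]),
    }

    # -- stage 5: statistics ----------------------------------------------
    reports: dict = {}
    stats_dir = outdir / "stats"
    stats_dir.mkdir(exist_ok=True)
    raw = imputed  # non-standardized values for correlations / rank tests
    try:
        feat_cols = raw.columns_by_role("feature")
        blocks = subject_correlation_blocks(
            raw.values.loc[scores.index, feat_cols], groups
        )
        reports["corr_blocks"] = blocks

        # four analysis groups: pooled controls + per-cluster patients
        group4 = pd.Series(index=scores.index, dtype=object)
        is_ctrl = groups == "control"
        group4[is_ctrl] = "controls"
        group4[~is_ctrl] = [f"cluster{j}" for j in labels[~is_ctrl]]

        top_feats = [f for f in top.index if raw.schema[f].role == "feature"]
        omnibus_rows = []
        posthoc_rows = []
        for col in top_feats:
            rep = kruskal_dunn(
                raw.values.loc[scores.index, col].to_numpy(),
                group4.to_numpy(),
            )
            omnibus_rows.append(
                {"variable": col, "test": rep.test_name,
                 "statistic": rep.statistic, "df": rep.df, "p": rep.p_value}
            )
            for (ga, gb), ph in rep.posthoc.items():
                posthoc_rows.append(
                    {"variable": col, "group_a": ga, "group_b": gb, **ph}
                )
        # clinical/medication scores compared across patient clusters only
        patient_idx = scores.index[~is_ctrl]
        for col in (*CLINICAL_COLUMNS, *MEDICATION_COLUMNS):
            if col not in raw.values.columns:
                continue
            vals = raw.values.loc[patient_idx, col]
            ok = vals.notna()
            rep = kruskal_dunn(
                vals[ok].to_numpy(), group4.loc[patient_idx][ok].to_numpy()
            )
            omnibus_rows.append(
                {"variable": col, "test": rep.test_name,
                 "statistic": rep.statistic, "df": rep.df, "p": rep.p_value}
            )
            for (ga, gb), ph in rep.posthoc.items():
                posthoc_rows.append(
                    {"variable": col, "group_a": ga, "group_b": gb, **ph}
                )
        omnibus = pd.DataFrame(omnibus_rows)
        posthoc = pd.DataFrame(posthoc_rows)
        omnibus.to_csv(stats_dir / "omnibus.tsv", sep="\t", index=False,
                       lineterminator="\n")
        posthoc.to_csv(stats_dir / "posthoc.tsv", sep="\t", index=False,
                       lineterminator="\n")
        reports["omnibus"] = omnibus
        reports["posthoc"] = posthoc

        # brain-network analysis on covariate-corrected volumes
        net_cols = raw.columns_by_role("network_volume")
        anova = None
        if net_cols and {"tiv", "age", "sex"} <= set(raw.values.columns):
            vols = raw.values.loc[scores.index, net_cols]
            corrected = residualize_volumes(
                vols,
                tiv=raw.values.loc[scores.index, "tiv"],
                age=raw.values.loc[scores.index, "age"],
                sex=raw.values.loc[scores.index, "sex"],
            )
            anova = ranked_anova_interaction(
                corrected, group4.to_numpy(), alpha=config.stats_alpha
            )
            reports["ranked_anova"] = anova
            payload = {
                "F": anova.statistic, "df1": anova.df, "df2": anova.df2,
                "p": anova.p_value,
                "posthoc": {str(kk): v for kk, v in anova.posthoc.items()},
            }
            (stats_dir / "ranked_anova.json").write_text(
                json.dumps(payload, indent=1)
            )

            # partial correlations across patients, controlling medication
            sig_nets = [kk for kk, v in anova.posthoc.items()
                        if v.get("significant")]
            cpz = raw.values.loc[patient_idx, "cpz_equivalent"] \
                if "cpz_equivalent" in raw.values.columns else None
            if cpz is not None and cpz.notna().all() and len(patient_idx) > 5:
                part_cols = (
                    raw.values.loc[patient_idx, top_feats]
                    .join(corrected.loc[patient_idx, sig_nets])
                )
                clin = [c for c in CLINICAL_COLUMNS
                        if c in raw.values.columns]
                part_cols = part_cols.join(raw.values.loc[patient_idx, clin])
                part_cols = part_cols.dropna(axis=0)
                if part_cols.shape[0] > part_cols.shape[1]:
                    partial = partial_correlation_matrix(
                        part_cols,
                        covariates=cpz.loc[part_cols.index].to_frame(),
                        correction=config.correction,
                    )
                    reports["partial_corr"] = partial
                    partial.pairs.to_csv(
                        stats_dir / "partial_corr.tsv", sep="\t",
                        index=False, lineterminator="\n",
                    )
    except Exception as exc:  # noqa: BLE001
        raise fail("stats", exc) from exc
    manifest["stages"]["stats"] = {
        "n_omnibus_tests": int(len(reports["omnibus"])),
        "interaction_p": (
            float(reports["ranked_anova"].p_value)
            if "ranked_anova" in reports else None
        ),
    }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    result = PipelineResult(
        config=config, table=normalized, raw_table=imputed, pca=pca,
        top_features=top, fuzzy=fuzzy, ratio=ratio, group4=group4,
        reports=reports, run_dir=outdir,
    )
    write_report(outdir)
    return result


def write_report(run_dir: str | Path) -> Path:
    """Render a markdown summary from the artifacts of a completed run.

    Reads only files inside ``run_dir``; regenerating the report from an
    untouched run directory is byte-identical.
    """
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    lines: list[str] = ["# Cognitive subtyping run report", ""]
    lines.append(f"Package version: {manifest['package_version']}  ")
    lines.append(f"Config hash: `{manifest['config_hash']}`  ")
    lines.append(f"Global seed: {manifest['config']['seed']}")
    lines.append("")

    pre = manifest["stages"].get("preprocess")
    if pre:
        lines += [
            "## Preprocessing",
            "",
            f"- variables retained: {pre['n_variables']} "
            f"(dropped {pre['n_dropped_variables']})",
            f"- subjects retained: {pre['n_subjects']} "
            f"(dropped {pre['n_dropped_subjects']})",
            "",
        ]

    evr_path = run_dir / "dimred" / "evr.csv"
    if evr_path.exists():
        evr = pd.read_csv(evr_path, index_col=0)
        sig = evr[evr["significant"]]
        lines += [
            "## Dimensionality reduction",
            "",
            f"- significant components: {len(sig)} of {len(evr)}",
            f"- variance captured by significant components: "
            f"{100 * sig['evr'].sum():.1f}%",
            "",
            "| component | explained variance (%) | significant |",
            "|---|---|---|",
        ]
        for name, row in evr.head(10).iterrows():
            lines.append(
                f"| {name} | {100 * row['evr']:.1f} | "
                f"{'yes' if row['significant'] else 'no'} |"
            )
        lines.append("")

    top_path = run_dir / "dimred" / "top_features.csv"
    if top_path.exists():
        top = pd.read_csv(top_path, index_col=0)
        lines += ["## Top contributing features", ""]
        for name, row in top.iterrows():
            lines.append(f"- {name}: {row['contribution']:.4f}")
        lines.append("")
    else:
        lines += ["## Top contributing features", "", "_unavailable_", ""]

    pct_path = run_dir / "cluster" / "ratio_percent.csv"
    if pct_path.exists():
        pct = pd.read_csv(pct_path, index_col=0)
        counts = pd.read_csv(run_dir / "cluster" / "ratio_counts.csv", index_col=0)
        lines += [
            "## Cluster composition (percent of each group per cluster)",
            "",
            "| group | " + " | ".join(pct.columns) + " |",
            "|" + "---|" * (len(pct.columns) + 1),
        ]
        for g in pct.index:
            cells = [
                f"{pct.loc[g, c]}% ({counts.loc[g, c]})" for c in pct.columns
            ]
            lines.append(f"| {g} | " + " | ".join(cells) + " |")
        lines.append("")
    else:
        lines += ["## Cluster composition", "", "_unavailable_", ""]

    omni_path = run_dir / "stats" / "omnibus.tsv"
    if omni_path.exists():
        omni = pd.read_csv(omni_path, sep="\t")
        lines += [
            "## Group comparisons (Kruskal-Wallis omnibus)",
            "",
            "| variable | H | df | p |",
            "|---|---|---|---|",
        ]
        for _, row in omni.iterrows():
            lines.append(
                f"| {row['variable']} | {row['statistic']:.3f} | "
                f"{int(row['df'])} | {row['p']:.2e} |"
            )
        lines.append("")

    anova_path = run_dir / "stats" / "ranked_anova.json"
    if anova_path.exists():
        payload = json.loads(anova_path.read_text())
        lines += [
            "## Brain-network ranked ANOVA (group x network interaction)",
            "",
            f"- F = {payload['F']:.3f}, df = ({int(payload['df1'])}, "
            f"{int(payload['df2'])}), p = {payload['p']:.2e}",
        ]
        sig_nets = [kk for kk, v in payload.get("posthoc", {}).items()
                    if v.get("significant")]
        lines.append(
            f"- networks significant after Bonferroni post-hoc: "
            f"{', '.join(sig_nets) if sig_nets else 'none'}"
        )
        lines.append("")

    text = "\n".join(lines) + "\n"
    path = run_dir / "report.md"
    path.write_text(text)
    return path
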