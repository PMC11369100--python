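"""Synthetic early-psychosis cohort generator with planted ground truth.

Restricted-access clinical cohorts cannot ship with an analysis pipeline, so
this module generates cohorts carrying the statistical structure the analysis
assumes: three diagnostic groups (controls, affective psychosis, non-affective
psychosis) whose residual heterogeneity increases in that order, three planted
cognitive clusters ("spared", "intermediate", "deficit") with distinct mean
profiles, symptom and antipsychotic-medication severity rising with planted
impairment (patients only), grey-matter volumes for a panel of brain networks
in which only a configurable subset carries a cluster effect, and
missing-completely-at-random entries at configurable per-variable and
per-subject rates.

Defaults reproduce the cohort shape of the motivating study: 56 controls,
52 affective, 118 non-affective (n = 226), 33 cognitive variables plus four
demographic covariates, 30 networks of which 3 are affected, and cluster
mixtures per group taken from the observed subgroup composition.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import (
    GROUPS,
    CohortTable,
    ConfigurationError,
    VariableSchema,
)

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "inject_missingness",
    "write_cohort",
    "read_cohort",
    "CLINICAL_COLUMNS",
    "MEDICATION_COLUMNS",
]

CLINICAL_COLUMNS = ("panss_total", "panss_positive", "panss_negative", "panss_general")
MEDICATION_COLUMNS = ("cpz_equivalent", "lifetime_exposure_months")


def _default_feature_schema(n_features: int) -> tuple[str, ...]:
    """Mostly continuous test scores with a few ordinal/binary items."""
    kinds = ["continuous"] * n_features
    # sprinkle discrete scales the way questionnaire batteries do
    for i in range(n_features):
        if i % 11 == 7:
            kinds[i] = "ordinal"
        elif i % 13 == 9:
            kinds[i] = "binary"
    return tuple(kinds)


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the generator; defaults encode the study conditions."""

    n_per_group: tuple[int, int, int] = (56, 52, 118)  # control, affective, non-affective
    n_features: int = 33
    feature_schema: tuple[str, ...] | None = None
    #: per-cluster mean offset applied to every continuous feature, in SD units
    cluster_profiles: tuple[float, ...] = (0.0, -1.0, -2.0)
    #: rows: groups in GROUPS order; columns: planted clusters.
    #: Defaults follow the observed subgroup composition of the three groups
    #: (48/6/2 of 56 controls, 19/28/5 of 52 affective, 20/42/56 of 118
    #: non-affective across spared/intermediate/deficit).
    cluster_mixture: tuple[tuple[float, ...], ...] = (
        (48 / 56, 6 / 56, 2 / 56),
        (19 / 52, 28 / 52, 5 / 52),
        (20 / 118, 42 / 118, 56 / 118),
    )
    noise_sd: float = 1.0
    group_hetero_scale: tuple[float, float, float] = (1.0, 1.2, 1.5)
    missing_var_rate: float = 0.05
    missing_subj_rate: float = 0.20
    flagged_subject_rate: float = 0.05
    n_networks: int = 30
    #: network index -> per-cluster volume effect (same units as network noise)
    affected_networks: dict[int, tuple[float, ...]] = field(
        default_factory=lambda: {
            17: (0.0, -0.4, -0.9),
            28: (0.0, -0.4, -0.9),
            29: (0.0, -0.5, -1.1),
        }
    )
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_profiles)

    def resolved_schema(self) -> tuple[str, ...]:
        if self.feature_schema is not None:
            return self.feature_schema
        return _default_feature_schema(self.n_features)

    def validate(self) -> None:
        for rate in (self.missing_var_rate, self.missing_subj_rate,
                     self.flagged_subject_rate):
            if not (0.0 <= rate <= 1.0):
                raise ConfigurationError(f"rate {rate} outside [0, 1]")
        if any(n < 2 for n in self.n_per_group):
            raise ConfigurationError("each group needs at least 2 subjects")
        if len(self.cluster_mixture) != len(GROUPS):
            raise ConfigurationError("cluster_mixture needs one row per group")
        for row in self.cluster_mixture:
            if len(row) != self.n_clusters:
                raise ConfigurationError("cluster_mixture row length != n_clusters")
            if abs(sum(row) - 1.0) > 1e-9:
                raise ConfigurationError("cluster_mixture rows must sum to 1")
        schema = self.resolved_schema()
        if len(schema) != self.n_features:
            raise ConfigurationError("feature_schema length != n_features")
        for kind in schema:
            if kind not in ("continuous", "ordinal", "binary", "categorical"):
                raise ConfigurationError(f"invalid schema kind {kind!r}")
        for idx in self.affected_networks:
            if not (0 <= idx < self.n_networks):
                raise ConfigurationError(f"affected network index {idx} out of range")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort, for recovery tests."""

    latent_cluster: pd.Series  # subject -> planted cluster id
    group: pd.Series  # subject -> diagnostic group
    effect_map: dict[str, tuple[float, ...]]  # feature -> per-cluster effect
    network_effects: dict[str, tuple[float, ...]]  # network -> per-cluster effect


# group-level demographic parameters (age means/SDs and female fractions
# mirror the study cohort's demographics table)
_AGE_MEAN = {"control": 24.55, "affective": 23.63, "non-affective": 22.73}
_AGE_SD = {"control": 4.42, "affective": 3.85, "non-affective": 3.38}
_FEMALE_FRAC = {"control": 0.339, "affective": 0.577, "non-affective": 0.305}

# clinical score generation: baseline + slope * planted severity + noise,
# patients only.  Baselines/SDs are in instrument units and sit near the
# study cohort's group means.
_CLINICAL_PARAMS = {
    "panss_total": (40.0, 8.0, 10.0),
    "panss_positive": (9.0, 1.8, 3.5),
    "panss_negative": (10.0, 2.2, 4.5),
    "panss_general": (21.0, 2.5, 5.0),
}
_MEDICATION_PARAMS = {
    "cpz_equivalent": (180.0, 140.0, 90.0),
    "lifetime_exposure_months": (10.0, 7.0, 6.0),
}


def generate_cohort(config: CohortConfig) -> tuple[CohortTable, GroundTruth]:
    """Draw a complete cohort (no missingness yet) plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    kinds = config.resolved_schema()
    n_clusters = config.n_clusters

    subject_ids: list[str] = []
    groups: list[str] = []
    clusters: list[int] = []
    for g_idx, (g, n_g) in enumerate(zip(GROUPS, config.n_per_group)):
        mix = np.asarray(config.cluster_mixture[g_idx], float)
        drawn = rng.choice(n_clusters, size=n_g, p=mix)
        for i in range(n_g):
            subject_ids.append(f"{g[:3].upper()}{i:04d}")
            groups.append(g)
            clusters.append(int(drawn[i]))

    n = len(subject_ids)
    index = pd.Index(subject_ids, name="subject_id")
    group = pd.Series(groups, index=index, name="group")
    cluster = pd.Series(clusters, index=index, name="latent_cluster")
    hetero = group.map(dict(zip(GROUPS, config.group_hetero_scale))).to_numpy(float)
    severity = cluster.to_numpy()  # 0 = spared ... n_clusters-1 = deficit

    columns: dict[str, np.ndarray] = {}
    schema: dict[str, VariableSchema] = {}
    effect_map: dict[str, tuple[float, ...]] = {}
    profiles = np.asarray(config.cluster_profiles, float)

    for f_idx, kind in enumerate(kinds):
        name = f"cog{f_idx:02d}"
        if kind == "continuous":
            offsets = profiles
            vals = offsets[severity] + config.noise_sd * hetero * rng.standard_normal(n)
        elif kind == "ordinal":
            # 1..5 scale; success probability shifts down with impairment
            p = np.clip(0.75 + 0.15 * profiles[severity], 0.05, 0.95)
            vals = rng.binomial(4, p) + 1.0
            offsets = np.clip(0.75 + 0.15 * profiles, 0.05, 0.95) * 4 + 1
        elif kind == "binary":
            p = np.clip(0.7 + 0.15 * profiles[severity], 0.05, 0.95)
            vals = rng.binomial(1, p).astype(float)
            offsets = np.clip(0.7 + 0.15 * profiles, 0.05, 0.95)
        elif kind == "categorical":
            # 3 unordered codes whose distribution shifts with impairment
            base = np.array([0.5, 0.3, 0.2])
            vals = np.empty(n)
            for c in range(n_clusters):
                sel = severity == c
                shift = min(c * 0.15, 0.45)
                p = np.array([base[0] - shift, base[1], base[2] + shift])
                p = p / p.sum()
                vals[sel] = rng.choice(3, size=int(sel.sum()), p=p)
            offsets = np.arange(n_clusters, dtype=float)
        else:  # pragma: no cover - validated upstream
            raise ConfigurationError(f"invalid schema kind {kind!r}")
        columns[name] = np.asarray(vals, float)
        schema[name] = VariableSchema(name, kind, "feature")
        effect_map[name] = tuple(float(o) for o in offsets)

    # demographic covariates
    age = np.array([rng.normal(_AGE_MEAN[g], _AGE_SD[g]) for g in groups])
    sex = np.array([rng.binomial(1, _FEMALE_FRAC[g]) for g in groups]).astype(float)
    ses = rng.integers(1, 6, size=n).astype(float)
    mother_edu = rng.integers(1, 6, size=n).astype(float)
    for name, vals, kind in (
        ("age", age, "continuous"),
        ("sex", sex, "binary"),
        ("ses", ses, "ordinal"),
        ("mother_education", mother_edu, "ordinal"),
    ):
        columns[name] = vals
        schema[name] = VariableSchema(name, kind, "covariate")

    # clinical and medication scores: patients only, controls explicitly missing
    is_patient = group.to_numpy() != "control"
    for name, (base, slope, sd) in _CLINICAL_PARAMS.items():
        vals = np.full(n, np.nan)
        vals[is_patient] = (
            base + slope * severity[is_patient]
            + sd * rng.standard_normal(int(is_patient.sum()))
        )
        columns[name] = vals
        schema[name] = VariableSchema(name, "continuous", "clinical")
    for name, (base, slope, sd) in _MEDICATION_PARAMS.items():
        vals = np.full(n, np.nan)
        raw = (
            base + slope * severity[is_patient]
            + sd * rng.standard_normal(int(is_patient.sum()))
        )
        vals[is_patient] = np.maximum(raw, 0.0)
        columns[name] = vals
        schema[name] = VariableSchema(name, "continuous", "medication")

    # grey-matter network volumes: TIV/age/sex coupling everywhere, cluster
    # effects only in the configured networks
    tiv = rng.normal(1500.0, 120.0, size=n)
    columns["tiv"] = tiv
    schema["tiv"] = VariableSchema("tiv", "continuous", "covariate")
    network_effects: dict[str, tuple[float, ...]] = {}
    for v in range(config.n_networks):
        name = f"network{v + 1:02d}"
        eff = np.asarray(
            config.affected_networks.get(v, tuple([0.0] * n_clusters)), float
        )
        vals = (
            0.004 * (tiv - 1500.0)
            - 0.01 * (age - 24.0)
            + 0.05 * sex
            + eff[severity]
            + rng.standard_normal(n)
        )
        columns[name] = vals
        schema[name] = VariableSchema(name, "continuous", "network_volume")
        network_effects[name] = tuple(float(e) for e in eff)

    values = pd.DataFrame(columns, index=index)
    mask = values.notna()
    table = CohortTable(values=values, mask=mask, group=group, schema=schema)
    truth = GroundTruth(
        latent_cluster=cluster,
        group=group.copy(),
        effect_map=effect_map,
        network_effects=network_effects,
    )
    return table, truth


def inject_missingness(table: CohortTable, config: CohortConfig) -> CohortTable:
    """Blank feature/covariate cells completely at random.

    Every feature/covariate cell is removed independently with probability
    ``missing_var_rate``; a ``flagged_subject_rate`` fraction of subjects
    additionally loses a ``missing_subj_rate`` fraction of those columns.
    Observed values are never altered, and group labels (held outside the
    value matrix) can never be masked.  Missingness draws are seeded from
    ``config.seed`` (offset so they do not reuse the generation stream).
    """
    config.validate()
    cols = table.columns_by_role("feature", "covariate")
    if not table.mask[cols].to_numpy().all():
        raise ValueError("table already contains missingness in feature/covariate columns")

    out = table.copy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n, p = len(out.values.index), len(cols)

    drop = rng.random((n, p)) < config.missing_var_rate
    flagged = rng.random(n) < config.flagged_subject_rate
    extra = rng.random((n, p)) < config.missing_subj_rate
    drop |= flagged[:, None] & extra

    sub_mask = out.mask[cols].to_numpy() & ~drop
    out.mask.loc[:, cols] = sub_mask
    vals = out.values[cols].to_numpy(float)
    vals[~sub_mask] = np.nan
    out.values.loc[:, cols] = vals
    out.log.append(
        {"event": "inject_missingness", "n_cells": int(drop.sum()),
         "n_flagged_subjects": int(flagged.sum())}
    )
    return out


# ---------------------------------------------------------------------------
# Plain-text round trip
# ---------------------------------------------------------------------------

def write_cohort(
    table: CohortTable,
    outdir: str | Path,
    truth: GroundTruth | None = None,
    config: CohortConfig | None = None,
) -> Path:
    """Write cohort CSV + JSON schema sidecar (+ ground truth, manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = table.values.copy()
    df.insert(0, "group", table.group)
    df.to_csv(outdir / "cohort.csv", na_rep="")
    schema_payload = {
        name: {"kind": s.kind, "role": s.role} for name, s in table.schema.items()
    }
    (outdir / "schema.json").write_text(json.dumps(schema_payload, indent=1))
    if truth is not None:
        gt = pd.DataFrame(
            {"group": truth.group, "latent_cluster": truth.latent_cluster}
        )
        gt.to_csv(outdir / "ground_truth.csv")
    if config is not None:
        cfg = dataclasses.asdict(config)
        cfg["affected_networks"] = {str(k): v for k, v in cfg["affected_networks"].items()}
        manifest = {"config": cfg, "seed": config.seed}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=list))
    return outdir


def read_cohort(indir: str | Path) -> CohortTable:
    """Read a cohort written by :func:`write_cohort`."""
    indir = Path(indir)
    df = pd.read_csv(indir / "cohort.csv", index_col="subject_id")
    group = df.pop("group")
    schema_payload = json.loads((indir / "schema.json").read_text())
    schema = {
        name: VariableSchema(name, spec["kind"], spec["role"])
        for name, spec in schema_payload.items()
    }
    return CohortTable.from_values(df, group, schema)
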