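"""Cohort container, missing-data filtering, stratified imputation and scaling.

The analysis operates on a subject-by-variable table of cognitive, perceptual
and emotional scores collected from three diagnostic groups (healthy controls,
affective psychosis, non-affective psychosis).  Real cohorts of this kind carry
substantial missingness, so the entry point of the pipeline is a filtering
cascade (drop variables with too many missing entries, then subjects with too
many missing variables), followed by group-stratified mean/mode imputation and
mixed-scale normalization.  Brain-network grey-matter volumes are corrected for
nuisance covariates (total intracranial volume, age, sex) by ordinary
least-squares residualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "PATIENT_GROUPS",
    "KINDS",
    "ROLES",
    "VariableSchema",
    "CohortTable",
    "ConfigurationError",
    "EmptyResultError",
    "filter_missing",
    "impute_stratified",
    "normalize_features",
    "residualize_volumes",
]

#: Diagnostic group labels, in canonical order.
GROUPS = ("control", "affective", "non-affective")
#: The two psychosis groups, pooled into one stratum for imputation.
PATIENT_GROUPS = ("affective", "non-affective")

KINDS = ("continuous", "ordinal", "binary", "categorical")
ROLES = ("feature", "covariate", "clinical", "medication", "network_volume")

#: Roles that enter the missing-data filter, imputation and normalization.
#: Clinical and medication columns are structurally missing for controls and
#: are analysed separately; network volumes are handled by residualization.
_PREPROCESS_ROLES = ("feature", "covariate")


class ConfigurationError(ValueError):
    """Invalid configuration value (schema kind, rate, threshold...)."""


class EmptyResultError(RuntimeError):
    """A filtering step removed every variable (or every subject)."""


@dataclass(frozen=True)
class VariableSchema:
    """Measurement scale (`kind`) and pipeline role of one column."""

    name: str
    kind: str
    role: str = "feature"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(
                f"unknown variable kind {self.kind!r} for {self.name!r}; "
                f"expected one of {KINDS}"
            )
        if self.role not in ROLES:
            raise ConfigurationError(
                f"unknown variable role {self.role!r} for {self.name!r}; "
                f"expected one of {ROLES}"
            )


@dataclass
class CohortTable:
    """Subject × variable matrix with explicit missingness mask.

    Attributes
    ----------
    values : DataFrame indexed by subject id; missing cells are NaN.
    mask : boolean DataFrame congruent with ``values``; True = observed.
    group : Series of diagnostic labels aligned with ``values.index``.
    schema : per-column :class:`VariableSchema`.
    log : free-form record of filtering/imputation events.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    group: pd.Series
    schema: dict[str, VariableSchema]
    log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not self.values.columns.equals(self.mask.columns):
            raise ValueError("values and mask columns differ")
        if not self.values.index.equals(self.mask.index):
            raise ValueError("values and mask indices differ")
        if not self.values.index.equals(self.group.index):
            raise ValueError("group labels not aligned with subjects")
        if not self.values.index.is_unique:
            raise ValueError("subject ids not unique")
        unknown = set(self.group.unique()) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown diagnostic groups: {sorted(unknown)}")
        missing_schema = set(self.values.columns) - set(self.schema)
        if missing_schema:
            raise ValueError(f"columns without schema: {sorted(missing_schema)}")

    # -- convenience -------------------------------------------------------

    def columns_by_role(self, *roles: str) -> list[str]:
        return [c for c in self.values.columns if self.schema[c].role in roles]

    def columns_by_kind(self, *kinds: str, roles: tuple[str, ...] | None = None) -> list[str]:
        cols = []
        for c in self.values.columns:
            s = self.schema[c]
            if s.kind in kinds and (roles is None or s.role in roles):
                cols.append(c)
        return cols

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "CohortTable":
        return CohortTable(
            values=self.values.copy(),
            mask=self.mask.copy(),
            group=self.group.copy(),
            schema=dict(self.schema),
            log=list(self.log),
        )

    @classmethod
    def from_values(
        cls,
        values: pd.DataFrame,
        group: pd.Series,
        schema: dict[str, VariableSchema],
    ) -> "CohortTable":
        """Build a table whose mask is inferred from NaN cells."""
        mask = values.notna()
        return cls(values=values, mask=mask, group=group, schema=schema)


# ---------------------------------------------------------------------------
# Missing-data filtering
# ---------------------------------------------------------------------------

def filter_missing(
    table: CohortTable,
    var_thresh: float = 0.10,
    subj_thresh: float = 0.20,
) -> CohortTable:
    """Drop high-missingness variables, then high-missingness subjects.

    A variable is removed when *strictly more than* ``var_thresh`` of its
    entries are missing (fractions computed over all subjects); a subject is
    then removed when strictly more than ``subj_thresh`` of the *retained*
    variables are missing for that subject.  Only feature and covariate
    columns participate; clinical, medication and network-volume columns pass
    through untouched (they are structurally missing for controls).

    Every removal is appended to ``table.log`` with its missing fraction.
    """
    if not (0 < var_thresh < 1) or not (0 < subj_thresh < 1):
        raise ConfigurationError("thresholds must lie strictly in (0, 1)")

    out = table.copy()
    filt_cols = out.columns_by_role(*_PREPROCESS_ROLES)
    if not filt_cols:
        raise ConfigurationError("no feature/covariate columns to filter")

    var_missing = 1.0 - out.mask[filt_cols].mean(axis=0)
    dropped_vars = var_missing.index[var_missing > var_thresh].tolist()
    for v in dropped_vars:
        out.log.append(
            {"event": "drop_variable", "name": v,
             "missing_fraction": float(var_missing[v]), "threshold": var_thresh}
        )
    kept_cols = [c for c in out.values.columns if c not in set(dropped_vars)]
    kept_filt = [c for c in filt_cols if c not in set(dropped_vars)]
    if not kept_filt:
        raise EmptyResultError(
            f"all {len(filt_cols)} feature/covariate variables exceeded the "
            f"{var_thresh:.0%} missingness threshold"
        )

    # subject missingness recomputed on retained variables only
    subj_missing = 1.0 - out.mask[kept_filt].mean(axis=1)
    dropped_subj = subj_missing.index[subj_missing > subj_thresh].tolist()
    for s in dropped_subj:
        out.log.append(
            {"event": "drop_subject", "name": s,
             "missing_fraction": float(subj_missing[s]), "threshold": subj_thresh}
        )
    kept_subj = [s for s in out.values.index if s not in set(dropped_subj)]
    if not kept_subj:
        raise EmptyResultError("all subjects exceeded the missingness threshold")

    return CohortTable(
        values=out.values.loc[kept_subj, kept_cols],
        mask=out.mask.loc[kept_subj, kept_cols],
        group=out.group.loc[kept_subj],
        schema={c: out.schema[c] for c in kept_cols},
        log=out.log,
    )


# ---------------------------------------------------------------------------
# Stratified imputation
# ---------------------------------------------------------------------------

def _mode_smallest(values: np.ndarray) -> float:
    """Most frequent value; ties broken by the smallest value."""
    uniq, counts = np.unique(values, return_counts=True)
    return float(uniq[np.argmax(counts)])  # np.unique sorts, argmax takes first


def impute_stratified(table: CohortTable) -> CohortTable:
    """Fill missing feature/covariate cells with stratum mean or mode.

    Strata are controls on one side and the two psychosis groups pooled on the
    other (patient/control base rates are unbalanced, so pooling the patient
    groups avoids biasing the fill values toward either diagnosis).
    Continuous cells receive the stratum mean; ordinal cells the stratum mean
    rounded to the nearest observed level; binary and categorical cells the
    stratum mode (ties to the smallest code).  Observed cells are never
    modified.
    """
    out = table.copy()
    is_control = out.group == "control"
    strata = {"control": is_control, "patient": ~is_control}

    for col in out.columns_by_role(*_PREPROCESS_ROLES):
        kind = out.schema[col].kind
        col_mask = out.mask[col]
        if col_mask.all():
            continue
        for stratum_name, in_stratum in strata.items():
            gap = in_stratum & ~col_mask
            if not gap.any():
                continue
            observed = out.values.loc[in_stratum & col_mask, col].to_numpy(float)
            if observed.size == 0:
                raise EmptyResultError(
                    f"variable {col!r} fully missing in stratum {stratum_name!r}"
                )
            if kind == "continuous":
                fill = float(np.mean(observed))
            elif kind == "ordinal":
                mean = float(np.mean(observed))
                levels = np.unique(observed)
                # nearest observed level; ties resolved toward the smaller one
                fill = float(levels[np.argmin(np.abs(levels - mean))])
            else:  # binary / categorical
                fill = _mode_smallest(observed)
            n_filled = int(gap.sum())
            out.values.loc[gap, col] = fill
            out.log.append(
                {"event": "impute", "name": col, "stratum": stratum_name,
                 "kind": kind, "fill": fill, "n_cells": n_filled}
            )
            out.mask.loc[gap, col] = True
    return out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_features(
    table: CohortTable,
    ddof: int = 0,
    on_constant: str = "error",
) -> CohortTable:
    """Z-score continuous columns, min-max scale ordinal/categorical, keep binary.

    Continuous feature and covariate columns are standardized to mean 0 and
    unit standard deviation (population convention, ``ddof=0``, switchable).
    Ordinal columns — and categorical codes, which in this pipeline live on
    small integer scales — are scaled to [0, 1]; binary columns pass through.

    ``on_constant`` controls zero-variance continuous columns: ``"error"``
    raises, ``"drop"`` removes the column with a logged warning.
    """
    out = table.copy()
    cols = out.columns_by_role(*_PREPROCESS_ROLES)
    if out.values[cols].isna().any().any():
        raise ConfigurationError("normalize_features requires imputed data")

    to_drop: list[str] = []
    for col in cols:
        kind = out.schema[col].kind
        x = out.values[col].to_numpy(float)
        if kind == "continuous":
            sd = float(np.std(x, ddof=ddof))
            if sd == 0.0:
                if on_constant == "drop":
                    to_drop.append(col)
                    out.log.append({"event": "drop_constant", "name": col})
                    continue
                raise ConfigurationError(f"zero-variance continuous column {col!r}")
            out.values[col] = (x - x.mean()) / sd
        elif kind in ("ordinal", "categorical"):
            lo, hi = float(np.min(x)), float(np.max(x))
            if hi == lo:
                if on_constant == "drop":
                    to_drop.append(col)
                    out.log.append({"event": "drop_constant", "name": col})
                    continue
                raise ConfigurationError(f"constant {kind} column {col!r}")
            out.values[col] = (x - lo) / (hi - lo)
        # binary: left as coded {0, 1}
    if to_drop:
        keep = [c for c in out.values.columns if c not in set(to_drop)]
        out = CohortTable(
            values=out.values[keep], mask=out.mask[keep], group=out.group,
            schema={c: out.schema[c] for c in keep}, log=out.log,
        )
    return out


# ---------------------------------------------------------------------------
# Brain-volume covariate correction
# ---------------------------------------------------------------------------

def residualize_volumes(
    volumes: pd.DataFrame,
    tiv: pd.Series,
    age: pd.Series,
    sex: pd.Series,
) -> pd.DataFrame:
    """Residualize each network volume on intercept + TIV + age + sex.

    Returns the OLS residuals per network, aligned with ``volumes``.  The
    residuals are orthogonal to every covariate column by construction, so
    downstream group comparisons of regional volume cannot be driven by head
    size, age or sex differences between groups.
    """
    for name, cov in (("tiv", tiv), ("age", age), ("sex", sex)):
        if cov.isna().any():
            raise ValueError(f"missing values in covariate {name!r}")
        if not cov.index.equals(volumes.index):
            raise ValueError(f"covariate {name!r} not aligned with volumes")
    n = volumes.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 subjects, got {n}")
    if volumes.isna().any().any():
        raise ValueError("missing values in volumes")

    design = np.column_stack(
        [np.ones(n), tiv.to_numpy(float), age.to_numpy(float), sex.to_numpy(float)]
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates: design matrix is rank deficient")
    y = volumes.to_numpy(float)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return pd.DataFrame(resid, index=volumes.index, columns=volumes.columns)
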