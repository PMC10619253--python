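"""Covariate-adjusted association models producing per-cohort effect estimates.

Two model families, as in the cohort analysis:

* linear group contrasts — outcome in SD units regressed on exposure-group
  indicators (reference-coded against the no-exposed control), adjusted for
  the covariate set;
* logistic outcome models — type 2 diabetes regressed on a per-SD exposure
  variable (diversity index, PCoA axis, or keystone index), Wald CIs, odds
  ratios reported as exp(beta).

Covariate sets mirror the study's models: model1 = age, sex, BMI, and the
two medication flags; model2 adds sequencing depth (and any diet/lifestyle
columns present); unadjusted = none. Missing covariate values are handled by
complete-case analysis per model; the dropped count is recorded on the
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "EffectEstimate",
    "CovariateSet",
    "MODEL1",
    "MODEL2",
    "UNADJUSTED",
    "linear_group_contrast",
    "logistic_outcome",
    "run_grid",
]


@dataclass
class EffectEstimate:
    """A single coefficient: the atom pooled by meta-analysis."""

    cohort: str
    term: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    kind: str = "linear"  # or "logistic" (beta on the log-odds scale)
    model: str = "model1"

    @property
    def odds_ratio(self) -> float:
        if self.kind != "logistic":
            raise ValueError("odds ratio defined only for logistic estimates")
        return float(np.exp(self.beta))

    def to_dict(self) -> dict:
        d = {
            "cohort": self.cohort,
            "term": self.term,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n": self.n,
            "kind": self.kind,
            "model": self.model,
        }
        if self.kind == "logistic":
            d["odds_ratio"] = self.odds_ratio
        return d


@dataclass
class CovariateSet:
    name: str
    columns: list[str] = field(default_factory=list)
    optional_columns: list[str] = field(default_factory=list)

    def resolve(self, metadata: pd.DataFrame) -> list[str]:
        missing = [c for c in self.columns if c not in metadata.columns]
        if missing:
            raise ValueError(f"covariate set {self.name!r} needs missing columns {missing}")
        extra = [c for c in self.optional_columns if c in metadata.columns]
        return self.columns + extra


MODEL1 = CovariateSet(
    "model1", ["age", "sex", "bmi", "hypoglycemic", "hypolipidemic"]
)
MODEL2 = CovariateSet(
    "model2",
    ["age", "sex", "bmi", "hypoglycemic", "hypolipidemic", "depth"],
    optional_columns=[
        "fruit", "vegetable", "fish", "red_meat", "dairy", "alcohol", "smoking",
    ],
)
UNADJUSTED = CovariateSet("unadjusted", [])

#: Covariate set for the T2D logistic models (age, sex, BMI only — medication
#: flags are on the causal path to the diagnosis and are not adjusted for).
LOGISTIC_MODEL = CovariateSet("logistic", ["age", "sex", "bmi"])


def _design(covariates: pd.DataFrame) -> pd.DataFrame:
    x = sm.add_constant(covariates.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cols: list[str] = []
        for c in x.columns:
            trial = x[cols + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(c)
            else:
                cols.append(c)
        raise ValueError(f"collinear covariates: {bad}")
    return x


def linear_group_contrast(
    outcome: pd.Series,
    groups: pd.Series,
    reference: str,
    covariates: pd.DataFrame | None = None,
    cohort: str = "",
    model: str = "model1",
) -> list[EffectEstimate]:
    """OLS of a standardized outcome on group indicators vs the reference.

    Returns one estimate per non-reference group: coefficient (SD units), SE,
    normal-approximation 95% CI, and p-value. Complete-case on outcome and
    covariates.
    """
    df = pd.DataFrame({"outcome": outcome.astype(float), "group": groups})
    if covariates is not None and covariates.shape[1]:
        df = df.join(covariates.astype(float))
    df = df.dropna()
    if (df["group"] == reference).sum() == 0:
        raise ValueError(f"reference group {reference!r} empty after complete-case filtering")
    dummies = pd.get_dummies(df["group"], dtype=float)
    if reference not in dummies.columns:
        raise ValueError(f"reference group {reference!r} not present")
    dummies = dummies.drop(columns=[reference])
    x = dummies
    if covariates is not None and covariates.shape[1]:
        x = pd.concat([dummies, df[covariates.columns]], axis=1)
    x = _design(x)
    fit = sm.OLS(df["outcome"], x).fit()
    z = 1.959963984540054
    out = []
    for g in dummies.columns:
        b, se = fit.params[g], fit.bse[g]
        out.append(
            EffectEstimate(
                cohort=cohort,
                term=f"{g} vs {reference}",
                beta=float(b),
                se=float(se),
                ci_low=float(b - z * se),
                ci_high=float(b + z * se),
                p_value=float(fit.pvalues[g]),
                n=int(fit.nobs),
                kind="linear",
                model=model,
            )
        )
    return out


def logistic_outcome(
    exposure: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    cohort: str = "",
    term: str = "per SD",
    model: str = "logistic",
) -> EffectEstimate:
    """Maximum-likelihood logistic regression of a binary outcome.

    ``exposure`` should be on the per-SD scale; the estimate's beta is the
    log-odds per SD, with Wald 95% CI. Complete separation raises with a
    diagnostic rather than returning a divergent fit.
    """
    df = pd.DataFrame({"x": exposure.astype(float), "y": outcome.astype(float)})
    if covariates is not None and covariates.shape[1]:
        df = df.join(covariates.astype(float))
    df = df.dropna()
    if df["y"].nunique() < 2:
        raise ValueError("both outcome classes must be present")
    x = df.drop(columns=["y"])
    x = _design(x)
    try:
        fit = sm.Logit(df["y"], x).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise ValueError(f"logistic fit failed (possible complete separation): {exc}") from exc
    if not np.isfinite(fit.bse["x"]) or fit.bse["x"] > 1e4:
        raise ValueError("complete separation: standard error diverged")
    b, se = float(fit.params["x"]), float(fit.bse["x"])
    z = 1.959963984540054
    return EffectEstimate(
        cohort=cohort,
        term=term,
        beta=b,
        se=se,
        ci_low=b - z * se,
        ci_high=b + z * se,
        p_value=float(fit.pvalues["x"]),
        n=int(fit.nobs),
        kind="logistic",
        model=model,
    )


def run_grid(
    outcomes: dict[str, pd.Series],
    metadata: pd.DataFrame,
    groups: pd.Series,
    reference: str,
    covariate_sets: list[CovariateSet],
    cohort: str = "",
    t2d: pd.Series | None = None,
    exclude_t2d_for_contrasts: bool = False,
) -> pd.DataFrame:
    """Run the full contrast grid for one cohort; one tidy row per estimate.

    For every outcome (SD units) and covariate set: group contrasts against
    the reference; and, when ``t2d`` is given, a logistic model of T2D on the
    outcome (adjusted for age, sex, BMI). Cells with infeasible fits are
    skipped and logged in the ``error`` column of a companion attribute.
    """
    rows: list[dict] = []
    errors: list[dict] = []
    for cov_set in covariate_sets:
        try:
            cols = cov_set.resolve(metadata)
        except ValueError as exc:
            errors.append({"stage": cov_set.name, "error": str(exc)})
            continue
        cov = metadata[cols] if cols else None
        for name, values in outcomes.items():
            vals, grp = values, groups
            if exclude_t2d_for_contrasts and t2d is not None:
                keep = t2d.loc[values.index] == 0
                vals, grp = values[keep], groups[keep]
                cov_use = cov.loc[vals.index] if cov is not None else None
            else:
                cov_use = cov
            try:
                ests = linear_group_contrast(
                    vals, grp, reference, cov_use, cohort=cohort, model=cov_set.name
                )
                rows += [dict(e.to_dict(), outcome=name) for e in ests]
            except ValueError as exc:
                errors.append({"stage": f"{cov_set.name}:{name}", "error": str(exc)})
    if t2d is not None:
        cov = metadata[LOGISTIC_MODEL.resolve(metadata)]
        for name, values in outcomes.items():
            try:
                est = logistic_outcome(
                    values, t2d.loc[values.index], cov.loc[values.index],
                    cohort=cohort, term=f"{name} per SD",
                )
                rows.append(dict(est.to_dict(), outcome=name))
            except ValueError as exc:
                errors.append({"stage": f"logistic:{name}", "error": str(exc)})
    out = pd.DataFrame(rows)
    out.attrs["errors"] = errors
    return out
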