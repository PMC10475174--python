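"""Parental-age models for de novo variant counts.

Offspring DNV counts rise with parental — especially paternal — age at
conception.  Two classical forms are fitted by ordinary least squares:

* linear:       dnm_counts ~ fatherAge + motherAge
* exponential:  log(dnm_counts) ~ fatherAge + motherAge

each also available with the father's or mother's age alone.  Fits report
coefficients, standard errors, t-based 95% confidence intervals, r-squared
(plain and adjusted), and Pearson correlations between each included age
and the (possibly log-transformed) response, plus scatter-plot data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ContractError, DNVWarning, ValidationError
from .io_dnv import ParentalAgeRecord
from .summaries import IndividualCounts

PREDICTOR_SETS: dict[str, tuple[str, ...]] = {
    "both": ("fatherAge", "motherAge"),
    "father_only": ("fatherAge",),
    "mother_only": ("motherAge",),
}

CI_LEVEL = 0.95


@dataclass
class RegressionFit:
    model_form: str  # "linear" | "exponential"
    predictors: str  # "both" | "father_only" | "mother_only"
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    r_squared: float
    r_squared_adj: float
    n: int
    residual_df: int
    pearson_r: dict[str, float]
    #: per-predictor scatter data: age values, raw counts, and the fitted
    #: curve on the count scale (exp of the linear predictor for the
    #: exponential form, no smearing correction)
    scatter: dict[str, dict[str, list[float]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model_form": self.model_form,
            "predictors": self.predictors,
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "r_squared": self.r_squared,
            "r_squared_adj": self.r_squared_adj,
            "n": self.n,
            "residual_df": self.residual_df,
            "pearson_r": self.pearson_r,
        }


def join_counts_ages(
    counts: IndividualCounts | Mapping[str, int],
    ages: pd.DataFrame,
) -> list[ParentalAgeRecord]:
    """Inner-join per-sample DNV counts with parental ages on sample id.

    ``counts`` may be the result of ``counts_per_individual`` or a plain
    mapping from a count table.  Samples present in only one input are
    reported by name in a warning; an empty intersection is an error.
    """
    if isinstance(counts, IndividualCounts):
        counts = counts.per_sample
    if not counts or ages.empty:
        raise ContractError("join_counts_ages requires non-empty counts and ages")
    age_samples = list(ages["sample"])
    shared = [s for s in counts if s in set(age_samples)]
    only_counts = sorted(set(counts) - set(age_samples))
    only_ages = sorted(set(age_samples) - set(counts))
    for name, extras in (("counts", only_counts), ("ages", only_ages)):
        if extras:
            warnings.warn(
                f"sample(s) only in {name} table, dropped from join: "
                f"{', '.join(extras)}",
                DNVWarning,
                stacklevel=2,
            )
    if not shared:
        raise ValidationError("no samples shared between counts and ages tables")
    age_rows = ages.set_index("sample")
    records = []
    for s in shared:
        records.append(
            ParentalAgeRecord(
                sample=s,
                dnm_counts=int(counts[s]),
                fatherAge=float(age_rows.loc[s, "fatherAge"]),
                motherAge=float(age_rows.loc[s, "motherAge"]),
            )
        )
    return records


def _complete_cases(
    records: Sequence[ParentalAgeRecord], terms: tuple[str, ...]
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sample": [r.sample for r in records],
            "dnm_counts": [r.dnm_counts for r in records],
            "fatherAge": [r.fatherAge for r in records],
            "motherAge": [r.motherAge for r in records],
        }
    )
    incomplete = df[list(terms)].isna().any(axis=1)
    if incomplete.any():
        dropped = ", ".join(df.loc[incomplete, "sample"])
        warnings.warn(
            f"dropped sample(s) with missing age(s) before fitting: {dropped}",
            DNVWarning,
            stacklevel=3,
        )
    return df[~incomplete].reset_index(drop=True)


def fit_parental_model(
    data: Sequence[ParentalAgeRecord],
    model_form: str = "linear",
    predictors: str = "both",
) -> RegressionFit:
    """Fit the linear or exponential parental-age model by OLS.

    The exponential form regresses log(dnm_counts) and therefore requires
    every count to be at least 1.  Confidence intervals are
    estimate +/- t(0.975, residual_df) * SE.  Rows with missing ages are
    dropped (complete-case analysis) with a warning.
    """
    if model_form not in ("linear", "exponential"):
        raise ContractError(f"unknown model_form {model_form!r}")
    if predictors not in PREDICTOR_SETS:
        raise ContractError(
            f"unknown predictors {predictors!r}; expected one of "
            f"{sorted(PREDICTOR_SETS)}"
        )
    terms = PREDICTOR_SETS[predictors]
    df = _complete_cases(data, terms)
    n = len(df)
    n_terms = len(terms) + 1
    if n < n_terms + 1:
        raise ContractError(
            f"need at least {n_terms + 1} complete samples for {n_terms} terms, "
            f"got {n}"
        )
    if model_form == "exponential":
        bad = df.loc[df["dnm_counts"] < 1, "sample"]
        if len(bad):
            raise ValidationError(
                "exponential model requires dnm_counts >= 1; offending "
                f"sample(s): {', '.join(bad)}"
            )
        response = np.log(df["dnm_counts"].to_numpy(dtype=float))
    else:
        response = df["dnm_counts"].to_numpy(dtype=float)

    X = df[list(terms)].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < n_terms:
        raise ValidationError(
            "rank-deficient design (constant or collinear ages); cannot fit"
        )
    design = sm.add_constant(pd.DataFrame(X, columns=list(terms)))
    fit = sm.OLS(response, design).fit()

    names = ["intercept", *terms]
    params = dict(zip(names, fit.params))
    ses = dict(zip(names, fit.bse))
    ci = fit.conf_int(alpha=1 - CI_LEVEL)
    ci95 = {
        name: (float(ci.iloc[i, 0]), float(ci.iloc[i, 1]))
        for i, name in enumerate(names)
    }
    pearson = {
        t: float(stats.pearsonr(df[t].to_numpy(dtype=float), response)[0])
        for t in terms
    }
    fitted_counts = fit.fittedvalues
    if model_form == "exponential":
        fitted_counts = np.exp(fitted_counts)
    scatter = {
        t: {
            "age": df[t].tolist(),
            "dnm_counts": df["dnm_counts"].tolist(),
            "fitted": np.asarray(fitted_counts).tolist(),
        }
        for t in terms
    }
    return RegressionFit(
        model_form=model_form,
        predictors=predictors,
        coefficients={k: float(v) for k, v in params.items()},
        standard_errors={k: float(v) for k, v in ses.items()},
        ci95=ci95,
        r_squared=float(fit.rsquared),
        r_squared_adj=float(fit.rsquared_adj),
        n=n,
        residual_df=int(fit.df_resid),
        pearson_r=pearson,
        scatter=scatter,
    )
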