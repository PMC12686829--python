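"""Mutation-load normalization, the age-burden model and group tests.

Observed autosomal substitution counts are corrected for the per-sample
somatic sensitivity ``p`` (callable fraction) after adding back the
estimated number of fetal mutations lost to germline filtering, then
expressed relative to the load expected at the sample's hematopoietic age
under a healthy baseline.  The baseline is a linear mixed-effects model
(burden ~ age with a per-donor random intercept); with one observation per
donor it reduces to ordinary least squares.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

#: 95% CI of the mutation load at birth from the healthy baseline, used when
#: no healthy cohort is supplied.
DEFAULT_BIRTH_LOAD_CI = (52.0, 121.0)


@dataclass
class BurdenObservation:
    sample: str
    donor: str
    age: float
    raw_count: int
    p: float
    genotype: str = "wildtype"

    def __post_init__(self):
        if self.raw_count < 0:
            raise ValueError("burden count must be nonnegative")
        if not 0 < self.p <= 1:
            raise ValueError("callable fraction p must be in (0, 1]")


@dataclass
class AgeBurdenModel:
    slope: float
    intercept: float
    birth_load_ci: tuple[float, float] = DEFAULT_BIRTH_LOAD_CI
    slope_ci: tuple[float, float] = (np.nan, np.nan)
    donor_variance: float = 0.0
    n_obs: int = 0

    def expected_burden(self, age: float) -> float:
        return self.intercept + self.slope * age


def fit_age_model(healthy: list[BurdenObservation]) -> AgeBurdenModel:
    """Fit burden ~ age with a per-donor random intercept.

    Burdens must already be corrected for ``p``.  When every donor
    contributes a single observation the random intercept is not
    identifiable and the fit is ordinary least squares; the 95% CI of the
    predicted burden at age 0 is taken from the fixed-intercept CI.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if len({o.age for o in healthy}) < 2:
        raise ValueError("need at least two distinct ages")
    df = pd.DataFrame(
        dict(
            burden=[o.raw_count / o.p for o in healthy],
            age=[o.age for o in healthy],
            donor=[o.donor for o in healthy],
        )
    )
    repeated = df["donor"].duplicated().any()
    if repeated:
        model = smf.mixedlm("burden ~ age", df, groups=df["donor"])
        fit = model.fit(reml=True, method="lbfgs")
        params = fit.fe_params
        ci = fit.conf_int().loc[["Intercept", "age"]]
        donor_var = float(fit.cov_re.iloc[0, 0])
    else:
        X = sm.add_constant(df["age"])
        fit = sm.OLS(df["burden"], X).fit()
        params = fit.params.rename({"const": "Intercept"})
        ci = fit.conf_int().rename(index={"const": "Intercept"})
        donor_var = 0.0
    return AgeBurdenModel(
        slope=float(params["age"]),
        intercept=float(params["Intercept"]),
        birth_load_ci=(float(ci.loc["Intercept", 0]), float(ci.loc["Intercept", 1])),
        slope_ci=(float(ci.loc["age", 0]), float(ci.loc["age", 1])),
        donor_variance=donor_var,
        n_obs=len(df),
    )


def corrected_burden(
    obs: BurdenObservation, fetal_add: float, model: AgeBurdenModel
) -> float:
    """Observed/expected burden ratio: ((raw + fetal_add) / p) / expected(age)."""
    expected = model.expected_burden(obs.age)
    if expected <= 0:
        raise ValueError(f"expected burden {expected:g} at age {obs.age:g} is not positive")
    return ((obs.raw_count + fetal_add) / obs.p) / expected


def compare_burdens(groups: dict[str, list[float]]) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests, Bonferroni corrected.

    The Bonferroni family is all pairwise comparisons in the call.  Exact
    ranks are used where sample sizes permit (scipy's exact method).
    """
    for name, values in groups.items():
        if len(values) == 0:
            raise ValueError(f"group {name!r} is empty")
    pairs = list(itertools.combinations(sorted(groups), 2))
    rows = []
    for a, b in pairs:
        res = st.mannwhitneyu(
            groups[a], groups[b], alternative="two-sided",
            method="exact" if len(groups[a]) + len(groups[b]) <= 30 else "auto",
        )
        rows.append((a, b, float(res.pvalue),
                     float(min(res.pvalue * len(pairs), 1.0))))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "p", "p_bonferroni"])


def mutant_fraction_test(expected_fraction: float, observed: tuple[int, int]) -> float:
    """Two-sided exact binomial test of an observed mutant-colony fraction.

    ``expected_fraction`` is typically 2 x VAF for a heterozygous driver.
    Uses the minimum-likelihood summation convention.
    """
    k, n = observed
    if n == 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if not 0 < expected_fraction < 1:
        raise ValueError("expected_fraction must be in (0, 1)")
    return float(st.binomtest(k, n, expected_fraction, alternative="two-sided").pvalue)


def expected_mutant_fraction(vaf: float) -> float:
    """Expected fraction of mutant colonies for a heterozygous clone at VAF v."""
    return 2.0 * vaf
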