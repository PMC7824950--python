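"""Comparison of medicinal knowledge across social groups.

Knowledge is measured per informant as the number of distinct species and
distinct diseases cited (zero for informants without reports).  Groups are
compared with tie-corrected rank tests (Mann-Whitney for two levels,
Kruskal-Wallis for three or more) and with a Poisson log-linear regression
of the counts on categorical factors, reported as rate ratios exp(B) with
Wald standard errors.  The dispersion is fixed at 1 (plain Poisson); the
Pearson dispersion statistic is reported for diagnostics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import FittingError, ParameterError
from .survey_data import SurveyDataset, _knowledge_by_informant
from .vocab import INFORMANT_FIELDS

__all__ = ["KnowledgeCount", "RateModelResult", "knowledge_counts", "rank_test", "poisson_rate_model"]

RESPONSES = ("n_species", "n_diseases")

#: Reference levels fixed a priori for the factors with planted contrasts;
#: any other factor defaults to its most frequent level.
DEFAULT_REFERENCE_LEVELS = {
    "gender": "male",
    "residence": "mbanza_ngungu_rural",
    "category": "traditional_health_practitioner",
}


@dataclass(frozen=True)
class KnowledgeCount:
    informant_id: str
    n_species: int
    n_diseases: int


@dataclass
class RateModelResult:
    """Fitted Poisson rate model for one response.

    ``terms`` has one row per coefficient (intercept, then each factor
    level): columns ``term, factor, level, coef, se, p_value, rate_ratio``.
    Reference levels appear with coefficient 0 and rate ratio 1.
    """

    response: str
    terms: pd.DataFrame
    reference_levels: dict[str, str]
    pearson_dispersion: float = float("nan")
    converged: bool = True

    def rate_ratio(self, factor: str, level: str) -> float:
        row = self.terms[(self.terms["factor"] == factor) & (self.terms["level"] == level)]
        if row.empty:
            raise ParameterError(f"no term for {factor}={level}")
        return float(row["rate_ratio"].iloc[0])


def knowledge_counts(ds: SurveyDataset) -> pd.DataFrame:
    """Per-informant distinct species/disease counts, roster-complete."""
    return _knowledge_by_informant(ds)


def rank_test(
    counts: pd.DataFrame,
    ds: SurveyDataset,
    factor: str,
    response: str = "n_species",
) -> tuple[float, float, str]:
    """Rank test of a knowledge response across the levels of one factor.

    Two levels: two-sided Mann-Whitney with the tie-corrected normal
    approximation (no continuity correction, so identical groups give
    p = 1.0 exactly).  Three or more levels: Kruskal-Wallis with tie
    correction.  Returns ``(statistic, p_value, method)``.
    """
    if factor not in INFORMANT_FIELDS:
        raise ParameterError(f"unknown informant factor '{factor}'")
    if response not in RESPONSES:
        raise ParameterError(f"response must be one of {RESPONSES}")
    merged = ds.informants[["informant_id", factor]].merge(counts, on="informant_id")
    groups = [g[response].to_numpy() for _, g in merged.groupby(factor)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ParameterError(f"factor '{factor}' needs at least 2 non-empty levels")
    if len(groups) == 2:
        stat, p = stats.mannwhitneyu(
            groups[0], groups[1], alternative="two-sided",
            method="asymptotic", use_continuity=False,
        )
        return float(stat), float(p), "mann-whitney"
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p), "kruskal-wallis"


def poisson_rate_model(
    counts: pd.DataFrame,
    ds: SurveyDataset,
    response: str = "n_species",
    factors: tuple[str, ...] = ("gender", "residence", "category"),
    reference_levels: dict[str, str] | None = None,
) -> RateModelResult:
    """Poisson log-linear model of a knowledge count on categorical factors.

    Fits ``response ~ factor_1 + ... + factor_k`` with treatment coding,
    intercept, no offset, dispersion fixed at 1.  Rate ratios are the
    exponentiated coefficients; reference levels carry coefficient 0 and
    rate ratio 1 by construction.
    """
    if response not in RESPONSES:
        raise ParameterError(f"response must be one of {RESPONSES}")
    for f in factors:
        if f not in INFORMANT_FIELDS:
            raise ParameterError(f"unknown informant factor '{f}'")
    data = ds.informants[["informant_id", *factors]].merge(counts, on="informant_id")

    refs: dict[str, str] = {}
    for f in factors:
        observed = data[f].value_counts()
        wanted = (reference_levels or {}).get(f, DEFAULT_REFERENCE_LEVELS.get(f))
        refs[f] = wanted if wanted in observed.index else observed.index[0]

    formula = response + " ~ " + " + ".join(
        f"C({f}, Treatment(reference={refs[f]!r}))" for f in factors
    )
    model = smf.glm(formula, data=data, family=sm.families.Poisson())

    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        raise FittingError(
            f"model matrix is rank deficient ({rank} < {model.exog.shape[1]}); "
            f"columns: {list(model.exog_names)}"
        )
    try:
        fit = model.fit()
    except Exception as exc:  # non-convergence surfaces as a fitting error
        raise FittingError(f"Poisson fit failed: {exc}") from exc

    rows = [
        {
            "term": "intercept",
            "factor": "(intercept)",
            "level": "",
            "coef": float(fit.params["Intercept"]),
            "se": float(fit.bse["Intercept"]),
            "p_value": float(fit.pvalues["Intercept"]),
            "rate_ratio": float(np.exp(fit.params["Intercept"])),
        }
    ]
    for f in factors:
        levels = list(dict.fromkeys(data[f]))
        ordered = [refs[f]] + sorted(lv for lv in levels if lv != refs[f])
        for lv in ordered:
            if lv == refs[f]:
                rows.append(
                    {
                        "term": f"{f}[{lv}]",
                        "factor": f,
                        "level": lv,
                        "coef": 0.0,
                        "se": float("nan"),
                        "p_value": float("nan"),
                        "rate_ratio": 1.0,
                    }
                )
                continue
            name = f"C({f}, Treatment(reference={refs[f]!r}))[T.{lv}]"
            rows.append(
                {
                    "term": f"{f}[{lv}]",
                    "factor": f,
                    "level": lv,
                    "coef": float(fit.params[name]),
                    "se": float(fit.bse[name]),
                    "p_value": float(fit.pvalues[name]),
                    "rate_ratio": float(np.exp(fit.params[name])),
                }
            )
    dispersion = float(fit.pearson_chi2 / fit.df_resid) if fit.df_resid > 0 else float("nan")
    return RateModelResult(
        response=response,
        terms=pd.DataFrame(rows),
        reference_levels=refs,
        pearson_dispersion=dispersion,
        converged=bool(getattr(fit, "converged", True)),
    )


def wald_confidence_interval(
    result: RateModelResult, factor: str, level: str, alpha: float = 0.05
) -> tuple[float, float]:
    """95% (by default) Wald interval for a rate ratio, on the ratio scale."""
    row = result.terms[(result.terms["factor"] == factor) & (result.terms["level"] == level)]
    if row.empty or not np.isfinite(row["se"].iloc[0]):
        raise ParameterError(f"no estimated term for {factor}={level}")
    z = stats.norm.ppf(1 - alpha / 2)
    coef, se = float(row["coef"].iloc[0]), float(row["se"].iloc[0])
    return float(np.exp(coef - z * se)), float(np.exp(coef + z * se))
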