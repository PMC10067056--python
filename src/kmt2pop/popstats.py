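"""Allele-frequency, prevalence and stratified comparison statistics.

Two prevalence conventions are used in population reports of
pathogenic/likely pathogenic (P/LP) burden and both are implemented and
always labelled:

* ``AC_BASED`` — carriers approximated by the summed allele count over
  P/LP variants, prevalence = 1 in round(n_individuals / AC);
* ``N_BASED`` — prevalence = 1 in round(n_individuals / N) where N is
  the number of distinct P/LP variants.

Overall allele frequency is AC/AN (AN = 2 x individuals); the
"abstract-style" companion is N/(2n). Sex comparisons use a Welch
two-sample t-test on per-variant allele-frequency vectors; ancestry and
sex group differences can also be modelled by logistic regression on
aggregated allele-carriage counts.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from kmt2pop.manual_classifier import Classification
from kmt2pop.variant_model import ANCESTRIES, Cohort, SEXES

__all__ = [
    "PrevalenceConvention",
    "allele_frequency",
    "format_af",
    "prevalence",
    "abstract_af",
    "summarize",
    "sex_af_comparison",
    "group_af_regression",
]


class PrevalenceConvention(enum.Enum):
    """How the numerator of a 1-in-D prevalence is counted."""

    AC_BASED = "AC_BASED"  # carriers ~ summed allele count
    N_BASED = "N_BASED"    # distinct P/LP variant count


def allele_frequency(ac: int, an: int) -> float:
    """Exact AC/AN quotient (round only at the reporting layer)."""
    if an <= 0:
        raise ValueError("allele number must be positive")
    if not 0 <= ac <= an:
        raise ValueError(f"ac={ac} outside [0, an={an}]")
    return ac / an


def format_af(af: float) -> str:
    """Render an allele frequency as 3-significant-digit scientific
    notation (``1.96E-03``), or ``0`` for zero."""
    if af == 0:
        return "0"
    return f"{af:.2E}"


def prevalence(
    count: int,
    n_individuals: int,
    convention: PrevalenceConvention = PrevalenceConvention.AC_BASED,
) -> int | None:
    """1-in-D prevalence denominator, D = round(n_individuals / count).

    ``count`` is summed AC under ``AC_BASED`` or the distinct P/LP
    variant count under ``N_BASED``. Returns None when count is zero
    (nothing observed, no ratio).
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    if count == 0:
        return None
    # round half away from zero so e.g. 2313.5 -> 2314
    return int(math.floor(n_individuals / count + 0.5))


def abstract_af(n_variants: int, n_individuals: int) -> float:
    """Variant-count allele frequency N/(2n), one allele per variant."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    return n_variants / (2 * n_individuals)


def sex_af_comparison(
    male_afs: Sequence[float], female_afs: Sequence[float]
) -> tuple[float | None, float | None, float | None]:
    """Mean per-variant AF by sex and a Welch two-sample t-test p-value.

    Returns ``(mean_male, mean_female, p)``; a mean is None for an
    empty group and p is None unless both groups have at least two
    variants. Degenerate zero-variance vectors yield p = 1 when the
    means agree and p = 0 when they differ.
    """
    male = np.asarray(list(male_afs), dtype=float)
    female = np.asarray(list(female_afs), dtype=float)
    mean_m = float(male.mean()) if male.size else None
    mean_f = float(female.mean()) if female.size else None
    if male.size < 2 or female.size < 2:
        return mean_m, mean_f, None
    import warnings as _warnings

    with _warnings.catch_warnings():
        # near-identical AF vectors trip scipy's precision-loss warning
        _warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(male, female, equal_var=False)
    if math.isnan(p):
        p = 1.0 if mean_m == mean_f else 0.0
    return mean_m, mean_f, float(p)


def summarize(
    cohort: Cohort,
    classifications: Sequence[Classification],
    method_label: str,
    convention: PrevalenceConvention = PrevalenceConvention.AC_BASED,
) -> pd.DataFrame:
    """Per-gene P/LP summary in the shape of a population report table.

    One row per gene with: N (distinct P/LP variants), AC (summed
    allele count), AF = AC / (2 x n_individuals), the 1-in-D prevalence
    under ``convention``, per-ancestry summed AC and AF, per-sex mean
    per-variant AF, and the Welch t-test p-value.

    Ancestry AF uses the stratum allele number (the largest AN seen for
    that stratum in the gene), not a sum over variants; allele numbers
    are a property of the cohort, not of the variant list.
    """
    if len(classifications) != len(cohort):
        raise ValueError("one classification per record required")
    rows = []
    for gene in cohort.genes:
        recs = [
            rec
            for rec, call in zip(cohort, classifications)
            if rec.variant.gene == gene
            and call in (Classification.P, Classification.LP)
        ]
        n_ind = cohort.n_individuals.get(gene)
        if n_ind is None:
            raise ValueError(f"n_individuals missing for gene {gene}")
        n = len(recs)
        ac = sum(rec.popcounts.ac_total for rec in recs)
        an = 2 * n_ind
        count = ac if convention is PrevalenceConvention.AC_BASED else n
        denom = prevalence(count, n_ind, convention)
        row: dict[str, object] = {
            "method": method_label,
            "gene": gene,
            "n_plp_variants": n,
            "ac": ac,
            "af": allele_frequency(ac, an) if ac <= an else ac / an,
            "prevalence_denominator": denom,
            "prevalence": f"1/{denom}" if denom else "none observed",
            "convention": convention.value,
        }
        for a in ANCESTRIES:
            strata = [rec.popcounts.per_ancestry.get(a) for rec in recs]
            strata = [s for s in strata if s is not None]
            ac_a = sum(s[0] for s in strata)
            an_a = max((s[1] for s in strata), default=0)
            if ac_a > 0 and an_a == 0:
                raise ValueError(f"{gene}/{a}: AC > 0 with AN = 0")
            row[f"ac_{a}"] = ac_a
            row[f"af_{a}"] = ac_a / an_a if an_a else 0.0
        male_afs = [
            rec.popcounts.per_sex["male"][0] / rec.popcounts.per_sex["male"][1]
            for rec in recs
            if rec.popcounts.per_sex.get("male", (0, 0))[1] > 0
        ]
        female_afs = [
            rec.popcounts.per_sex["female"][0] / rec.popcounts.per_sex["female"][1]
            for rec in recs
            if rec.popcounts.per_sex.get("female", (0, 0))[1] > 0
        ]
        mean_m, mean_f, p = sex_af_comparison(male_afs, female_afs)
        row["af_male"] = mean_m
        row["af_female"] = mean_f
        row["sex_p_value"] = p
        rows.append(row)
    df = pd.DataFrame(rows)
    # allele conservation sanity: summed per-ancestry AC never exceeds
    # the overall AC (equality when all strata are present)
    if len(df):
        strat_sum = df[[f"ac_{a}" for a in ANCESTRIES]].sum(axis=1)
        if (strat_sum > df["ac"]).any():
            raise AssertionError("per-ancestry AC exceeds overall AC")
        if convention is PrevalenceConvention.AC_BASED:
            # AC >= N always (each variant carries >= 1 allele), so the
            # AC-based denominator can never exceed the N-based one
            n_based = df.apply(
                lambda r: prevalence(
                    int(r["n_plp_variants"]),
                    cohort.n_individuals[r["gene"]],
                    PrevalenceConvention.N_BASED,
                )
                if r["n_plp_variants"]
                else None,
                axis=1,
            )
            both = df["prevalence_denominator"].notna() & n_based.notna()
            if (df.loc[both, "prevalence_denominator"] > n_based[both]).any():
                raise AssertionError(
                    "AC-based prevalence denominator exceeds N-based"
                )
    return df


def group_af_regression(
    groups: Mapping[str, tuple[int, int]], reference: str
) -> pd.DataFrame:
    """Logistic regression of allele carriage on group membership.

    ``groups`` maps label -> (ac, an): ``ac`` alleles carried out of
    ``an`` trials. Fits a binomial GLM with ``reference`` as baseline
    and returns one row per non-reference group with the odds ratio,
    Wald 95% CI and p-value. Groups with ac = 0 or ac = an separate
    perfectly: they are flagged and their CI is reported unbounded.
    """
    import statsmodels.api as sm

    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not in groups")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    labels = [reference] + [g for g in groups if g != reference]
    endog = np.array([[groups[g][0], groups[g][1] - groups[g][0]] for g in labels])
    if (endog < 0).any():
        raise ValueError("ac must lie in [0, an] for every group")
    exog = np.zeros((len(labels), len(labels)))
    exog[:, 0] = 1.0
    for i in range(1, len(labels)):
        exog[i, i] = 1.0

    separated = {
        g: groups[g][0] == 0 or groups[g][0] == groups[g][1] for g in labels
    }
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    import warnings as _warnings

    with np.errstate(all="ignore"), _warnings.catch_warnings():
        # a saturated grouped design predicts each row exactly, which
        # statsmodels reports as perfect prediction; expected here
        _warnings.simplefilter("ignore")
        fit = model.fit(maxiter=200)
    rows = []
    for i, g in enumerate(labels[1:], start=1):
        flagged = separated[g] or separated[reference]
        coef = fit.params[i]
        se = fit.bse[i]
        if flagged or not np.isfinite(se) or se > 1e3:
            ci_low, ci_high, p = 0.0, math.inf, None
            flagged = True
        else:
            ci_low = math.exp(coef - 1.96 * se)
            ci_high = math.exp(coef + 1.96 * se)
            p = float(fit.pvalues[i])
        rows.append(
            {
                "group": g,
                "odds_ratio": float(math.exp(coef)) if np.isfinite(coef) else math.inf,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "p_value": p,
                "separation": flagged,
            }
        )
    return pd.DataFrame(
        rows, columns=["group", "odds_ratio", "ci_low", "ci_high", "p_value", "separation"]
    )
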