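"""Cohort-level statistics: group comparisons, correlation, logistic risk model.

The analysis layer for a per-eye cohort table: two-group comparisons
(Mann-Whitney U for independent numeric data, Wilcoxon signed-rank for
paired numeric data, Pearson chi-squared with a Fisher-exact fallback for
categorical data), Spearman rank correlation, and uni/multivariate binary
logistic regression of the recurrence outcome with Wald 95 % confidence
intervals.  All p-values are two-sided; no multiple-testing correction is
applied by default (a Holm adjuster is provided but off by default).

Odds-ratio derivations translate a per-unit OR into a percent risk increase
per unit and the smallest whole-unit increment that doubles the odds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import StatsError

Z_95 = 1.96


def snellen_to_logmar(acuity) -> float:
    """Convert Snellen acuity to logMAR = −log10(numerator/denominator).

    Accepts a "20/32"-style string, a (numerator, denominator) pair, or a
    decimal acuity fraction.
    """
    if isinstance(acuity, str):
        num_s, _, den_s = acuity.partition("/")
        if not den_s:
            raise ValueError(f"cannot parse Snellen acuity {acuity!r}")
        num, den = float(num_s), float(den_s)
    elif isinstance(acuity, (tuple, list)):
        num, den = float(acuity[0]), float(acuity[1])
    else:
        num, den = float(acuity), 1.0
    if num <= 0 or den <= 0:
        raise ValueError("Snellen numerator and denominator must be positive")
    return -math.log10(num / den)


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    test: str
    n1: int
    n2: int
    note: str = ""


def compare_groups(table: pd.DataFrame, variable: str, group: str,
                   test: str = "mann_whitney") -> GroupComparison:
    """Two-sided comparison of ``variable`` between the two levels of ``group``.

    tests: ``mann_whitney`` (independent numeric; exact enumeration when both
    groups have n ≤ 10 and no ties, tie-corrected normal approximation
    otherwise), ``wilcoxon_paired`` (matched numeric), ``chi2`` (categorical;
    warns when any expected count is below 5, echoing the usual fall back to
    Fisher), ``fisher`` (2×2 exact).
    """
    levels = sorted(pd.unique(table[group].dropna()))
    if len(levels) != 2:
        raise StatsError(f"grouping variable {group!r} must have exactly two "
                         f"levels, got {levels}")
    a = table.loc[table[group] == levels[0], variable].dropna().to_numpy()
    b = table.loc[table[group] == levels[1], variable].dropna().to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise StatsError(f"empty group for {group!r}")

    if test == "mann_whitney":
        pooled = np.concatenate([a, b])
        ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(a) <= 10 and len(b) <= 10 and not ties) \
            else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return GroupComparison(float(res.statistic), float(res.pvalue),
                               f"mann_whitney[{method}]", len(a), len(b))
    if test == "wilcoxon_paired":
        if len(a) != len(b):
            raise StatsError("paired test requires matched samples")
        res = sps.wilcoxon(a, b, alternative="two-sided")
        return GroupComparison(float(res.statistic), float(res.pvalue),
                               "wilcoxon_paired", len(a), len(b))
    if test in ("chi2", "fisher"):
        contingency = pd.crosstab(table[group], table[variable]).to_numpy()
        if test == "fisher":
            if contingency.shape != (2, 2):
                raise StatsError("Fisher exact test requires a 2x2 table")
            odds, p = sps.fisher_exact(contingency, alternative="two-sided")
            return GroupComparison(float(odds), float(p), "fisher",
                                   len(a), len(b))
        chi2, p, _, expected = sps.chi2_contingency(contingency,
                                                    correction=False)
        note = ""
        if (expected < 5).any():
            note = "expected count < 5; consider Fisher's exact test"
            warnings.warn(note, stacklevel=2)
        return GroupComparison(float(chi2), float(p), "chi2", len(a), len(b),
                               note=note)
    raise ValueError(f"unknown test {test!r}")


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    undefined: bool = False


def spearman_corr(x, y) -> SpearmanResult:
    """Spearman rank correlation (mid-ranks for ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise StatsError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(math.nan, math.nan, len(x), undefined=True)
    rho, p = sps.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p), len(x))


@dataclass
class TermResult:
    term: str
    coefficient: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class LogisticFitResult:
    terms: list[TermResult]
    intercept: float
    log_likelihood: float
    converged: bool
    separation_flag: bool = False
    n: int = 0

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)


def _fit_logit(y: np.ndarray, x: pd.DataFrame) -> LogisticFitResult:
    design = sm.add_constant(x, has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception as exc:  # perfect separation raises in statsmodels
            raise StatsError(f"logistic fit failed: {exc}") from exc
    converged = bool(fit.mle_retvals.get("converged", False))
    if not converged or np.abs(fit.params.to_numpy()).max() > 50:
        separation = np.abs(fit.params.to_numpy()).max() > 50
    terms = []
    for name in x.columns:
        coef = float(fit.params[name])
        se = float(fit.bse[name])
        terms.append(TermResult(
            term=name, coefficient=coef, se=se,
            odds_ratio=math.exp(coef),
            ci_low=math.exp(coef - Z_95 * se),
            ci_high=math.exp(coef + Z_95 * se),
            p_value=float(fit.pvalues[name])))
    return LogisticFitResult(terms=terms,
                             intercept=float(fit.params["const"]),
                             log_likelihood=float(fit.llf),
                             converged=converged,
                             separation_flag=separation,
                             n=len(y))


def logistic_fit(table: pd.DataFrame, outcome: str, terms: list[str],
                 mode: str = "multivariate"
                 ) -> LogisticFitResult | dict[str, LogisticFitResult]:
    """Binary logistic regression by maximum likelihood.

    ``multivariate`` fits all terms jointly; ``univariate`` fits each term
    alone and returns a dict keyed by term.  Non-convergence or suspected
    separation is flagged on the result rather than silently reported.
    """
    y = table[outcome].astype(float).to_numpy()
    if set(np.unique(y)) != {0.0, 1.0}:
        raise StatsError("outcome must be binary with both classes present")
    x = table[terms].astype(float)
    if mode == "multivariate":
        rank = np.linalg.matrix_rank(np.column_stack(
            [np.ones(len(x)), x.to_numpy()]))
        if rank < len(terms) + 1:
            raise StatsError("perfectly collinear terms")
        return _fit_logit(y, x)
    if mode == "univariate":
        return {t: _fit_logit(y, x[[t]]) for t in terms}
    raise ValueError("mode must be 'univariate' or 'multivariate'")


def select_univariate_terms(table: pd.DataFrame, outcome: str,
                            candidates: list[str],
                            alpha: float = 0.05) -> list[str]:
    """Terms entering the multivariate model: univariate p < alpha.

    This explicit rule (logged by the pipeline) governs which candidate
    covariates progress to the joint model; override by passing terms
    directly to :func:`logistic_fit`.
    """
    fits = logistic_fit(table, outcome, candidates, mode="univariate")
    return [t for t in candidates if fits[t].terms[0].p_value < alpha]


@dataclass
class OrDerivation:
    odds_ratio: float
    pct_increase_per_unit: float
    doubling_units: int


def or_derivations(or_per_unit: float) -> OrDerivation:
    """Translate a per-unit odds ratio into interpretable risk statements.

    Percent odds increase per unit = (OR − 1)·100; the doubling increment is
    the smallest integer k with OR^k ≥ 2.  Requires OR > 1 (no doubling
    exists otherwise).
    """
    if or_per_unit <= 1.0:
        raise StatsError("odds ratio must exceed 1 for a doubling increment")
    pct = (or_per_unit - 1.0) * 100.0
    k = max(1, math.ceil(math.log(2.0) / math.log(or_per_unit)))
    while or_per_unit ** (k - 1) >= 2.0 and k > 1:
        k -= 1
    while or_per_unit ** k < 2.0:
        k += 1
    return OrDerivation(or_per_unit, pct, k)


def recurrence_percentage(table: pd.DataFrame,
                          flag_col: str = "recurrent") -> float:
    """Percent of eyes with the recurrence flag set."""
    flags = table[flag_col].astype(bool)
    if len(flags) == 0:
        raise StatsError("empty cohort table")
    return float(flags.mean() * 100.0)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default everywhere)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
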