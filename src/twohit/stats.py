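"""Case–control allelic association and auxiliary statistics.

A 2x2 allele-count table compares allele A1 against A2 between cases and
controls.  The odds ratio is the cross-product (a·d)/(b·c) with a Woolf
(log-scale normal) 95% CI; zero cells take the Haldane–Anscombe +0.5
correction when enabled.  Exact p-values come from Fisher's test (summing
hypergeometric point probabilities no larger than the observed one, margins
fixed).  The logistic route fits case status on the binary allele indicator
by maximum likelihood; for a single binary predictor the fitted odds ratio
coincides with the cross-product OR, which the tests exploit as an identity
check.  A chi-square contingency test covers r x c staining-pattern style
comparisons, and a small screen runs the allelic test across phenotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .model import ConfigError, InputError

__all__ = [
    "TwoByTwoTable",
    "AssociationResult",
    "odds_ratio_2x2",
    "fisher_exact",
    "logistic_fit_binary",
    "genotype_concordance",
    "chi_square_contingency",
    "multi_phenotype_screen",
]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Allele counts: a/b = A1/A2 in cases, c/d = A1/A2 in controls."""

    a: int
    b: int
    c: int
    d: int
    allele_a1: str = "A1"
    allele_a2: str = "A2"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError("2x2 cell counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def freq_a1(self) -> Optional[float]:
        return (self.a + self.c) / self.total if self.total else None


@dataclass
class AssociationResult:
    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float]
    method: str
    case_alleles: int
    control_alleles: int
    freq_a1: Optional[float]
    continuity_corrected: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (
            self.odds_ratio is not None
            and self.ci_low is not None
            and not (self.ci_low <= self.odds_ratio <= self.ci_high)
        ):
            raise ValueError("CI must bracket the odds ratio")

    def to_dict(self) -> dict:
        return {
            "odds_ratio": self.odds_ratio,
            "ci95": [self.ci_low, self.ci_high],
            "p_value": self.p_value,
            "method": self.method,
            "case_alleles": self.case_alleles,
            "control_alleles": self.control_alleles,
            "freq_a1": self.freq_a1,
            "continuity_corrected": self.continuity_corrected,
            "flags": list(self.flags),
        }


def odds_ratio_2x2(
    table: TwoByTwoTable, continuity: str = "auto"
) -> AssociationResult:
    """Cross-product odds ratio with Woolf 95% CI and Fisher p-value.

    ``continuity``: ``auto`` applies the Haldane–Anscombe +0.5 to every cell
    when any cell is zero (flagged in the result); ``off`` raises on tables
    whose OR is undefined.
    """
    if continuity not in ("auto", "off"):
        raise ConfigError(f"continuity must be auto|off, got {continuity!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = False
    if min(a, b, c, d) == 0:
        if continuity == "off":
            if (a == 0 and b == 0) or (c == 0 and d == 0) \
                    or (a == 0 and c == 0) or (b == 0 and d == 0):
                raise InputError("odds ratio undefined: empty margin")
            if b == 0 or c == 0:
                raise InputError("odds ratio infinite without continuity correction")
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        corrected = True
    odds = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = odds * math.exp(-1.96 * se), odds * math.exp(1.96 * se)
    return AssociationResult(
        odds_ratio=odds,
        ci_low=lo,
        ci_high=hi,
        p_value=fisher_exact(table),
        method="fisher",
        case_alleles=table.a + table.b,
        control_alleles=table.c + table.d,
        freq_a1=table.freq_a1,
        continuity_corrected=corrected,
    )


def fisher_exact(table: TwoByTwoTable) -> float:
    """Two-sided Fisher exact p (hypergeometric point-probability rule)."""
    if table.total == 0:
        return 1.0
    return float(
        stats.fisher_exact(
            [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
        ).pvalue
    )


def logistic_fit_binary(
    table: TwoByTwoTable,
) -> tuple[Optional[float], Optional[float], float, Optional[float]]:
    """ML logistic fit of case status on the binary A1-allele indicator.

    Returns ``(intercept, slope, odds_ratio, wald_p)``.  With a zero cell the
    MLE diverges (separation); the fit is flagged by returning ``None`` for
    intercept, slope and p, with the odds ratio from the continuity-corrected
    cross-product instead.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a + c, b + d, a + b, c + d) == 0:
        raise InputError("logistic fit needs positive margins")
    if min(a, b, c, d) == 0:
        orr = odds_ratio_2x2(table, continuity="auto")
        return None, None, orr.odds_ratio, None
    y = np.array([1, 1, 0, 0], dtype=float)          # case status
    x = np.array([1, 0, 1, 0], dtype=float)          # A1 indicator
    w = np.array([a, b, c, d], dtype=float)
    X = sm.add_constant(x)
    fit = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit(
        tol=1e-10, maxiter=50
    )
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    wald_p = float(fit.pvalues[1])
    return intercept, slope, math.exp(slope), wald_p


def genotype_concordance(
    calls_a: Sequence[str], calls_b: Sequence[str]
) -> tuple[Optional[float], int]:
    """Fraction of matching calls among pairwise non-missing pairs.

    Returns ``(concordance, n_comparable)``; concordance is ``None`` when no
    pair is comparable.
    """
    if len(calls_a) != len(calls_b):
        raise InputError("call vectors must have equal length")
    pairs = [
        (x, y) for x, y in zip(calls_a, calls_b)
        if x != "missing" and y != "missing"
    ]
    if not pairs:
        return None, 0
    matches = sum(1 for x, y in pairs if x == y)
    return matches / len(pairs), len(pairs)


def chi_square_contingency(observed) -> tuple[float, int, float]:
    """Pearson chi-square over an r x c table: ``(statistic, df, p)``."""
    arr = np.asarray(observed, dtype=float)
    if arr.ndim != 2:
        raise InputError("contingency table must be 2-dimensional")
    if (arr < 0).any():
        raise InputError("contingency counts must be nonnegative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise InputError("contingency table has a zero margin")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), int(df), float(p)


def multi_phenotype_screen(
    tables: dict[str, TwoByTwoTable], alpha: float = 0.05
) -> list[dict]:
    """Allelic association per phenotype, ranked by p-value.

    Every phenotype is retained in the output; those with p < ``alpha`` are
    flagged.  A Bonferroni-adjusted p is included for information only (no
    correction is applied to the flagging rule).
    """
    m = len(tables)
    results = []
    for phenotype, table in tables.items():
        res = odds_ratio_2x2(table)
        results.append(
            {
                "phenotype": phenotype,
                **res.to_dict(),
                "significant": res.p_value is not None and res.p_value < alpha,
                "p_bonferroni": (
                    None if res.p_value is None else min(res.p_value * m, 1.0)
                ),
            }
        )
    results.sort(key=lambda r: (r["p_value"] is None, r["p_value"]))
    return results
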