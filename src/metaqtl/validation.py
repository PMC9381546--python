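"""Marker-allele vs extreme-phenotype association (validation panel)."""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import pandas as pd

from .errors import DegenerateTableError, DomainError

DEFAULT_LOW_MAX = 12.50
DEFAULT_HIGH_MIN = 25.00


@dataclass
class ValidationResult:
    table: list[list[int]]  # rows: phenotype classes; cols: allele classes
    fisher_p: float
    concordance: float
    phenotype_classes: list[str] = field(default_factory=list)
    allele_classes: list[str] = field(default_factory=list)
    thresholds: tuple[float, float] = (DEFAULT_LOW_MAX, DEFAULT_HIGH_MIN)
    validated: bool = False

    def to_dict(self) -> dict:
        return {
            "table": self.table,
            "fisher_p": self.fisher_p,
            "concordance": self.concordance,
            "phenotype_classes": self.phenotype_classes,
            "allele_classes": self.allele_classes,
            "thresholds": list(self.thresholds),
            "validated": self.validated,
        }


def classify_phenotypes(
    panel: pd.DataFrame,
    low_max: float = DEFAULT_LOW_MAX,
    high_min: float = DEFAULT_HIGH_MIN,
) -> pd.Series:
    """Label each genotype low / high / excluded by its grain weight.

    Strictly below ``low_max`` is low, strictly above ``high_min`` is high,
    anything in between is excluded from the test.
    """
    if not low_max < high_min:
        raise DomainError("low_max must be below high_min")
    tgw = panel["tgw_g"].astype(float)

    def label(v: float) -> str:
        if v < low_max:
            return "low"
        if v > high_min:
            return "high"
        return "excluded"

    labels = tgw.map(label)
    if (labels == "excluded").all():
        raise DomainError("all genotypes fall between the thresholds")
    return labels


def fisher_exact_two_sided(table: list[list[int]]) -> float:
    """Two-sided Fisher exact p for a 2×2 table by full enumeration.

    All tables with the observed margins are enumerated; the p-value is the
    sum of hypergeometric probabilities not exceeding the observed table's
    (with a small relative slack for float round-off).
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if min(r1, r2, c1, n - c1) < 0:
        raise DomainError("table cells must be non-negative")
    denom = comb(n, c1)

    def prob(k: int) -> float:
        return comb(r1, k) * comb(r2, c1 - k) / denom

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = sum(
        prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-7)
    )
    return min(total, 1.0)


def association_test(
    labels: pd.Series | list[str],
    alleles: pd.Series | list[str],
    thresholds: tuple[float, float] = (DEFAULT_LOW_MAX, DEFAULT_HIGH_MIN),
    p_threshold: float = 0.05,
) -> ValidationResult:
    """Test a 2×2 phenotype-class × allele-class association.

    Requires exactly two phenotype classes and at most two allele classes
    among the retained genotypes.  Reports the Fisher exact p (two-sided, by
    enumeration) and the concordance: the best achievable matched fraction
    over the two allele-to-class pairings.  A marker is flagged validated
    when p < ``p_threshold`` and concordance is perfect.
    """
    pairs = [
        (str(l), str(a))
        for l, a in zip(list(labels), list(alleles))
        if str(l) != "excluded"
    ]
    pheno_classes = sorted({l for l, _ in pairs})
    allele_classes = sorted({a for _, a in pairs})
    if len(pheno_classes) != 2:
        raise DomainError(
            f"need exactly 2 phenotype classes, found {pheno_classes}"
        )
    if len(allele_classes) > 2:
        raise DomainError(
            f"more than 2 allele classes ({allele_classes}); collapse rare "
            "alleles before testing"
        )
    if len(allele_classes) < 2:
        raise DegenerateTableError("only one allele class present")

    table = [
        [sum(1 for l, a in pairs if l == pc and a == ac) for ac in allele_classes]
        for pc in pheno_classes
    ]
    if any(sum(row) == 0 for row in table) or any(
        sum(table[r][c] for r in range(2)) == 0 for c in range(2)
    ):
        raise DegenerateTableError(f"empty margin in table {table}")

    p = fisher_exact_two_sided(table)
    n = len(pairs)
    matched = table[0][0] + table[1][1]
    swapped = table[0][1] + table[1][0]
    concordance = max(matched, swapped) / n
    return ValidationResult(
        table=table,
        fisher_p=p,
        concordance=concordance,
        phenotype_classes=pheno_classes,
        allele_classes=allele_classes,
        thresholds=thresholds,
        validated=bool(p < p_threshold and concordance == 1.0),
    )
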