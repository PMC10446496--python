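"""Mendelian dosage model for trans-heterozygote complementation crosses.

A reduced-rate promoter allele can be tested against a null allele by
selfing a heterozygous hermaphrodite and scoring larval arrest in the
progeny.  Each allele carries an activity in [0, 1] relative to one
wild-type copy (a null is 0; a promoter mutant with a 26% rate reduction
is 0.74).  Expression of a genotype is the additive mean of its two allele
activities, so a null heterozygote shows a 50% reduction and a
promoter-mutant/null trans-heterozygote ~63%.  Selfing a heterozygote
yields the Mendelian ¼ : ½ : ¼ genotype split; combining those fractions
with a genotype → viable/arrest rule gives the expected arrest fraction
(¼ when only the null homozygote arrests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "Allele",
    "CrossDesign",
    "genotype_key",
    "selfing_genotype_fractions",
    "expression_reduction",
    "expected_arrest_fraction",
]

WILD_TYPE_ACTIVITY = 1.0


@dataclass(frozen=True)
class Allele:
    """A named allele with expression activity relative to one WT copy."""

    name: str
    activity: float

    def __post_init__(self):
        if not 0.0 <= self.activity <= 1.0:
            raise ValueError("allele activity must be in [0, 1]")


def genotype_key(a: Allele, b: Allele) -> tuple[str, str]:
    """Order-free genotype identifier (sorted allele names)."""
    return tuple(sorted((a.name, b.name)))


@dataclass(frozen=True)
class CrossDesign:
    """A selfing parent genotype plus a genotype → viability rule.

    viability_rule maps genotype keys to "viable" or "arrest".
    """

    parent_genotype: tuple[Allele, Allele]
    viability_rule: Mapping[tuple[str, str], str] = field(default_factory=dict)
    selfing: bool = True


def selfing_genotype_fractions(
    parent: CrossDesign | tuple[Allele, Allele],
) -> dict[tuple[str, str], float]:
    """Mendelian progeny fractions from selfing.

    A heterozygote yields ¼ / ½ / ¼ of the two homozygotes and the
    heterozygote; a homozygous parent yields a single genotype.
    """
    a, b = parent.parent_genotype if isinstance(parent, CrossDesign) else parent
    if a.name == b.name:
        return {genotype_key(a, b): 1.0}
    return {
        genotype_key(a, a): 0.25,
        genotype_key(a, b): 0.5,
        genotype_key(b, b): 0.25,
    }


def expression_reduction(genotype: tuple[Allele, Allele]) -> float:
    """Percent expression reduction vs wild type, additive allele model.

    100 × (1 − mean activity): WT/null → 50; promoter-mutant(0.74)/null →
    63.  No dominance term — each allele contributes independently.
    """
    a, b = genotype
    return 100.0 * (1.0 - (a.activity + b.activity) / 2.0)


def expected_arrest_fraction(
    fractions: Mapping[tuple[str, str], float],
    viability_rule: Mapping[tuple[str, str], str],
) -> float:
    """Expected arrest fraction: total probability of arresting genotypes."""
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("genotype fractions must sum to 1")
    arrest = 0.0
    for genotype, frac in fractions.items():
        if genotype not in viability_rule:
            raise ValueError(f"viability rule missing genotype {genotype}")
        if viability_rule[genotype] == "arrest":
            arrest += frac
    return arrest
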