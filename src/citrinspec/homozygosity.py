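"""Observed and theoretical homozygosity (allelic heterogeneity).

Theoretical homozygosity is the gene identity J = sum_i Xi^2 over allele
frequencies Xi = m/N: the probability that two alleles drawn at random from
a region are identical; 1 - J is the gene diversity.  Each undetected
("obscure") allele is treated as a distinct allele of frequency 1/N, so a
region with u unknown alleles contributes u * (1/N)^2 to J.  Observed
homozygosity is the fraction of included families whose two alleles carry
the same variant identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .geo_stats import TestResult, omnibus_test
from .spectrum import GenotypeSpectrum, RegionalSpectrum

__all__ = [
    "HomozygosityReport",
    "observed_homozygosity",
    "theoretical_homozygosity",
    "compare_homozygosity",
]


@dataclass
class HomozygosityReport:
    region: str
    observed_numerator: int | None = None
    observed_denominator: int | None = None
    theoretical_J: float | None = None
    n_families: int | None = None
    allele_frequencies_used: dict[str, float] = field(default_factory=dict)
    unknown_allele_policy: str = "each-unique"

    @property
    def observed(self) -> float | None:
        if self.observed_numerator is None:
            return None
        return self.observed_numerator / self.observed_denominator


def observed_homozygosity(gspec: GenotypeSpectrum, region: str) -> HomozygosityReport:
    """Fraction of families in a region with two identical allele identities."""
    denom = gspec.n_families.get(region, 0)
    if denom == 0:
        raise ValueError(f"region {region!r} has no families")
    num = sum(
        c.get(region, 0)
        for g, c in gspec.counts.items()
        if gspec.is_homozygous(g)
    )
    return HomozygosityReport(
        region=region,
        observed_numerator=num,
        observed_denominator=denom,
        n_families=denom,
    )


def theoretical_homozygosity(
    spec: RegionalSpectrum, region: str, n_families: int | None = None
) -> HomozygosityReport:
    """Gene identity J = sum Xi^2, unknown alleles each unique at 1/N.

    Computed in exact rational arithmetic; a compound allele enters as its
    own identity with a single Xi, so sum Xi = 1 within each region.
    """
    n = spec.n_alleles.get(region, 0)
    if n == 0:
        raise ValueError(f"region {region!r} has N = 0 alleles")
    j = Fraction(0)
    freqs: dict[str, float] = {}
    for ident in spec.identities:
        m = spec.count(ident, region)
        if m:
            x = Fraction(m, n)
            j += x * x
            freqs[ident] = float(x)
    u = spec.unknown_counts.get(region, 0)
    j += u * Fraction(1, n) ** 2
    return HomozygosityReport(
        region=region,
        theoretical_J=float(j),
        n_families=n_families,
        allele_frequencies_used=freqs,
    )


def _round_half_away(x: float) -> int:
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def compare_homozygosity(
    a: HomozygosityReport, b: HomozygosityReport, kind: str
) -> TestResult:
    """2x2 homozygous-vs-heterozygous comparison between two regions.

    ``kind="observed"`` uses the observed family counts directly.
    ``kind="theoretical"`` forms expected homozygote counts round(J x
    families) -- a declared convention, since J is a probability, not a
    count.  Test selection follows the shared carrier-table rule (Pearson
    without continuity correction when expected counts allow, else exact).
    """
    if kind == "observed":
        if a.observed_numerator is None or b.observed_numerator is None:
            raise ValueError("observed comparison requires observed reports")
        counts = [a.observed_numerator, b.observed_numerator]
        totals = [a.observed_denominator, b.observed_denominator]
    elif kind == "theoretical":
        if a.theoretical_J is None or b.theoretical_J is None:
            raise ValueError("theoretical comparison requires J reports")
        if a.n_families is None or b.n_families is None:
            raise ValueError("theoretical comparison requires family counts")
        counts = [
            _round_half_away(a.theoretical_J * a.n_families),
            _round_half_away(b.theoretical_J * b.n_families),
        ]
        totals = [a.n_families, b.n_families]
    else:
        raise ValueError(f"unknown comparison kind {kind!r}")
    return omnibus_test(counts, totals)
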