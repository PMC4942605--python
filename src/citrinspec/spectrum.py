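"""Region-stratified allele and genotype spectra.

The allele spectrum tallies, per region, how many of the 2-per-family
independent chromosomes carry each catalogued variant identity; alleles on
which no mutation was detected are kept in a separate "unknown" row that
still participates in every denominator.  A cis-compound allele counts once,
under its compound identity, so column sums always equal the regional allele
total N.  Frequencies are Xi = m/N, reported on the percentage scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .variant_model import UNKNOWN_TOKEN
from .cohort_io import Cohort

__all__ = [
    "RegionalSpectrum",
    "GenotypeSpectrum",
    "allele_spectrum",
    "genotype_spectrum",
    "relative_frequencies",
    "diagnostic_efficiency",
    "combined_frequency",
    "round_pct",
]


def round_pct(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching printed table conventions."""
    scale = 10**ndigits
    return (int(abs(x) * scale * 2 + 1) // 2) / scale * (1 if x >= 0 else -1)


@dataclass
class RegionalSpectrum:
    """Per-region allele counts per variant identity, plus unknown alleles.

    Invariant: for every region, sum of variant counts + unknown count = N.
    """

    counts: dict[str, dict[str, int]]
    unknown_counts: dict[str, int] = field(default_factory=dict)
    n_alleles: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for region, n in self.n_alleles.items():
            tot = self.region_detected(region) + self.unknown_counts.get(region, 0)
            if tot != n:
                raise ValueError(
                    f"region {region!r}: counts sum to {tot}, N is {n}"
                )

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.n_alleles)

    @property
    def identities(self) -> list[str]:
        return sorted(self.counts)

    def count(self, identity: str, region: str) -> int:
        if identity == UNKNOWN_TOKEN:
            return self.unknown_counts.get(region, 0)
        return self.counts.get(identity, {}).get(region, 0)

    def region_detected(self, region: str) -> int:
        return sum(c.get(region, 0) for c in self.counts.values())

    def total_n(self) -> int:
        return sum(self.n_alleles.values())

    def total_count(self, identity: str) -> int:
        return sum(self.count(identity, r) for r in self.regions)

    def frequency(self, identity: str, region: str) -> Fraction:
        """Exact allele frequency Xi = m/N for one region."""
        n = self.n_alleles[region]
        if n == 0:
            raise ZeroDivisionError(f"region {region!r} has N = 0")
        return Fraction(self.count(identity, region), n)


@dataclass
class GenotypeSpectrum:
    """Per-region counts of unordered genotype identities over families."""

    counts: dict[str, dict[str, int]]
    n_families: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for region, n in self.n_families.items():
            tot = sum(c.get(region, 0) for c in self.counts.values())
            if tot != n:
                raise ValueError(
                    f"region {region!r}: genotype counts sum to {tot}, N is {n}"
                )

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.n_families)

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.counts)

    @property
    def n_genotypes(self) -> int:
        return sum(1 for g, c in self.counts.items() if any(c.values()))

    def count(self, genotype: str, region: str) -> int:
        return self.counts.get(genotype, {}).get(region, 0)

    def total_count(self, genotype: str) -> int:
        return sum(self.count(genotype, r) for r in self.regions)

    def is_homozygous(self, genotype: str) -> bool:
        left, right = split_genotype_identity(genotype)
        return left == right


def split_genotype_identity(genotype: str) -> tuple[str, str]:
    """Split an unordered genotype identity string into its two allele ids."""
    parts, depth, buf = [], 0, []
    for ch in genotype:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
        if ch == "/" and depth == 0:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    parts.append("".join(buf))
    if len(parts) != 2:
        raise ValueError(f"malformed genotype identity {genotype!r}")
    return parts[0], parts[1]


def allele_spectrum(cohort: Cohort) -> RegionalSpectrum:
    """Tally 2 alleles per family representative, stratified by region.

    The cohort should already be family-deduplicated; every record
    contributes exactly two chromosomes to its region's column.
    """
    counts: dict[str, dict[str, int]] = {}
    unknown: dict[str, int] = {}
    n_alleles: dict[str, int] = {}
    for rec in cohort.records:
        for allele in rec.genotype:
            region = rec.region
            n_alleles[region] = n_alleles.get(region, 0) + 1
            if allele.unknown:
                unknown[region] = unknown.get(region, 0) + 1
            else:
                row = counts.setdefault(allele.identity, {})
                row[region] = row.get(region, 0) + 1
    return RegionalSpectrum(counts=counts, unknown_counts=unknown, n_alleles=n_alleles)


def genotype_spectrum(cohort: Cohort) -> GenotypeSpectrum:
    """Tally unordered genotype identities per region over families."""
    counts: dict[str, dict[str, int]] = {}
    n_families: dict[str, int] = {}
    for rec in cohort.records:
        region = rec.region
        n_families[region] = n_families.get(region, 0) + 1
        row = counts.setdefault(rec.genotype_identity, {})
        row[region] = row.get(region, 0) + 1
    return GenotypeSpectrum(counts=counts, n_families=n_families)


def relative_frequencies(
    spec: RegionalSpectrum, region: str = "all"
) -> dict[str, float]:
    """Relative frequency (%) of every identity, including the unknown row.

    ``region="all"`` pools regional counts before dividing by the summed N.
    """
    idents = spec.identities + (
        [UNKNOWN_TOKEN] if any(spec.unknown_counts.values()) else []
    )
    if region == "all":
        n = spec.total_n()
        if n == 0:
            raise ZeroDivisionError("pooled N is 0")
        return {i: 100.0 * spec.total_count(i) / n for i in idents}
    return {i: 100.0 * float(spec.frequency(i, region)) for i in idents}


def diagnostic_efficiency(spec: RegionalSpectrum) -> float:
    """Percentage of pooled alleles on which a mutation was identified."""
    n = spec.total_n()
    if n == 0:
        raise ZeroDivisionError("pooled N is 0")
    unknown = sum(spec.unknown_counts.values())
    return 100.0 * (n - unknown) / n


def combined_frequency(spec: RegionalSpectrum, identities: list[str]) -> float:
    """Pooled relative frequency (%) of the listed identities together."""
    for ident in identities:
        if ident != UNKNOWN_TOKEN and ident not in spec.counts:
            raise KeyError(f"identity {ident!r} not in spectrum")
    n = spec.total_n()
    return 100.0 * sum(spec.total_count(i) for i in identities) / n
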