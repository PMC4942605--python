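"""Cohort table I/O, geographic region resolution and inclusion filters.

A cohort is a TSV with columns ``patient_id, family_id, sex,
father_province, mother_province, allele1, allele2`` (``?`` marks an
undetected allele, ``NA`` an unstated field).  Provinces are resolved to
north/border/south relative to the Yangtze boundary; a patient whose
parents resolve to different regions is ``mixed``.  The module also
rebuilds region-stratified allele/genotype count matrices from published
relative-frequency tables, validating that every reconstructed column sums
exactly to its printed margin.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

from .variant_model import (
    Allele,
    GenotypeParseError,
    VariantLookupError,
    VariantRegistry,
    genotype_identity,
    load_default_registry,
    parse_allele,
    render_allele,
)

__all__ = [
    "REGIONS",
    "PatientRecord",
    "RegionMap",
    "Cohort",
    "ReconstructionError",
    "SiblingConsistencyError",
    "load_default_region_map",
    "read_cohort",
    "write_cohort",
    "load_packaged_cohort",
    "dedupe_families",
    "genotype_analysis_subset",
    "build_allele_count_fixture",
    "build_genotype_count_fixture",
]

logger = logging.getLogger(__name__)

#: Geographic strata, south-to-north of the Yangtze plus the river corridor.
REGIONS = ("north", "border", "south")

#: Published allele totals per region (north, border, south).
ALLELE_REGION_N = {"north": 55, "border": 81, "south": 392}
#: Published genotype-analysis family totals per region.
GENOTYPE_REGION_N = {"north": 23, "border": 35, "south": 187}

_UNSTATED = "NA"
_COLUMNS = (
    "patient_id",
    "family_id",
    "sex",
    "father_province",
    "mother_province",
    "allele1",
    "allele2",
)


class ReconstructionError(ValueError):
    """A rebuilt count column does not sum to its printed margin."""


class SiblingConsistencyError(ValueError):
    """Same-family records carry discordant genotypes."""


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    family_id: str
    sex: str
    father_province: str
    mother_province: str
    region: str
    genotype: tuple[Allele, Allele]

    @property
    def genotype_identity(self) -> str:
        return genotype_identity(self.genotype)

    @property
    def has_unknown_allele(self) -> bool:
        return self.genotype[0].unknown or self.genotype[1].unknown


class RegionMap:
    """Province name -> region, case-insensitive, unstated-tolerant."""

    def __init__(self, mapping: dict[str, str]):
        self._map: dict[str, str] = {}
        for prov, region in mapping.items():
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r} for {prov!r}")
            self._map[prov.strip().lower()] = region

    @property
    def provinces(self) -> tuple[str, ...]:
        return tuple(self._map)

    def resolve(self, province: str | None) -> str:
        if not province or province.strip().upper() == _UNSTATED:
            return "unstated"
        return self._map.get(province.strip().lower(), "unstated")

    def patient_region(self, father: str | None, mother: str | None) -> str:
        fr, mr = self.resolve(father), self.resolve(mother)
        if fr == "unstated":
            return mr
        if mr == "unstated":
            return fr
        return fr if fr == mr else "mixed"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegionMap":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls._from_region_lists(raw)

    @classmethod
    def _from_region_lists(cls, raw: dict[str, list[str]]) -> "RegionMap":
        mapping: dict[str, str] = {}
        for region, provinces in raw.items():
            for prov in provinces:
                if prov.lower() in {p.lower() for p in mapping}:
                    raise ValueError(f"province {prov!r} listed in two regions")
                mapping[prov] = region
        return cls(mapping)


def load_default_region_map() -> RegionMap:
    ref = resources.files("citrinspec.data") / "region_map.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        return RegionMap._from_region_lists(yaml.safe_load(fh))


@dataclass
class Cohort:
    records: list[PatientRecord] = field(default_factory=list)
    row_errors: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def family_ids(self) -> list[str]:
        return sorted({r.family_id for r in self.records})

    def families(self) -> dict[str, list[PatientRecord]]:
        out: dict[str, list[PatientRecord]] = {}
        for r in self.records:
            out.setdefault(r.family_id, []).append(r)
        return out


def read_cohort(
    path: str | Path,
    region_map: RegionMap | None = None,
    registry: VariantRegistry | None = None,
) -> Cohort:
    """Read a cohort TSV; collect per-row parse errors instead of aborting."""
    region_map = region_map or load_default_region_map()
    registry = registry or load_default_registry()
    cohort = Cohort()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"cohort file missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                a1 = parse_allele(row["allele1"], registry)
                a2 = parse_allele(row["allele2"], registry)
            except (GenotypeParseError, VariantLookupError) as exc:
                msg = f"line {i} ({row.get('patient_id', '?')}): {exc}"
                cohort.row_errors.append(msg)
                logger.warning("skipping cohort row: %s", msg)
                continue
            father = row["father_province"]
            mother = row["mother_province"]
            cohort.records.append(
                PatientRecord(
                    patient_id=row["patient_id"].strip(),
                    family_id=row["family_id"].strip(),
                    sex=row["sex"].strip().lower() or "unstated",
                    father_province=father,
                    mother_province=mother,
                    region=region_map.patient_region(father, mother),
                    genotype=(a1, a2),
                )
            )
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to the standard TSV layout (canonical spellings)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_COLUMNS)
        for r in cohort.records:
            w.writerow(
                [
                    r.patient_id,
                    r.family_id,
                    r.sex,
                    r.father_province,
                    r.mother_province,
                    render_allele(r.genotype[0]),
                    render_allele(r.genotype[1]),
                ]
            )


def load_packaged_cohort(
    region_map: RegionMap | None = None,
    registry: VariantRegistry | None = None,
) -> Cohort:
    """Load the packaged 154-patient NICCD cohort table."""
    ref = resources.files("citrinspec.data") / "cohort_niccd.tsv"
    with resources.as_file(ref) as p:
        return read_cohort(p, region_map=region_map, registry=registry)


def dedupe_families(cohort: Cohort) -> Cohort:
    """Keep one representative record per family.

    Siblings must carry identical (unordered) genotypes; the representative
    is the lexicographically smallest patient id, which in this cohort is
    the proband (sibling ids append an ``S`` suffix).
    """
    out = Cohort(row_errors=list(cohort.row_errors))
    for fam, members in sorted(cohort.families().items()):
        idents = {m.genotype_identity for m in members}
        if len(idents) > 1:
            raise SiblingConsistencyError(
                f"family {fam!r} has discordant genotypes: {sorted(idents)}"
            )
        out.records.append(min(members, key=lambda m: m.patient_id))
    return out


def genotype_analysis_subset(
    cohort: Cohort,
) -> tuple[Cohort, dict[str, str]]:
    """Apply the genotype-analysis inclusion filters.

    Excludes families whose representative has any undetected allele and
    families of mixed parental geographic origin.  Returns the retained
    cohort and an exclusion log mapping family id -> reason.
    """
    kept = Cohort(row_errors=list(cohort.row_errors))
    excluded: dict[str, str] = {}
    for rec in cohort.records:
        if rec.has_unknown_allele:
            excluded[rec.family_id] = "single-mutation (unknown allele)"
        elif rec.region == "mixed":
            excluded[rec.family_id] = "mixed-region parents"
        else:
            kept.records.append(rec)
    return kept, excluded


def _round_half_away(x: Fraction) -> int:
    """Round a non-negative rational half away from zero."""
    n, d = x.numerator, x.denominator
    return (2 * n + d) // (2 * d)


def _reconstruct_column(
    freqs: dict[str, str | float], n_total: int, column: str
) -> dict[str, int]:
    counts = {}
    for ident, pct in freqs.items():
        frac = Fraction(str(pct)) * n_total / 100
        counts[ident] = _round_half_away(frac)
    total = sum(counts.values())
    if total != n_total:
        raise ReconstructionError(
            f"column {column!r}: reconstructed counts sum to {total}, "
            f"expected {n_total} (residual {total - n_total})"
        )
    return counts


def _read_freq_table(name: str, key_col: str) -> dict[str, dict[str, str]]:
    ref = resources.files("citrinspec.data") / name
    table: dict[str, dict[str, str]] = {}
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            table[row[key_col]] = {r: row[r] for r in REGIONS}
    return table


def build_allele_count_fixture():
    """Rebuild the region-stratified allele spectrum from published
    relative frequencies (N = 55/81/392 alleles; column sums validated)."""
    from .spectrum import RegionalSpectrum

    freq = _read_freq_table("allele_frequencies.tsv", "identity")
    counts: dict[str, dict[str, int]] = {}
    unknown: dict[str, int] = {}
    for region, n_total in ALLELE_REGION_N.items():
        col = _reconstruct_column(
            {ident: row[region] for ident, row in freq.items()}, n_total, region
        )
        for ident, c in col.items():
            if ident == "?":
                unknown[region] = c
            else:
                counts.setdefault(ident, {})[region] = c
    return RegionalSpectrum(
        counts=counts, unknown_counts=unknown, n_alleles=dict(ALLELE_REGION_N)
    )


def build_genotype_count_fixture(registry: VariantRegistry | None = None):
    """Rebuild the region-stratified genotype table from published relative
    frequencies (families N = 23/35/187; column sums validated).

    Genotype strings are normalized through the variant registry so legacy
    spellings collapse onto canonical identities.
    """
    from .spectrum import GenotypeSpectrum
    from .variant_model import parse_genotype

    registry = registry or load_default_registry()
    freq = _read_freq_table("genotype_frequencies.tsv", "genotype")
    canon: dict[str, dict[str, str]] = {}
    for raw, row in freq.items():
        pair = parse_genotype(raw, registry)
        canon[genotype_identity(pair)] = row
    counts: dict[str, dict[str, int]] = {}
    for region, n_total in GENOTYPE_REGION_N.items():
        col = _reconstruct_column(
            {g: row[region] for g, row in canon.items()}, n_total, region
        )
        for g, c in col.items():
            counts.setdefault(g, {})[region] = c
    return GenotypeSpectrum(counts=counts, n_families=dict(GENOTYPE_REGION_N))
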