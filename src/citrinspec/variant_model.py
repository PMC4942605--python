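"""Canonical representation and parsing of SLC25A13 mutation nomenclature.

Cohort sources mix systematic cDNA-level names (``c.851_854del4``) with
legacy intron-based aliases (``IVS16ins3kb``), print Unicode minus signs and
stray whitespace (``c.1452 + 1G > A``), annotate alleles with protein-level
consequences (``c.550C>T(p.R184X)``), and write cis-compound alleles in
brackets (``[c.851_854del4; c.1452+1G>A]``).  This module normalizes all of
that against a fixed variant registry and never tries to interpret HGVS
semantics positionally: a string either resolves to a catalogued variant (by
canonical id or alias) or parsing fails loudly.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator

__all__ = [
    "CATEGORIES",
    "UNKNOWN_TOKEN",
    "Variant",
    "Allele",
    "VariantRegistry",
    "VariantLookupError",
    "GenotypeParseError",
    "normalize_variant_string",
    "parse_allele",
    "parse_genotype",
    "render_allele",
    "render_genotype",
    "load_default_registry",
]

#: The nine variant classes used in the catalogue.
CATEGORIES = frozenset(
    {
        "missense",
        "nonsense",
        "deletion",
        "insertion",
        "duplication",
        "splice-site",
        "complex",
        "pathogenic-SNP",
        "aberrant-transcript",
    }
)

#: Raw token denoting an allele on which no mutation was detected.
UNKNOWN_TOKEN = "?"

# Unicode dash variants that occur in typeset mutation names.
_DASHES = {"−": "-", "–": "-", "—": "-"}
# Parenthesized protein-level annotation, e.g. "(p.R467X)" or "(p. R467X)".
_PROTEIN_ANNOT = re.compile(r"\(p\.[^)]*\)")


class VariantLookupError(KeyError):
    """A variant string does not resolve against the registry."""


class GenotypeParseError(ValueError):
    """A genotype or allele string is structurally malformed."""


def normalize_variant_string(raw: str) -> str:
    """Collapse a printed mutation name to its canonical spelling.

    Removes all whitespace, maps Unicode minus/dash characters to ASCII
    ``-``, and leaves brackets intact.  The transform is idempotent and
    purely lexical; it performs no registry lookup.
    """
    out = []
    for ch in raw:
        if ch.isspace():
            continue
        out.append(_DASHES.get(ch, ch))
    return "".join(out)


@dataclass(frozen=True)
class Variant:
    """One catalogued SLC25A13 mutation/variation."""

    canonical_id: str
    protein_effect: str = ""
    category: str = ""
    location_label: str = ""
    aliases: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.category and self.category not in CATEGORIES:
            raise ValueError(f"unknown variant category: {self.category!r}")


@dataclass(frozen=True)
class Allele:
    """One inherited chromosome: >=1 cis variants, or unknown.

    ``variants`` preserves the bracketed cis order of the source string.
    ``identity`` is the string used for counting: the canonical id for a
    single-variant allele, ``[a;b]`` for a compound, ``?`` for unknown.
    """

    variants: tuple[Variant, ...] = ()
    unknown: bool = False
    parent_of_origin: str = "unstated"

    def __post_init__(self) -> None:
        if self.unknown and self.variants:
            raise ValueError("unknown allele cannot carry variants")
        if not self.unknown and not self.variants:
            raise ValueError("known allele must carry at least one variant")

    @property
    def is_compound(self) -> bool:
        return len(self.variants) > 1

    @property
    def identity(self) -> str:
        if self.unknown:
            return UNKNOWN_TOKEN
        if self.is_compound:
            return "[" + ";".join(v.canonical_id for v in self.variants) + "]"
        return self.variants[0].canonical_id


class VariantRegistry:
    """Lookup table over catalogued variants, by canonical id or alias."""

    def __init__(self, entries: Iterable[Variant]):
        self._by_id: dict[str, Variant] = {}
        self._by_alias: dict[str, str] = {}
        for v in entries:
            if v.canonical_id in self._by_id:
                raise ValueError(f"duplicate canonical id {v.canonical_id!r}")
            self._by_id[v.canonical_id] = v
        for v in self._by_id.values():
            for a in v.aliases:
                if a in self._by_id or a in self._by_alias:
                    raise ValueError(f"alias {a!r} collides with another entry")
                self._by_alias[a] = v.canonical_id

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self._by_id.values())

    def __contains__(self, name: str) -> bool:
        n = normalize_variant_string(name)
        return n in self._by_id or n in self._by_alias

    def lookup(self, name: str) -> Variant:
        """Resolve a (possibly un-normalized, alias) name to its Variant."""
        n = normalize_variant_string(name)
        if n in self._by_id:
            return self._by_id[n]
        if n in self._by_alias:
            return self._by_id[self._by_alias[n]]
        raise VariantLookupError(name)


def load_default_registry() -> VariantRegistry:
    """Load the packaged 41-entry SLC25A13 variant catalogue."""
    ref = resources.files("citrinspec.data") / "variant_registry.tsv"
    entries = []
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t", restkey=None):
            aliases = row.get("aliases") or ""
            entries.append(
                Variant(
                    canonical_id=row["canonical_id"],
                    protein_effect=row["protein_effect"] or "",
                    category=row["category"],
                    location_label=row["location_label"],
                    aliases=frozenset(a for a in aliases.split("|") if a),
                )
            )
    return VariantRegistry(entries)


def _strip_protein_annotation(name: str) -> str:
    return _PROTEIN_ANNOT.sub("", name)


def parse_allele(raw: str, registry: VariantRegistry) -> Allele:
    """Parse one side of a genotype string into an :class:`Allele`.

    ``?`` yields the unknown allele.  A bracketed string is first tried as a
    single catalogued entity (the complex exon-5 del/ins mutation is one
    bracketed registry entry); otherwise it is split on ``;`` into a cis
    compound whose variants are resolved individually.
    """
    norm = _strip_protein_annotation(normalize_variant_string(raw))
    if not norm:
        raise GenotypeParseError("empty allele string")
    if norm == UNKNOWN_TOKEN:
        return Allele(unknown=True)
    if norm.startswith("[") and norm.endswith("]"):
        if norm in registry:
            return Allele(variants=(registry.lookup(norm),))
        parts = [p for p in norm[1:-1].split(";") if p]
        if len(parts) < 2:
            raise GenotypeParseError(f"malformed compound allele: {raw!r}")
        return Allele(variants=tuple(registry.lookup(p) for p in parts))
    return Allele(variants=(registry.lookup(norm),))


def _split_top_level(raw: str, sep: str = "/") -> list[str]:
    parts, depth, buf = [], 0, []
    for ch in raw:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
        if ch == sep and depth == 0:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    parts.append("".join(buf))
    return parts


def parse_genotype(raw: str, registry: VariantRegistry) -> tuple[Allele, Allele]:
    """Parse ``allele1/allele2`` into a pair of Alleles (source order kept)."""
    parts = _split_top_level(raw)
    if len(parts) != 2:
        raise GenotypeParseError(
            f"expected exactly one top-level '/' in genotype {raw!r}"
        )
    return parse_allele(parts[0], registry), parse_allele(parts[1], registry)


def render_allele(allele: Allele) -> str:
    """Render an Allele back to its canonical string form."""
    return allele.identity


def render_genotype(pair: tuple[Allele, Allele]) -> str:
    return f"{render_allele(pair[0])}/{render_allele(pair[1])}"


def genotype_identity(pair: tuple[Allele, Allele]) -> str:
    """Unordered genotype identity: allele identities, sorted."""
    return "/".join(sorted((pair[0].identity, pair[1].identity)))
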