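"""Domain types for the apricot S-locus pipeline.

Apricot (*Prunus armeniaca*) carries a gametophytic self-incompatibility
(GSI) system controlled by the multiallelic S-locus: the pistil-expressed
S-RNase arrests pollen tubes whose single S-haplotype matches either pistil
allele, while the pollen-expressed SFB gene determines pollen specificity.
One haplotype, Sc, carries a 358 bp insertion in SFB that abolishes
pollen-side rejection, so Sc-carrying cultivars are self-compatible.

This module defines the closed S-allele vocabulary, canonical unordered
S-genotypes, cultivar records, PCR primer-panel assay definitions, assay
results and the historical incompatibility-group registry, together with
their validation rules.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "UNKNOWN",
    "ALLELES",
    "SC",
    "parse_allele",
    "allele_sort_key",
    "SGenotype",
    "OriginClass",
    "CultivarRecord",
    "AssayId",
    "PrimerAssayDef",
    "AssayResult",
    "GroupRegistry",
    "normalize_name",
    "roman_to_int",
    "int_to_roman",
]

#: Sentinel for an unidentified allele (one-allele genotypes).
UNKNOWN = "?"

#: Closed vocabulary of named apricot S-alleles: S1..S20, S22..S31, S52,
#: S53, Sv, Sx plus the self-compatibility-associated Sc. S31 is included
#: because the compiled cultivar registry carries it ('Cow-1', 'Cow-2').
ALLELES: tuple[str, ...] = tuple(
    [f"S{i}" for i in range(1, 21)]
    + [f"S{i}" for i in range(22, 32)]
    + ["S52", "S53", "Sv", "Sx", "Sc"]
)

SC = "Sc"

_ALLELE_LOOKUP = {a.lower(): a for a in ALLELES}

# Fixed ordering used for genotype canonicalization: numeric alleles by
# number, then Sv, Sx, and Sc last (matching the conventional notation
# S1Sc etc.); UNKNOWN sorts after everything.
_ORDER = {a: i for i, a in enumerate(ALLELES)}
_ORDER[UNKNOWN] = len(ALLELES)


class AlleleError(ValueError):
    """Raised for tokens outside the closed S-allele vocabulary."""


def parse_allele(token: str) -> str:
    """Parse one allele token (case-insensitive) into canonical form.

    Empty/blank tokens and the literal ``?`` parse to :data:`UNKNOWN`.
    """
    tok = token.strip()
    if tok in ("", UNKNOWN):
        return UNKNOWN
    try:
        return _ALLELE_LOOKUP[tok.lower()]
    except KeyError:
        raise AlleleError(f"unknown S-allele token: {token!r}") from None


def allele_sort_key(allele: str) -> int:
    return _ORDER[allele]


@dataclass(frozen=True)
class SGenotype:
    """Unordered pair of S-allele labels; ``a2`` may be UNKNOWN.

    ``presumed_homozygous`` marks single-Sc cultivars reported elsewhere as
    ScSc: the second allele is formally unidentified (sequencing would be
    needed to prove homozygosity) but downstream compatibility verdicts
    treat the genotype as Sc Sc via :meth:`effective`.
    """

    a1: str
    a2: str = UNKNOWN
    presumed_homozygous: bool = False

    def __post_init__(self) -> None:
        a1, a2 = self.a1, self.a2
        if a1 not in _ORDER or a2 not in _ORDER:
            bad = a1 if a1 not in _ORDER else a2
            raise AlleleError(f"unknown S-allele token: {bad!r}")
        if a1 == UNKNOWN and a2 != UNKNOWN:
            a1, a2 = a2, a1
        if a1 == UNKNOWN:
            raise AlleleError("genotype needs at least one known allele")
        if allele_sort_key(a1) > allele_sort_key(a2):
            a1, a2 = a2, a1
        object.__setattr__(self, "a1", a1)
        object.__setattr__(self, "a2", a2)
        if self.presumed_homozygous and self.a1 != SC:
            raise AlleleError(
                "presumed_homozygous is reserved for single-Sc genotypes"
            )

    @classmethod
    def parse(
        cls, t1: str, t2: str = "", presumed_homozygous: bool = False
    ) -> "SGenotype":
        return cls(parse_allele(t1), parse_allele(t2), presumed_homozygous)

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.a1, self.a2)

    def complete(self) -> bool:
        return self.a2 != UNKNOWN

    def effective(self) -> tuple[str, str]:
        """Allele pair used for compatibility verdicts.

        A presumed-homozygous single-Sc genotype is treated as (Sc, Sc).
        """
        if self.presumed_homozygous and self.a2 == UNKNOWN:
            return (SC, SC)
        return (self.a1, self.a2)

    def contains(self, allele: str) -> bool:
        return allele in self.effective()

    def known_alleles(self) -> tuple[str, ...]:
        return tuple(a for a in self.effective() if a != UNKNOWN)

    def __str__(self) -> str:  # "S1S4", "S3?", "Sc(Sc)"
        if self.presumed_homozygous and self.a2 == UNKNOWN:
            return f"{self.a1}({SC})"
        return f"{self.a1}{self.a2}"


class OriginClass(str, Enum):
    TRADITIONAL = "traditional"
    BREEDING = "breeding"
    UNKNOWN = "unknown"


def normalize_name(name: str) -> str:
    """Case- and accent-insensitive key for cultivar-name uniqueness."""
    decomposed = unicodedata.normalize("NFKD", name)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return stripped.casefold().strip()


@dataclass
class CultivarRecord:
    """A named accession with origin metadata and an S-genotype.

    The four provenance flags mirror the compilation-table footnotes:
    ``a`` S-RNase genotype first reported in the source study, ``b``
    genotype completed from a previous single-allele report, ``c`` the
    Sc/S8 ambiguity resolved by fluorescence microscopy, ``d`` Sc/S8
    confirmed with the SFB-specific AprFBC8 primers.
    ``documented_self_compatible`` records prior field/laboratory
    pollination evidence of self-compatibility independent of genotype
    (e.g. M-locus pollen-part mutants such as 'Katy').
    """

    name: str
    genotype: SGenotype
    country: str = "?"
    origin_class: OriginClass = OriginClass.UNKNOWN
    flags: frozenset[str] = frozenset()
    source: str = "study"  # study | previous
    documented_self_compatible: bool = False

    def __post_init__(self) -> None:
        bad = set(self.flags) - {"a", "b", "c", "d"}
        if bad:
            raise ValueError(f"unknown provenance flags: {sorted(bad)}")
        self.flags = frozenset(self.flags)

    @property
    def first_reported_here(self) -> bool:
        return "a" in self.flags

    @property
    def completed_here(self) -> bool:
        return "b" in self.flags

    @property
    def microscopy_resolved(self) -> bool:
        return "c" in self.flags

    @property
    def sfb_confirmed(self) -> bool:
        return "d" in self.flags


class AssayId(str, Enum):
    """The five PCR assays of the genotyping panel."""

    SRC_FIRST_INTRON = "SRC_FIRST_INTRON"  # SRc-(F/R), S-RNase 1st intron
    PRUC_SECOND_INTRON = "PRUC_SECOND_INTRON"  # PruC2/C4R, 2nd intron
    SHLM12 = "SHLM12"  # SHLM1/SHLM2, S1-specific
    SHLM34 = "SHLM34"  # SHLM3/SHLM4, S7-specific
    APRFBC8 = "APRFBC8"  # AprFBC8-(F/R), SFB V2/HVb region


@dataclass(frozen=True)
class SizeEntry:
    expected_bp: int
    candidates: frozenset[str]
    verified: bool = True


@dataclass
class PrimerAssayDef:
    """One primer pair with its diagnostic fragment-size table.

    ``size_map`` lists (expected size, candidate allele set) pairs; two
    expected sizes within one assay must differ by more than twice the
    matching tolerance so any observation matches at most one entry.
    """

    assay_id: AssayId
    primer_f: str
    primer_r: str
    size_map: tuple[SizeEntry, ...]
    tolerance_bp: int = 3

    def __post_init__(self) -> None:
        if self.tolerance_bp < 0:
            raise ValueError("tolerance_bp must be non-negative")
        sizes = sorted(e.expected_bp for e in self.size_map)
        for lo, hi in zip(sizes, sizes[1:]):
            if hi - lo <= 2 * self.tolerance_bp:
                raise ValueError(
                    f"{self.assay_id.value}: expected sizes {lo} and {hi} "
                    f"are not separated by more than 2x tolerance "
                    f"({self.tolerance_bp} bp)"
                )

    def alleles_with_products(self) -> frozenset[str]:
        out: set[str] = set()
        for entry in self.size_map:
            out |= entry.candidates
        return frozenset(out)


@dataclass(frozen=True)
class AssayResult:
    """Observed fragment sizes (bp) of one assay on one cultivar.

    An empty size list records a no-amplification outcome, which is
    itself informative (e.g. AprFBC8 primer mismatch).
    """

    cultivar: str
    assay_id: AssayId
    observed_sizes: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.observed_sizes):
            raise ValueError("fragment sizes must be positive")


class RegistryConflictError(ValueError):
    """Same genotype registered under two different group labels."""


_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"),
    (100, "C"), (90, "XC"), (50, "L"), (40, "XL"),
    (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def int_to_roman(n: int) -> str:
    if n <= 0:
        raise ValueError("roman numerals start at 1")
    out = []
    for val, sym in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


def roman_to_int(s: str) -> int:
    vals = {"I": 1, "V": 5, "X": 10, "L": 50, "C": 100, "D": 500, "M": 1000}
    total = 0
    prev = 0
    for ch in reversed(s.upper()):
        v = vals[ch]
        total += v if v >= prev else -v
        prev = max(prev, v)
    if int_to_roman(total) != s.upper():
        raise ValueError(f"not a canonical roman numeral: {s!r}")
    return total


class GroupRegistry:
    """Historical incompatibility-group register.

    Maps complete S-genotypes to group labels: Roman numerals for the
    accreted series of mutually cross-incompatible groups, or "0" for
    genotypes so far unique to a single cultivar (universal-pollinizer
    candidates).
    """

    def __init__(self, mapping: Mapping[SGenotype, str] | None = None):
        self._map: dict[SGenotype, str] = {}
        if mapping:
            for g, label in mapping.items():
                self.register(g, label)

    def register(self, genotype: SGenotype, label: str) -> None:
        if not genotype.complete():
            raise ValueError("registry keys must be complete genotypes")
        if genotype.contains(SC):
            raise ValueError("Sc-carrying genotypes are not registrable")
        if label != "0":
            roman_to_int(label)  # validates
        existing = self._map.get(genotype)
        if existing is not None and existing != label:
            raise RegistryConflictError(
                f"genotype {genotype} registered as both "
                f"{existing!r} and {label!r}"
            )
        self._map[genotype] = label

    def get(self, genotype: SGenotype) -> str | None:
        return self._map.get(genotype)

    def max_numbered(self) -> int:
        nums = [roman_to_int(v) for v in self._map.values() if v != "0"]
        return max(nums, default=0)

    def items(self) -> Iterable[tuple[SGenotype, str]]:
        return self._map.items()

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, genotype: SGenotype) -> bool:
        return genotype in self._map
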