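"""Self-(in)compatibility classification, incompatibility groups and
pollinizer verdicts.

Under gametophytic self-incompatibility a pollen grain expressing one
S-haplotype is rejected by a pistil carrying that same allele — except
for Sc pollen, whose SFB loss-of-function insertion escapes rejection.
Consequences operationalized here:

* a cultivar carrying Sc is self-compatible; one carrying S8 (the intact
  progenitor of Sc) without Sc, or any two non-Sc alleles, is
  self-incompatible by genotype — unless direct pollination evidence
  says otherwise (M-locus pollen-part mutants such as 'Katy' are
  self-compatible despite an S1S2 genotype);
* a cross is fully compatible when neither donor haplotype is rejected,
  semi-compatible when one is (half the pollen lost), incompatible when
  both are;
* self-incompatible cultivars sharing both S-alleles form an
  incompatibility group; a genotype seen in only one cultivar so far
  goes to group 0, whose members — like all self-compatible cultivars —
  are universal-pollinizer candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    SC,
    UNKNOWN,
    CultivarRecord,
    GroupRegistry,
    SGenotype,
    int_to_roman,
    roman_to_int,
)
from .pollen import PollinationSummary, SelfCall

__all__ = [
    "Basis",
    "CompatStatus",
    "SelfCompatCall",
    "classify_self_compatibility",
    "classify_record",
    "pollen_rejected",
    "CrossCategory",
    "CrossVerdict",
    "cross_verdict",
    "assign_groups",
    "GroupAssignment",
    "pollinizer_matrix",
    "VERDICT_CODES",
]


class Basis(str, Enum):
    SC_PRESENT = "Sc_present"
    S8_NO_SC = "S8_no_Sc"
    TWO_NONSC_ALLELES = "two_nonSc_alleles"
    MICROSCOPY = "microscopy"
    DOCUMENTED = "documented"
    INSUFFICIENT_GENOTYPE = "insufficient_genotype"


class CompatStatus(str, Enum):
    SELF_COMPATIBLE = "SELF_COMPATIBLE"
    SELF_INCOMPATIBLE = "SELF_INCOMPATIBLE"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class SelfCompatCall:
    call: CompatStatus
    basis: Basis


def classify_self_compatibility(
    genotype: SGenotype,
    microscopy: PollinationSummary | None = None,
    documented_self_compatible: bool = False,
) -> SelfCompatCall:
    """Classify a cultivar as self-compatible/-incompatible/unclassified.

    Precedence: Sc in the genotype is decisive for self-compatibility;
    next, direct pollination evidence (a conclusive microscopy summary,
    or a documented prior pollination result) overrides genotype
    *inference*; otherwise S8 without Sc, or a complete two-non-Sc-allele
    genotype, implies self-incompatibility; anything else is
    unclassified. The call is UNCLASSIFIED iff the basis is
    ``insufficient_genotype``.
    """
    if genotype.contains(SC):
        return SelfCompatCall(CompatStatus.SELF_COMPATIBLE, Basis.SC_PRESENT)
    if microscopy is not None and microscopy.call is not SelfCall.INCONCLUSIVE:
        status = (
            CompatStatus.SELF_COMPATIBLE
            if microscopy.call is SelfCall.SELF_COMPATIBLE
            else CompatStatus.SELF_INCOMPATIBLE
        )
        return SelfCompatCall(status, Basis.MICROSCOPY)
    if documented_self_compatible:
        return SelfCompatCall(CompatStatus.SELF_COMPATIBLE, Basis.DOCUMENTED)
    if genotype.contains("S8"):
        return SelfCompatCall(CompatStatus.SELF_INCOMPATIBLE, Basis.S8_NO_SC)
    if genotype.complete():
        return SelfCompatCall(CompatStatus.SELF_INCOMPATIBLE, Basis.TWO_NONSC_ALLELES)
    return SelfCompatCall(CompatStatus.UNCLASSIFIED, Basis.INSUFFICIENT_GENOTYPE)


def classify_record(
    record: CultivarRecord, microscopy: PollinationSummary | None = None
) -> SelfCompatCall:
    """Classify a cultivar record, honouring its documented-SC flag."""
    return classify_self_compatibility(
        record.genotype,
        microscopy=microscopy,
        documented_self_compatible=record.documented_self_compatible,
    )


def pollen_rejected(pollen_allele: str, pistil: SGenotype) -> bool:
    """GSI rejection rule: pistil rejects matching pollen, Sc excepted."""
    if pollen_allele == UNKNOWN:
        raise ValueError("pollen allele must be known")
    if not pistil.complete() and not pistil.presumed_homozygous:
        raise ValueError("pistil genotype must be complete")
    if pollen_allele == SC:
        return False
    return pollen_allele in pistil.effective()


class CrossCategory(str, Enum):
    FULLY_COMPATIBLE = "FULLY_COMPATIBLE"
    SEMI_COMPATIBLE = "SEMI_COMPATIBLE"
    INCOMPATIBLE = "INCOMPATIBLE"
    UNDETERMINED = "UNDETERMINED"


_FRACTIONS = {
    CrossCategory.FULLY_COMPATIBLE: 1.0,
    CrossCategory.SEMI_COMPATIBLE: 0.5,
    CrossCategory.INCOMPATIBLE: 0.0,
}

VERDICT_CODES = {
    CrossCategory.FULLY_COMPATIBLE: "F",
    CrossCategory.SEMI_COMPATIBLE: "S",
    CrossCategory.INCOMPATIBLE: "I",
    CrossCategory.UNDETERMINED: "U",
}


@dataclass(frozen=True)
class CrossVerdict:
    category: CrossCategory
    compatible_pollen_fraction: float | None

    @property
    def code(self) -> str:
        return VERDICT_CODES[self.category]


def cross_verdict(donor: SGenotype, pistil: SGenotype) -> CrossVerdict:
    """Verdict for pollen of ``donor`` on the pistil of ``pistil``.

    Counts rejected donor haplotypes r: 0 → fully compatible (all pollen
    accepted), 1 → semi-compatible (half accepted), 2 → incompatible.
    Any unknown allele on either side (not covered by the presumed-ScSc
    convention) yields UNDETERMINED.
    """
    donor_alleles = donor.effective()
    pistil_alleles = pistil.effective()
    if UNKNOWN in donor_alleles or UNKNOWN in pistil_alleles:
        return CrossVerdict(CrossCategory.UNDETERMINED, None)
    rejected = sum(1 for a in donor_alleles if a != SC and a in pistil_alleles)
    category = {
        0: CrossCategory.FULLY_COMPATIBLE,
        1: CrossCategory.SEMI_COMPATIBLE,
        2: CrossCategory.INCOMPATIBLE,
    }[rejected]
    return CrossVerdict(category, _FRACTIONS[category])


@dataclass
class GroupAssignment:
    """Result of allocating self-incompatible cultivars to groups."""

    groups: dict[str, str] = field(default_factory=dict)  # cultivar -> label
    new_groups: dict[str, SGenotype] = field(default_factory=dict)
    unclassified: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)  # not self-incompatible

    def members(self, label: str) -> list[str]:
        return [c for c, g in self.groups.items() if g == label]


def assign_groups(
    cultivars: Sequence[CultivarRecord], registry: GroupRegistry
) -> GroupAssignment:
    """Allocate self-incompatible cultivars to incompatibility groups.

    Only self-incompatible cultivars with complete genotypes are
    assigned: a registered genotype gets its registry label (numbered
    group or "0"); an unregistered genotype shared by at least two input
    cultivars opens a new numbered group continuing the historical
    series; an unregistered genotype unique in the input goes to group 0
    (universal-pollinizer candidate). Cultivars whose
    self-(in)compatibility cannot be established are listed separately
    as unclassified; self-compatible ones are excluded.
    """
    result = GroupAssignment()
    assignable: list[CultivarRecord] = []
    for record in cultivars:
        call = classify_record(record)
        if call.call is CompatStatus.SELF_COMPATIBLE:
            result.excluded.append(record.name)
        elif call.call is CompatStatus.SELF_INCOMPATIBLE and record.genotype.complete():
            assignable.append(record)
        else:
            result.unclassified.append(record.name)

    genotype_counts: dict[SGenotype, int] = {}
    for record in assignable:
        genotype_counts[record.genotype] = genotype_counts.get(record.genotype, 0) + 1

    next_number = registry.max_numbered() + 1
    new_labels: dict[SGenotype, str] = {}
    for record in assignable:
        label = registry.get(record.genotype)
        if label is None:
            if genotype_counts[record.genotype] >= 2:
                if record.genotype not in new_labels:
                    new_labels[record.genotype] = int_to_roman(next_number)
                    result.new_groups[new_labels[record.genotype]] = record.genotype
                    next_number += 1
                label = new_labels[record.genotype]
            else:
                label = "0"
        result.groups[record.name] = label
    return result


def pollinizer_matrix(cultivars: Sequence[CultivarRecord]) -> pd.DataFrame:
    """Square donor (rows) × pistil (columns) matrix of cross verdicts.

    Cells hold single-letter codes: F fully compatible, S
    semi-compatible, I incompatible, U undetermined. The diagonal is the
    self-pollination verdict.
    """
    names = [r.name for r in cultivars]
    if len(set(names)) != len(names):
        raise ValueError("duplicate cultivar names in matrix input")
    data = [
        [cross_verdict(d.genotype, p.genotype).code for p in cultivars]
        for d in cultivars
    ]
    return pd.DataFrame(data, index=names, columns=names)
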