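"""S-genotype calling from multi-primer PCR fragment sizes.

The genotyping panel resolves alleles in two tiers. The SRc first-intron
assay places each amplified fragment into a size class that may be shared
by two alleles (358 bp is common to Sc and S8, whose first-intron products
are indistinguishable; 408 bp is common to S1 and S7). Allele-specific
secondary assays then split the classes: SHLM1/2 (650 bp) is diagnostic
for S1, SHLM3/4 (413 bp) for S7, the SFB-region AprFBC8 pair yields
150 bp for S8 and 500 bp for Sc, and the PruC2/C4R second-intron assay
separates S6 from S9. When an Sc/S8 class cannot be split because AprFBC8
gives no amplification (primer mismatch), the call is returned incomplete
and flagged for a controlled-pollination test, which discriminates the
two alleles phenotypically (Sc confers self-compatibility).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .core import SC, UNKNOWN, AssayId, AssayResult, PrimerAssayDef, SGenotype

__all__ = [
    "NO_MATCH",
    "match_size",
    "call_genotype",
    "predict_amplicons",
    "resolvable_alleles",
    "CallTrace",
    "CallStatus",
    "AmbiguousGenotype",
    "InconsistentAssaysError",
]

#: Sentinel returned by :func:`match_size` for out-of-table sizes.
NO_MATCH = frozenset()


class InconsistentAssaysError(ValueError):
    """More than two distinct alleles supported by the assay evidence."""

    def __init__(self, message: str, trace: "CallTrace"):
        super().__init__(message)
        self.trace = trace


class CallStatus(str, Enum):
    COMPLETE = "COMPLETE"
    INCOMPLETE = "INCOMPLETE"
    UNRESOLVED = "UNRESOLVED"


@dataclass
class SizeMatch:
    assay_id: AssayId
    observed_bp: float
    matched_bp: int | None
    candidates: frozenset[str]
    resolved: frozenset[str] = frozenset()  # filled during narrowing


@dataclass
class CallTrace:
    """Audit trail of one genotype call."""

    matches: list[SizeMatch] = field(default_factory=list)
    resolved_alleles: dict[str, list[str]] = field(default_factory=dict)
    ambiguities: list[frozenset[str]] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)
    needs_pollination_test: bool = False
    presumed_homozygous_candidate: bool = False
    status: CallStatus = CallStatus.UNRESOLVED
    genotype: SGenotype | None = None

    def src_peak_for(self, allele: str) -> float | None:
        """First-intron peak size attributed to ``allele``, if any."""
        for m in self.matches:
            if m.assay_id is AssayId.SRC_FIRST_INTRON and allele in m.resolved:
                return m.observed_bp
        return None


def match_size(assay: PrimerAssayDef, observed: float) -> frozenset[str]:
    """Candidate allele set of the unique expected size within tolerance.

    Returns :data:`NO_MATCH` when no table entry is within
    ``tolerance_bp`` of the observation. Two entries within tolerance is
    impossible under the panel invariant (pairwise separation greater
    than twice the tolerance) and raises.
    """
    if observed <= 0:
        raise ValueError("observed fragment size must be positive")
    hits = [
        e for e in assay.size_map if abs(observed - e.expected_bp) <= assay.tolerance_bp
    ]
    if len(hits) > 1:
        raise ValueError(
            f"{assay.assay_id.value}: {observed} bp matches several expected "
            "sizes; panel tolerance configuration is inconsistent"
        )
    return hits[0].candidates if hits else NO_MATCH


def _panel_by_id(panel: list[PrimerAssayDef]) -> dict[AssayId, PrimerAssayDef]:
    return {a.assay_id: a for a in panel}


def call_genotype(
    assays: list[AssayResult], panel: list[PrimerAssayDef]
) -> tuple[SGenotype | None, CallTrace]:
    """Resolve an S-genotype from one cultivar's assay results.

    Requires at least one SRc first-intron result (possibly a recorded
    no-amplification). Singleton size classes resolve alleles directly;
    shared classes are narrowed by the allele-specific assays. Raises
    :class:`InconsistentAssaysError` when more than two distinct alleles
    are supported. Returns ``(None, trace)`` with ``UNRESOLVED`` status
    when nothing is supported.
    """
    defs = _panel_by_id(panel)
    if not any(a.assay_id is AssayId.SRC_FIRST_INTRON for a in assays):
        raise ValueError("an SRc first-intron assay result is required")
    cultivars = {a.cultivar for a in assays}
    if len(cultivars) > 1:
        raise ValueError(f"assay results span several cultivars: {sorted(cultivars)}")

    trace = CallTrace()
    # evidence[a] -> supporting "assay@size" strings; singleton candidates only
    evidence: dict[str, list[str]] = {}
    src_classes: list[SizeMatch] = []
    aprfbc8_no_amp = False

    for result in sorted(assays, key=lambda a: a.assay_id.value):
        assay = defs.get(result.assay_id)
        if assay is None:
            continue
        if result.assay_id is AssayId.APRFBC8 and not result.observed_sizes:
            aprfbc8_no_amp = True
        for obs in sorted(result.observed_sizes):
            cands = match_size(assay, obs)
            matched = None
            if cands:
                matched = min(
                    (e.expected_bp for e in assay.size_map), key=lambda s: abs(obs - s)
                )
            m = SizeMatch(result.assay_id, obs, matched, cands)
            trace.matches.append(m)
            if not cands:
                continue
            if len(cands) == 1:
                (allele,) = cands
                evidence.setdefault(allele, []).append(
                    f"{result.assay_id.value}@{obs:g}"
                )
                m.resolved = cands
            else:
                src_classes.append(m)

    # Narrow shared first-intron classes with the allele-specific evidence.
    for m in src_classes:
        confirmed = frozenset(a for a in m.candidates if a in evidence)
        if confirmed:
            m.resolved = confirmed
            for allele in confirmed:
                evidence[allele].append(
                    f"{m.assay_id.value}@{m.observed_bp:g}"
                )
        else:
            trace.ambiguities.append(m.candidates)
            if m.candidates == frozenset({SC, "S8"}):
                trace.needs_pollination_test = True
                if not aprfbc8_no_amp:
                    trace.conflicts.append(
                        "Sc/S8 class unresolved without an AprFBC8 result"
                    )

    resolved = sorted(evidence)
    trace.resolved_alleles = {a: evidence[a] for a in resolved}
    open_classes = [c for c in trace.ambiguities if not (c & set(resolved))]
    if len(resolved) > 2 or (len(resolved) == 2 and open_classes):
        msg = (
            f"assays support more than two distinct alleles: {resolved}"
            + (f" plus unresolved class(es) {open_classes}" if open_classes else "")
        )
        trace.conflicts.append(msg)
        raise InconsistentAssaysError(msg, trace)
    if not resolved:
        trace.status = CallStatus.UNRESOLVED
        trace.genotype = None
        return None, trace
    if len(resolved) == 2:
        genotype = SGenotype(resolved[0], resolved[1])
        trace.status = CallStatus.COMPLETE
    else:
        # one supported allele, or a residual ambiguity for the second
        genotype = SGenotype(resolved[0], UNKNOWN)
        trace.status = CallStatus.INCOMPLETE
        if resolved == [SC] and not open_classes:
            # single Sc amplification: candidate for presumed homozygosity
            trace.presumed_homozygous_candidate = True
    trace.genotype = genotype
    return genotype, trace


@dataclass(frozen=True)
class AmbiguousGenotype:
    """A partially resolved genotype carrying one open size-class.

    ``known`` is the resolved partner allele (``None`` when no allele was
    resolved); ``ambiguity`` is the open candidate set, e.g. {Sc, S8}.
    """

    ambiguity: frozenset[str]
    known: str | None = None

    @classmethod
    def from_trace(cls, trace: CallTrace) -> "AmbiguousGenotype":
        open_classes = [
            c for c in trace.ambiguities if not (c & set(trace.resolved_alleles))
        ]
        if len(open_classes) != 1:
            raise ValueError(
                f"expected exactly one open ambiguity, found {len(open_classes)}"
            )
        known = next(iter(trace.resolved_alleles), None)
        return cls(ambiguity=open_classes[0], known=known)


def predict_amplicons(
    genotype: SGenotype, panel: list[PrimerAssayDef]
) -> list[tuple[AssayId, int]]:
    """Forward prediction of diagnostic products for a complete genotype.

    Each amplicon is listed once even when both alleles yield the same
    product (capillary electrophoresis shows a single peak). Alleles
    without a diagnostic product in an assay are omitted.
    """
    if not genotype.complete():
        raise ValueError("amplicon prediction requires a complete genotype")
    out: list[tuple[AssayId, int]] = []
    seen: set[tuple[AssayId, int]] = set()
    for assay in panel:
        for entry in assay.size_map:
            if any(a in entry.candidates for a in genotype.alleles):
                key = (assay.assay_id, entry.expected_bp)
                if key not in seen:
                    seen.add(key)
                    out.append(key)
    return sorted(out, key=lambda kv: (kv[0].value, kv[1]))


def resolvable_alleles(panel: list[PrimerAssayDef]) -> frozenset[str]:
    """Alleles the panel can pin down to a singleton.

    An allele is resolvable when some assay entry names it alone, or it
    belongs to a shared first-intron class whose other members are all
    individually identifiable.
    """
    singletons = {
        next(iter(e.candidates))
        for assay in panel
        for e in assay.size_map
        if len(e.candidates) == 1
    }
    return frozenset(singletons)
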