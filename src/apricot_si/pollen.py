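"""Controlled-pollination summaries and the microscopy-based SC/SI call.

After hand self-pollination, squashed pistils stained with aniline blue
show the path of each pollen tube under fluorescence microscopy. In a
self-compatible cultivar the tubes reach the base of the style; under
gametophytic self-incompatibility growth is arrested mid-style with a
characteristic callose tip. A cultivar is called self-incompatible when
growth is arrested in most self-pollinated pistils, and self-compatible
when tubes reach the base in most of them; at least ``min_pistils``
observations are required for a non-inconclusive call.

This call is the wet-lab fallback for the one ambiguity PCR cannot
always split: the Sc and S8 first-intron products are identical in size,
and when the SFB-specific AprFBC8 primers fail to amplify, only the
phenotype separates self-compatible (Sc) from self-incompatible (S8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .core import SC, SGenotype
from .calling import AmbiguousGenotype

__all__ = [
    "CrossType",
    "SelfCall",
    "PistilObservation",
    "PollinationSummary",
    "summarize_self_pollination",
    "resolve_sc_s8",
    "CrossControlWarning",
]

DEFAULT_MIN_PISTILS = 10
DEFAULT_MAJORITY = 0.5


class CrossType(str, Enum):
    SELF = "self"
    CROSS = "cross"


class SelfCall(str, Enum):
    SELF_COMPATIBLE = "SELF_COMPATIBLE"
    SELF_INCOMPATIBLE = "SELF_INCOMPATIBLE"
    INCONCLUSIVE = "INCONCLUSIVE"


class CrossControlWarning(UserWarning):
    """Cross-pollination control pistils failed to validate pollen/pistil."""


@dataclass(frozen=True)
class PistilObservation:
    """One pollinated pistil's pollen-tube outcome."""

    cultivar: str
    cross: CrossType
    donor: str
    percent_style_traveled: float
    reached_base: bool
    arrested_with_callose_tip: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.percent_style_traveled <= 100:
            raise ValueError("percent_style_traveled must be within [0, 100]")
        if self.reached_base and self.percent_style_traveled != 100:
            raise ValueError("reached_base implies 100% of the style traveled")


@dataclass(frozen=True)
class PollinationSummary:
    n_pistils: int
    fraction_reached_base: float
    fraction_arrested: float
    mean_percent_traveled: float
    call: SelfCall
    reason: str = ""


def summarize_self_pollination(
    observations: Sequence[PistilObservation],
    min_pistils: int = DEFAULT_MIN_PISTILS,
    majority: float = DEFAULT_MAJORITY,
    cross_controls: Iterable[PistilObservation] = (),
) -> PollinationSummary:
    """Summarize one cultivar's self-pollinated pistils into an SC/SI call.

    The call is SELF_COMPATIBLE when the fraction of pistils with tubes
    at the style base exceeds ``majority``, SELF_INCOMPATIBLE when the
    arrested fraction exceeds it, otherwise (or with fewer than
    ``min_pistils`` pistils) INCONCLUSIVE. The mean percent of style
    traveled is computed over all pistils, counting reached-base ones at
    100%. Optional ``cross_controls`` (pistils cross-pollinated with a
    known-compatible donor) raise a warning — not an error — when their
    tubes did not reach the base.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("no pistil observations supplied")
    cultivars = {o.cultivar for o in obs}
    if len(cultivars) > 1:
        raise ValueError(f"observations span several cultivars: {sorted(cultivars)}")
    if any(o.cross is not CrossType.SELF for o in obs):
        raise ValueError("summarize_self_pollination expects self-pollinations only")

    controls = list(cross_controls)
    if controls and not all(o.reached_base for o in controls):
        warnings.warn(
            "cross-pollination control pistils did not all reach the style "
            "base; the self-incompatibility call may reflect poor pollen "
            "or pistil condition",
            CrossControlWarning,
            stacklevel=2,
        )

    n = len(obs)
    frac_base = sum(o.reached_base for o in obs) / n
    frac_arrested = sum(not o.reached_base for o in obs) / n
    mean_pct = sum(o.percent_style_traveled for o in obs) / n

    if n < min_pistils:
        call, reason = SelfCall.INCONCLUSIVE, (
            f"only {n} pistils observed (minimum {min_pistils})"
        )
    elif frac_base > majority:
        call, reason = SelfCall.SELF_COMPATIBLE, ""
    elif frac_arrested > majority:
        call, reason = SelfCall.SELF_INCOMPATIBLE, ""
    else:
        call, reason = SelfCall.INCONCLUSIVE, "no majority outcome"
    return PollinationSummary(
        n_pistils=n,
        fraction_reached_base=frac_base,
        fraction_arrested=frac_arrested,
        mean_percent_traveled=mean_pct,
        call=call,
        reason=reason,
    )


def resolve_sc_s8(
    ambiguous: AmbiguousGenotype, summary: PollinationSummary
) -> SGenotype:
    """Resolve an open Sc/S8 size class from the pollination phenotype.

    Self-compatible behaviour attributes the shared 358 bp product to Sc,
    self-incompatible behaviour to S8. An inconclusive summary retains
    the ambiguity (raises ValueError).
    """
    if ambiguous.ambiguity != frozenset({SC, "S8"}):
        raise ValueError(
            f"not an Sc/S8 ambiguity: {sorted(ambiguous.ambiguity)}"
        )
    if summary.call is SelfCall.INCONCLUSIVE:
        raise ValueError(f"pollination summary inconclusive: {summary.reason}")
    allele = SC if summary.call is SelfCall.SELF_COMPATIBLE else "S8"
    if ambiguous.known is None:
        return SGenotype(allele)
    return SGenotype(ambiguous.known, allele)
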