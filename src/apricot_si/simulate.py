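"""Synthetic data with the statistical structure the analysis assumes.

Each population is an allele pool with a frequency vector; diploid
genotypes are drawn allele-by-allele. Under the GSI constraint, non-Sc
homozygotes are rejected and resampled (a self-incompatible cultivar
cannot be homozygous at the S-locus, whereas ScSc homozygotes arise
freely in self-compatible material). The self-compatible fraction of a
population is the probability that a genotype is forced to carry Sc.
Assay observations add Gaussian size jitter and per-assay amplification
dropout; pistil observations follow a self-compatible model (all tubes
reach the style base) or a self-incompatible model (tubes arrested
mid-style, uniform on 40–80% of the style, with callose tips).

One global seed fans out deterministically to per-stage child seeds via
:class:`numpy.random.SeedSequence`, so end-to-end runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    SC,
    UNKNOWN,
    AssayId,
    AssayResult,
    CultivarRecord,
    OriginClass,
    PrimerAssayDef,
    SGenotype,
)
from .calling import predict_amplicons
from .pollen import CrossType, PistilObservation

__all__ = [
    "PopulationSpec",
    "simulate_cultivars",
    "simulate_assays",
    "simulate_pistils",
    "child_rng",
]

# SI pistil model: arrest mid-style, bracketing the observed 62.5% mean
SI_TRAVEL_RANGE = (40.0, 80.0)


def child_rng(seed: int | np.random.SeedSequence, *path: int) -> np.random.Generator:
    """Deterministic per-stage generator derived from one global seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for idx in path:
        ss = ss.spawn(max(idx + 1, 1))[idx]
    return np.random.default_rng(ss)


@dataclass
class PopulationSpec:
    """Parameters of one simulated population.

    ``frequencies`` are per-allele sampling weights over ``pool`` (they
    must sum to 1); ``sc_fraction`` is the probability that a genotype is
    forced to include Sc; ``missingness`` masks the second allele to
    UNKNOWN with the given probability.
    """

    name: str
    pool: tuple[str, ...]
    frequencies: tuple[float, ...]
    n_cultivars: int
    sc_fraction: float = 0.0
    missingness: float = 0.0
    origin_class: OriginClass = OriginClass.UNKNOWN

    def __post_init__(self) -> None:
        if len(self.pool) != len(self.frequencies):
            raise ValueError("pool and frequencies must align")
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        for rate in (self.sc_fraction, self.missingness):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.sc_fraction > 0 and SC not in self.pool:
            raise ValueError("sc_fraction > 0 requires Sc in the pool")

    @classmethod
    def dirichlet(
        cls,
        name: str,
        pool: tuple[str, ...],
        n_cultivars: int,
        rng: np.random.Generator,
        concentration: float = 1.0,
        **kwargs,
    ) -> "PopulationSpec":
        freqs = rng.dirichlet(np.full(len(pool), concentration))
        return cls(name, tuple(pool), tuple(freqs), n_cultivars, **kwargs)


def simulate_cultivars(
    specs: list[PopulationSpec],
    seed: int,
    gsi_constraint: bool = True,
) -> tuple[list[CultivarRecord], pd.DataFrame]:
    """Sample diploid genotypes for each population spec.

    Returns the records (with missingness applied) plus a ground-truth
    table holding the full simulated genotype of every cultivar, for
    recovery tests.
    """
    records: list[CultivarRecord] = []
    truth_rows: list[dict] = []
    for pop_idx, spec in enumerate(specs):
        rng = child_rng(seed, 0, pop_idx)
        pool = np.array(spec.pool)
        probs = np.array(spec.frequencies)
        for i in range(spec.n_cultivars):
            force_sc = rng.random() < spec.sc_fraction
            while True:
                a1, a2 = rng.choice(pool, size=2, p=probs)
                if force_sc and SC not in (a1, a2):
                    a1 = SC
                if gsi_constraint and a1 == a2 and a1 != SC:
                    continue  # GSI forbids non-Sc homozygotes
                break
            genotype = SGenotype(a1, a2)
            masked = rng.random() < spec.missingness
            observed = SGenotype(genotype.a1) if masked else genotype
            name = f"{spec.name}-{i:04d}"
            records.append(
                CultivarRecord(
                    name=name,
                    genotype=observed,
                    country=spec.name,
                    origin_class=spec.origin_class,
                )
            )
            truth_rows.append(
                {
                    "name": name,
                    "population": spec.name,
                    "allele1": genotype.a1,
                    "allele2": genotype.a2,
                    "masked": masked,
                    "self_compatible": genotype.contains(SC),
                }
            )
    return records, pd.DataFrame(truth_rows)


def simulate_assays(
    cultivars: list[CultivarRecord],
    panel: list[PrimerAssayDef],
    seed: int,
    size_noise_sd: float = 0.0,
    dropout: float = 0.0,
    truth: pd.DataFrame | None = None,
) -> list[AssayResult]:
    """Forward-simulate the genotyping panel on each cultivar.

    Observed sizes are the predicted amplicons plus Gaussian jitter;
    with probability ``dropout`` an assay returns no amplification. The
    SRc first-intron assay is always reported (possibly empty), matching
    the real workflow where it is run on every sample. When ``truth``
    is given (from :func:`simulate_cultivars`), amplicons are predicted
    from the full simulated genotype rather than the masked one.
    """
    if size_noise_sd < 0:
        raise ValueError("size_noise_sd must be non-negative")
    truth_map = (
        {row["name"]: SGenotype(row["allele1"], row["allele2"]) for _, row in truth.iterrows()}
        if truth is not None
        else {}
    )
    results: list[AssayResult] = []
    for cult_idx, record in enumerate(cultivars):
        rng = child_rng(seed, 1, cult_idx)
        genotype = truth_map.get(record.name, record.genotype)
        if not genotype.complete():
            genotype = SGenotype(genotype.a1, genotype.a1)  # best effort
        predicted = predict_amplicons(genotype, panel)
        by_assay: dict[AssayId, list[float]] = {AssayId.SRC_FIRST_INTRON: []}
        for assay_id, bp in predicted:
            by_assay.setdefault(assay_id, []).append(float(bp))
        for assay_id in sorted(by_assay, key=lambda a: a.value):
            sizes = by_assay[assay_id]
            if rng.random() < dropout:
                sizes = []
            elif size_noise_sd > 0:
                # capillary sizing error: Gaussian, clipped at 3 sigma
                # (measurement error is bounded in practice)
                jitter = np.clip(
                    rng.normal(0.0, size_noise_sd, size=len(sizes)),
                    -3 * size_noise_sd,
                    3 * size_noise_sd,
                )
                sizes = [max(s + d, 1.0) for s, d in zip(sizes, jitter)]
            results.append(
                AssayResult(record.name, assay_id, tuple(sizes))
            )
    return results


def simulate_pistils(
    cultivar: str,
    truth: str,
    n: int,
    seed: int,
    donor: str | None = None,
) -> list[PistilObservation]:
    """Simulate self-pollinated pistil outcomes for an SC or SI cultivar.

    ``truth`` is "SC" (tubes reach the base, 100% of style) or "SI"
    (growth arrested mid-style with a callose tip).
    """
    if n < 1:
        raise ValueError("at least one pistil is required")
    if truth not in ("SC", "SI"):
        raise ValueError("truth must be 'SC' or 'SI'")
    rng = child_rng(seed, 2)
    donor = donor or cultivar
    out = []
    for _ in range(n):
        if truth == "SC":
            obs = PistilObservation(
                cultivar, CrossType.SELF, donor, 100.0, True, False
            )
        else:
            pct = float(rng.uniform(*SI_TRAVEL_RANGE))
            obs = PistilObservation(
                cultivar, CrossType.SELF, donor, pct, False, True
            )
        out.append(obs)
    return out
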