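# Methods

## Model

Gametophytic self-incompatibility (GSI) at the apricot S-locus is
modelled by a single rejection rule: pollen expressing haplotype *a* is
rejected by a pistil of genotype {*p₁*, *p₂*} iff *a* ∈ {*p₁*, *p₂*}
and *a* ≠ *S<sub>c</sub>*. The *S<sub>c</sub>* exception encodes the
358 bp *SFB* insertion that abolishes pollen-side rejection. Everything
else in the package is bookkeeping over this rule:

- **self-compatibility**: a genotype containing *S<sub>c</sub>* is
  self-compatible; a complete genotype of two non-*S<sub>c</sub>*
  alleles — or *S₈* without *S<sub>c</sub>*, even when the partner
  allele is unknown — is self-incompatible;
- **cross verdicts**: with r ∈ {0, 1, 2} rejected donor haplotypes, the
  compatible pollen fraction is 1, ½, 0 (fully / semi / incompatible);
  any unknown allele yields UNDETERMINED rather than a guess;
- **incompatibility groups**: self-incompatible cultivars sharing both
  alleles are mutually incompatible and form a group; the partition
  property (pairwise incompatibility within a numbered group, never
  across two numbered groups) follows from genotype identity and is
  asserted exhaustively in the tests.

Two pieces of direct evidence can override genotype *inference* (never
the *S<sub>c</sub>*-presence rule): a conclusive pollen-tube microscopy
summary, and a documented prior pollination result carried on the
record. The latter is what keeps known pollen-part mutants (e.g.
'Katy', self-compatible despite S₁S₂ through an M-locus mutation
outside the S-locus, which this package does not model) correctly
classified.

## Allele calling

Observed fragment sizes are matched to a panel table of expected sizes
with an integer tolerance (default **3 bp**, the scale of capillary
electrophoresis sizing error). Within one assay, expected sizes must
differ by more than twice the tolerance, so a match is unique or
absent. Singleton size classes resolve alleles directly; the two shared
first-intron classes (358 bp → {*S<sub>c</sub>*, *S₈*}, 408 bp →
{*S₁*, *S₇*}) are narrowed by the allele-specific assays. A class in
which *both* members are confirmed (e.g. AprFBC8 yielding 150 and
500 bp over a single 358 bp peak) resolves to both alleles — the two
products co-migrate in the first intron. Calls are invariant to assay
order and to within-tolerance jitter.

Decision policy at the end of a call: more than two supported alleles
(or two supported plus an open class) is an inconsistency error
carrying the full trace; two supported alleles give a complete
genotype; one gives an incomplete genotype, flagged as a
presumed-homozygosity candidate when that allele is *S<sub>c</sub>*
(single-*S<sub>c</sub>* amplification); an open
{*S<sub>c</sub>*, *S₈*} class sets the NEEDS_POLLINATION_TEST flag.
The first-intron size table ships with only the two anchored classes;
sizes for other alleles, and the PruC2/C4R second-intron sizes used to
separate *S₆* from *S₉* (1300/1500 bp), are configurable table entries
marked `verified=0` — placeholders standing where the literature gives
the assay's discriminating role but not its product lengths. Tests
treat them as opaque table entries, never as measured values.

## Pollination summaries

A cultivar is called self-compatible when the fraction of
self-pollinated pistils with tubes at the style base exceeds the
majority threshold (default 0.5, "most"), self-incompatible when the
arrested fraction does, and inconclusive otherwise or below the minimum
of **10 pistils**. The mean percent of style traveled is computed over
all pistils with reached-base pistils at 100%. A failed cross-pollinated
control (known-compatible donor whose tubes do not reach the base)
raises a warning, not an error: it questions flower or pollen condition
without invalidating the arrest phenotype. The summary call resolves an
open {*S<sub>c</sub>*, *S₈*} class: self-compatible → *S<sub>c</sub>*,
self-incompatible → *S₈*.

## Group allocation

The packaged registry maps complete non-*S<sub>c</sub>* genotypes to
the historical group series (I–XXVI present in the compilation) and
maps the compiled group-0 genotypes to "0". Allocation: registered
genotype → its label; unregistered genotype shared by ≥ 2 input
cultivars → a new numbered label continuing the historical series
(XXVII, …); unregistered and unique → group 0. Only self-incompatible
cultivars with complete genotypes are assignable; unclassified records
are listed separately. The registry rejects a genotype under two
labels.

## Diversity statistics

A population × allele table counts two copies per complete genotype.
A single-allele genotype contributes one copy (discarding the known
allele would silently change N<sub>a</sub>); presumed-homozygous
single-*S<sub>c</sub>* records count two *S<sub>c</sub>* copies by
default. Optional mean-frequency imputation distributes each missing
copy over alleles in proportion to pooled frequencies, producing
fractional counts; it is **off by default** because its downstream
behaviour in the original tables cannot be verified.

Allelic richness is the hypergeometric rarefaction expectation
A<sub>r</sub>(g) = Σ<sub>i</sub> [1 − C(N−N<sub>i</sub>, g)/C(N, g)],
computed in log-gamma space; with fractional counts the binomial
coefficients generalize through the gamma function, with C(n, g)
treated as zero once n ≤ g − 1. The subsample depth g defaults to the
smallest population's copy total (standard rarefaction practice — the
smallest population sets the scale; configurable). Populations with a
single cultivar are retained by default (`min_cultivars=1`).
A private allele has a positive count in exactly one population of the
table; privacy is therefore relative to the comparison set (the same
allele can be private to different populations in different groupings).

The association test uses Pearson's X² with the null distribution
sampled under both margins fixed (Patefield's algorithm via
`scipy.stats.random_table`, B = 2000 by default) and the add-one
correction p = (1 + #{X²_b ≥ X²_obs}) / (B + 1), which avoids p = 0 and
is deterministic given a seed. Zero-margin rows/columns are dropped
with a warning. Fractional (imputed) margins are rounded to integers
for the null sampler only; the observed statistic keeps the fractional
table.

The published per-country N<sub>a</sub>/A<sub>r</sub>/P<sub>a</sub>
tables are **not** reproduced: per-cultivar country and origin-class
assignments live in an appendix that the packaged tables do not
include, and the printed A<sub>r</sub> = 1.67 for single-cultivar
countries with two distinct alleles is inconsistent with plain
hypergeometric rarefaction at g = 2 (which gives exactly 2.0), so the
upstream convention cannot be reverse-engineered. The statistics are
instead validated against an exhaustive-enumeration oracle (all
compositions of ≤ 12 copies, every valid g), the endpoint identity
A<sub>r</sub>(N) = N<sub>a</sub>, the closed-form X², and a type-I
calibration of the Monte-Carlo p-value.

## Synthetic data

The generator emulates exactly the structure the analysis assumes:
populations are allele pools with frequency vectors; diploid genotypes
are two independent draws, with non-*S<sub>c</sub>* homozygotes
rejected and resampled when the GSI constraint is on (GSI forbids them;
*S<sub>c</sub>S<sub>c</sub>* arises freely); a configurable fraction of
genotypes is forced to carry *S<sub>c</sub>* (self-compatible
fraction); missingness masks the second allele. Assay simulation
predicts amplicons forward and adds Gaussian sizing jitter clipped at
±3σ — a bounded measurement-error model under which recovery of all
resolvable heterozygous genotypes is exact whenever σ ≤ tolerance/3 —
plus per-assay amplification dropout; an SRc result is always emitted
(possibly empty), as in the real workflow. Pistil simulation draws the
self-incompatible arrest point uniformly on 40–80% of the style
(bracketing the observed 62.5% mean) with callose tips, and the
self-compatible model puts every tube at the base. One global seed fans
out deterministically to per-stage child seeds
(`numpy.random.SeedSequence`), so end-to-end runs repeat byte-for-byte.

What passing tests on synthetic data do **not** show: population
structure beyond frequency draws (no pedigree, drift or migration), the
M-locus/ParMDO modifiers, electropherogram peak calling upstream of the
size lists, flowering-time overlap between pollinizer and target, and
real assay failure modes beyond uniform dropout.

## Problem sizes and numerical choices

The analysis drivers and tests run at desk scale: 15 resolvable
heterozygous genotype pairs for recovery, 40–60 cultivars per synthetic
population (500 for the frequency-recovery check, where a 0.03
tolerance corresponds to ~2 standard errors on 1000 allele copies),
B = 2000 Monte-Carlo replicates in the drivers and 199 in the type-I
calibration (500 null tables, giving a p-value grid of 1/200 — fine
enough to test the 0.05 level). Floating-point comparisons against the
exhaustive rarefaction oracle and closed-form X² use 1e-9 absolute
tolerance; rarefaction feasibility uses a 1e-12 guard around the
C(n, g) = 0 cutoff. Roman-numeral labels are validated by a round-trip
(parse ∘ format = id), so malformed registry labels fail at load time.

## Known limitations

- Country and origin-class metadata of the packaged compilations are
  unknown ("?"/unknown); per-country diversity over the real tables is
  therefore out of reach by construction, and the diversity module is
  exercised on synthetic populations.
- The *S₆*/*S₉* second-intron product sizes are unverified
  placeholders; calling *S₆* or *S₉* on real data requires filling in
  the panel table from the primary sources.
- Presumed homozygosity of single-*S<sub>c</sub>* cultivars is a
  convention, not a sequencing result; reports carry the flag so users
  can treat those genotypes conservatively.
- The historic group series between the compiled groups (e.g. VI, VII,
  IX, XIV) is absent from the registry because the source compilation
  lists no members for them; new-group numbering continues after the
  highest registered numeral (XXVI).
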