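"""S-locus diversity statistics per population.

Populations are groups of cultivars (typically country × origin class).
Each cultivar with a complete genotype contributes two allele copies
(homozygotes contribute two copies of one allele); a single-allele
genotype contributes its known allele as one copy, and optionally the
missing copy can be imputed by the allele's mean frequency across
populations, which produces fractional counts.

Statistics:

* N_a — number of distinct alleles observed in a population;
* A_r — rarefied allelic richness, the expected number of distinct
  alleles in a random subsample of g allele copies,
  ``A_r(g) = sum_i [1 - C(N - N_i, g) / C(N, g)]`` with N the population's
  copy total and N_i the copies of allele i. With fractional (imputed)
  counts the binomial coefficients generalize through the gamma
  function. A_r standardizes richness across unequal sample sizes;
* P_a — private alleles, present in exactly one population of the set;
* a chi-square test of allele × population association, with the null
  distribution obtained by Monte-Carlo resampling of tables with both
  margins fixed (Patefield's algorithm) and the add-one p-value
  correction p = (1 + #{X²_b >= X²_obs}) / (B + 1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .core import UNKNOWN, CultivarRecord, OriginClass

__all__ = [
    "count_alleles",
    "impute_missing",
    "allelic_richness",
    "private_alleles",
    "chisq_monte_carlo",
    "frequency_matrix",
    "frequency_heatmap",
    "diversity_report",
    "PopulationStats",
    "DiversityReport",
]


def count_alleles(
    cultivars: Sequence[CultivarRecord],
    grouping: str | Callable[[CultivarRecord], str] = "country",
    impute: bool = False,
    count_presumed_homozygous: bool = True,
) -> pd.DataFrame:
    """Population × allele table of allele-copy counts.

    ``grouping`` is an attribute name or a callable mapping a record to
    its population key. Presumed-homozygous single-Sc cultivars count as
    two Sc copies by default (set ``count_presumed_homozygous=False`` to
    count the raw single copy); other single-allele genotypes contribute
    one copy unless ``impute`` is on, in which case the missing copy is
    spread over alleles by mean frequency (fractional counts).
    """
    if isinstance(grouping, str):
        attr = grouping
        def key(record: CultivarRecord) -> str:
            value = getattr(record, attr)
            return value.value if isinstance(value, OriginClass) else str(value)
    else:
        key = grouping

    counts: dict[str, dict[str, float]] = {}
    missing: dict[str, float] = {}
    for record in cultivars:
        pop = key(record)
        row = counts.setdefault(pop, {})
        genotype = record.genotype
        alleles = (
            genotype.effective()
            if count_presumed_homozygous
            else genotype.alleles
        )
        for allele in alleles:
            if allele == UNKNOWN:
                missing[pop] = missing.get(pop, 0.0) + 1.0
            else:
                row[allele] = row.get(allele, 0.0) + 1.0

    table = pd.DataFrame.from_dict(counts, orient="index").fillna(0.0)
    table = table.sort_index()
    table = table[sorted(table.columns, key=_allele_order)]
    table.index.name = "population"
    table.columns.name = "allele"
    if impute and missing:
        table = impute_missing(table, missing)
    return table


def _allele_order(allele: str) -> tuple:
    from .core import allele_sort_key

    return (allele_sort_key(allele),)


def impute_missing(table: pd.DataFrame, missing: Mapping[str, float]) -> pd.DataFrame:
    """Distribute missing allele copies by overall mean allele frequency.

    Each population's missing copies are spread across alleles in
    proportion to the allele's pooled frequency, yielding fractional
    counts (the row total is preserved exactly).
    """
    total = table.values.sum()
    if total == 0:
        raise ValueError("cannot impute into an all-zero table")
    mean_freq = table.sum(axis=0) / total
    out = table.astype(float).copy()
    for pop, n_missing in missing.items():
        if pop in out.index and n_missing > 0:
            out.loc[pop] = out.loc[pop] + n_missing * mean_freq
    return out


def _log_comb(n: np.ndarray | float, k: float) -> np.ndarray | float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def allelic_richness(counts, g: int) -> float:
    """Expected number of distinct alleles in a subsample of g copies.

    ``counts`` maps alleles to copy counts (dict, Series, or array of
    counts). Fractional counts (from imputation) are supported through
    the gamma-function generalization of the binomial coefficients.
    ``g`` must satisfy 1 <= g <= N; ``g = N`` returns N_a exactly.
    """
    if hasattr(counts, "values"):
        arr = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts.values, dtype=float)
    else:
        arr = np.asarray(list(counts), dtype=float)
    arr = arr[arr > 0]
    n_total = arr.sum()
    if g < 1:
        raise ValueError("subsample size g must be at least 1")
    if g > n_total + 1e-9:
        raise ValueError(
            f"subsample size g={g} exceeds the population's {n_total:g} allele copies"
        )
    terms = np.zeros_like(arr)
    rest = n_total - arr  # copies not of allele i
    # C(rest, g) vanishes (allele certain in every subsample) once
    # rest <= g - 1; the gamma generalization stays positive above that.
    feasible = rest - (g - 1) > 1e-12
    terms[~feasible] = 1.0
    if feasible.any():
        log_ratio = _log_comb(rest[feasible], g) - _log_comb(n_total, g)
        terms[feasible] = 1.0 - np.exp(log_ratio)
    return float(terms.sum())


def private_alleles(table: pd.DataFrame) -> dict[str, list[str]]:
    """Alleles present in exactly one population of the table."""
    if table.shape[0] < 1:
        raise ValueError("at least one population required")
    presence = table > 0
    out: dict[str, list[str]] = {pop: [] for pop in table.index}
    for allele in table.columns:
        pops = presence.index[presence[allele]].tolist()
        if len(pops) == 1:
            out[pops[0]].append(str(allele))
    return out


def chisq_monte_carlo(
    table: pd.DataFrame | np.ndarray,
    B: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Pearson X² with a Monte-Carlo p-value under fixed margins.

    Zero rows/columns are dropped with a warning. Null tables are drawn
    uniformly with both margins fixed (Patefield's algorithm);
    ``p = (1 + #{X²_b >= X²_obs}) / (B + 1)``. Deterministic given a seed.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("contingency table must be two-dimensional")
    row_ok = arr.sum(axis=1) > 0
    col_ok = arr.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn(
            "dropping zero-margin rows/columns before the chi-square test",
            UserWarning,
            stacklevel=2,
        )
        arr = arr[row_ok][:, col_ok]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least a 2x2 table with positive margins")

    x2_obs = stats.chi2_contingency(arr, correction=False).statistic
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    row_margins = arr.sum(axis=1)
    col_margins = arr.sum(axis=0)
    # Patefield needs integer margins; imputed fractional tables are rounded
    null_dist = stats.random_table(
        np.rint(row_margins).astype(int), np.rint(col_margins).astype(int)
    )
    samples = null_dist.rvs(B, method="patefield", random_state=rng)
    expected = np.outer(row_margins, col_margins) / arr.sum()
    x2_null = (((samples - expected) ** 2) / expected).sum(axis=(1, 2))
    p = (1 + int((x2_null >= x2_obs - 1e-12).sum())) / (B + 1)
    return float(x2_obs), float(p)


def frequency_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Row-percentage matrix: each cell = 100 × count / row total."""
    row_sums = table.sum(axis=1)
    if (row_sums == 0).any():
        empty = table.index[row_sums == 0].tolist()
        raise ValueError(f"populations without allele copies: {empty}")
    return table.div(row_sums, axis=0) * 100.0


def frequency_heatmap(table: pd.DataFrame, out_path=None, ax=None):
    """Plot the row-percentage allele-frequency heatmap.

    Returns the percentage matrix; when ``out_path`` is given the figure
    is written there (PNG/PDF by extension).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    pct = frequency_matrix(table)
    created = ax is None
    if created:
        _, ax = plt.subplots(
            figsize=(1.0 + 0.6 * pct.shape[1], 1.0 + 0.45 * pct.shape[0])
        )
    sns.heatmap(
        pct,
        annot=True,
        fmt=".0f",
        cmap="YlOrRd",
        cbar_kws={"label": "% of population's allele copies"},
        ax=ax,
    )
    ax.set_xlabel("S-allele")
    ax.set_ylabel("population")
    if out_path is not None:
        ax.figure.savefig(out_path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return pct


@dataclass
class PopulationStats:
    population: str
    n_cultivars: int
    n_copies: float
    n_alleles: int
    allelic_richness: float
    private_alleles: list[str]


@dataclass
class DiversityReport:
    """Per-population and pooled S-locus diversity statistics."""

    populations: list[PopulationStats]
    g: int
    mean_n_alleles: float
    sd_n_alleles: float
    se_n_alleles: float
    mean_allelic_richness: float
    sd_allelic_richness: float
    se_allelic_richness: float
    total_private_alleles: int
    chi2: float
    p_value: float
    B: int
    seed: int | None

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), indent=2, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(p) for p in self.populations]).set_index(
            "population"
        )


def diversity_report(
    cultivars: Sequence[CultivarRecord],
    grouping: str | Callable[[CultivarRecord], str] = "country",
    origin_class: OriginClass | str | None = None,
    g: int | str = "auto",
    B: int = 2000,
    seed: int | None = None,
    min_cultivars: int = 1,
    impute: bool = False,
) -> DiversityReport:
    """Assemble the full per-population diversity report.

    ``g="auto"`` rarefies at the smallest population's copy total.
    ``origin_class`` filters to traditional or breeding accessions
    before grouping. Populations with fewer than ``min_cultivars``
    cultivars are dropped (default keeps all).
    """
    if origin_class is not None:
        origin_class = OriginClass(origin_class)
        cultivars = [c for c in cultivars if c.origin_class is origin_class]
    if not cultivars:
        raise ValueError("no cultivars to analyze after filtering")

    if isinstance(grouping, str):
        attr = grouping
        keyfn = lambda r: str(getattr(r, attr))
    else:
        keyfn = grouping
    pop_sizes: dict[str, int] = {}
    for record in cultivars:
        pop_sizes[keyfn(record)] = pop_sizes.get(keyfn(record), 0) + 1
    keep = {p for p, n in pop_sizes.items() if n >= min_cultivars}
    cultivars = [c for c in cultivars if keyfn(c) in keep]

    table = count_alleles(cultivars, grouping=grouping, impute=impute)
    copy_totals = table.sum(axis=1)
    g_value = int(np.floor(copy_totals.min())) if g == "auto" else int(g)

    privates = private_alleles(table)
    pops = [
        PopulationStats(
            population=str(pop),
            n_cultivars=pop_sizes[str(pop)],
            n_copies=float(copy_totals[pop]),
            n_alleles=int((table.loc[pop] > 0).sum()),
            allelic_richness=allelic_richness(table.loc[pop], g_value),
            private_alleles=privates[pop],
        )
        for pop in table.index
    ]
    na = np.array([p.n_alleles for p in pops], dtype=float)
    ar = np.array([p.allelic_richness for p in pops])
    k = len(pops)
    sd_na = float(na.std(ddof=1)) if k > 1 else 0.0
    sd_ar = float(ar.std(ddof=1)) if k > 1 else 0.0
    if k >= 2 and table.shape[1] >= 2:
        chi2, p = chisq_monte_carlo(table, B=B, seed=seed)
    else:
        chi2, p = float("nan"), float("nan")
    return DiversityReport(
        populations=pops,
        g=g_value,
        mean_n_alleles=float(na.mean()),
        sd_n_alleles=sd_na,
        se_n_alleles=sd_na / np.sqrt(k) if k else float("nan"),
        mean_allelic_richness=float(ar.mean()),
        sd_allelic_richness=sd_ar,
        se_allelic_richness=sd_ar / np.sqrt(k) if k else float("nan"),
        total_private_alleles=int(sum(len(v) for v in privates.values())),
        chi2=chi2,
        p_value=p,
        B=B,
        seed=seed,
    )
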