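"""Diversity statistics: rarefaction against an exhaustive oracle,
private alleles, the Monte-Carlo chi-square and report assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from apricot_si.core import SC, CultivarRecord, OriginClass, SGenotype
from apricot_si.diversity import (
    allelic_richness,
    chisq_monte_carlo,
    count_alleles,
    diversity_report,
    frequency_matrix,
    impute_missing,
    private_alleles,
)
from apricot_si.simulate import PopulationSpec, simulate_cultivars


def rarefaction_oracle(counts: dict[str, int], g: int) -> float:
    """Mean distinct-allele count over every explicit g-subsample."""
    copies = [a for allele, n in counts.items() for a in [allele] * n]
    subsets = list(itertools.combinations(range(len(copies)), g))
    distinct = [len({copies[i] for i in idx}) for idx in subsets]
    return sum(distinct) / len(subsets)


class TestCountAlleles:
    def test_heterozygote_contributes_one_copy_each(self):
        table = count_alleles(
            [CultivarRecord("Shalakh", SGenotype("S5", "S11"), country="Armenia")]
        )
        assert table.loc["Armenia", "S5"] == 1
        assert table.loc["Armenia", "S11"] == 1

    def test_homozygote_contributes_two_copies(self):
        table = count_alleles([CultivarRecord("Martinet", SGenotype("S2", "S2"))])
        assert table.loc["?", "S2"] == 2

    def test_incomplete_genotype_contributes_single_copy(self):
        table = count_alleles([CultivarRecord("Mogador", SGenotype("S3"))])
        assert table.loc["?", "S3"] == 1
        assert table.values.sum() == 1

    def test_presumed_homozygous_sc_counts_double_by_default(self):
        record = CultivarRecord("Currot", SGenotype(SC, presumed_homozygous=True))
        assert count_alleles([record]).loc["?", SC] == 2
        assert (
            count_alleles([record], count_presumed_homozygous=False).loc["?", SC] == 1
        )

    def test_imputation_preserves_row_totals_fractionally(self):
        records = [
            CultivarRecord("a", SGenotype("S1", "S2"), country="P1"),
            CultivarRecord("b", SGenotype("S1"), country="P1"),
            CultivarRecord("c", SGenotype("S2", "S2"), country="P2"),
        ]
        table = count_alleles(records, impute=True)
        assert table.loc["P1"].sum() == pytest.approx(4.0)  # 3 observed + 1 imputed
        assert ((table.values % 1) != 0).any()  # fractional counts appear


class TestAllelicRichness:
    def test_all_distinct_copies(self):
        assert allelic_richness({"A": 1, "B": 1}, g=2) == pytest.approx(2.0)

    def test_enumeration_example(self):
        # C(3,2)=3 subsamples of {A,A,B}: distinct counts (1,2,2) -> 5/3
        assert allelic_richness({"A": 2, "B": 1}, g=2) == pytest.approx(5 / 3, abs=1e-9)

    def test_monomorphic(self):
        assert allelic_richness({"A": 4}, g=2) == pytest.approx(1.0)

    def test_g_equals_n_returns_n_alleles(self):
        counts = {"A": 3, "B": 2, "C": 4}
        assert allelic_richness(counts, g=9) == pytest.approx(3.0, abs=1e-12)

    def test_g_beyond_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            allelic_richness({"A": 2}, g=3)

    @given(
        counts=st.lists(st.integers(1, 4), min_size=1, max_size=4),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_oracle(self, counts, data):
        total = sum(counts)
        if total > 12:
            counts = counts[:2]
            total = sum(counts)
        g = data.draw(st.integers(1, total))
        named = {f"A{i}": c for i, c in enumerate(counts)}
        assert allelic_richness(named, g) == pytest.approx(
            rarefaction_oracle(named, g), abs=1e-9
        )

    def test_non_decreasing_in_g(self):
        counts = {"A": 5, "B": 2, "C": 1}
        values = [allelic_richness(counts, g) for g in range(1, 9)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_fractional_counts_supported(self):
        # gamma-generalized rarefaction interpolates the integer lattice
        low = allelic_richness({"A": 3.0, "B": 1.0}, g=2)  # 1.5 exactly
        high = allelic_richness({"A": 3.0, "B": 2.0}, g=2)  # 1.6 exactly
        mid = allelic_richness({"A": 3.0, "B": 1.5}, g=2)
        assert low == pytest.approx(1.5) and high == pytest.approx(1.6)
        assert low < mid < high


class TestPrivateAlleles:
    def test_table3_style_private_allele(self):
        table = pd.DataFrame(
            {"S19": [1, 0], "S2": [1, 5], "Sc": [0, 3]},
            index=["Romania", "Spain"],
        )
        result = private_alleles(table)
        assert result["Romania"] == ["S19"]
        assert result["Spain"] == ["Sc"]

    def test_identical_populations_share_everything(self):
        table = pd.DataFrame({"S1": [2, 2], "S2": [1, 1]}, index=["a", "b"])
        assert private_alleles(table) == {"a": [], "b": []}

    def test_single_population_owns_all_present_alleles(self):
        table = pd.DataFrame({"S1": [2], "S2": [0], "S3": [1]}, index=["only"])
        assert private_alleles(table) == {"only": ["S1", "S3"]}


class TestChisqMonteCarlo:
    def test_perfect_independence(self):
        x2, p = chisq_monte_carlo(np.full((2, 2), 5.0), B=199, seed=0)
        assert x2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_statistic(self):
        x2, p = chisq_monte_carlo(np.array([[10, 0], [0, 10]]), B=499, seed=0)
        assert x2 == pytest.approx(20.0, abs=1e-12)
        assert p < 0.01

    def test_statistic_matches_reference_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            table = rng.integers(1, 30, size=rng.integers(2, 5, size=2))
            x2, _ = chisq_monte_carlo(table, B=9, seed=0)
            ref = stats.chi2_contingency(table, correction=False).statistic
            assert x2 == pytest.approx(ref, abs=1e-9)

    def test_deterministic_given_seed(self):
        table = np.array([[8, 3, 4], [2, 9, 5]])
        assert chisq_monte_carlo(table, B=299, seed=11) == chisq_monte_carlo(
            table, B=299, seed=11
        )

    def test_zero_margin_dropped_with_warning(self):
        table = np.array([[5, 0, 5], [3, 0, 7], [0, 0, 0]])
        with pytest.warns(UserWarning, match="zero-margin"):
            x2, _ = chisq_monte_carlo(table, B=99, seed=0)
        ref = stats.chi2_contingency(table[:2][:, [0, 2]], correction=False).statistic
        assert x2 == pytest.approx(ref)

    def test_type_i_error_near_nominal(self):
        """Null calibration: ~5% of MC p-values fall below 0.05."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sims = 500
        null = stats.random_table([12, 15, 13], [20, 20])
        tables = null.rvs(n_sims, method="patefield", random_state=rng)
        for i in range(n_sims):
            _, p = chisq_monte_carlo(tables[i], B=199, seed=int(rng.integers(2**31)))
            rejections += p <= 0.05
        assert 0.03 <= rejections / n_sims <= 0.07


class TestFrequencyMatrix:
    def test_rows_sum_to_hundred(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.integers(0, 9, size=(4, 6)) + rng.random((4, 6)))
        pct = frequency_matrix(table)
        assert np.allclose(pct.sum(axis=1), 100.0, atol=1e-9)

    def test_single_allele_population(self):
        pct = frequency_matrix(pd.DataFrame({"Sc": [4]}, index=["pop"]))
        assert pct.loc["pop", "Sc"] == pytest.approx(100.0)

    def test_absent_allele_is_zero(self):
        records = [
            CultivarRecord("a", SGenotype("S11", "S13"), country="Armenia"),
            CultivarRecord("b", SGenotype("S2", SC), country="Spain"),
        ]
        pct = frequency_matrix(count_alleles(records))
        assert pct.loc["Armenia", SC] == 0.0


class TestDiversityReport:
    def _population_records(self):
        specs = [
            PopulationSpec("P1", ("S1", "S2", "S3"), (0.5, 0.3, 0.2), 30),
            PopulationSpec("P2", ("S6", "S9", "S11"), (0.4, 0.4, 0.2), 30),
            PopulationSpec("P3", ("S12", "S13"), (0.5, 0.5), 30),
        ]
        records, _ = simulate_cultivars(specs, seed=5)
        return records, specs

    def test_disjoint_pools_recovered_as_private(self):
        records, specs = self._population_records()
        report = diversity_report(records, B=199, seed=1)
        by_pop = {p.population: p for p in report.populations}
        for spec in specs:
            assert set(by_pop[spec.name].private_alleles) == set(spec.pool)

    def test_structure_and_pooled_statistics(self):
        records, _ = self._population_records()
        report = diversity_report(records, B=199, seed=1)
        assert report.g == 60  # min copy total with 30 complete genotypes
        for p in report.populations:
            assert len(p.private_alleles) <= p.n_alleles
            assert p.allelic_richness <= p.n_alleles + 1e-9
        na = [p.n_alleles for p in report.populations]
        assert report.mean_n_alleles == pytest.approx(np.mean(na))
        assert report.se_n_alleles == pytest.approx(
            np.std(na, ddof=1) / np.sqrt(len(na))
        )

    def test_origin_class_filter(self):
        records = [
            CultivarRecord(
                "t", SGenotype("S1", "S2"), country="X",
                origin_class=OriginClass.TRADITIONAL,
            ),
            CultivarRecord(
                "b1", SGenotype("S3", "S6"), country="X",
                origin_class=OriginClass.BREEDING,
            ),
            CultivarRecord(
                "b2", SGenotype("S3", "S9"), country="Y",
                origin_class=OriginClass.BREEDING,
            ),
        ]
        report = diversity_report(records, origin_class="breeding", B=99, seed=0)
        assert {p.population for p in report.populations} == {"X", "Y"}
        assert all(p.n_cultivars == 1 for p in report.populations)

    def test_frequency_recovery_at_scale(self):
        """Estimated allele frequencies within 0.03 of the generator's."""
        freqs = (0.35, 0.25, 0.2, 0.12, 0.08)
        pool = ("S1", "S2", "S3", "S6", "S9")
        spec = PopulationSpec("big", pool, freqs, 500)
        records, _ = simulate_cultivars([spec], seed=9, gsi_constraint=False)
        table = count_alleles(records)
        est = (table / table.values.sum()).loc["big"]
        for allele, f in zip(pool, freqs):
            assert abs(est[allele] - f) <= 0.03
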