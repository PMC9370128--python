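"""Self-compatibility classification, cross verdicts, group allocation
and the pollinizer matrix, including the partition property on the
compiled reference table."""

import itertools

import pytest

from apricot_si.core import SC, CultivarRecord, SGenotype
from apricot_si.compat import (
    Basis,
    CompatStatus,
    CrossCategory,
    assign_groups,
    classify_record,
    classify_self_compatibility,
    cross_verdict,
    pollen_rejected,
    pollinizer_matrix,
)
from apricot_si.pollen import CrossType, PistilObservation, summarize_self_pollination
from apricot_si.simulate import PopulationSpec, simulate_cultivars


class TestClassify:
    @pytest.mark.parametrize(
        "alleles,expected,basis",
        [
            (("S2", "S6"), CompatStatus.SELF_INCOMPATIBLE, Basis.TWO_NONSC_ALLELES),
            (("S5", SC), CompatStatus.SELF_COMPATIBLE, Basis.SC_PRESENT),
            (("S3", None), CompatStatus.UNCLASSIFIED, Basis.INSUFFICIENT_GENOTYPE),
            (("S8", None), CompatStatus.SELF_INCOMPATIBLE, Basis.S8_NO_SC),
        ],
    )
    def test_genotype_rules(self, alleles, expected, basis):
        a1, a2 = alleles
        g = SGenotype(a1, a2) if a2 else SGenotype(a1)
        call = classify_self_compatibility(g)
        assert call.call is expected
        assert call.basis is basis

    def test_unclassified_iff_insufficient_genotype(self):
        statuses = [
            classify_self_compatibility(g)
            for g in (SGenotype("S1", "S2"), SGenotype("S3"), SGenotype(SC, SC))
        ]
        for call in statuses:
            assert (call.call is CompatStatus.UNCLASSIFIED) == (
                call.basis is Basis.INSUFFICIENT_GENOTYPE
            )

    def test_microscopy_fallback(self):
        obs = [
            PistilObservation("Samourai", CrossType.SELF, "Samourai", 62.5, False, True)
            for _ in range(10)
        ]
        summary = summarize_self_pollination(obs)
        call = classify_self_compatibility(SGenotype("S3"), microscopy=summary)
        assert call.call is CompatStatus.SELF_INCOMPATIBLE
        assert call.basis is Basis.MICROSCOPY

    def test_documented_evidence_overrides_genotype_inference(self):
        # 'Katy' is self-compatible by prior pollination evidence despite S1S2
        record = CultivarRecord(
            "Katy", SGenotype("S1", "S2"), documented_self_compatible=True
        )
        call = classify_record(record)
        assert call.call is CompatStatus.SELF_COMPATIBLE
        assert call.basis is Basis.DOCUMENTED

    def test_study_cohort_counts(self, study66):
        counts = {s: 0 for s in CompatStatus}
        for record in study66:
            counts[classify_record(record).call] += 1
        assert counts[CompatStatus.SELF_COMPATIBLE] == 49
        assert counts[CompatStatus.SELF_INCOMPATIBLE] == 12
        assert counts[CompatStatus.UNCLASSIFIED] == 5
        assert sum(counts.values()) == 66

    def test_every_compiled_compatible_record_classifies_sc(self, table2):
        assert all(
            classify_record(r).call is CompatStatus.SELF_COMPATIBLE for r in table2
        )


class TestPollenRejected:
    def test_matching_allele_rejected(self):
        assert pollen_rejected("S1", SGenotype("S1", "S2"))

    def test_sc_pollen_never_rejected(self):
        assert not pollen_rejected(SC, SGenotype(SC, SC))

    def test_non_matching_accepted(self):
        assert not pollen_rejected("S3", SGenotype("S1", "S2"))


class TestCrossVerdict:
    @pytest.mark.parametrize(
        "donor,pistil,category,fraction",
        [
            (("S1", "S2"), ("S1", "S2"), CrossCategory.INCOMPATIBLE, 0.0),
            (("S1", "S2"), ("S1", "S3"), CrossCategory.SEMI_COMPATIBLE, 0.5),
            ((SC, SC), ("S6", "S9"), CrossCategory.FULLY_COMPATIBLE, 1.0),
            (("S1", "S2"), ("S3", "S4"), CrossCategory.FULLY_COMPATIBLE, 1.0),
        ],
    )
    def test_worked_examples(self, donor, pistil, category, fraction):
        v = cross_verdict(SGenotype(*donor), SGenotype(*pistil))
        assert v.category is category
        assert v.compatible_pollen_fraction == fraction

    def test_unknown_allele_undetermined(self):
        v = cross_verdict(SGenotype("S1"), SGenotype("S1", "S2"))
        assert v.category is CrossCategory.UNDETERMINED
        assert v.compatible_pollen_fraction is None

    def test_sc_carrier_self_verdict_at_least_half(self):
        for other in ("S1", "S9", SC):
            g = SGenotype(other, SC)
            assert cross_verdict(g, g).compatible_pollen_fraction >= 0.5

    def test_category_fraction_bijective(self):
        seen = {}
        for donor, pistil in itertools.product(
            [SGenotype("S1", "S2"), SGenotype("S1", "S3"), SGenotype("S4", "S5")],
            repeat=2,
        ):
            v = cross_verdict(donor, pistil)
            assert seen.setdefault(v.category, v.compatible_pollen_fraction) == (
                v.compatible_pollen_fraction
            )


class TestAssignGroups:
    def test_registered_genotype_gets_registry_label(self, registry):
        result = assign_groups(
            [CultivarRecord("Farely", SGenotype("S1", "S9"))], registry
        )
        assert result.groups["Farely"] == "XXV"

    def test_unique_unregistered_goes_to_group_zero(self):
        from apricot_si.core import GroupRegistry

        result = assign_groups(
            [CultivarRecord("Martinet", SGenotype("S2", "S2"))], GroupRegistry()
        )
        assert result.groups["Martinet"] == "0"

    def test_shared_unregistered_opens_new_numbered_group(self, registry):
        records = [
            CultivarRecord("A", SGenotype("S14", "S15")),
            CultivarRecord("B", SGenotype("S14", "S15")),
        ]
        result = assign_groups(records, registry)
        assert result.groups == {"A": "XXVII", "B": "XXVII"}
        assert result.new_groups["XXVII"] == SGenotype("S14", "S15")

    def test_empty_input(self, registry):
        assert assign_groups([], registry).groups == {}

    def test_self_compatible_excluded_and_incomplete_unclassified(self, registry):
        records = [
            CultivarRecord("SCcv", SGenotype("S1", SC)),
            CultivarRecord("Mogador", SGenotype("S3")),
        ]
        result = assign_groups(records, registry)
        assert result.groups == {}
        assert result.excluded == ["SCcv"]
        assert result.unclassified == ["Mogador"]

    def test_previous_studies_cohort_count(self, table1, registry):
        prev = [r for r in table1 if r.source == "previous"]
        result = assign_groups(prev, registry)
        assert len(result.groups) == 77
        assert not result.new_groups

    def test_partition_property_on_compiled_table(self, table1, registry):
        """Within a numbered group every pair is cross-incompatible; across
        two different numbered groups no pair is."""
        result = assign_groups(table1, registry)
        by_name = {r.name: r for r in table1}
        numbered = {
            name: label for name, label in result.groups.items() if label != "0"
        }
        for (n1, l1), (n2, l2) in itertools.combinations(numbered.items(), 2):
            v = cross_verdict(by_name[n1].genotype, by_name[n2].genotype)
            if l1 == l2:
                assert v.category is CrossCategory.INCOMPATIBLE, (n1, n2)
            else:
                assert v.category is not CrossCategory.INCOMPATIBLE, (n1, n2)


class TestPollinizerMatrix:
    def test_same_group_members_pairwise_incompatible(self, table1):
        group8 = [r for r in table1 if r.genotype == SGenotype("S6", "S9")]
        m = pollinizer_matrix(group8)
        assert (m.values == "I").all()

    def test_scsc_row_fully_compatible(self, table1):
        records = [
            CultivarRecord("Currot", SGenotype(SC, SC)),
            *[r for r in table1 if r.genotype.complete()][:5],
        ]
        m = pollinizer_matrix(records)
        assert (m.loc["Currot"] == "F").all()

    def test_diagonal_is_self_verdict(self):
        records = [
            CultivarRecord("si", SGenotype("S1", "S2")),
            CultivarRecord("sc", SGenotype("S1", SC)),
        ]
        m = pollinizer_matrix(records)
        assert m.loc["si", "si"] == "I"
        assert m.loc["sc", "sc"] == "S"  # Sc pollen accepted, S1 rejected

    def test_symmetric_for_complete_non_sc_genotypes(self):
        """Brute force over all ordered pairs of a simulated set."""
        spec = PopulationSpec(
            name="sim",
            pool=("S1", "S2", "S3", "S6", "S9"),
            frequencies=(0.2, 0.2, 0.2, 0.2, 0.2),
            n_cultivars=10,
        )
        records, _ = simulate_cultivars([spec], seed=42)
        m = pollinizer_matrix(records)
        assert (m.values == m.values.T).all()
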