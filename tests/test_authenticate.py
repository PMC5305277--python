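"""The comparison engine: genotype matching, coverage/concordance,
contamination screens, panels, pairwise comparisons, characterisation."""

import numpy as np
import pytest

from snvauth.authenticate import (
    characterize,
    compare_to_panel,
    compare_to_reference,
    match_genotype,
    pairwise_concordance,
    screen_contaminant,
    snvs_per_million,
    verdict,
)
from snvauth.filtering import SnvProfile
from snvauth.types import (
    ComparisonResult,
    Effect,
    GenomicPosition,
    Impact,
    PanelLocus,
    ReferenceProfile,
    ReferenceVariant,
    Zygosity,
)

from .conftest import ann, make_call


def rv(pos=100, chrom="chr1", ref="A", mut="G", zygosity=Zygosity.UNKNOWN):
    return ReferenceVariant(
        position=GenomicPosition(chrom, pos), ref_allele=ref, mut_allele=mut,
        zygosity=zygosity,
    )


def profile_from(calls, sample_id="S"):
    return SnvProfile(
        sample_id=sample_id,
        calls={c.position: c for c in calls},
        n_input_calls=len(calls),
    )


class TestMatchGenotype:
    def test_het_call_carrying_mut_allele_matches(self):
        assert match_genotype(make_call(alts=("G",), gt=(0, 1)), rv(mut="G"))

    def test_hom_ref_at_mutation_position_mismatches(self):
        call = make_call(alts=(), gt=(0, 0), depths=(25,))
        assert not match_genotype(call, rv(mut="G"))

    def test_wrong_alt_allele_mismatches(self):
        assert not match_genotype(make_call(alts=("T",), gt=(0, 1)), rv(mut="G"))

    def test_position_disagreement_is_contract_violation(self):
        with pytest.raises(ValueError, match="position"):
            match_genotype(make_call(pos=100), rv(pos=200))

    def test_strict_mode_requires_zygosity_agreement(self):
        het_call = make_call(alts=("G",), gt=(0, 1))
        hom_call = make_call(alts=("G",), gt=(1, 1))
        hom_ref_var = rv(mut="G", zygosity=Zygosity.HOM)
        het_ref_var = rv(mut="G", zygosity=Zygosity.HET)
        assert match_genotype(het_call, het_ref_var, mode="strict")
        assert not match_genotype(het_call, hom_ref_var, mode="strict")
        assert match_genotype(hom_call, hom_ref_var, mode="strict")
        assert not match_genotype(hom_call, het_ref_var, mode="strict")
        # allele mode ignores zygosity entirely
        assert match_genotype(het_call, hom_ref_var, mode="allele")


def brute_force_compare(profile, reference):
    """Oracle: dict scan, position by position."""
    ref_by_pos = {}
    for v in reference.variants:
        ref_by_pos.setdefault(v.position, set()).add(v.mut_allele)
    overlap = match = 0
    for pos, call in profile.calls.items():
        if pos not in ref_by_pos:
            continue
        overlap += 1
        if ref_by_pos[pos] & set(call.called_alleles):
            match += 1
    return overlap, match


class TestCompareToReference:
    def test_colo205_scale_worked_example(self):
        """241 reference variants, 68 covered, 67 matching -> 28.2% / 98.5%."""
        reference = ReferenceProfile(
            "X", tuple(rv(pos=1000 + 50 * i, ref="A", mut="G") for i in range(241))
        )
        calls = [make_call(pos=1000 + 50 * i, alts=("G",)) for i in range(67)]
        calls.append(make_call(pos=1000 + 50 * 67, alts=("T",)))  # the one mismatch
        result = compare_to_reference(profile_from(calls), reference)
        assert (result.n_overlap, result.n_match) == (68, 67)
        assert result.coverage_pct == 28.2
        assert result.concordance_pct == 98.5

    def test_small_full_match(self):
        reference = ReferenceProfile("X", tuple(rv(pos=100 * i) for i in range(1, 11)))
        calls = [make_call(pos=100 * i, alts=("G",)) for i in range(1, 5)]
        result = compare_to_reference(profile_from(calls), reference)
        assert result.coverage_pct == 40.0 and result.concordance_pct == 100.0

    def test_zero_overlap_concordance_is_na_never_zero(self):
        reference = ReferenceProfile("X", (rv(pos=100),))
        result = compare_to_reference(profile_from([make_call(pos=999)]), reference)
        assert result.n_overlap == 0
        assert result.concordance is None and result.concordance_pct is None
        assert result.coverage_pct == 0.0

    def test_empty_reference_is_no_profile_error(self):
        with pytest.raises(ValueError, match="no profile"):
            compare_to_reference(profile_from([make_call()]), ReferenceProfile("X", ()))

    def test_multiple_mut_alleles_any_match_counts(self):
        reference = ReferenceProfile("X", (rv(mut="G"), rv(mut="T")))
        assert len(reference) == 2 and len(reference.positions) == 1
        result = compare_to_reference(profile_from([make_call(alts=("T",))]), reference)
        assert (result.n_overlap, result.n_match) == (1, 1)

    def test_hom_ref_counts_as_overlap_mismatch_unless_disabled(self):
        reference = ReferenceProfile("X", (rv(mut="G"),))
        hom_ref = make_call(alts=(), gt=(0, 0), depths=(25,))
        with_hr = compare_to_reference(profile_from([hom_ref]), reference)
        assert (with_hr.n_overlap, with_hr.n_mismatch) == (1, 1)
        without = compare_to_reference(
            profile_from([hom_ref]), reference, count_hom_ref=False
        )
        assert without.n_overlap == 0

    def test_match_plus_mismatch_equals_overlap_and_self_is_100(self):
        rng = np.random.default_rng(11)
        calls = [
            make_call(pos=int(p), alts=("ACGT"[rng.integers(1, 4)],))
            for p in rng.choice(100_000, size=300, replace=False) + 1
        ]
        profile = profile_from(calls)
        own_reference = ReferenceProfile(
            "self",
            tuple(
                ReferenceVariant(c.position, c.ref_allele, c.alt_alleles[0])
                for c in calls
                if c.alt_alleles[0] != c.ref_allele
            ),
        )
        result = compare_to_reference(profile, own_reference)
        assert result.n_match + result.n_mismatch == result.n_overlap
        assert result.concordance == 1.0

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_ref = int(rng.integers(1, 500))
            ref_positions = rng.choice(5000, size=n_ref, replace=False) + 1
            reference = ReferenceProfile(
                "X",
                tuple(
                    rv(pos=int(p), ref="A", mut="ACGT"[rng.integers(1, 4)])
                    for p in ref_positions
                ),
            )
            n_calls = int(rng.integers(0, 500))
            call_positions = rng.choice(5000, size=n_calls, replace=False) + 1
            calls = [
                make_call(pos=int(p), ref="A", alts=("ACGT"[rng.integers(1, 4)],))
                for p in call_positions
            ]
            profile = profile_from(calls)
            overlap, match = brute_force_compare(profile, reference)
            if len(reference) == 0:
                continue
            result = compare_to_reference(profile, reference)
            assert (result.n_overlap, result.n_match) == (overlap, match)

    def test_uncalled_reference_growth_lowers_coverage_not_concordance(self):
        reference = ReferenceProfile("X", tuple(rv(pos=100 * i) for i in range(1, 6)))
        calls = [make_call(pos=100 * i, alts=("G",)) for i in range(1, 4)]
        base = compare_to_reference(profile_from(calls), reference)
        grown = ReferenceProfile(
            "X", reference.variants + tuple(rv(pos=7777 + i) for i in range(20))
        )
        bigger = compare_to_reference(profile_from(calls), grown)
        assert bigger.coverage < base.coverage
        assert bigger.concordance == base.concordance


class TestScreen:
    def test_zero_matches_of_two_is_clean_reading_no_warning(self):
        reference = ReferenceProfile("HELA", (rv(pos=100, mut="G"), rv(pos=200, mut="G")))
        calls = [make_call(pos=100, alts=("T",)), make_call(pos=200, alts=("T",))]
        screen = screen_contaminant(profile_from(calls), reference)
        assert screen.summary == "0/2"
        assert screen.status == "no_match" and not screen.warning

    def test_zero_overlap_is_indeterminate_not_clean(self):
        reference = ReferenceProfile("HELA", (rv(pos=100),))
        screen = screen_contaminant(profile_from([make_call(pos=900)]), reference)
        assert screen.summary == "0/0"
        assert screen.status == "indeterminate" and not screen.warning

    def test_full_matches_raise_contamination_warning(self):
        reference = ReferenceProfile(
            "HELA", tuple(rv(pos=100 * i, mut="G") for i in range(1, 6))
        )
        calls = [make_call(pos=100 * i, alts=("G",)) for i in range(1, 6)]
        screen = screen_contaminant(profile_from(calls), reference)
        assert screen.summary == "5/5" and screen.warning


class TestPanel:
    def _panel(self):
        return [
            PanelLocus("rs1", GenomicPosition("chr1", 100), frozenset("AG")),
            PanelLocus("rs2", GenomicPosition("chr1", 200), frozenset("CT")),
            PanelLocus("rs3", GenomicPosition("chr1", 300), frozenset("A")),
        ]

    def test_covered_matching_counts(self):
        calls = [
            make_call(pos=100, ref="A", alts=("G",), gt=(0, 1)),
            make_call(pos=200, ref="C", alts=("T",), gt=(0, 1)),
        ]
        result = compare_to_panel(profile_from(calls), self._panel())
        assert result.summary == "2/2" and result.n_loci == 3

    def test_genotype_disagreement_in_overlap_not_match(self):
        calls = [make_call(pos=100, ref="A", alts=("C",), gt=(0, 1))]
        result = compare_to_panel(profile_from(calls), self._panel())
        assert (result.n_overlap, result.n_match) == (1, 0)

    def test_hom_genotype_comparison(self):
        calls = [make_call(pos=300, ref="A", alts=("G",), gt=(0, 0), depths=(20, 0))]
        result = compare_to_panel(profile_from(calls), self._panel())
        assert result.summary == "1/1"


class TestPairwise:
    def test_self_comparison_is_100(self):
        profile = profile_from([make_call(pos=p) for p in (100, 200)], "A")
        matrix = pairwise_concordance([profile, profile])
        assert matrix.iloc[0, 0] == 100.0 and matrix.iloc[0, 1] == 100.0

    def test_two_thirds_shared_allele_sets(self):
        a = profile_from(
            [
                make_call(pos=100, alts=("G",)),
                make_call(pos=200, alts=("T",)),
                make_call(pos=300, alts=("C",)),
                make_call(pos=999, alts=("G",)),
            ],
            "A",
        )
        b = profile_from(
            [
                make_call(pos=100, alts=("G",)),
                make_call(pos=200, alts=("T",)),
                make_call(pos=300, alts=("G",)),
            ],
            "B",
        )
        matrix = pairwise_concordance([a, b])
        assert matrix.loc["A", "B"] == 66.7
        assert matrix.loc["B", "A"] == 66.7

    def test_no_shared_positions_is_nan(self):
        a = profile_from([make_call(pos=100)], "A")
        b = profile_from([make_call(pos=200)], "B")
        matrix = pairwise_concordance([a, b])
        assert np.isnan(matrix.loc["A", "B"])

    def test_simulated_same_patient_pair_recovers_identity(self):
        rng = np.random.default_rng(5)
        identity = 0.99
        n = 2000
        calls_a, calls_b = [], []
        for i in range(n):
            pos = 1000 + i * 50
            calls_a.append(make_call(pos=pos, alts=("G",)))
            same = rng.random() < identity
            calls_b.append(make_call(pos=pos, alts=("G",) if same else ("T",)))
        matrix = pairwise_concordance(
            [profile_from(calls_a, "A"), profile_from(calls_b, "B")]
        )
        se = 100 * np.sqrt(identity * (1 - identity) / n)
        assert abs(matrix.loc["A", "B"] - 99.0) <= 3 * se


class TestCharacterize:
    def test_proportions_per_column(self):
        matches = (
            [make_call(pos=i, annotations=[ann(impact=Impact.HIGH)]) for i in range(1, 28)]
            + [make_call(pos=i, annotations=[ann(impact=Impact.MODERATE)])
               for i in range(100, 1073)]
        )
        mismatches = (
            [make_call(pos=i, annotations=[ann(impact=Impact.MODIFIER)]) for i in range(1, 19)]
            + [make_call(pos=i, annotations=[ann(impact=Impact.LOW)]) for i in range(100, 184)]
        )
        table = characterize(matches, mismatches)
        assert table.n_match == 1000 and table.n_mismatch == 102
        props = table.proportions("impact")
        assert props.loc["HIGH", "matches"] == 2.7
        assert props.loc["MODIFIER", "mismatches"] == 17.6
        assert abs(props["matches"].sum() - 100.0) < 0.2  # rounding slack

    def test_highest_impact_annotation_wins(self):
        call = make_call(
            annotations=[
                ann(tx="T1", impact=Impact.LOW, effect=Effect.SYNONYMOUS),
                ann(tx="T2", impact=Impact.HIGH, effect=Effect.NONSENSE),
            ]
        )
        table = characterize([call], [])
        assert table.impact_counts.loc["HIGH", "matches"] == 1
        assert table.effect_counts.loc["nonsense", "matches"] == 1

    def test_empty_category_is_zero_and_unannotated_ignored(self):
        hom_ref = make_call(alts=(), gt=(0, 0), depths=(25,))
        table = characterize([make_call(annotations=[ann()])], [hom_ref])
        assert table.impact_counts["mismatches"].sum() == 0
        assert table.impact_counts.loc["HIGH", "matches"] == 0


class TestRates:
    def test_snvs_per_million_paper_scale_values(self):
        assert snvs_per_million(72_203, 37_087_864) == 1947
        assert snvs_per_million(670_153, 255_394_483) == 2624

    def test_zero_snvs(self):
        assert snvs_per_million(0, 1_000_000) == 0

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            snvs_per_million(10, 0)


class TestVerdict:
    def _result(self, n_ref, n_overlap, n_match):
        return ComparisonResult(
            sample_id="S", reference_cell_line="X", n_reference=n_ref,
            n_overlap=n_overlap, n_match=n_match, n_mismatch=n_overlap - n_match,
        )

    def test_high_concordance_large_overlap_authenticates(self):
        v = verdict(self._result(2428, 1379, 1327))  # 96.2% over 1379
        assert v.authenticated

    def test_perfect_concordance_tiny_overlap_does_not(self):
        v = verdict(self._result(500, 3, 3))
        assert not v.authenticated
        assert any("insufficient overlap" in n for n in v.notes)

    def test_non_related_level_concordance_fails(self):
        v = verdict(self._result(2000, 1000, 679))  # 67.9%
        assert not v.authenticated

    def test_zero_overlap_is_undefined_not_authenticated(self):
        v = verdict(self._result(2000, 0, 0))
        assert not v.authenticated
        assert any("undefined" in n for n in v.notes)
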