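"""Variant calling, clone classification and library accounting."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mappitmap import (
    AlphabetError,
    CloneCalls,
    CloneClass,
    CloneRecord,
    Consequence,
    FrameError,
    LibraryError,
    ReferenceConstruct,
    VariantCall,
    call_variants,
    classify_clone,
    classify_library,
    select_pcr_condition,
    summarize_library,
    translate_cds,
)
from mappitmap.library import NUCLEOTIDES, SUBSTITUTION_TYPES


def clone(seq: str, cid: str = "P1_A1", cond: str = "") -> CloneRecord:
    return CloneRecord(clone_id=cid, sequence=seq, pcr_condition=cond)


class TestTranslate:
    @pytest.mark.parametrize(
        "cds,protein",
        [("ATGGCTGAA", "MAE"), ("ATGTAA", "M*"), ("TTATAAGCT", "L*A")],
    )
    def test_standard_code(self, cds, protein):
        assert translate_cds(cds) == protein

    def test_frame_error(self):
        with pytest.raises(FrameError):
            translate_cds("ATGGC")

    def test_alphabet_error(self):
        with pytest.raises(AlphabetError):
            translate_cds("ATGGXT")


class TestReference:
    def test_internal_stop_rejected(self):
        with pytest.raises(LibraryError):
            ReferenceConstruct(construct_id="bad", cds="ATGTAAGAA")

    def test_residue_numbering_offset(self):
        ref = ReferenceConstruct(construct_id="r", cds="ATGGCTGAA", residue_offset=159)
        assert ref.residue_number(1) == 159
        assert ref.residue_number(3) == 161
        assert ref.n_codons == 3


class TestCallVariants:
    def test_single_missense(self, tiny_ref):
        calls = call_variants(clone("ATGCCTGAA"), tiny_ref)
        (v,) = calls.calls
        assert (v.nt_pos, v.ref_base, v.alt_base) == (4, "G", "C")
        assert (v.codon_index, v.ref_aa, v.alt_aa) == (2, "A", "P")
        assert v.consequence is Consequence.MISSENSE

    def test_silent(self, tiny_ref):
        calls = call_variants(clone("ATGGCCGAA"), tiny_ref)
        (v,) = calls.calls
        assert (v.nt_pos, v.ref_base, v.alt_base) == (6, "T", "C")
        assert v.consequence is Consequence.SILENT

    def test_length_mismatch_routes_to_indel(self, tiny_ref):
        calls = call_variants(clone("ATGGCTGAAA"), tiny_ref)
        assert calls.indel and calls.calls == ()

    def test_two_changes_one_codon_joint_consequence(self, tiny_ref):
        # GCT -> ACA: both calls carry the jointly mutated codon's A->T change
        calls = call_variants(clone("ATGACAGAA"), tiny_ref)
        assert len(calls.calls) == 2
        assert {c.alt_aa for c in calls.calls} == {"T"}
        assert len(calls.missense_codons) == 1

    def test_nonsense(self, tiny_ref):
        calls = call_variants(clone("ATGGCTTAA"), tiny_ref)
        assert calls.has_nonsense

    def test_n_codon_produces_no_call_and_flags_ambiguous(self, tiny_ref):
        calls = call_variants(clone("ATGNCTGAA"), tiny_ref)
        assert calls.calls == () and calls.ambiguous

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_round_trip_against_generating_substitutions(self, data, ref50):
        """Applying a substitution list to the reference must be recovered
        exactly by call_variants (the generating list is the oracle)."""
        n = len(ref50.cds)
        positions = data.draw(
            st.lists(st.integers(0, n - 1), unique=True, max_size=8)
        )
        bases = list(ref50.cds)
        applied = []
        for pos in sorted(positions):
            alt = data.draw(
                st.sampled_from([b for b in NUCLEOTIDES if b != bases[pos]])
            )
            applied.append((pos + 1, bases[pos], alt))
            bases[pos] = alt
        calls = call_variants(clone("".join(bases)), ref50)
        observed = [(c.nt_pos, c.ref_base, c.alt_base) for c in calls.calls]
        assert observed == applied


def make_call(codon_index: int, consequence: Consequence) -> VariantCall:
    aa = {"silent": ("A", "A"), "missense": ("A", "P"), "nonsense": ("A", "*")}
    ref_aa, alt_aa = aa[consequence.value]
    return VariantCall(
        nt_pos=codon_index * 3,
        ref_base="T",
        alt_base="G",
        codon_index=codon_index,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=consequence,
    )


class TestClassify:
    @pytest.mark.parametrize(
        "consequences,expected",
        [
            ([], CloneClass.WILDTYPE),
            (["missense"], CloneClass.SINGLE_MISSENSE),
            (["missense", "silent"], CloneClass.SINGLE_MISSENSE),
            (["missense", "missense"], CloneClass.MULTI_MISSENSE),
            (["silent"], CloneClass.SILENT_ONLY),
            (["silent", "silent"], CloneClass.SILENT_ONLY),
            (["nonsense"], CloneClass.NONSENSE),
            (["missense", "nonsense"], CloneClass.NONSENSE),
        ],
    )
    def test_rule_table(self, consequences, expected):
        calls = CloneCalls(
            calls=tuple(
                make_call(i + 1, Consequence(c)) for i, c in enumerate(consequences)
            )
        )
        assert classify_clone(calls) is expected

    def test_total_over_all_flag_combinations(self):
        """classify_clone is a total single-valued function over every
        combination of per-consequence counts and the indel/ambiguous flags,
        checked against an independent restatement of the precedence rules."""
        for n_sil, n_mis, n_non, indel, amb in itertools.product(
            range(3), range(3), range(2), (False, True), (False, True)
        ):
            consequences = (
                [Consequence.SILENT] * n_sil
                + [Consequence.MISSENSE] * n_mis
                + [Consequence.NONSENSE] * n_non
            )
            calls = CloneCalls(
                calls=tuple(
                    make_call(i + 1, c) for i, c in enumerate(consequences)
                ),
                indel=indel,
                ambiguous=amb,
            )
            got = classify_clone(calls)
            if indel:
                expected = CloneClass.INDEL
            elif amb:
                expected = CloneClass.AMBIGUOUS
            elif n_non:
                expected = CloneClass.NONSENSE
            elif n_mis == 1:
                expected = CloneClass.SINGLE_MISSENSE
            elif n_mis > 1:
                expected = CloneClass.MULTI_MISSENSE
            elif n_sil:
                expected = CloneClass.SILENT_ONLY
            else:
                expected = CloneClass.WILDTYPE
            assert got is expected


class TestSummarize:
    def test_single_missense_fraction_one_third(self, ref50):
        """24 clones of which 8 single missense: the yield the screen banks on."""
        cds = ref50.cds
        clones = []
        for i in range(8):  # 8 distinct single missense (codon i+1 GCT-like swap)
            bases = list(cds)
            pos = i * 3 + 3  # wobble-free first base of codons 2..9
            bases[pos] = {"A": "C", "C": "A", "G": "C", "T": "G"}[bases[pos]]
            clones.append(clone("".join(bases), cid=f"P1_A{i + 1}"))
        clones += [clone(cds, cid=f"P1_B{i}") for i in range(16)]
        classified = classify_library(clones, ref50)
        summary = summarize_library(classified, ref50)
        n_single = sum(
            1 for c in classified if c.classification is CloneClass.SINGLE_MISSENSE
        )
        assert n_single >= 6  # first-base swaps are almost always missense
        assert summary.single_missense_fraction == pytest.approx(n_single / 24)

    def test_coverage_fraction(self, ref50):
        """Single-missense mutants at 39 of 50 codons -> coverage 0.78."""
        clones = []
        for codon in range(1, 40):
            bases = list(ref50.cds)
            pos = (codon - 1) * 3
            # transversion of the first codon base changes the amino acid for
            # every sense codon except the L/R wobble families; pick per-base
            bases[pos] = {"A": "C", "C": "G", "G": "C", "T": "G"}[bases[pos]]
            seq = "".join(bases)
            clones.append(clone(seq, cid=f"P1_C{codon}"))
        classified = classify_library(clones, ref50)
        kept = [
            c for c in classified if c.classification is CloneClass.SINGLE_MISSENSE
        ]
        summary = summarize_library(classified, ref50)
        covered = {c.missense_substitution[0] for c in kept}
        assert summary.coverage == pytest.approx(len(covered) / 50)

    def test_all_wildtype(self, ref50):
        classified = classify_library(
            [clone(ref50.cds, cid=f"P1_D{i}") for i in range(5)], ref50
        )
        summary = summarize_library(classified, ref50)
        assert all(v == 0 for v in summary.spectrum.values())
        assert summary.coverage == 0.0
        assert summary.n_unique_missense == 0

    def test_spectrum_equals_brute_force_tally(self, ref50, rng):
        """Spectrum counts must equal a direct positional mismatch tally."""
        from mappitmap import simulate_clone_sequences, MutationSpectrum

        clones, _ = simulate_clone_sequences(
            ref50, 60, MutationSpectrum(per_base_rate=0.02), seed=99
        )
        classified = classify_library(clones, ref50)
        summary = summarize_library(classified, ref50)
        tally = {t: 0 for t in SUBSTITUTION_TYPES}
        for c in clones:
            for i, (a, b) in enumerate(zip(ref50.cds, c.sequence)):
                if a != b and b != "N":
                    tally[f"{a}>{b}"] += 1
        assert summary.spectrum == tally

    def test_coverage_monotone_in_clones(self, ref50, rng):
        from mappitmap import simulate_clone_sequences, MutationSpectrum

        clones, _ = simulate_clone_sequences(
            ref50, 80, MutationSpectrum(per_base_rate=0.006), seed=5
        )
        classified = classify_library(clones, ref50)
        previous = 0.0
        for k in range(1, len(classified) + 1, 10):
            cov = summarize_library(classified[:k], ref50).coverage
            assert cov >= previous
            previous = cov

    def test_empty_input_errors(self, ref50):
        with pytest.raises(LibraryError):
            summarize_library([], ref50)

    def test_unique_missense_deduplicates_by_aa_change(self, tiny_ref):
        # GCT->CCT and GCT->CCA both give A2P: one unique mutant
        classified = classify_library(
            [clone("ATGCCTGAA", cid="P1_A1"), clone("ATGCCAGAA", cid="P1_A2")],
            tiny_ref,
        )
        summary = summarize_library(classified, tiny_ref)
        assert summary.n_unique_missense == 1


class TestSelectCondition:
    def _summary(self, n_clones, n_single, ref):
        counts = {CloneClass.SINGLE_MISSENSE.value: n_single}
        from mappitmap import LibrarySummary

        return LibrarySummary(
            n_clones=n_clones,
            class_counts=counts,
            spectrum={},
            n_unique_missense=n_single,
            coverage=0.0,
        )

    def test_argmax_count(self, ref50):
        summaries = {
            "A": self._summary(24, 8, ref50),
            "B": self._summary(24, 5, ref50),
        }
        assert select_pcr_condition(summaries) == "A"

    def test_tie_broken_by_fraction(self, ref50):
        summaries = {
            "A": self._summary(24, 8, ref50),
            "B": self._summary(20, 8, ref50),
        }
        assert select_pcr_condition(summaries) == "B"

    def test_single_condition(self, ref50):
        assert select_pcr_condition({"only": self._summary(24, 3, ref50)}) == "only"
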