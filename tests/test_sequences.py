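import math

import pytest
from hypothesis import given, settings, strategies as st

from arisc import (
    PairwiseAlignment,
    ProteinSequence,
    ScoringScheme,
    align_pair,
    arisc,
    arisc_pair,
    arisc_profile,
    categorize,
    identity_similarity,
    pair_from_msa,
    read_fasta,
    read_msa,
    score_alignment,
    write_fasta,
)
from arisc.synthetic import mutate_family, random_sequence

from .oracles import enumerate_alignment_score

short_seq = st.text(alphabet="ACDG", min_size=1, max_size=6)


class TestFastaIO:
    def test_single_record(self, tmp_path):
        p = tmp_path / "one.fasta"
        p.write_text(">a\nACDE\n")
        (rec,) = read_fasta(p)
        assert rec.id == "a" and rec.residues == "ACDE"

    def test_two_records_order_preserved_and_upcased(self, tmp_path):
        p = tmp_path / "two.fasta"
        p.write_text(">x\nacd\ne\n>y\nGGG\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["x", "y"]
        assert recs[0].residues == "ACDE"

    def test_nonstandard_character_names_record(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">ok\nACDE\n>bad\nACBDE\n")
        with pytest.raises(ValueError, match="bad.*B|B.*bad"):
            read_fasta(p)
        assert [r.id for r in read_fasta(p, permissive=True)] == ["ok"]

    def test_empty_and_duplicate_errors(self, tmp_path):
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        with pytest.raises(ValueError):
            read_fasta(empty)
        dup = tmp_path / "dup.fasta"
        dup.write_text(">a\nAC\n>a\nGG\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(dup)

    def test_write_read_round_trip(self, tmp_path):
        seqs = [ProteinSequence("a", "ACDEFGHIKLMNPQRSTVWY" * 4), ProteinSequence("b", "GGG")]
        p = tmp_path / "rt.fasta"
        write_fasta(seqs, p)
        back = read_fasta(p)
        assert [(s.id, s.residues) for s in back] == [(s.id, s.residues) for s in seqs]


class TestAlignment:
    def test_identical_sequences_align_gapless(self, toy_seqs, scheme):
        aln = align_pair(toy_seqs["acde"], toy_seqs["acde"], scheme)
        assert aln.aligned_a == aln.aligned_b == "ACDE"

    def test_gap_placement_matches_enumeration(self, toy_seqs, scheme):
        aln = align_pair(toy_seqs["acde"], toy_seqs["ace"], scheme)
        assert len(aln) == 4 and aln.aligned_b.count("-") == 1
        expected = enumerate_alignment_score(
            "ACDE", "ACE", scheme.matrix, scheme.gap_open, scheme.gap_extend
        )
        assert aln.score == pytest.approx(expected)

    def test_mismatches_preferred_over_gaps(self, scheme):
        aln = align_pair(ProteinSequence("x", "AAAA"), ProteinSequence("y", "GGGG"), scheme)
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_degapping_recovers_inputs(self, scheme):
        a = ProteinSequence("a", "MKVLAWT")
        b = ProteinSequence("b", "MKAWTG")
        aln = align_pair(a, b, scheme)
        assert aln.seq_a == a.residues and aln.seq_b == b.residues

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(short_seq, short_seq)
    def test_score_is_global_optimum(self, sa, sb):
        scheme = ScoringScheme()
        aln = align_pair(ProteinSequence("a", sa), ProteinSequence("b", sb), scheme)
        expected = enumerate_alignment_score(
            sa, sb, scheme.matrix, scheme.gap_open, scheme.gap_extend
        )
        assert aln.score == pytest.approx(expected)
        # the emitted alignment itself must score what it claims
        assert score_alignment(aln, scheme) == pytest.approx(aln.score)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACDEFGHIKL", min_size=1, max_size=40),
           st.text(alphabet="ACDEFGHIKL", min_size=1, max_size=40))
    def test_score_agrees_with_reference_aligner(self, sa, sb):
        from Bio.Align import PairwiseAligner, substitution_matrices

        scheme = ScoringScheme()
        ref = PairwiseAligner(
            mode="global",
            substitution_matrix=substitution_matrices.load("BLOSUM62"),
            open_gap_score=-scheme.gap_open,
            extend_gap_score=-scheme.gap_extend,
        )
        ours = align_pair(ProteinSequence("a", sa), ProteinSequence("b", sb), scheme)
        assert ours.score == pytest.approx(ref.score(sa, sb))


class TestIdentitySimilarity:
    def test_self_alignment_is_fully_identical(self, scheme):
        seq = ProteinSequence("s", "MKWVTFISLLFLFSSAYS")
        aln = align_pair(seq, seq, scheme)
        res = identity_similarity(aln, scheme)
        assert res.identity == res.similarity == 1.0

    def test_direct_counts(self, scheme):
        aln = PairwiseAlignment("a", "b", "ACDE", "ACDF", score=0.0)
        res = identity_similarity(aln, scheme, "shorter-sequence")
        assert res.n_identical == 3 and res.identity == 0.75

    def test_denominator_modes(self, scheme):
        aln = PairwiseAlignment("a", "b", "ACDE", "AC-E", score=0.0)
        shorter = identity_similarity(aln, scheme, "shorter-sequence")
        mean = identity_similarity(aln, scheme, "mean-length")
        full = identity_similarity(aln, scheme, "alignment-length")
        assert shorter.denominator == 3
        assert mean.denominator == 3.5
        assert full.denominator == 4
        with pytest.raises(ValueError, match="denominator_mode"):
            identity_similarity(aln, scheme, "bogus")

    def test_similar_residues_counted_in_similarity_only(self, scheme):
        # D/E share the acidic/amide class; E/F do not share any class
        aln = PairwiseAlignment("a", "b", "ADE", "AEF", score=0.0)
        res = identity_similarity(aln, scheme)
        assert res.n_identical == 1 and res.n_similar == 2

    def test_matrix_positive_mode(self):
        scheme = ScoringScheme(similarity_mode="matrix-positive")
        aln = PairwiseAlignment("a", "b", "KY", "RW", score=0.0)
        # BLOSUM62: K/R = +2 similar, Y/W = +2 similar
        res = identity_similarity(aln, scheme)
        assert res.n_similar == 2 and res.n_identical == 0


class TestArisc:
    @pytest.mark.parametrize(
        "identity,similarity,expected_value,expected_category",
        [
            (1.0, 1.0, 1.0, "high"),
            (0.40, 0.60, 0.50, "medium-high"),
            (0.20, 0.28, 0.24, "low"),
            (0.70, 0.80, 0.75, "high"),
            (0.20, 0.30, 0.25, "medium-low"),
        ],
    )
    def test_mean_and_category(self, identity, similarity, expected_value, expected_category):
        from arisc.sequences import IdentitySimilarityResult

        res = arisc(
            IdentitySimilarityResult(
                id_a="a", id_b="b", n_identical=0, n_similar=0, denominator=1.0,
                denominator_mode="shorter-sequence",
                identity=identity, similarity=similarity,
            )
        )
        assert res.arisc == pytest.approx(expected_value)
        assert res.category == expected_category

    def test_category_monotone_in_arisc(self):
        order = {"low": 0, "medium-low": 1, "medium-high": 2, "high": 3}
        values = [i / 200 for i in range(201)]
        cats = [order[categorize(v)] for v in values]
        assert cats == sorted(cats)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10 ** 6), st.integers(0, 10 ** 6))
    def test_pair_symmetry_and_bounds(self, seed_a, seed_b):
        a = random_sequence(30, seed=seed_a)
        b = random_sequence(25, seed=seed_b + 1)
        a = ProteinSequence("a", a.residues)
        b = ProteinSequence("b", b.residues)
        ab = arisc_pair(a, b)
        ba = arisc_pair(b, a)
        assert ab.arisc == ba.arisc
        assert ab.identity == ba.identity and ab.similarity == ba.similarity
        assert 0.0 <= ab.identity <= ab.similarity
        assert 0.0 <= ab.arisc <= 1.0


class TestProfile:
    def test_self_copy_scores_one(self):
        q = random_sequence(50, seed=5)
        twin = ProteinSequence("twin", q.residues)
        frame = arisc_profile(q, [twin])
        assert len(frame) == 1 and frame.loc[0, "arisc"] == 1.0

    def test_query_excluded_and_empty_family_rejected(self):
        q = random_sequence(50, seed=5)
        with pytest.raises(ValueError):
            arisc_profile(q, [q])

    def test_ordering_tracks_mutation_rates(self):
        ancestor = random_sequence(200, seed=11, alphabet="ACDEFGHIKLMNQRSTVWY")
        family = mutate_family(ancestor, [0.1, 0.3, 0.6], within_group_fraction=0.5, seed=12)
        frame = arisc_profile(ancestor, family)
        assert list(frame["id"]) == [s.id for s in family]  # 0.1 first, 0.6 last
        assert frame["arisc"].is_monotonic_decreasing


class TestMsa:
    def _write_msa(self, tmp_path, rows):
        p = tmp_path / "msa.fasta"
        p.write_text("".join(f">{i}\n{s}\n" for i, s in rows))
        return p

    def test_identical_rows_give_identity_one(self, tmp_path, scheme):
        msa = read_msa(self._write_msa(tmp_path, [("a", "ACDE"), ("b", "ACDE")]))
        aln = pair_from_msa(msa, "a", "b", scheme)
        assert identity_similarity(aln, scheme).identity == 1.0

    def test_shared_gap_column_dropped(self, tmp_path, scheme):
        msa = read_msa(
            self._write_msa(tmp_path, [("a", "AC-DE"), ("b", "AC-DF"), ("c", "ACGDF")])
        )
        aln = pair_from_msa(msa, "a", "b", scheme)
        assert len(aln) == 4
        assert aln.seq_a == "ACDE" and aln.seq_b == "ACDF"

    def test_missing_id_raises(self, tmp_path, scheme):
        msa = read_msa(self._write_msa(tmp_path, [("a", "ACDE"), ("b", "ACDE")]))
        with pytest.raises(KeyError):
            pair_from_msa(msa, "a", "zz", scheme)

    def test_round_trip_from_pairwise_alignment(self, tmp_path, scheme):
        a = random_sequence(60, seed=21)
        b = random_sequence(55, seed=22)
        direct = align_pair(a, b, scheme)
        msa = read_msa(
            self._write_msa(tmp_path, [(a.id, direct.aligned_a), (b.id, direct.aligned_b)])
        )
        extracted = pair_from_msa(msa, a.id, b.id, scheme)
        d1 = identity_similarity(direct, scheme)
        d2 = identity_similarity(extracted, scheme)
        assert (d1.n_identical, d1.n_similar) == (d2.n_identical, d2.n_similar)

    def test_clustal_format_readable(self, tmp_path, scheme):
        p = tmp_path / "msa.aln"
        p.write_text(
            "CLUSTAL W multiple sequence alignment\n\n"
            "a    ACDE\n"
            "b    ACDF\n"
        )
        msa = read_msa(p)
        aln = pair_from_msa(msa, "a", "b", scheme)
        assert aln.seq_b == "ACDF"
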