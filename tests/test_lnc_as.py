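import itertools

import numpy as np
import pytest

from lineagespec import lnc_as
from lineagespec.lnc_as import (
    TranscriptModel,
    builtin_scorers,
    classify_context,
    classify_pair,
    compare_across_cells,
    detect_as_events,
    filter_candidates,
    longest_orf_codons,
    vote_lncRNA,
)


def tx(tid, exons, strand="+", chrom="chr1", gene=None, biotype="candidate"):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene or tid.split(".")[0], chrom=chrom,
        strand=strand, exons=exons, biotype=biotype,
    )


CODING = [
    tx("c1.1", [(1000, 1400), (1600, 2000)], "+", biotype="coding"),
    tx("c2.1", [(5000, 5400), (5600, 6000)], "-", biotype="coding"),
]


class TestCandidateFilter:
    def test_six_transcript_fixture(self):
        fixture = [
            tx("t1", [(100, 249)]),                       # 150 nt: short
            tx("t2", [(30000, 30189)]),                   # 190 nt: short
            tx("t3", [(1100, 1499)], "+"),                # 1-exon sense overlap
            tx("t4", [(40000, 40449), (40900, 41349)]),   # clean 2-exon
            tx("t5", [(1100, 1299), (1700, 1999)], "+"),  # multi-exon sense
            tx("t6", [(5100, 5499)], "+"),                # 1-exon antisense ok
        ]
        kept = filter_candidates(fixture, CODING)
        assert {t.transcript_id for t in kept} == {"t4", "t5", "t6"}

    def test_short_intergenic_removed(self):
        assert filter_candidates([tx("t", [(10, 159)])], CODING) == []

    def test_two_exon_intergenic_retained(self):
        t = tx("t", [(100000, 100449), (100900, 101349)])
        assert filter_candidates([t], CODING) == [t]

    def test_malformed_exons_rejected(self):
        with pytest.raises(ValueError):
            tx("t", [(100, 50)])
        with pytest.raises(ValueError):
            tx("t", [(100, 200), (150, 300)])


class TestContext:
    def test_same_strand_overlap_is_sense(self):
        assert classify_context(tx("t", [(1100, 1500)], "+"), CODING) == "sense"

    def test_opposite_strand_only_is_antisense(self):
        assert classify_context(tx("t", [(1100, 1500)], "-"),
                                CODING) == "antisense"

    def test_no_overlap_is_intergenic(self):
        assert classify_context(tx("t", [(90000, 90500)]),
                                CODING) == "intergenic"

    def test_intron_only_overlap_is_not_sense(self):
        # candidate entirely inside the coding gene's intron
        assert classify_context(tx("t", [(1450, 1550)], "+"),
                                CODING) == "intergenic"


class TestVoting:
    def test_at_least_four_of_five(self):
        assert vote_lncRNA([True, True, True, True, False]) is True
        assert vote_lncRNA([True, True, True, False, False]) is False

    def test_exhaustive_enumeration(self):
        accepted = [v for v in itertools.product([True, False], repeat=5)
                    if vote_lncRNA(list(v))]
        # brute-force oracle: vectors with >= 4 True
        oracle = [v for v in itertools.product([True, False], repeat=5)
                  if sum(v) >= 4]
        assert accepted == oracle
        assert len(accepted) == 6

    def test_wrong_vote_count_rejected(self):
        with pytest.raises(ValueError):
            vote_lncRNA([True, True])


class TestScorers:
    def brute_force_orf(self, seq):
        """6-frame ORF enumeration oracle (codons incl. stop)."""
        best = 0
        for s in (seq, lnc_as.revcomp(seq)):
            for frame in range(3):
                codons = [s[i:i + 3] for i in range(frame, len(s) - 2, 3)]
                start = None
                for idx, c in enumerate(codons):
                    if start is None and c == "ATG":
                        start = idx
                    elif start is not None and c in lnc_as.STOP_CODONS:
                        best = max(best, idx - start + 1)
                        start = None
                if start is not None:
                    best = max(best, len(codons) - start)
        return best

    def test_long_orf_votes_coding(self):
        rng = np.random.default_rng(0)
        body = "".join(rng.choice([c for c in map("".join, itertools.product(
            "ACGT", repeat=3)) if c not in lnc_as.STOP_CODONS], 132))
        seq = "ATG" + body + "TAA"  # 400-nt ORF within the sequence
        votes = builtin_scorers(seq)
        assert votes["orf"] is False  # coding

    def test_repeated_taa_noncoding_by_stop_density(self):
        votes = builtin_scorers("TAA" * 60)
        assert votes["stop_density"] is True

    def test_orf_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
            assert longest_orf_codons(seq) == self.brute_force_orf(seq)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            builtin_scorers("")

    def test_hexamer_scorer_separates_training_styles(self, default_bundle):
        tb = default_bundle.transcripts
        truth = tb.truth
        correct = 0
        total = 0
        for tid, row in truth.iterrows():
            vote = builtin_scorers(tb.sequences[tid],
                                   tb.hexamer_tables)["hexamer"]
            correct += vote == (not row["coding"])
            total += 1
        assert correct / total >= 0.9


AS_FIXTURES = {
    "exon_skipping": ([(1, 100), (200, 300), (400, 500)],
                      [(1, 100), (400, 500)]),
    "intron_retention": ([(1, 100), (200, 300)], [(1, 300)]),
    "alt_donor": ([(1, 100), (200, 300)], [(1, 120), (200, 300)]),
    "alt_acceptor": ([(1, 100), (200, 300)], [(1, 100), (180, 300)]),
    "complex": ([(1, 100), (200, 300)], [(1, 80), (230, 300)]),
}


class TestASEvents:
    @pytest.mark.parametrize("kind", list(AS_FIXTURES))
    def test_fixture_types(self, kind):
        ex_a, ex_b = AS_FIXTURES[kind]
        events = classify_pair(tx("a.1", ex_a, gene="g"),
                               tx("a.2", ex_b, gene="g"))
        assert [e.type for e in events] == [kind]

    @pytest.mark.parametrize("kind", list(AS_FIXTURES))
    def test_isoform_order_invariance(self, kind):
        ex_a, ex_b = AS_FIXTURES[kind]
        e1 = classify_pair(tx("a.1", ex_a, gene="g"), tx("a.2", ex_b, gene="g"))
        e2 = classify_pair(tx("a.2", ex_b, gene="g"), tx("a.1", ex_a, gene="g"))
        assert [e.type for e in e1] == [e.type for e in e2]
        assert [e.region for e in e1] == [e.region for e in e2]

    @pytest.mark.parametrize("kind", list(AS_FIXTURES))
    def test_strand_mirror_swaps_donor_acceptor(self, kind):
        ex_a, ex_b = AS_FIXTURES[kind]
        M = 1000

        def mirror(exons):
            return sorted((M - e, M - s) for s, e in exons)

        fwd = classify_pair(tx("a.1", ex_a, gene="g"),
                            tx("a.2", ex_b, gene="g"))
        rev = classify_pair(tx("a.1", mirror(ex_a), "-", gene="g"),
                            tx("a.2", mirror(ex_b), "-", gene="g"))
        assert [e.type for e in fwd] == [e.type for e in rev]

    def test_mirrored_coordinates_on_same_strand_swap_types(self):
        # flipping geometry without flipping the strand swaps donor/acceptor
        ex_a, ex_b = AS_FIXTURES["alt_donor"]
        M = 1000
        mirror = lambda exons: sorted((M - e, M - s) for s, e in exons)
        events = classify_pair(tx("a.1", mirror(ex_a), gene="g"),
                               tx("a.2", mirror(ex_b), gene="g"))
        assert [e.type for e in events] == ["alt_acceptor"]

    def test_identical_chains_no_events(self):
        ex = [(1, 100), (200, 300)]
        assert classify_pair(tx("a.1", ex, gene="g"),
                             tx("a.2", ex, gene="g")) == []

    def test_different_strands_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(tx("a.1", [(1, 100)], "+", gene="g"),
                          tx("a.2", [(1, 100)], "-", gene="g"))

    def test_expression_filter(self):
        import pandas as pd

        ex_a, ex_b = AS_FIXTURES["exon_skipping"]
        isoforms = [tx("a.1", ex_a, gene="g"), tx("a.2", ex_b, gene="g")]
        fpkm = pd.DataFrame({"AC": [5.0, 0.2]}, index=["a.1", "a.2"])
        assert detect_as_events(isoforms, fpkm, "AC") == []
        fpkm.loc["a.2", "AC"] = 2.0
        assert len(detect_as_events(isoforms, fpkm, "AC")) == 1


class TestCompareAcrossCells:
    def test_specific_sets(self):
        out = compare_across_cells({"AC": {"x", "y"}, "BC": {"y", "z"}})
        assert out["AC_specific"] == {"x"}
        assert out["BC_specific"] == {"z"}

    def test_identical_sets_nothing_specific(self):
        out = compare_across_cells({"AC": {"x"}, "BC": {"x"}})
        assert out["AC_specific"] == set()

    def test_lineage_maintained_isoforms(self):
        out = compare_across_cells({
            "AC": {"a", "s"}, "BC": {"b", "s"},
            "32E": {"a", "s"}, "32S": {"b", "s"},
        })
        assert out["ACL_maintained"] == {"a"}
        assert out["BCL_maintained"] == {"b"}

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            compare_across_cells({"XX": set()})


def test_gtf_round_trip(tmp_path, default_bundle):
    models = default_bundle.transcripts.transcripts
    path = tmp_path / "t.gtf"
    lnc_as.write_gtf(models, path)
    back = {t.transcript_id: t for t in lnc_as.read_gtf(path)}
    assert len(back) == len(models)
    for t in models:
        b = back[t.transcript_id]
        assert b.exons == t.exons
        assert b.strand == t.strand
        assert b.biotype == t.biotype
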