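from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sagesig.sagetags import (
    ConcatemerRead,
    TagLibrary,
    TagToGeneMap,
    aggregate_to_genes,
    count_tags,
    extract_ditags,
    read_concatemer_fasta,
    read_tag_gene_map,
    read_tag_table,
    reverse_complement,
    split_ditag,
    write_tag_table,
)
from sagesig.synthetic import make_tag_map, simulate_library

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


class TestConcatemerRead:
    def test_rejects_empty_sequence(self):
        with pytest.raises(ValueError):
            ConcatemerRead("r1", "")

    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError):
            ConcatemerRead("r1", "ACGU")

    def test_accepts_n(self):
        assert ConcatemerRead("r1", "ACGTN").sequence == "ACGTN"


class TestExtractDitags:
    def test_single_inbounds_ditag(self):
        read = ConcatemerRead("r", "CATG" + "A" * 10 + "T" * 10 + "CATG")
        assert extract_ditags(read, 20, 26) == ["A" * 10 + "T" * 10]

    def test_zero_length_segment_rejected(self):
        assert extract_ditags(ConcatemerRead("r", "CATGCATG"), 20, 26) == []

    def test_read_without_site(self):
        assert extract_ditags(ConcatemerRead("r", "AAA"), 20, 26) == []

    def test_out_of_bounds_segments_discarded(self):
        seq = "CATG" + "A" * 5 + "CATG" + "C" * 21 + "CATG" + "G" * 30 + "CATG"
        assert extract_ditags(ConcatemerRead("r", seq), 20, 26) == ["C" * 21]

    def test_order_preserved(self):
        d1, d2 = "A" * 20, "C" * 20
        seq = "CATG" + d1 + "CATG" + d2 + "CATG"
        assert extract_ditags(ConcatemerRead("r", seq), 20, 26) == [d1, d2]

    def test_min_gt_max_rejected(self):
        with pytest.raises(ValueError):
            extract_ditags(ConcatemerRead("r", "ACGT"), 26, 20)

    @given(dna)
    def test_never_contains_site(self, seq):
        for ditag in extract_ditags(ConcatemerRead("r", seq), 1, 100):
            assert "CATG" not in ditag

    def test_generator_round_trip(self):
        """Concatemers built from known ditags give back exactly those."""
        tag_map = make_tag_map(50, seed=5)
        sim = simulate_library(
            np.ones(50) / 50,
            depth=80,
            seed=5,
            tag_map=tag_map,
            emit_concatemers=True,
            ditags_per_read=2,  # 40 ditags -> 20 reads
        )
        recovered = []
        for read in sim.reads:
            recovered.extend(extract_ditags(read, 20, 26))
        assert Counter(recovered) == Counter(sim.ditags)


class TestSplitDitag:
    def test_poly_a_poly_t(self):
        assert split_ditag("A" * 10 + "T" * 10, 10) == ("A" * 10, "A" * 10)

    def test_hand_computed_revcomp(self):
        ditag = "ACGTACGTACGTACGTACGTAC"  # 22-mer
        first, second = split_ditag(ditag, 10)
        assert first == "ACGTACGTAC"
        assert second == reverse_complement("ACGTACGTAC")
        assert second == "GTACGTACGT"

    def test_short_ditag_rejected(self):
        with pytest.raises(ValueError):
            split_ditag("ACGT", 10)

    def test_overlapping_short_ditag_allowed(self):
        # lengths in [tag_len, 2*tag_len) give two overlapping tags
        ditag = "ACGTACGTACGTACG"  # 15-mer
        first, second = split_ditag(ditag, 10)
        assert first == ditag[:10]
        assert second == reverse_complement(ditag[-10:])

    def test_generator_round_trip(self, rng):
        tag_map = make_tag_map(20, seed=9)
        sim = simulate_library(
            np.ones(20) / 20, depth=40, seed=9,
            tag_map=tag_map, emit_concatemers=True,
        )
        stream_pairs = [
            (sim.ditags[i][:10], reverse_complement(sim.ditags[i][-10:]))
            for i in range(len(sim.ditags))
        ]
        for ditag, expected in zip(sim.ditags, stream_pairs):
            assert split_ditag(ditag, 10) == expected


class TestCountTags:
    def test_duplicate_collapse_on(self):
        ditag = "A" * 10 + "C" * 10
        lib, stats = count_tags([ditag, ditag], dedupe=True)
        assert lib.counts["A" * 10] == 1
        assert stats["ditags_after_dedupe"] == 1

    def test_duplicate_collapse_off(self):
        ditag = "A" * 10 + "C" * 10
        lib, _ = count_tags([ditag, ditag], dedupe=False)
        assert lib.counts["A" * 10] == 2

    def test_empty_input(self):
        lib, _ = count_tags([])
        assert lib.total_tags == 0

    def test_blacklist_excluded(self):
        ditag = "A" * 10 + "C" * 10
        lib, stats = count_tags([ditag], linker_blacklist={"A" * 10})
        assert "A" * 10 not in lib.counts
        assert stats["blacklisted_tags"] == 1

    def test_n_tags_discarded(self):
        ditag = "N" + "A" * 9 + "C" * 10
        lib, stats = count_tags([ditag])
        assert stats["n_tags_discarded"] == 1
        assert lib.total_tags == 1  # only the second tag survives

    def test_planted_duplicates_post_dedupe_truth(self):
        tag_map = make_tag_map(30, seed=3)
        sim = simulate_library(
            np.ones(30) / 30, depth=200, seed=3, tag_map=tag_map,
            emit_concatemers=True, duplicate_rate=0.1,
        )
        lib, _ = count_tags(sim.ditags, dedupe=True)
        assert lib.counts == sim.dedupe_tag_counts


class TestTagToGeneMap:
    def test_repeated_distinct_rows_are_ambiguous(self):
        m = TagToGeneMap.from_pairs([("A" * 10, "g1"), ("A" * 10, "g2")])
        assert m.ambiguous_tags == {"A" * 10}
        assert not m.entries

    def test_repeated_identical_rows_are_not(self):
        m = TagToGeneMap.from_pairs([("A" * 10, "g1"), ("A" * 10, "g1")])
        assert m.entries == {"A" * 10: "g1"}


class TestAggregateToGenes:
    def _lib(self, counts):
        return TagLibrary("L", Counter(counts))

    def test_additivity(self):
        lib = self._lib({"A" * 10: 3, "C" * 10: 4})
        mapping = TagToGeneMap.from_pairs([("A" * 10, "G"), ("C" * 10, "G")])
        assert aggregate_to_genes(lib, mapping).counts == {"G": 7}

    def test_unmapped_total(self):
        lib = self._lib({"A" * 10: 3})
        result = aggregate_to_genes(lib, TagToGeneMap())
        assert result.counts == {}
        assert result.unmapped_total == 3

    def test_ambiguous_dropped_by_default(self):
        lib = self._lib({"A" * 10: 5})
        mapping = TagToGeneMap.from_pairs([("A" * 10, "g1"), ("A" * 10, "g2")])
        result = aggregate_to_genes(lib, mapping)
        assert result.ambiguous_total == 5
        assert result.counts == {}

    def test_ambiguous_keep_first(self):
        lib = self._lib({"A" * 10: 5})
        mapping = TagToGeneMap.from_pairs([("A" * 10, "g1"), ("A" * 10, "g2")])
        result = aggregate_to_genes(lib, mapping, ambiguous_policy="keep_first")
        assert result.counts == {"g1": 5}

    def test_conservation(self, rng):
        """gene counts + unmapped + ambiguous == total tags."""
        tags = make_tag_map(40, seed=11)
        counts = {t: int(rng.integers(1, 10)) for t in tags}
        lib = self._lib(counts)
        pairs = [(t, f"g{i % 10}") for i, t in enumerate(tags[:30])]
        pairs += [(tags[30], "gx"), (tags[30], "gy")]  # ambiguous
        mapping = TagToGeneMap.from_pairs(pairs)
        result = aggregate_to_genes(lib, mapping)
        assert (
            sum(result.counts.values())
            + result.unmapped_total
            + result.ambiguous_total
            == lib.total_tags
        )

    def test_synthetic_library_matches_generator(self):
        tag_map = make_tag_map(25, seed=2)
        sim = simulate_library(
            np.ones(25) / 25, depth=500, seed=2, tag_map=tag_map,
        )
        mapping = TagToGeneMap.from_pairs(
            [(t, f"G{i + 1:05d}") for i, t in enumerate(tag_map)]
        )
        result = aggregate_to_genes(sim.tag_library, mapping)
        assert result.counts == sim.gene_counts.counts


class TestIO:
    def test_tag_table_round_trip(self, tmp_path):
        lib = TagLibrary("L1", Counter({"A" * 10: 5, "C" * 10: 2}))
        write_tag_table(lib, tmp_path / "t.tsv", sidecar_stats={"ditags_raw": 7})
        back = read_tag_table(tmp_path / "t.tsv", library_id="L1")
        assert back.counts == lib.counts
        assert (tmp_path / "t.tsv.json").exists()

    def test_tag_table_sorted_by_count_then_tag(self, tmp_path):
        lib = TagLibrary(
            "L1", Counter({"C" * 10: 5, "A" * 10: 5, "G" * 10: 9})
        )
        write_tag_table(lib, tmp_path / "t.tsv")
        rows = (tmp_path / "t.tsv").read_text().splitlines()[1:]
        assert [r.split("\t")[0] for r in rows] == ["G" * 10, "A" * 10, "C" * 10]

    def test_fasta_reader(self, tmp_path):
        (tmp_path / "r.fa").write_text(">r1 extra\nacgt\n>r2\nCATG\n")
        reads = read_concatemer_fasta(tmp_path / "r.fa")
        assert [r.read_id for r in reads] == ["r1", "r2"]
        assert reads[0].sequence == "ACGT"

    def test_mapping_reader(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "tag\tgene_id\n" + "A" * 10 + "\tg1\n" + "C" * 10 + "\tg2\n"
            + "C" * 10 + "\tg3\n"
        )
        m = read_tag_gene_map(tmp_path / "m.tsv")
        assert m.entries == {"A" * 10: "g1"}
        assert m.ambiguous_tags == {"C" * 10}
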