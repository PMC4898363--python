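"""ss-count ingestion, fragment merging, the at-least-half rule, partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnasig import (
    GenomeRecord,
    classify_ss_ds,
    merge_fragment_profiles,
    partition_positions,
    read_ct,
    read_dotbracket,
    read_sscount,
)
from rnasig.structure import (
    PairingProfile,
    StructureError,
    dotbracket_profile,
    split_into_fragments,
    write_sscount,
)


class TestReadSscount:
    def test_header_dialect(self, tmp_path):
        path = tmp_path / "a.sscount"
        path.write_text("50\n1 25\n2 24\n3 50\n")
        p = read_sscount(path)
        assert p.n_structures == 50 and p.length == 3
        assert list(p.ss_count) == [25, 24, 50]

    def test_count_exceeding_header_rejected(self, tmp_path):
        path = tmp_path / "a.sscount"
        path.write_text("50\n1 51\n")
        with pytest.raises(StructureError, match="exceeds"):
            read_sscount(path)

    def test_empty_body_rejected(self, tmp_path):
        path = tmp_path / "a.sscount"
        path.write_text("50\n")
        with pytest.raises(StructureError, match="no ss-count"):
            read_sscount(path)

    @pytest.mark.parametrize("body", ["1 5\n3 5\n", "1 5\n1 5\n", "2 5\n1 5\n"])
    def test_gaps_duplicates_disorder_rejected(self, tmp_path, body):
        path = tmp_path / "a.sscount"
        path.write_text("10\n" + body)
        with pytest.raises(StructureError, match="contiguous"):
            read_sscount(path)

    def test_headerless_requires_n_structures(self, tmp_path):
        path = tmp_path / "a.sscount"
        path.write_text("1 5\n2 6\n")
        with pytest.raises(StructureError, match="n_structures"):
            read_sscount(path)
        p = read_sscount(path, n_structures=10)
        assert p.n_structures == 10 and list(p.ss_count) == [5, 6]

    def test_round_trip(self, tmp_path):
        p = PairingProfile(ss_count=np.array([0, 3, 7, 10]), n_structures=10)
        path = tmp_path / "rt.sscount"
        write_sscount(p, path)
        back = read_sscount(path)
        assert back.n_structures == 10 and np.array_equal(back.ss_count, p.ss_count)


class TestSingleStructureReaders:
    @pytest.mark.parametrize(
        "db,expected",
        [("((..))", [0, 0, 1, 1, 0, 0]), ("......", [1, 1, 1, 1, 1, 1])],
    )
    def test_dotbracket(self, tmp_path, db, expected):
        path = tmp_path / "s.db"
        path.write_text(f">s\n{db}\n")
        p = read_dotbracket(path)
        assert p.n_structures == 1 and list(p.ss_count) == expected

    @pytest.mark.parametrize("db", ["((.)", "(..))", "(.>.)"])
    def test_unbalanced_dotbracket_rejected(self, db):
        with pytest.raises(StructureError):
            dotbracket_profile(db)

    def test_ct_parses_and_checks_symmetry(self, tmp_path):
        # hairpin ((..)) in CT form: column 5 is the partner (0 = unpaired)
        lines = ["6 synthetic hairpin"]
        partners = [6, 5, 0, 0, 2, 1]
        for i, (nt, j) in enumerate(zip("GGAACC", partners), 1):
            lines.append(f"{i} {nt} {i - 1} {i + 1} {j} {i}")
        path = tmp_path / "s.ct"
        path.write_text("\n".join(lines) + "\n")
        p = read_ct(path)
        assert list(p.ss_count) == [0, 0, 1, 1, 0, 0]

    def test_ct_asymmetric_pairing_rejected(self, tmp_path):
        lines = ["2 bad", "1 G 0 2 2 1", "2 C 1 3 0 2"]
        path = tmp_path / "s.ct"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(StructureError, match="asymmetric"):
            read_ct(path)

    def test_ct_header_mismatch_rejected(self, tmp_path):
        path = tmp_path / "s.ct"
        path.write_text("3 bad\n1 G 0 2 0 1\n")
        with pytest.raises(StructureError, match="declares"):
            read_ct(path)


class TestMergeFragments:
    def test_overlap_values_are_averaged(self):
        p1 = PairingProfile(ss_count=np.array([1.0, 2.0, 10.0]), n_structures=50)
        p2 = PairingProfile(ss_count=np.array([20.0, 3.0, 4.0]), n_structures=50)
        merged = merge_fragment_profiles(p1, p2, overlap=1)
        assert list(merged.ss_count) == [1.0, 2.0, 15.0, 3.0, 4.0]
        assert merged.length == p1.length + p2.length - 1

    def test_identical_fragments_full_overlap_identity(self):
        p = PairingProfile(ss_count=np.array([1.0, 2.0, 3.0]), n_structures=10)
        merged = merge_fragment_profiles(p, p, overlap=3)
        assert np.array_equal(merged.ss_count, p.ss_count)

    def test_zero_overlap_concatenates(self):
        p1 = PairingProfile(ss_count=np.array([1.0]), n_structures=10)
        p2 = PairingProfile(ss_count=np.array([2.0]), n_structures=10)
        assert list(merge_fragment_profiles(p1, p2, overlap=0).ss_count) == [1.0, 2.0]

    def test_mismatched_ensembles_rejected(self):
        p1 = PairingProfile(ss_count=np.array([1.0]), n_structures=10)
        p2 = PairingProfile(ss_count=np.array([1.0]), n_structures=20)
        with pytest.raises(StructureError, match="n_structures"):
            merge_fragment_profiles(p1, p2, overlap=1)

    def test_oversized_overlap_rejected(self):
        p = PairingProfile(ss_count=np.array([1.0, 2.0]), n_structures=10)
        with pytest.raises(StructureError, match="overlap"):
            merge_fragment_profiles(p, p, overlap=3)

    def test_merge_then_classify_matches_unsplit_when_fragments_agree(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 51, size=200).astype(float)
        whole = PairingProfile(ss_count=counts, n_structures=50)
        p1 = PairingProfile(ss_count=counts[:120], n_structures=50)
        p2 = PairingProfile(ss_count=counts[70:], n_structures=50)
        merged = merge_fragment_profiles(p1, p2, overlap=50)
        assert np.array_equal(classify_ss_ds(merged), classify_ss_ds(whole))


class TestClassify:
    @pytest.mark.parametrize(
        "count,expected_ss",
        [(25, True), (24, False), (24.5, False), (25.5, True), (50, True), (0, False)],
    )
    def test_at_least_half_rule_inclusive(self, count, expected_ss):
        p = PairingProfile(ss_count=np.array([count]), n_structures=50)
        assert classify_ss_ds(p)[0] == expected_ss

    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=60),
        st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_ss_count(self, counts, data):
        """Raising any single ss-count never flips a position ss -> ds."""
        p = PairingProfile(ss_count=np.array(counts, dtype=float), n_structures=50)
        before = classify_ss_ds(p)
        i = data.draw(st.integers(min_value=0, max_value=len(counts) - 1))
        bump = np.array(counts, dtype=float)
        bump[i] = min(50.0, bump[i] + data.draw(st.floats(0, 10)))
        after = classify_ss_ds(PairingProfile(ss_count=bump, n_structures=50))
        assert not np.any(before & ~after)


class TestPartition:
    def test_small_example(self):
        record = GenomeRecord(id="x", sequence="AUCG")
        ss, ds = partition_positions(record, np.array(["ss", "ds", "ds", "ss"]))
        assert (ss, ds) == ("AG", "UC")

    def test_all_single_stranded(self):
        record = GenomeRecord(id="x", sequence="AUCG")
        ss, ds = partition_positions(record, np.ones(4, dtype=bool))
        assert ss == "AUCG" and ds == ""

    def test_length_mismatch_rejected(self):
        record = GenomeRecord(id="x", sequence="AUCG")
        with pytest.raises(StructureError):
            partition_positions(record, np.ones(3, dtype=bool))

    @given(st.text(alphabet="ACGU", min_size=1, max_size=200), st.data())
    @settings(max_examples=50, deadline=None)
    def test_conservation(self, seq, data):
        """|ss| + |ds| = genome length; multiset union equals the genome."""
        record = GenomeRecord(id="x", sequence=seq)
        mask = np.array(
            data.draw(st.lists(st.booleans(), min_size=len(seq), max_size=len(seq)))
        )
        ss, ds = partition_positions(record, mask)
        assert len(ss) + len(ds) == record.length
        assert sorted(ss + ds) == sorted(seq)


def test_split_into_fragments_covers_genome_with_overlap():
    record = GenomeRecord(id="x", sequence="A" * 10794)
    (a0, a1), (b0, b1) = split_into_fragments(record)
    assert a0 == 0 and b1 == 10794
    assert a1 - b0 == 1000  # shared overlap
    assert a1 <= 9000 and b1 - b0 <= 9000
    assert split_into_fragments(GenomeRecord(id="y", sequence="A" * 500)) == [(0, 500)]
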