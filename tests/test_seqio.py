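"""Sequence/metadata I/O, haplotype collapsing and the numt screen."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodeval.errors import ParseError, ValidationError
from barcodeval.seqio import (Dataset, SequenceRecord, SpecimenRecord,
                              collapse_haplotypes, read_fasta,
                              read_specimen_table, screen_numts, write_fasta)

# 20 sense codons of the invertebrate mitochondrial code (no TAA/TAG).
SENSE_CODONS = ["ATT", "GCT", "TTA", "GGA", "TGA", "CAT", "AAA", "CCT"]


def test_read_fasta_parses_entries_and_flags_alignment(tmp_path):
    path = tmp_path / "x.fasta"
    path.write_text(">s1\nACGT\n>s2\nAC-GT\n")
    records = read_fasta(path, "COI")
    assert [r.sequence_id for r in records] == ["s1", "s2"]
    assert records[0].residues == "ACGT" and not records[0].is_aligned
    assert records[1].is_aligned


def test_read_fasta_header_tokenisation_and_case(tmp_path):
    path = tmp_path / "x.fasta"
    path.write_text(">s1 Agonum viduum|COI\nacgt\n")
    (rec,) = read_fasta(path, "COI")
    assert rec.sequence_id == "s1"
    assert rec.residues == "ACGT"


@pytest.mark.parametrize("content", ["", "ACGT\n>s1\nACGT\n"])
def test_read_fasta_rejects_malformed(tmp_path, content):
    path = tmp_path / "bad.fasta"
    path.write_text(content)
    with pytest.raises(ParseError):
        read_fasta(path, "COI")


def test_read_fasta_rejects_duplicate_ids(tmp_path):
    path = tmp_path / "dup.fasta"
    path.write_text(">s1\nACGT\n>s1\nACGT\n")
    with pytest.raises(ParseError, match="duplicate"):
        read_fasta(path, "COI")


def test_fasta_round_trip_is_lossless(tmp_path):
    records = [
        SequenceRecord("a1", "V4", "ACGTRYN"),
        SequenceRecord("b2", "V4", "AC--GT", is_aligned=True),
    ]
    path = tmp_path / "rt.fasta"
    write_fasta(records, path)
    back = read_fasta(path, "V4")
    assert [(r.sequence_id, r.residues) for r in back] == [
        ("a1", "ACGTRYN"), ("b2", "AC--GT")
    ]


def test_specimen_table_round_trip_and_genus_derivation(tmp_path):
    path = tmp_path / "spec.tsv"
    path.write_text(
        "specimen_id\tspecies\tCOI\tD3\tV4\tV7\n"
        "p1\tPterostichus nigrita\tp1_COI\t\t\t\n"
        "p2\tPterostichus nigrita\tp2_COI\t\t\t\n"
        "a1\tAgonum viduum\ta1_COI\t\t\t\n"
    )
    specimens = read_specimen_table(path)
    assert len(specimens) == 3
    assert specimens[0].genus == "Pterostichus"
    assert specimens[0].sequences == {"COI": "p1_COI"}


def test_specimen_table_rejects_unknown_sequence_reference(tmp_path):
    path = tmp_path / "spec.tsv"
    path.write_text("specimen_id\tspecies\tCOI\nx1\tA b\tmissing_seq\n")
    with pytest.raises(ValidationError, match="missing_seq"):
        read_specimen_table(path, sequences={"COI": {}})


def _specimens_for(mapping):
    return [
        SpecimenRecord(sid, sp, sequences={"COI": f"{sid}_COI"})
        for sid, sp in mapping.items()
    ]


def test_collapse_haplotypes_partitions_by_exact_identity():
    records = [
        SequenceRecord("s1_COI", "COI", "ACGT"),
        SequenceRecord("s2_COI", "COI", "ACGT"),
        SequenceRecord("s3_COI", "COI", "ACGA"),
    ]
    specimens = _specimens_for({"s1": "A b", "s2": "C d", "s3": "A b"})
    haps = collapse_haplotypes(records, specimens)
    assert len(haps) == 2
    assert sorted(haps[0].members) == ["s1_COI", "s2_COI"]
    assert haps[0].species_counts == {"A b": 1, "C d": 1}


@given(st.lists(st.sampled_from(["ACGT", "ACGA", "TTTT", "ACGC"]),
                min_size=1, max_size=12))
@settings(max_examples=50, derandomize=True)
def test_collapse_haplotypes_preserves_multiset(seqs):
    records = [SequenceRecord(f"s{i}_COI", "COI", s) for i, s in enumerate(seqs)]
    specimens = _specimens_for({f"s{i}": "A b" for i in range(len(seqs))})
    haps = collapse_haplotypes(records, specimens)
    assert sum(len(h.members) for h in haps) == len(seqs)
    expanded = sorted(h.residues for h in haps for _ in h.members)
    assert expanded == sorted(seqs)
    assert len({h.residues for h in haps}) == len(haps)


def test_numt_screen_clean_on_sense_codons():
    seq = "".join(SENSE_CODONS * 4)
    result, = screen_numts([SequenceRecord("ok", "COI", seq)])
    assert not result.internal_stop_found
    assert result.frame_used == 0


def test_numt_screen_flags_inserted_stop():
    codons = SENSE_CODONS * 4
    codons.insert(10, "TAA")
    result, = screen_numts([SequenceRecord("bad", "COI", "".join(codons))],
                           reading_frame=0)
    assert result.internal_stop_found
    assert result.stop_positions == [10]


def test_numt_screen_auto_frame_matches_brute_force():
    """Frame auto must pick what per-frame translation enumeration picks."""
    from Bio.Seq import Seq

    seq = "G" + "".join(SENSE_CODONS * 4)  # coding in frame 1
    result, = screen_numts([SequenceRecord("f1", "COI", seq)])

    def stops(frame):
        sub = seq[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        return str(Seq(sub).translate(table=5))[:-1].count("*")

    per_frame = [stops(f) for f in range(3)]
    assert result.frame_used == per_frame.index(min(per_frame)) == 1
    assert not result.internal_stop_found


def test_numt_screen_rejects_sub_codon_sequence():
    with pytest.raises(ValidationError):
        screen_numts([SequenceRecord("tiny", "COI", "AC")])


def test_dataset_rejects_dangling_reference():
    specimens = [SpecimenRecord("s1", "A b", sequences={"COI": "nope"})]
    with pytest.raises(ValidationError):
        Dataset(specimens=specimens, sequences={"COI": {}})


def test_dataset_write_read_round_trip(tmp_path, small_dataset):
    dataset, _ = small_dataset
    dataset.write(tmp_path / "ds")
    back = Dataset.read(tmp_path / "ds")
    assert back.species_map() == dataset.species_map()
    for marker, recs in dataset.sequences.items():
        assert {r.sequence_id: r.residues for r in back.sequences[marker].values()} \
            == {r.sequence_id: r.residues for r in recs.values()}
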