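"""Species discrimination scoring, barcoding gap, unresolved-pairs table."""

import math

import numpy as np
import pytest

from barcodeval.aligner import MarkerAlignment, align_by_genus, align_coi
from barcodeval.distances import DistanceMatrix, pairwise_matrix
from barcodeval.errors import ValidationError
from barcodeval.resolution import (IDENTICAL, ResolutionCriterion,
                                   barcoding_gap, coi_resolution,
                                   combined_resolution, count_differences,
                                   deep_split_species, marker_resolution,
                                   resolved_count, table1_report)
from barcodeval.seqio import Dataset, SequenceRecord, SpecimenRecord


@pytest.mark.parametrize("a,b,mode,expected", [
    ("ACGT", "ACGT", "event", 0),
    ("AC--T", "ACGGT", "event", 1),   # one indel event spanning two columns
    ("AC--T", "ACGGT", "column", 2),
    ("ACGT", "TCGA", "event", 2),
    ("A-C-T", "AGCGT", "event", 2),   # two separate single-column gaps
    ("AC--T", "AC-GT", "event", 1),   # both-gap column does not break a run
])
def test_count_differences(a, b, mode, expected):
    assert count_differences(a, b, mode) == expected


def test_count_differences_rejects_length_mismatch():
    with pytest.raises(ValidationError):
        count_differences("AC", "ACG")


def _toy_dataset(marker_seqs: dict[str, dict[str, str]]):
    """specimen -> species from 'Genus sp' prefix of the id."""
    specimens, sequences = [], {m: {} for m in marker_seqs}
    ids = sorted({sid for seqs in marker_seqs.values() for sid in seqs})
    for sid in ids:
        refs = {}
        for m, seqs in marker_seqs.items():
            if sid in seqs:
                ref = f"{sid}_{m}"
                sequences[m][ref] = SequenceRecord(ref, m, seqs[sid])
                refs[m] = ref
        species = sid.rsplit("_", 1)[0].replace("_", " ")
        specimens.append(SpecimenRecord(sid, species, sequences=refs))
    return Dataset(specimens=specimens, sequences=sequences)


def test_marker_resolution_identity_toy():
    # S1 and S3 share a sequence; S2 differs by one base from both
    ds = _toy_dataset({"D3": {
        "G1_s1_a": "AAAAAAAAAA", "G1_s2_a": "AAAAAAAAAT", "G1_s3_a": "AAAAAAAAAA",
    }})
    alignments = align_by_genus(ds, "D3")
    res = {r.species: r for r in marker_resolution(ds, "D3", alignments)}
    assert res["G1 s2"].resolved
    assert not res["G1 s1"].resolved and not res["G1 s3"].resolved
    evidence = {c.evidence for c in res["G1 s1"].confusions
                if c.other_species == "G1 s3"}
    assert evidence == {IDENTICAL}


def test_marker_resolution_detects_cross_genus_identity():
    ds = _toy_dataset({"V4": {
        "G1_s1_a": "ACGTACGTAC", "G2_s1_a": "ACGTACGTAC", "G2_s2_a": "ACGTACGTAA",
    }})
    res = {r.species: r for r in marker_resolution(ds, "V4",
                                                   align_by_genus(ds, "V4"))}
    assert not res["G1 s1"].resolved      # identical across genera
    assert not res["G2 s1"].resolved
    assert res["G2 s2"].resolved


def test_unique_haplotypes_resolve_everything():
    ds = _toy_dataset({"D3": {
        "G1_s1_a": "AAAAAAAAAA", "G1_s2_a": "AATTAAAAAA", "G1_s3_a": "AAAACCAAAA",
    }})
    res = marker_resolution(ds, "D3", align_by_genus(ds, "D3"))
    assert resolved_count(res) == (3, 3)


def test_raising_min_differences_never_adds_resolved_species():
    ds = _toy_dataset({"D3": {
        "G1_s1_a": "AAAAAAAAAA", "G1_s2_a": "AAAAAAAAAT", "G1_s3_a": "AAAATTTAAA",
    }})
    alignments = align_by_genus(ds, "D3")
    counts = []
    for md in (1, 2, 3, 4):
        res = marker_resolution(ds, "D3", alignments,
                                ResolutionCriterion(min_differences=md))
        counts.append(resolved_count(res)[0])
    assert counts == sorted(counts, reverse=True)


def test_combined_resolution_sums_differences_across_markers(small_dataset):
    dataset, truth = small_dataset
    alignments = {m: align_by_genus(dataset, m) for m in ("D3", "V4", "V7")}
    combined = combined_resolution(dataset, alignments)
    unresolved = sorted(r.species for r in combined if not r.resolved)
    assert unresolved == truth.unresolved["combined"]


def test_combined_is_monotone_over_single_markers(small_dataset):
    dataset, _ = small_dataset
    alignments = {m: align_by_genus(dataset, m) for m in ("D3", "V4", "V7")}
    combined_ok = {r.species for r in combined_resolution(dataset, alignments)
                   if r.resolved}
    for m in ("D3", "V4", "V7"):
        single_ok = {r.species
                     for r in marker_resolution(dataset, m, alignments[m])
                     if r.resolved}
        assert single_ok <= combined_ok


def test_coi_resolution_on_designed_five_species():
    # species 1 and 2 share a haplotype; 3, 4, 5 unique -> 3 of 5 resolved
    base = "ACGTACGTACGTACGTACGT"
    ds = _toy_dataset({"COI": {
        "G1_s1_a": base, "G1_s1_b": base,
        "G1_s2_a": base,
        "G1_s3_a": base[:-1] + "A",
        "G2_s4_a": "TTTTACGTACGTACGTACGT",
        "G2_s5_a": "ACGTACGTACGTACGTCCCC",
    }})
    aln = align_coi([(s.specimen_id, ds.residues(s.specimen_id, "COI"))
                     for s in ds.specimens])
    res = coi_resolution(ds, aln)
    resolved = {r.species for r in res if r.resolved}
    assert resolved == {"G1 s3", "G2 s4", "G2 s5"}


def test_deep_split_species_is_resolved_but_flagged(small_dataset):
    dataset, truth = small_dataset
    aln = align_coi([(s.specimen_id, dataset.residues(s.specimen_id, "COI"))
                     for s in dataset.specimens])
    res = {r.species: r for r in coi_resolution(dataset, aln)}
    deep = truth.deep_split_species
    assert res[deep].resolved
    mat = pairwise_matrix(aln, "k2p")
    assert deep in deep_split_species(mat, dataset.species_map(), 0.02)


def test_barcoding_gap_designed_margins():
    rows = [("a1", "A" * 100), ("a2", "A" * 99 + "T"),
            ("b1", "G" * 5 + "A" * 95), ("b2", "G" * 5 + "A" * 94 + "T")]
    mat = pairwise_matrix(
        MarkerAlignment(marker="COI", scope="global", rows=rows), "p")
    species = {"a1": "X", "a2": "X", "b1": "Y", "b2": "Y"}
    report = barcoding_gap(mat, species)
    per = report.per_species.set_index("species")
    assert (per["gap"] > 0).all()
    assert not report.overlap
    assert per.loc["X", "nearest_neighbor"] == "Y"


def test_barcoding_gap_singleton_species_undefined():
    rows = [("a1", "AAAA"), ("b1", "AATT"), ("b2", "AATT")]
    mat = pairwise_matrix(
        MarkerAlignment(marker="COI", scope="global", rows=rows), "p")
    report = barcoding_gap(mat, {"a1": "X", "b1": "Y", "b2": "Y"})
    per = report.per_species.set_index("species")
    assert math.isnan(per.loc["X", "max_intraspecific"])
    assert math.isnan(per.loc["X", "gap"])


def test_barcoding_gap_overlap_flag_on_deep_split():
    # intra spread 0.05 in X exceeds min inter 0.03
    rows = [("a1", "A" * 100), ("a2", "T" * 5 + "A" * 95),
            ("b1", "G" * 3 + "A" * 97)]
    mat = pairwise_matrix(
        MarkerAlignment(marker="COI", scope="global", rows=rows), "p")
    report = barcoding_gap(mat, {"a1": "X", "a2": "X", "b1": "Y"})
    assert report.overlap


def _full_reports(dataset):
    alignments = {m: align_by_genus(dataset, m) for m in ("D3", "V4", "V7")}
    aln = align_coi([(s.specimen_id, dataset.residues(s.specimen_id, "COI"))
                     for s in dataset.specimens])
    coi_mat = pairwise_matrix(aln, "k2p")
    rdna_res = {m: marker_resolution(dataset, m, alignments[m])
                for m in alignments}
    combined = combined_resolution(dataset, alignments)
    coi_res = coi_resolution(dataset, aln)
    table = table1_report(dataset, coi_mat, alignments, coi_res, rdna_res,
                          combined)
    return table, rdna_res, combined, coi_res


def test_table1_rows_are_exactly_the_failing_pairs(small_dataset):
    dataset, truth = small_dataset
    table, rdna_res, combined, coi_res = _full_reports(dataset)
    failing = set()
    for rs in (*rdna_res.values(), combined, coi_res):
        for r in rs:
            for c in r.confusions:
                if c.n_differences < 1:
                    failing.add(tuple(sorted((r.species, c.other_species))))
    assert len(table) == len(failing)
    assert set(table["species_pair"]) == {f"{a} / {b}" for a, b in failing}
    # the all-marker-identical sibling pair shows identical cells throughout
    shared = " / ".join(sorted(truth.shared_haplotype_pair))
    row = table[table["species_pair"] == shared].iloc[0]
    assert all(row[m] == IDENTICAL for m in ("D3", "V4", "V7", "combined", "COI"))


def test_table1_empty_on_fully_resolved_dataset():
    ds = _toy_dataset({
        "COI": {"G1_s1_a": "ACGTACGTAC", "G1_s2_a": "ACGTACGTTT"},
        "D3": {"G1_s1_a": "AAAAAAAAAA", "G1_s2_a": "AAAATTAAAA"},
        "V4": {"G1_s1_a": "CCCCCCCCCC", "G1_s2_a": "CCCCTTCCCC"},
        "V7": {"G1_s1_a": "GGGGGGGGGG", "G1_s2_a": "GGGGTTGGGG"},
    })
    table, *_ = _full_reports(ds)
    assert table.empty
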