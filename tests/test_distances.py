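"""Site-class counting, p and K2P distances, matrices and summaries."""

import math
from decimal import Decimal, getcontext

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodeval.aligner import MarkerAlignment
from barcodeval.distances import (SiteCounts, at_content, count_site_classes,
                                  k2p_distance, p_distance, pairwise_matrix,
                                  summarize_divergences)
from barcodeval.errors import DistanceError


def k2p_oracle(ts: int, tv: int, n: int) -> float:
    """High-precision evaluation of -1/2 ln((1-2P-Q) sqrt(1-2Q))."""
    getcontext().prec = 50
    P = Decimal(ts) / Decimal(n)
    Q = Decimal(tv) / Decimal(n)
    arg = (1 - 2 * P - Q) * (1 - 2 * Q).sqrt()
    return float(-arg.ln() / 2)


@pytest.mark.parametrize("a,b,n,ts,tv,excl", [
    ("ACGT", "ACGT", 4, 0, 0, 0),
    ("ACGT", "AGGT", 4, 0, 1, 0),   # C<->G crosses purine/pyrimidine classes
    ("AC-T", "ACGT", 3, 0, 0, 1),
    ("ACGT", "GCGT", 4, 1, 0, 0),   # A<->G within purines
    ("ACNT", "ACGT", 3, 0, 0, 1),   # ambiguity excluded pairwise
])
def test_site_class_counting(a, b, n, ts, tv, excl):
    c = count_site_classes(a, b)
    assert (c.compared_sites, c.transitions, c.transversions,
            c.excluded_sites) == (n, ts, tv, excl)


def test_site_class_counting_rejects_length_mismatch():
    with pytest.raises(DistanceError):
        count_site_classes("ACG", "AC")


def test_p_distance_values():
    assert p_distance(SiteCounts(8, 1, 0, 0)) == 0.125
    assert p_distance(SiteCounts(4, 0, 0, 0)) == 0.0
    assert math.isnan(p_distance(SiteCounts(0, 0, 0, 4)))


def test_k2p_matches_high_precision_closed_form():
    # P = 0.1, Q = 0.05 over 100 sites
    d = k2p_distance(SiteCounts(100, 10, 5, 0))
    assert d == pytest.approx(k2p_oracle(10, 5, 100), abs=1e-12)
    assert d == pytest.approx(0.1701811651, abs=1e-9)


def test_k2p_boundaries():
    assert k2p_distance(SiteCounts(10, 0, 0, 0)) == 0.0
    assert math.isnan(k2p_distance(SiteCounts(10, 5, 0, 0)))  # 1-2P-Q = 0
    assert math.isnan(k2p_distance(SiteCounts(0, 0, 0, 0)))


@given(st.integers(1, 400), st.integers(0, 400), st.integers(0, 400))
@settings(max_examples=300, derandomize=True)
def test_k2p_at_least_p_on_valid_domain(n, ts, tv):
    if ts + tv > n:
        return
    c = SiteCounts(n, ts, tv, 0)
    k2p, p = k2p_distance(c), p_distance(c)
    if not math.isnan(k2p):
        assert k2p >= p - 1e-15
        if ts + tv == 0:
            assert k2p == 0.0
        else:
            assert k2p > p  # log correction is strict off zero


def _aln(rows):
    return MarkerAlignment(marker="COI", scope="global", rows=rows)


def test_pairwise_matrix_values_and_symmetry():
    aln = _aln([("a", "ACGT"), ("b", "ACGA"), ("c", "ACGT")])
    mat = pairwise_matrix(aln, "p")
    assert mat.labels == ["a", "b", "c"]
    assert mat.values[0, 1] == pytest.approx(0.25)
    assert mat.values[0, 2] == 0.0
    assert np.allclose(mat.values, mat.values.T)
    assert np.all(np.diag(mat.values) == 0.0)


def test_pairwise_matrix_invariant_under_row_reordering():
    rows = [("a", "ACGTACGT"), ("b", "ACTTACGA"), ("c", "GCGTACGT")]
    m1 = pairwise_matrix(_aln(rows), "k2p")
    m2 = pairwise_matrix(_aln(rows[::-1]), "k2p")
    for i, li in enumerate(m1.labels):
        for j, lj in enumerate(m1.labels):
            assert m1.values[i, j] == pytest.approx(m2.get(li, lj))


def test_pairwise_matrix_dense_and_loop_paths_agree():
    rng = np.random.default_rng(0)
    rows = [(f"s{i}", "".join(rng.choice(list("ACGT"), 60))) for i in range(6)]
    clean = pairwise_matrix(_aln(rows), "k2p")
    # appending an ambiguous-base row forces the per-pair loop path
    dirty_rows = rows + [("amb", rows[0][1][:-1] + "N")]
    dirty = pairwise_matrix(_aln(dirty_rows), "k2p")
    assert np.allclose(clean.values, dirty.values[:6, :6], equal_nan=True)


def test_estimated_rates_converge_to_generating_process():
    """P-hat and Q-hat approach the per-site generating probabilities
    (within 3 SE) as sequences grow."""
    rng = np.random.default_rng(42)
    L, p_ts, p_tv = 40000, 0.08, 0.04
    pairs = {"A": ("G", "C"), "G": ("A", "C"), "C": ("T", "A"), "T": ("C", "A")}
    a = rng.choice(list("ACGT"), L)
    b = a.copy()
    u = rng.random(L)
    for i in range(L):
        if u[i] < p_ts:
            b[i] = pairs[a[i]][0]
        elif u[i] < p_ts + p_tv:
            b[i] = pairs[a[i]][1]
    c = count_site_classes("".join(a), "".join(b))
    se_ts = math.sqrt(p_ts * (1 - p_ts) / L)
    se_tv = math.sqrt(p_tv * (1 - p_tv) / L)
    assert abs(c.transitions / L - p_ts) < 3 * se_ts
    assert abs(c.transversions / L - p_tv) < 3 * se_tv


def test_summarize_divergences_groups_and_species_level():
    rows = [("a1", "AAAA"), ("a2", "AAAA"), ("b1", "AAAT"), ("b2", "AAAT")]
    species = {"a1": "X", "a2": "X", "b1": "Y", "b2": "Y"}
    out = summarize_divergences(pairwise_matrix(_aln(rows), "p"), species,
                                level="species")
    assert out["intraspecific"].mean == 0.0
    assert out["interspecific"].mean == pytest.approx(0.25)
    assert out["interspecific"].n_pairs == 4
    stats = out["species-level"]
    assert stats.max_intraspecific == {"X": 0.0, "Y": 0.0}
    assert stats.pair_ranges[("X", "Y")] == (0.25, 0.25)


def test_summarize_divergences_singleton_species_reported_absent():
    rows = [("a1", "AAAA"), ("b1", "AAAT")]
    out = summarize_divergences(pairwise_matrix(_aln(rows), "p"),
                                {"a1": "X", "b1": "Y"})
    assert "intraspecific" not in out
    assert out["interspecific"].n_pairs == 1


def test_histogram_counts_cross_foot():
    rng = np.random.default_rng(1)
    rows = [(f"s{i}", "".join(rng.choice(list("ACGT"), 50))) for i in range(8)]
    species = {f"s{i}": f"sp{i % 3}" for i in range(8)}
    out = summarize_divergences(pairwise_matrix(_aln(rows), "p"), species)
    for summary in out.values():
        assert summary.histogram_counts.sum() == summary.n_pairs


@pytest.mark.parametrize("seqs,expected", [
    (["AATT"], 1.0),
    (["ACGT"], 0.5),
    (["AAAA", "CCCC"], 0.5),      # mean of per-sequence fractions
    (["AANN"], 1.0),              # ambiguity excluded from both sides
])
def test_at_content(seqs, expected):
    assert at_content(seqs) == pytest.approx(expected)
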