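"""Deterministic internal alignment: affine-gap pairwise and progressive MSA.

The rDNA expansion segments are aligned per genus, independently of all
other taxa, because indel-rich expansion segments cannot be homologised
reliably across distant genera; COI is length-uniform and is stacked
without alignment when input lengths agree.

The pairwise engine is a Gotoh affine-gap global aligner (gap of length g
costs open + g*extend) with a fixed tie-break: match/mismatch preferred
over gaps, then gap-in-first-sequence over gap-in-second.  Groups are
aligned progressively along a neighbor-joining guide tree built from
pairwise-alignment p-distances, merging alignments as frequency profiles.
Ambiguity codes score zero against everything.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .distances import count_site_classes, p_distance
from .errors import AlignmentError
from .seqio import GAP, NUCLEAR_MARKERS, Dataset, SequenceRecord
from .trees import nj_join_order

logger = logging.getLogger(__name__)

_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_NEG_INF = -1e30


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap scoring; defaults suit low-divergence rDNA segments."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 4.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0.0:
            raise AlignmentError("require gap_open >= gap_extend >= 0")


DEFAULT_PARAMS = AlignmentParams()


@dataclass
class MarkerAlignment:
    """Equal-length aligned rows for one marker within one scope."""

    marker: str
    scope: str
    rows: list[tuple[str, str]]
    offsets: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        lengths = {len(r) for _, r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(
                f"{self.marker}/{self.scope}: unequal row lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def row(self, row_id: str) -> str:
        for rid, residues in self.rows:
            if rid == row_id:
                return residues
        raise KeyError(row_id)

    def degapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")


# ---------------------------------------------------------------------------
# Profiles and the Gotoh engine
# ---------------------------------------------------------------------------

def _profile(rows: Sequence[str]) -> np.ndarray:
    """(L, 4) base-frequency profile; gaps/ambiguity contribute nothing."""
    L = len(rows[0])
    prof = np.zeros((L, 4))
    for row in rows:
        for i, ch in enumerate(row):
            k = _IDX.get(ch)
            if k is not None:
                prof[i, k] += 1.0
    return prof / len(rows)


def _column_scores(p1: np.ndarray, p2: np.ndarray, params: AlignmentParams):
    W = np.full((4, 4), params.mismatch)
    np.fill_diagonal(W, params.match)
    return p1 @ W @ p2.T


def _gotoh(S: np.ndarray, params: AlignmentParams):
    """Affine-gap DP over a column-score matrix; returns (score, ops).

    ops is a list over alignment columns: 'D' consumes one column of both
    inputs, 'E' a gap in the first input, 'F' a gap in the second.
    """
    L1, L2 = S.shape
    go = params.gap_open + params.gap_extend  # cost of a gap's first column
    ge = params.gap_extend
    M = np.full((L1 + 1, L2 + 1), _NEG_INF)
    E = np.full((L1 + 1, L2 + 1), _NEG_INF)
    F = np.full((L1 + 1, L2 + 1), _NEG_INF)
    M[0, 0] = 0.0
    j_idx = np.arange(L2 + 1)

    for i in range(L1 + 1):
        if i > 0:
            Hprev = np.maximum(np.maximum(M[i - 1], E[i - 1]), F[i - 1])
            M[i, 1:] = S[i - 1, :] + Hprev[:-1]
            M[i, 0] = _NEG_INF
            F[i, :] = np.maximum(M[i - 1, :] - go, F[i - 1, :] - ge)
        # E closed over the row: a gap in the first input starting after
        # column k costs go + ge*(j-k-1), so
        #   E[i][j] = max_{k<j} M[i][k] - go - ge*(j-1-k)
        # which a running maximum of M[i][k] + ge*k evaluates in one pass.
        C = np.maximum.accumulate(M[i, :] + ge * j_idx)
        E[i, 1:] = C[:-1] - go - ge * (j_idx[1:] - 1)
        E[i, 0] = _NEG_INF

    # Traceback with fixed preference M > E > F.
    i, j = L1, L2
    vals = (M[i, j], E[i, j], F[i, j])
    score = max(vals)
    state = 0 if vals[0] == score else (1 if vals[1] == score else 2)
    ops: list[str] = []
    while (i, j) != (0, 0):
        if state == 0:  # M
            ops.append("D")
            m, e, f = M[i - 1, j - 1], E[i - 1, j - 1], F[i - 1, j - 1]
            mx = max(m, e, f)
            state = 0 if m == mx else (1 if e == mx else 2)
            i, j = i - 1, j - 1
        elif state == 1:  # E: gap in first input
            ops.append("E")
            from_m = M[i, j - 1] - go
            from_e = E[i, j - 1] - ge
            state = 0 if from_m >= from_e else 1
            j -= 1
        else:  # F: gap in second input
            ops.append("F")
            from_m = M[i - 1, j] - go
            from_f = F[i - 1, j] - ge
            state = 0 if from_m >= from_f else 2
            i -= 1
    ops.reverse()
    return float(score), ops


def _apply_ops(rows: Sequence[str], ops: Sequence[str], gap_op: str) -> list[str]:
    """Insert gap columns into rows wherever ops shows gap_op."""
    out = []
    for row in rows:
        chars = []
        it = iter(row)
        for op in ops:
            chars.append(GAP if op == gap_op else next(it))
        out.append("".join(chars))
    return out


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def pairwise_align(
    a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS
) -> tuple[str, str, float]:
    """Optimal global alignment of two gap-free sequences."""
    if not a or not b:
        raise AlignmentError("pairwise_align: empty sequence")
    if GAP in a or GAP in b:
        raise AlignmentError("pairwise_align: inputs must be gap-free")
    S = _column_scores(_profile([a]), _profile([b]), params)
    score, ops = _gotoh(S, params)
    aligned_a = _apply_ops([a], ops, "E")[0]
    aligned_b = _apply_ops([b], ops, "F")[0]
    return aligned_a, aligned_b, score


def alignment_score(aligned_a: str, aligned_b: str, params: AlignmentParams) -> float:
    """Recompute the affine score of an aligned pair from its columns."""
    score = 0.0
    for row_self, row_other in ((aligned_a, aligned_b), (aligned_b, aligned_a)):
        in_gap = False
        for ch in row_self:
            if ch == GAP:
                score -= params.gap_extend + (0.0 if in_gap else params.gap_open)
                in_gap = True
            else:
                in_gap = False
    for x, y in zip(aligned_a, aligned_b):
        if x != GAP and y != GAP:
            if x in _IDX and y in _IDX:
                score += params.match if x == y else params.mismatch
    return score


def _normalise(records: Iterable) -> list[tuple[str, str, bool, str | None]]:
    """(id, residues, is_aligned, marker) from records or (id, seq) pairs."""
    out = []
    for rec in records:
        if isinstance(rec, SequenceRecord):
            out.append((rec.sequence_id, rec.residues, rec.is_aligned, rec.marker))
        else:
            rid, residues = rec
            out.append((rid, residues, GAP in residues, None))
    return out


def align_group(
    records: Iterable,
    params: AlignmentParams = DEFAULT_PARAMS,
    marker: str = "",
    scope: str = "global",
) -> MarkerAlignment:
    """Progressively align a group of sequences of one marker.

    Pre-aligned inputs (rows containing gaps) pass through after length
    validation.  Output row order equals input order; degapping any row
    recovers its input sequence exactly.
    """
    items = _normalise(records)
    if not items:
        raise AlignmentError("align_group: no sequences")
    markers = {m for *_, m in items if m is not None}
    if len(markers) > 1:
        raise AlignmentError(f"align_group: mixed markers {sorted(markers)}")
    if not marker and markers:
        marker = next(iter(markers))

    if any(aligned for _, _, aligned, _ in items):
        if not all(aligned or GAP not in res for _, res, aligned, _ in items):
            raise AlignmentError("align_group: mixed aligned and unaligned input")
        return MarkerAlignment(
            marker=marker, scope=scope, rows=[(rid, res) for rid, res, _, _ in items]
        )

    ids = [rid for rid, _, _, _ in items]
    seqs = [res for _, res, _, _ in items]
    for rid, s in zip(ids, seqs):
        if not s:
            raise AlignmentError(f"align_group: empty sequence {rid!r}")
    n = len(seqs)
    if n == 1:
        return MarkerAlignment(marker=marker, scope=scope, rows=[(ids[0], seqs[0])])

    # Collapse duplicate sequences; align unique ones only.
    uniq: dict[str, int] = {}
    for s in seqs:
        uniq.setdefault(s, len(uniq))
    useqs = list(uniq)
    if len(useqs) == 1:
        return MarkerAlignment(marker=marker, scope=scope, rows=list(zip(ids, seqs)))

    k = len(useqs)
    D = np.zeros((k, k))
    pair_cache: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            aa, bb, _ = pairwise_align(useqs[i], useqs[j], params)
            d = p_distance(count_site_classes(aa, bb))
            if np.isnan(d):
                d = 0.75
            D[i, j] = D[j, i] = d
            pair_cache[(i, j)] = d

    # node id -> (unique indices, aligned rows)
    state: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [useqs[i]]) for i in range(k)
    }
    for a, b, new in nj_join_order(D):
        idx_a, rows_a = state.pop(a)
        idx_b, rows_b = state.pop(b)
        S = _column_scores(_profile(rows_a), _profile(rows_b), params)
        _, ops = _gotoh(S, params)
        rows_a = _apply_ops(rows_a, ops, "E")
        rows_b = _apply_ops(rows_b, ops, "F")
        state[new] = (idx_a + idx_b, rows_a + rows_b)

    (indices, aligned) = next(iter(state.values()))
    by_unique = {u: row for u, row in zip(indices, aligned)}
    rows = [(rid, by_unique[uniq[s]]) for rid, s in zip(ids, seqs)]
    return MarkerAlignment(marker=marker, scope=scope, rows=rows)


def align_coi(
    records: Iterable, params: AlignmentParams = DEFAULT_PARAMS
) -> MarkerAlignment:
    """Global COI alignment: stacked as-is when lengths are uniform."""
    items = _normalise(records)
    lengths = {len(res.replace(GAP, "")) for _, res, _, _ in items}
    if len(lengths) == 1 and not any(al for _, _, al, _ in items):
        return MarkerAlignment(
            marker="COI", scope="global",
            rows=[(rid, res) for rid, res, _, _ in items],
        )
    if len(lengths) > 1 and not any(al for _, _, al, _ in items):
        logger.warning("COI lengths not uniform (%s); aligning globally", sorted(lengths))
    return align_group(records, params, marker="COI", scope="global")


def partition_by_genus(dataset: Dataset, marker: str) -> dict[str, list[tuple[str, str]]]:
    """Group a marker's sequences by genus: genus → [(specimen_id, residues)]."""
    out: dict[str, list[tuple[str, str]]] = {}
    for specimen, rec in dataset.marker_records(marker):
        out.setdefault(specimen.genus, []).append(
            (specimen.specimen_id, rec.degapped())
        )
    return out


def align_by_genus(
    dataset: Dataset, marker: str, params: AlignmentParams = DEFAULT_PARAMS
) -> dict[str, MarkerAlignment]:
    """Per-genus alignments of one rDNA marker (rows keyed by specimen id)."""
    return {
        genus: align_group(pairs, params, marker=marker, scope=genus)
        for genus, pairs in partition_by_genus(dataset, marker).items()
    }


def concatenate_nuclear(
    alignments: dict[str, MarkerAlignment],
    order: Sequence[str] = NUCLEAR_MARKERS,
) -> MarkerAlignment:
    """Column-wise concatenation of the nuclear markers in fixed order."""
    missing_markers = [m for m in order if m not in alignments]
    if missing_markers:
        raise AlignmentError(f"concatenate_nuclear: missing markers {missing_markers}")
    first = alignments[order[0]]
    row_ids = [rid for rid, _ in first.rows]
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    for m in order:
        offsets[m] = (pos, pos + alignments[m].length)
        pos += alignments[m].length
    rows = []
    for rid in row_ids:
        parts = []
        for m in order:
            try:
                parts.append(alignments[m].row(rid))
            except KeyError:
                raise AlignmentError(
                    f"concatenate_nuclear: specimen {rid!r} missing marker {m!r}"
                ) from None
        rows.append((rid, "".join(parts)))
    scope = first.scope
    return MarkerAlignment(
        marker="+".join(order), scope=scope, rows=rows, offsets=offsets
    )
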