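"""Pairwise sequence divergence: site-class counting, p- and K2P distances.

The Kimura 2-parameter distance corrects the observed proportions of
transitions (P, the A<->G and C<->T changes) and transversions (Q, all other
changes) for multiple hits:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Columns holding a gap or an ambiguity code in either row of a pair are
excluded for that pair only (pairwise deletion).  Saturated pairs, where the
formula's logarithm argument is non-positive, are flagged undefined (NaN)
rather than imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DistanceError

logger = logging.getLogger(__name__)

# Base encoding: purines even, pyrimidines odd, so a substitution is a
# transition exactly when the two codes share parity.
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_EXCLUDED = 255


def encode_rows(rows: list[str]) -> np.ndarray:
    """Encode aligned rows as a (n, L) uint8 array; gaps/ambiguity -> 255."""
    lut = np.full(256, _EXCLUDED, dtype=np.uint8)
    for base, code in _CODE.items():
        lut[ord(base)] = code
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8)
    return lut[arr].reshape(len(rows), -1)


@dataclass
class SiteCounts:
    """Per-pair site classification under pairwise deletion."""

    compared_sites: int
    transitions: int
    transversions: int
    excluded_sites: int

    def __post_init__(self) -> None:
        if self.transitions + self.transversions > self.compared_sites:
            raise DistanceError("more substitutions than compared sites")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix; undefined entries are NaN."""

    labels: list[str]
    values: np.ndarray
    metric: str
    deletion_policy: str = "pairwise"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DistanceError("matrix shape does not match labels")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    @property
    def n_undefined(self) -> int:
        iu = np.triu_indices(len(self.labels), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            labels=list(labels),
            values=self.values[np.ix_(idx, idx)].copy(),
            metric=self.metric,
            deletion_policy=self.deletion_policy,
        )


@dataclass
class DivergenceSummary:
    """Min/max/mean and histogram of one group of pairwise distances."""

    grouping: str
    n_pairs: int
    minimum: float
    maximum: float
    mean: float
    histogram_edges: np.ndarray
    histogram_counts: np.ndarray
    n_undefined: int = 0
    composition_at: float | None = None


def count_site_classes(row_a: str, row_b: str) -> SiteCounts:
    """Classify the columns of one aligned pair of rows."""
    if len(row_a) != len(row_b):
        raise DistanceError(
            f"row length mismatch: {len(row_a)} vs {len(row_b)}"
        )
    enc = encode_rows([row_a, row_b])
    x, y = enc[0], enc[1]
    valid = (x != _EXCLUDED) & (y != _EXCLUDED)
    diff = valid & (x != y)
    ts = diff & ((x & 1) == (y & 1))
    n_valid = int(valid.sum())
    return SiteCounts(
        compared_sites=n_valid,
        transitions=int(ts.sum()),
        transversions=int(diff.sum()) - int(ts.sum()),
        excluded_sites=len(row_a) - n_valid,
    )


def p_distance(c: SiteCounts) -> float:
    """Uncorrected proportion of differing compared sites (NaN if n=0)."""
    if c.compared_sites == 0:
        return math.nan
    return (c.transitions + c.transversions) / c.compared_sites


def k2p_distance(c: SiteCounts) -> float:
    """Kimura 2-parameter distance; NaN (with a log note) on saturation."""
    if c.compared_sites == 0:
        return math.nan
    p = c.transitions / c.compared_sites
    q = c.transversions / c.compared_sites
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        logger.warning(
            "K2P undefined (saturation): P=%.4f Q=%.4f over %d sites",
            p, q, c.compared_sites,
        )
        return math.nan
    return -0.5 * math.log(w1 * math.sqrt(w2))


def _pair_counts_dense(enc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs (transitions, transversions, compared) via one-hot matmuls.

    Valid only when no column of any row is excluded (the common COI case);
    the caller falls back to the per-pair loop otherwise.
    """
    n, L = enc.shape
    onehot = np.zeros((4, n, L), dtype=np.float32)
    for c in range(4):
        onehot[c] = enc == c
    counts = np.zeros((4, 4, n, n), dtype=np.float32)
    for a in range(4):
        for b in range(4):
            counts[a, b] = onehot[a] @ onehot[b].T
    ts = counts[0, 2] + counts[2, 0] + counts[1, 3] + counts[3, 1]
    diff_total = np.zeros((n, n), dtype=np.float32)
    for a in range(4):
        for b in range(4):
            if a != b:
                diff_total += counts[a, b]
    compared = np.full((n, n), float(L), dtype=np.float32)
    return ts, diff_total - ts, compared


def _pair_counts_loop(enc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = enc.shape[0]
    ts = np.zeros((n, n))
    tv = np.zeros((n, n))
    compared = np.zeros((n, n))
    valid_rows = enc != _EXCLUDED
    for i in range(n):
        xi, vi = enc[i], valid_rows[i]
        for j in range(i + 1, n):
            valid = vi & valid_rows[j]
            diff = valid & (xi != enc[j])
            t = diff & ((xi & 1) == (enc[j] & 1))
            nts, ndiff = int(t.sum()), int(diff.sum())
            ts[i, j] = ts[j, i] = nts
            tv[i, j] = tv[j, i] = ndiff - nts
            compared[i, j] = compared[j, i] = int(valid.sum())
    return ts, tv, compared


def pairwise_matrix(alignment, metric: str) -> DistanceMatrix:
    """Compute all pairwise distances over a :class:`MarkerAlignment`.

    ``metric`` is ``"p"`` or ``"k2p"``.  Row order is preserved as the label
    order of the matrix.
    """
    rows = alignment.rows
    if len(rows) < 2:
        raise DistanceError("pairwise_matrix needs at least 2 rows")
    if metric not in ("p", "k2p"):
        raise DistanceError(f"unknown metric {metric!r}")
    labels = [rid for rid, _ in rows]
    enc = encode_rows([r for _, r in rows])
    if (enc == _EXCLUDED).any():
        ts, tv, compared = _pair_counts_loop(enc)
    else:
        ts, tv, compared = _pair_counts_dense(enc)
    ts = ts.astype(np.float64)
    tv = tv.astype(np.float64)
    compared = compared.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        if metric == "p":
            values = np.where(compared > 0, (ts + tv) / compared, np.nan)
        else:
            P = ts / compared
            Q = tv / compared
            w = (1.0 - 2.0 * P - Q) * np.sqrt(1.0 - 2.0 * Q)
            values = np.where((compared > 0) & (w > 0), -0.5 * np.log(w), np.nan)
    np.fill_diagonal(values, 0.0)
    mat = DistanceMatrix(labels=labels, values=values, metric=metric)
    if mat.n_undefined:
        logger.warning("%d undefined %s distances", mat.n_undefined, metric)
    return mat


def _summary(values: np.ndarray, grouping: str, bin_width: float) -> DivergenceSummary:
    defined = values[~np.isnan(values)]
    n_undef = values.size - defined.size
    if defined.size == 0:
        return DivergenceSummary(
            grouping=grouping, n_pairs=0, minimum=math.nan, maximum=math.nan,
            mean=math.nan, histogram_edges=np.array([]),
            histogram_counts=np.array([], dtype=int), n_undefined=n_undef,
        )
    top = max(float(defined.max()), bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(defined, bins=edges)
    return DivergenceSummary(
        grouping=grouping,
        n_pairs=int(defined.size),
        minimum=float(defined.min()),
        maximum=float(defined.max()),
        mean=float(defined.mean()),
        histogram_edges=edges,
        histogram_counts=counts,
        n_undefined=n_undef,
    )


@dataclass
class SpeciesLevelStats:
    """Per-species and per-species-pair distance ranges."""

    max_intraspecific: dict[str, float]
    pair_ranges: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )


def summarize_divergences(
    matrix: DistanceMatrix,
    species_map: dict[str, str],
    level: str = "all-pairs",
    bin_width: float = 0.005,
) -> dict[str, DivergenceSummary | SpeciesLevelStats]:
    """Summarise intra- vs interspecific distance distributions.

    Intraspecific pairs are conspecific specimen pairs; singleton species
    contribute none and are reported as absent from the per-species stats.
    With ``level="species"`` the result also carries per-species maximum
    intraspecific distances and per-species-pair min/max ranges.
    """
    labels = matrix.labels
    species = [species_map[l] for l in labels]
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    same = np.array([species[i] == species[j] for i, j in zip(iu, ju)])
    vals = matrix.values[iu, ju]

    out: dict[str, DivergenceSummary | SpeciesLevelStats] = {}
    intra = vals[same]
    inter = vals[~same]
    if intra.size:
        out["intraspecific"] = _summary(intra, "intraspecific", bin_width)
    if inter.size:
        out["interspecific"] = _summary(inter, "interspecific", bin_width)

    if level == "species":
        max_intra: dict[str, float] = {}
        pair_ranges: dict[tuple[str, str], tuple[float, float]] = {}
        for v, i, j in zip(vals, iu, ju):
            if math.isnan(v):
                continue
            a, b = species[i], species[j]
            if a == b:
                max_intra[a] = max(max_intra.get(a, 0.0), float(v))
            else:
                key = tuple(sorted((a, b)))
                lo, hi = pair_ranges.get(key, (math.inf, -math.inf))
                pair_ranges[key] = (min(lo, float(v)), max(hi, float(v)))
        out["species-level"] = SpeciesLevelStats(
            max_intraspecific=max_intra, pair_ranges=pair_ranges
        )
    return out


def at_content(records) -> float:
    """Mean per-sequence A+T fraction; gaps and ambiguity codes excluded."""
    fractions = []
    for rec in records:
        residues = rec if isinstance(rec, str) else rec.residues
        counts = {b: residues.count(b) for b in "ACGT"}
        total = sum(counts.values())
        if total:
            fractions.append((counts["A"] + counts["T"]) / total)
    if not fractions:
        return math.nan
    return float(np.mean(fractions))
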