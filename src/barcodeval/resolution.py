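"""Species-discrimination scoring and barcoding-gap analysis.

Two criteria operate side by side:

* rDNA markers resolve a species pair when the sequences differ by at least
  one base change — substitution, insertion or deletion — where a contiguous
  indel run counts as one event by default.  Identity is checked by exact
  string matching across the whole dataset (catching cross-genus identical
  sequences), difference counts come from the within-genus alignments.
* COI resolves a species when every heterospecific specimen differs from
  every conspecific specimen by at least ``min_differences`` substitutions
  (specimen-level diagnosability).  A species with a deep intraspecific
  split still counts as resolved; such species are flagged separately by a
  configurable distance threshold (default 2%).

Combined nuclear resolution sums difference counts across D3+V4+V7 per
specimen pair, so a pair fails the combined criterion only when it is
identical at every nuclear marker.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aligner as _aligner
from .distances import DistanceMatrix, count_site_classes, p_distance
from .errors import ValidationError
from .seqio import GAP, NUCLEAR_MARKERS, Dataset

logger = logging.getLogger(__name__)

IDENTICAL = "identical sequences"


@dataclass(frozen=True)
class ResolutionCriterion:
    marker_class: str = "rDNA"  # "rDNA" | "COI" | "combined"
    min_differences: int = 1
    indel_counting: str = "event"  # "event" | "column"
    comparison_scope: str = "aligned-within-scope"  # or "global-exact"

    def __post_init__(self) -> None:
        if self.min_differences < 1:
            raise ValidationError("min_differences must be >= 1")


@dataclass
class Confusion:
    other_species: str
    evidence: str  # IDENTICAL or "differences"
    n_differences: int
    distance: float


@dataclass
class SpeciesResolution:
    species: str
    marker: str
    resolved: bool
    confusions: list[Confusion] = field(default_factory=list)


@dataclass
class BarcodingGapReport:
    per_species: pd.DataFrame  # species, max_intra, min_inter, nearest, gap
    dataset_min_interspecific: float
    overlap: bool


def count_differences(a: str, b: str, indel_counting: str = "event") -> int:
    """Count base changes between two aligned rows.

    Substitutions are counted per column; a maximal run of gap columns in
    one row counts as one event (``"event"``) or per column (``"column"``).
    Columns gapped in both rows are skipped without interrupting a run.
    """
    if len(a) != len(b):
        raise ValidationError(f"length mismatch: {len(a)} vs {len(b)}")
    total = 0
    gap_state = None  # which row is currently inside a gap run
    for x, y in zip(a, b):
        if x == GAP and y == GAP:
            continue
        if x == GAP or y == GAP:
            side = "a" if x == GAP else "b"
            if indel_counting == "column" or side != gap_state:
                total += 1
            gap_state = side
        else:
            gap_state = None
            if x != y:
                total += 1
    return total


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _species_specimens(dataset: Dataset, marker: str) -> dict[str, list[str]]:
    """species → specimen ids holding the marker; empty species logged."""
    out: dict[str, list[str]] = {sp: [] for sp in dataset.species}
    for specimen, _ in dataset.marker_records(marker):
        out[specimen.species].append(specimen.specimen_id)
    empty = [sp for sp, ids in out.items() if not ids]
    for sp in empty:
        logger.warning("species %r has no %s sequences; excluded", sp, marker)
        del out[sp]
    return out


def _identity_groups(dataset: Dataset, marker: str) -> dict[str, list[str]]:
    """Exact gap-free residue string → specimen ids (global scope)."""
    groups: dict[str, list[str]] = {}
    for specimen, rec in dataset.marker_records(marker):
        groups.setdefault(rec.degapped(), []).append(specimen.specimen_id)
    return groups


def _substitution_counts(rows: list[tuple[str, str]]) -> tuple[list[str], np.ndarray]:
    """All-pairs substitution counts over aligned rows (gaps excluded)."""
    from .distances import _EXCLUDED, encode_rows

    ids = [rid for rid, _ in rows]
    enc = encode_rows([r for _, r in rows])
    n = len(ids)
    counts = np.zeros((n, n), dtype=int)
    valid = enc != _EXCLUDED
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            d = int((both & (enc[i] != enc[j])).sum())
            counts[i, j] = counts[j, i] = d
    return ids, counts


def _pair_min_differences(
    dataset: Dataset,
    marker: str,
    alignments: dict[str, _aligner.MarkerAlignment] | None,
    criterion: ResolutionCriterion,
) -> dict[tuple[str, str], tuple[int, float, int]]:
    """Minimum (differences, p-distance, compared sites) per species pair.

    Within a genus the counts come from the genus alignment; across genera
    only exact identity is detected (count 0), other cross-genus pairs are
    omitted (their counts are computed on demand where reports need them).
    """
    by_species = _species_specimens(dataset, marker)
    species_of = dataset.species_map()
    genus_of = {s.specimen_id: s.genus for s in dataset.specimens}
    best: dict[tuple[str, str], tuple[int, float, int]] = {}

    def update(sp_a: str, sp_b: str, ndiff: int, dist: float, compared: int) -> None:
        key = tuple(sorted((sp_a, sp_b)))
        cur = best.get(key)
        if cur is None or ndiff < cur[0]:
            best[key] = (ndiff, dist, compared)

    # global exact identity
    for residues, members in _identity_groups(dataset, marker).items():
        for a, b in itertools.combinations(members, 2):
            if species_of[a] != species_of[b]:
                update(species_of[a], species_of[b], 0, 0.0, len(residues))

    if alignments:
        for genus, aln in alignments.items():
            present = [
                (rid, row) for rid, row in aln.rows
                if rid in species_of and species_of[rid] in by_species
            ]
            for (ra, rowa), (rb, rowb) in itertools.combinations(present, 2):
                if species_of[ra] == species_of[rb]:
                    continue
                if genus_of[ra] != genus or genus_of[rb] != genus:
                    continue
                nd = count_differences(rowa, rowb, criterion.indel_counting)
                c = count_site_classes(rowa, rowb)
                pd_ = p_distance(c)
                update(species_of[ra], species_of[rb], nd,
                       0.0 if math.isnan(pd_) else pd_, c.compared_sites)
    return best


def _resolutions_from_pairs(
    species: list[str],
    best: dict[tuple[str, str], tuple[int, float, int]],
    marker: str,
    criterion: ResolutionCriterion,
    near_report: int = 3,
) -> list[SpeciesResolution]:
    out = []
    for sp in species:
        confusions = []
        for (a, b), (nd, dist, _compared) in best.items():
            if sp not in (a, b):
                continue
            other = b if sp == a else a
            if nd < criterion.min_differences:
                confusions.append(Confusion(other, IDENTICAL if nd == 0 else
                                            "differences", nd, dist))
            elif nd <= near_report:
                confusions.append(Confusion(other, "differences", nd, dist))
        resolved = all(
            c.n_differences >= criterion.min_differences for c in confusions
        )
        out.append(SpeciesResolution(sp, marker, resolved, confusions))
    return out


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def marker_resolution(
    dataset: Dataset,
    marker: str,
    alignments: dict[str, _aligner.MarkerAlignment] | None,
    criterion: ResolutionCriterion = ResolutionCriterion(),
) -> list[SpeciesResolution]:
    """Per-species resolution for one rDNA marker."""
    by_species = _species_specimens(dataset, marker)
    best = _pair_min_differences(dataset, marker, alignments, criterion)
    return _resolutions_from_pairs(list(by_species), best, marker, criterion)


def combined_resolution(
    dataset: Dataset,
    alignments: dict[str, dict[str, _aligner.MarkerAlignment]],
    criterion: ResolutionCriterion = ResolutionCriterion(marker_class="combined"),
    markers: tuple[str, ...] = NUCLEAR_MARKERS,
) -> list[SpeciesResolution]:
    """Combined nuclear resolution: difference counts summed across markers."""
    species_of = dataset.species_map()
    genus_of = {s.specimen_id: s.genus for s in dataset.specimens}
    complete = [
        s for s in dataset.specimens if all(m in s.sequences for m in markers)
    ]
    skipped = len(dataset.specimens) - len(complete)
    if skipped:
        logger.warning("combined_resolution: %d specimens lack a nuclear marker",
                       skipped)
    species = sorted({s.species for s in complete},
                     key=[s.species for s in complete].index)

    best: dict[tuple[str, str], tuple[int, float, int]] = {}

    def update(sp_a, sp_b, ndiff, dist, compared):
        key = tuple(sorted((sp_a, sp_b)))
        cur = best.get(key)
        if cur is None or ndiff < cur[0]:
            best[key] = (ndiff, dist, compared)

    res_map = {
        m: {
            s.specimen_id: dataset.sequences[m][s.sequences[m]].degapped()
            for s in complete
        }
        for m in markers
    }
    for sa, sb in itertools.combinations(complete, 2):
        if sa.species == sb.species:
            continue
        if sa.genus == sb.genus:
            total, compared, subs = 0, 0, 0
            ok = True
            for m in markers:
                aln = alignments.get(m, {}).get(sa.genus)
                if aln is None:
                    ok = False
                    break
                ra, rb = aln.row(sa.specimen_id), aln.row(sb.specimen_id)
                total += count_differences(ra, rb, criterion.indel_counting)
                c = count_site_classes(ra, rb)
                compared += c.compared_sites
                subs += c.transitions + c.transversions
            if not ok:
                continue
            update(sa.species, sb.species, total,
                   subs / compared if compared else 0.0, compared)
        else:
            idents = sum(
                res_map[m][sa.specimen_id] == res_map[m][sb.specimen_id]
                for m in markers
            )
            if idents == len(markers):
                total_len = sum(len(res_map[m][sa.specimen_id]) for m in markers)
                update(sa.species, sb.species, 0, 0.0, total_len)
    return _resolutions_from_pairs(species, best, "+".join(markers), criterion)


def coi_resolution(
    dataset: Dataset,
    alignment: _aligner.MarkerAlignment,
    criterion: ResolutionCriterion = ResolutionCriterion(marker_class="COI"),
) -> list[SpeciesResolution]:
    """COI diagnosability: every heterospecific specimen pair must differ by
    at least ``min_differences`` substitutions."""
    by_species = _species_specimens(dataset, "COI")
    species_of = dataset.species_map()
    ids, counts = _substitution_counts(alignment.rows)

    best: dict[tuple[str, str], tuple[int, float, int]] = {}
    n = len(ids)
    L = alignment.length
    for i in range(n):
        for j in range(i + 1, n):
            a, b = species_of[ids[i]], species_of[ids[j]]
            if a == b:
                continue
            key = tuple(sorted((a, b)))
            nd = int(counts[i, j])
            cur = best.get(key)
            if cur is None or nd < cur[0]:
                best[key] = (nd, nd / L, L)
    return _resolutions_from_pairs(list(by_species), best, "COI", criterion)


def resolved_count(resolutions: list[SpeciesResolution]) -> tuple[int, int]:
    return sum(r.resolved for r in resolutions), len(resolutions)


def barcoding_gap(matrix: DistanceMatrix, species_map: dict[str, str]) -> BarcodingGapReport:
    """Per-species max-intra vs nearest-neighbour min-inter distances."""
    labels = matrix.labels
    species = [species_map[l] for l in labels]
    uniq = list(dict.fromkeys(species))
    vals = matrix.values
    rows = []
    dataset_min_inter = math.inf
    for sp in uniq:
        own = [i for i, s in enumerate(species) if s == sp]
        other = [i for i, s in enumerate(species) if s != sp]
        max_intra = math.nan
        if len(own) > 1:
            sub = vals[np.ix_(own, own)]
            iu = np.triu_indices(len(own), k=1)
            d = sub[iu]
            d = d[~np.isnan(d)]
            if d.size:
                max_intra = float(d.max())
        min_inter, nearest = math.nan, ""
        if other:
            inter = vals[np.ix_(own, other)]
            if not np.isnan(inter).all():
                flat = np.nanargmin(inter)
                min_inter = float(np.nanmin(inter))
                nearest = species[other[flat % len(other)]]
                dataset_min_inter = min(dataset_min_inter, min_inter)
        gap = (min_inter - max_intra
               if not (math.isnan(max_intra) or math.isnan(min_inter)) else math.nan)
        rows.append({"species": sp, "max_intraspecific": max_intra,
                     "min_interspecific": min_inter, "nearest_neighbor": nearest,
                     "gap": gap})
    df = pd.DataFrame(rows)
    overlap = bool(
        (df["max_intraspecific"] >= dataset_min_inter).fillna(False).any()
    )
    return BarcodingGapReport(
        per_species=df,
        dataset_min_interspecific=(
            dataset_min_inter if math.isfinite(dataset_min_inter) else math.nan
        ),
        overlap=overlap,
    )


def deep_split_species(
    matrix: DistanceMatrix, species_map: dict[str, str], threshold: float = 0.02
) -> list[str]:
    """Species whose maximum intraspecific distance reaches the threshold."""
    report = barcoding_gap(matrix, species_map)
    df = report.per_species
    hits = df[df["max_intraspecific"] >= threshold]
    return list(hits["species"])


# ---------------------------------------------------------------------------
# Table-1-style report
# ---------------------------------------------------------------------------

def _format_cell(ndiff: int, dist: float) -> str:
    if ndiff == 0:
        return IDENTICAL
    return f"{dist:.4g}/{ndiff}"


def _cross_genus_cell(
    dataset: Dataset, marker: str, sp_a: str, sp_b: str,
    criterion: ResolutionCriterion, params: _aligner.AlignmentParams,
) -> tuple[int, float]:
    """Difference count for a cross-genus pair via on-demand pairwise alignment."""
    seq_a = next(
        dataset.residues(s.specimen_id, marker)
        for s in dataset.specimens
        if s.species == sp_a and marker in s.sequences
    )
    seq_b = next(
        dataset.residues(s.specimen_id, marker)
        for s in dataset.specimens
        if s.species == sp_b and marker in s.sequences
    )
    if seq_a == seq_b:
        return 0, 0.0, len(seq_a)
    ra, rb, _ = _aligner.pairwise_align(seq_a, seq_b, params)
    nd = count_differences(ra, rb, criterion.indel_counting)
    c = count_site_classes(ra, rb)
    pd_ = p_distance(c)
    return nd, 0.0 if math.isnan(pd_) else pd_, c.compared_sites


def table1_report(
    dataset: Dataset,
    coi_matrix: DistanceMatrix,
    rdna_alignments: dict[str, dict[str, _aligner.MarkerAlignment]],
    coi_resolutions: list[SpeciesResolution],
    rdna_resolutions: dict[str, list[SpeciesResolution]],
    combined_resolutions: list[SpeciesResolution],
    criterion: ResolutionCriterion = ResolutionCriterion(),
    params: _aligner.AlignmentParams = _aligner.DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Species pairs failing at least one marker, with per-marker evidence.

    Cells are ``identical sequences`` or ``p-distance/differences`` for the
    rDNA markers and their combination, and a K2P distance range for COI.
    """
    failing: set[tuple[str, str]] = set()
    for resolutions in (
        list(rdna_resolutions.values()) + [coi_resolutions, combined_resolutions]
    ):
        for r in resolutions:
            if r.resolved:
                continue
            for c in r.confusions:
                if c.n_differences < criterion.min_differences:
                    failing.add(tuple(sorted((r.species, c.other_species))))

    species_of = dataset.species_map()
    genus_of = {sp.species: sp.genus for sp in dataset.specimens}
    pair_best = {
        m: _pair_min_differences(dataset, m, rdna_alignments.get(m), criterion)
        for m in rdna_alignments
    }

    labels = coi_matrix.labels
    rows = []
    for sp_a, sp_b in sorted(failing):
        row: dict[str, object] = {"species_pair": f"{sp_a} / {sp_b}"}
        combined_nd, combined_sites = 0, 0
        for m in NUCLEAR_MARKERS:
            cell = pair_best.get(m, {}).get((sp_a, sp_b))
            if cell is None:
                if genus_of[sp_a] != genus_of[sp_b]:
                    cell = _cross_genus_cell(dataset, m, sp_a, sp_b, criterion, params)
                else:
                    row[m] = "no data"
                    continue
            nd, dist, compared = cell
            row[m] = _format_cell(nd, dist)
            combined_nd += nd
            combined_sites += compared
        if combined_nd == 0:
            row["combined"] = IDENTICAL
        else:
            row["combined"] = f"{combined_nd / combined_sites:.4g}/{combined_nd}"
        own = [i for i, l in enumerate(labels) if species_of[l] == sp_a]
        oth = [i for i, l in enumerate(labels) if species_of[l] == sp_b]
        if own and oth:
            block = coi_matrix.values[np.ix_(own, oth)]
            lo, hi = float(np.nanmin(block)), float(np.nanmax(block))
            if lo == 0.0:
                # sharing any haplotype is reported as identity, as the
                # remaining spread is within-haplotype-pool noise
                row["COI"] = IDENTICAL
            elif math.isclose(lo, hi, abs_tol=5e-5):
                row["COI"] = f"{lo:.4g}"
            else:
                row["COI"] = f"{lo:.4g} - {hi:.4g}"
        else:
            row["COI"] = "no data"
        rows.append(row)
    return pd.DataFrame(rows, columns=["species_pair", *NUCLEAR_MARKERS,
                                       "combined", "COI"])
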