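"""Sequence and metadata I/O, haplotype collapsing, and the COI numt screen.

The package works on four markers per specimen by default: the mitochondrial
COI barcode fragment and three nuclear rDNA expansion segments (28S D3,
18S V4, 18S V7).  Sequences live in per-marker FASTA files; specimens in a
tab-separated table that references sequence ids per marker.

The numt screen translates COI with the invertebrate mitochondrial code and
flags sequences whose best reading frame still contains an internal stop
codon — the classic signature of a nuclear mitochondrial pseudogene.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Default marker set, in the fixed reporting order used throughout.
DEFAULT_MARKERS: tuple[str, ...] = ("COI", "D3", "V4", "V7")

#: Nuclear markers in the fixed concatenation order.
NUCLEAR_MARKERS: tuple[str, ...] = ("D3", "V4", "V7")

#: NCBI translation table for the invertebrate mitochondrial code.
INVERTEBRATE_MITO_TABLE = 5

IUPAC_NUCLEOTIDES = set("ACGTRYSWKMBDHVN")
GAP = "-"
_VALID_CHARS = IUPAC_NUCLEOTIDES | {GAP}
AMBIGUITY_CODES = IUPAC_NUCLEOTIDES - set("ACGT")


@dataclass
class SequenceRecord:
    """One nucleotide sequence for one marker.

    ``residues`` may contain ``-`` only when ``is_aligned`` is set.
    """

    sequence_id: str
    marker: str
    residues: str
    is_aligned: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"sequence {self.sequence_id!r}: empty residues")
        bad = set(self.residues) - _VALID_CHARS
        if bad:
            raise ValidationError(
                f"sequence {self.sequence_id!r}: non-IUPAC characters {sorted(bad)}"
            )
        if GAP in self.residues and not self.is_aligned:
            self.is_aligned = True

    def degapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass
class SpecimenRecord:
    """One specimen: identity, binomial species name, and marker sequences.

    ``sequences`` maps marker name to the sequence id in that marker's file;
    markers without data are simply absent from the map.
    """

    specimen_id: str
    species: str
    genus: str = ""
    locality: str = ""
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genus:
            self.genus = self.species.split()[0]


@dataclass
class Haplotype:
    """A distinct gap-free sequence and the specimens carrying it."""

    residues: str
    members: list[str]
    species_counts: dict[str, int]

    def __post_init__(self) -> None:
        if sum(self.species_counts.values()) != len(self.members):
            raise ValidationError("haplotype species_counts do not sum to member count")


@dataclass
class NumtScreenResult:
    sequence_id: str
    frame_used: int
    internal_stop_found: bool
    stop_positions: list[int]

    def __post_init__(self) -> None:
        if self.internal_stop_found != bool(self.stop_positions):
            raise ValidationError("internal_stop_found inconsistent with stop_positions")


# ---------------------------------------------------------------------------
# FASTA and table I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, marker: str) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The header token before the first whitespace becomes the sequence id;
    residues are upper-cased.  Records containing ``-`` are flagged aligned.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}: line {lineno}: expected FASTA header '>' "
                        f"before sequence data"
                    )
                break
        else:
            raise ParseError(f"{path}: empty FASTA file")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq_id = entry.id
        if seq_id in seen:
            raise ParseError(f"{path}: duplicate sequence id {seq_id!r}")
        seen.add(seq_id)
        residues = str(entry.seq).upper()
        if not residues:
            raise ParseError(f"{path}: sequence {seq_id!r} has no residues")
        records.append(
            SequenceRecord(
                sequence_id=seq_id,
                marker=marker,
                residues=residues,
                is_aligned=GAP in residues,
            )
        )
    if not records:
        raise ParseError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA; round-trips ids and residues byte-exactly."""
    path = Path(path)
    entries = [
        SeqRecord(Seq(r.residues), id=r.sequence_id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(entries, fh, "fasta-2line")


def read_specimen_table(
    path: str | Path,
    sequences: Mapping[str, Mapping[str, SequenceRecord]] | None = None,
    markers: Sequence[str] = DEFAULT_MARKERS,
) -> list[SpecimenRecord]:
    """Read the tab-separated specimen table.

    Required columns: ``specimen_id``, ``species``, plus one column per
    marker holding the sequence id (empty cell = marker absent).  Optional
    columns ``genus`` and ``locality``.  When ``sequences`` (marker →
    sequence_id → record) is given, every referenced id is validated.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"specimen_id", "species"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    marker_cols = [m for m in markers if m in df.columns]
    if not marker_cols:
        raise ParseError(f"{path}: no marker columns found (expected any of {markers})")

    specimens: list[SpecimenRecord] = []
    seen: set[str] = set()
    offenders: list[str] = []
    for _, row in df.iterrows():
        sid = row["specimen_id"]
        if sid in seen:
            raise ValidationError(f"{path}: duplicate specimen_id {sid!r}")
        seen.add(sid)
        seq_map = {}
        for m in marker_cols:
            ref = row[m]
            if not ref:
                continue
            if sequences is not None and ref not in sequences.get(m, {}):
                offenders.append(f"{sid}:{m}:{ref}")
                continue
            seq_map[m] = ref
        specimens.append(
            SpecimenRecord(
                specimen_id=sid,
                species=row["species"],
                genus=row.get("genus", ""),
                locality=row.get("locality", ""),
                sequences=seq_map,
            )
        )
    if offenders:
        raise ValidationError(
            f"{path}: unknown sequence-id references: {', '.join(offenders)}"
        )
    return specimens


def write_table(rows: pd.DataFrame | Iterable[Mapping], path: str | Path) -> None:
    """Write a report table as TSV (no index column)."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Haplotype collapsing
# ---------------------------------------------------------------------------

def collapse_haplotypes(
    records: Sequence[SequenceRecord],
    specimens: Sequence[SpecimenRecord],
) -> list[Haplotype]:
    """Partition sequences into exact-identity haplotypes (gaps stripped).

    ``species_counts`` is populated from the specimen metadata; sequences not
    referenced by any specimen are counted under species ``"?"``.
    """
    markers = {r.marker for r in records}
    if len(markers) > 1:
        raise ValidationError(f"collapse_haplotypes: mixed markers {sorted(markers)}")
    seq_to_specimen: dict[str, SpecimenRecord] = {}
    for sp in specimens:
        for ref in sp.sequences.values():
            seq_to_specimen[ref] = sp

    groups: dict[str, list[SequenceRecord]] = {}
    order: list[str] = []
    for rec in records:
        key = rec.degapped()
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    haplotypes = []
    for residues in order:
        members = [r.sequence_id for r in groups[residues]]
        counts: Counter[str] = Counter()
        for r in groups[residues]:
            sp = seq_to_specimen.get(r.sequence_id)
            counts[sp.species if sp else "?"] += 1
        haplotypes.append(
            Haplotype(residues=residues, members=members, species_counts=dict(counts))
        )
    return haplotypes


# ---------------------------------------------------------------------------
# numt screen
# ---------------------------------------------------------------------------

def _translate_frame(residues: str, frame: int, table: int) -> str:
    sub = residues[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    return str(Seq(sub).translate(table=table))


def screen_numts(
    records: Sequence[SequenceRecord],
    genetic_code: int = INVERTEBRATE_MITO_TABLE,
    reading_frame: int | str = "auto",
) -> list[NumtScreenResult]:
    """Translate COI sequences and flag internal stop codons.

    With ``reading_frame="auto"`` the frame minimising internal stops is
    chosen (ties → lowest frame index).  A stop in the final codon of a frame
    is not counted as internal.
    """
    results = []
    for rec in records:
        residues = rec.degapped()
        if len(residues) < 3:
            raise ValidationError(
                f"screen_numts: sequence {rec.sequence_id!r} shorter than one codon"
            )
        frames = (0, 1, 2) if reading_frame == "auto" else (int(reading_frame),)
        best: tuple[int, list[int]] | None = None
        for f in frames:
            if len(residues) - f < 3:
                continue
            protein = _translate_frame(residues, f, genetic_code)
            stops = [i for i, aa in enumerate(protein[:-1]) if aa == "*"]
            if best is None or len(stops) < len(best[1]):
                best = (f, stops)
        if best is None:
            raise ValidationError(
                f"screen_numts: sequence {rec.sequence_id!r} too short for frame "
                f"{reading_frame}"
            )
        frame_used, stops = best
        results.append(
            NumtScreenResult(
                sequence_id=rec.sequence_id,
                frame_used=frame_used,
                internal_stop_found=bool(stops),
                stop_positions=stops,
            )
        )
    flagged = sum(r.internal_stop_found for r in results)
    if flagged:
        logger.warning("numt screen flagged %d of %d sequences", flagged, len(results))
    return results


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Specimens plus per-marker sequence collections, with consistency checks."""

    specimens: list[SpecimenRecord]
    sequences: dict[str, dict[str, SequenceRecord]]

    def __post_init__(self) -> None:
        ids = [s.specimen_id for s in self.specimens]
        dup = [i for i, c in Counter(ids).items() if c > 1]
        if dup:
            raise ValidationError(f"duplicate specimen ids: {dup}")
        missing = [
            f"{s.specimen_id}:{m}:{ref}"
            for s in self.specimens
            for m, ref in s.sequences.items()
            if ref not in self.sequences.get(m, {})
        ]
        if missing:
            raise ValidationError(f"dangling sequence references: {missing}")

    @property
    def markers(self) -> list[str]:
        return list(self.sequences)

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.specimens:
            seen.setdefault(s.species, None)
        return list(seen)

    def specimen(self, specimen_id: str) -> SpecimenRecord:
        for s in self.specimens:
            if s.specimen_id == specimen_id:
                return s
        raise KeyError(specimen_id)

    def species_map(self) -> dict[str, str]:
        """specimen_id → species."""
        return {s.specimen_id: s.species for s in self.specimens}

    def specimens_by_species(self) -> dict[str, list[SpecimenRecord]]:
        out: dict[str, list[SpecimenRecord]] = {}
        for s in self.specimens:
            out.setdefault(s.species, []).append(s)
        return out

    def residues(self, specimen_id: str, marker: str) -> str | None:
        """Gap-free residues of one specimen's marker sequence, or None."""
        sp = self.specimen(specimen_id)
        ref = sp.sequences.get(marker)
        if ref is None:
            return None
        return self.sequences[marker][ref].degapped()

    def marker_records(self, marker: str) -> list[tuple[SpecimenRecord, SequenceRecord]]:
        """(specimen, sequence) pairs for one marker, in specimen order."""
        out = []
        for s in self.specimens:
            ref = s.sequences.get(marker)
            if ref is not None:
                out.append((s, self.sequences[marker][ref]))
        return out

    def write(self, directory: str | Path) -> None:
        """Write per-marker FASTA files plus specimens.tsv into a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for marker, recs in self.sequences.items():
            write_fasta(recs.values(), directory / f"{marker}.fasta")
        rows = [
            {
                "specimen_id": s.specimen_id,
                "species": s.species,
                "genus": s.genus,
                "locality": s.locality,
                **{m: s.sequences.get(m, "") for m in self.sequences},
            }
            for s in self.specimens
        ]
        write_table(pd.DataFrame(rows), directory / "specimens.tsv")

    @classmethod
    def read(
        cls, directory: str | Path, markers: Sequence[str] = DEFAULT_MARKERS
    ) -> "Dataset":
        directory = Path(directory)
        sequences: dict[str, dict[str, SequenceRecord]] = {}
        for marker in markers:
            fasta = directory / f"{marker}.fasta"
            if fasta.exists():
                sequences[marker] = {
                    r.sequence_id: r for r in read_fasta(fasta, marker)
                }
        specimens = read_specimen_table(
            directory / "specimens.tsv", sequences, markers=markers
        )
        return cls(specimens=specimens, sequences=sequences)
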