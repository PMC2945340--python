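"""Seeded multi-marker dataset generator with designed ground truth.

The generator emulates the statistical structure of a multi-marker species
identification study of ground beetles: ~75 species in ~25-30 genera with
2-13 specimens each (mean ~4.6), an AT-biased 658-bp COI barcode with low
intraspecific and 3-15% interspecific K2P divergence, and three nuclear
rDNA expansion segments (D3 ~200 bp, V4 ~380 bp, V7 ~410 bp) that are
invariant within species and differ between congeneric species by a
handful of substitutions and occasional short indels flanked by conserved
margins.

Designed pathologies mirror the hard cases such studies hit:

* a sibling pair sharing COI haplotypes and all rDNA sequences
  (unresolved by every marker),
* a species pair identical at all three rDNA markers but divergent at COI
  (unresolved by the combined nuclear criterion only),
* a cross-genus pair with an identical V4 sequence,
* a deep-split species with two COI clusters ~3.8% apart (and optionally
  two V7 variants tracking the clusters).

Every designed outcome is recorded in a :class:`SyntheticTruth` and
re-checked against the emitted sequences by brute force after generation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError, TruthMismatchError
from .seqio import Dataset, SequenceRecord, SpecimenRecord

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": "CT", "G": "CT", "C": "AG", "T": "AG",
}


def _base_frequencies(at_fraction: float) -> dict[str, float]:
    return {
        "A": at_fraction / 2.0, "T": at_fraction / 2.0,
        "C": (1.0 - at_fraction) / 2.0, "G": (1.0 - at_fraction) / 2.0,
    }


@dataclass(frozen=True)
class RdnaMarkerConfig:
    """Length distribution and between-species difference range of one marker."""

    length_min: int
    length_max: int
    length_mean: float
    sub_count_range: tuple[int, int]


@dataclass(frozen=True)
class PathologyConfig:
    shared_haplotype_pair: bool = True
    rdna_identical_pair: bool = True
    cross_genus_identical_pair: bool = True
    cross_genus_marker: str = "V4"
    deep_split_species: bool = True
    deep_split_divergence: float = 0.038
    deep_split_v7_variant: bool = True


@dataclass(frozen=True)
class SyntheticConfig:
    n_species: int = 75
    specimens_min: int = 2
    specimens_max: int = 13
    specimens_decay: float = 0.74  # P(n) ~ decay**(n - specimens_min)
    coi_length: int = 658
    coi_at_bias: float = 0.676
    coi_founder_divergence: tuple[float, float] = (0.017, 0.105)
    intraspecific_rate_max: float = 0.003  # per-site, per-specimen
    ts_tv_ratio: float = 2.0
    rdna: dict[str, RdnaMarkerConfig] = field(default_factory=lambda: {
        "D3": RdnaMarkerConfig(185, 254, 198.0, (1, 11)),
        "V4": RdnaMarkerConfig(355, 515, 384.0, (1, 13)),
        "V7": RdnaMarkerConfig(388, 504, 414.0, (2, 17)),
    })
    rdna_indel_prob: float = 0.3
    rdna_indel_max: int = 8
    rdna_flank: int = 10
    filler_genus_max: int = 6
    pathologies: PathologyConfig = PathologyConfig()
    # Extra per-marker identical groups (list of group sizes per marker).
    marker_identity_groups: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            "D3": (2, 2, 2, 2, 2),
            "V4": (3, 3, 2, 2, 2),
            "V7": (2, 2, 2),
        }
    )
    numt_copies: int = 0
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Designed outcomes, serialisable, re-checked post-generation."""

    n_species: int
    n_specimens: int
    unresolved: dict[str, list[str]]  # marker / "combined" / "COI" -> species
    identity_groups: dict[str, list[list[str]]]
    shared_haplotype_pair: tuple[str, str] | None
    rdna_identical_pair: tuple[str, str] | None
    cross_genus_identical_pair: tuple[str, str] | None
    cross_genus_marker: str | None
    deep_split_species: str | None
    deep_split_divergence: float | None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("shared_haplotype_pair", "rdna_identical_pair",
                    "cross_genus_identical_pair"):
            if raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Low-level sequence machinery
# ---------------------------------------------------------------------------

def _random_sequence(rng, length: int, at_fraction: float = 0.5) -> str:
    freqs = _base_frequencies(at_fraction)
    bases = list(freqs)
    return "".join(rng.choice(bases, size=length, p=list(freqs.values())))


def _composed_sequence(rng, length: int, at_fraction: float) -> str:
    """Random sequence whose composition hits the target exactly (counts
    fixed per base, order shuffled) — the whole dataset descends from this
    one founder, so its composition must not carry sampling noise."""
    freqs = _base_frequencies(at_fraction)
    counts = {b: int(round(f * length)) for b, f in freqs.items()}
    counts["A"] += length - sum(counts.values())
    chars = [b for b, c in counts.items() for _ in range(c)]
    return "".join(np.array(chars)[rng.permutation(length)])


def _mutate_at(rng, seq: list[str], pos: int, ts_tv_ratio: float,
               at_fraction: float = 0.5) -> None:
    """Substitute one site, HKY-style: the replacement base is drawn with
    weight stationary-frequency x (2*ratio for the transition partner), so
    the realised transition:transversion ratio is ~``ts_tv_ratio`` and the
    base composition is approximately preserved under mutation."""
    base = seq[pos]
    freqs = _base_frequencies(at_fraction)
    kappa = 2.0 * ts_tv_ratio
    targets = [b for b in _BASES if b != base]
    weights = np.array([
        freqs[b] * (kappa if b == _TRANSITION[base] else 1.0) for b in targets
    ])
    seq[pos] = targets[int(rng.choice(3, p=weights / weights.sum()))]


def _substituted(rng, seq: str, positions, ts_tv_ratio: float,
                 at_fraction: float = 0.5) -> str:
    chars = list(seq)
    for pos in positions:
        _mutate_at(rng, chars, int(pos), ts_tv_ratio, at_fraction)
    return "".join(chars)


# Invertebrate-mitochondrial stop codons (TGA codes for Trp and is fine),
# replaced by same-composition leucine codons so the A+T target holds.
_STOP_REPAIR = {"TAA": "TTA", "TAG": "TTG"}


def _sanitize_coding(seq: str) -> str:
    """Remove frame-0 internal stop codons so COI behaves like a real,
    numt-free protein-coding barcode under translation screening."""
    chars = list(seq)
    for c0 in range(0, len(seq) - 2, 3):
        repair = _STOP_REPAIR.get("".join(chars[c0:c0 + 3]))
        if repair:
            chars[c0:c0 + 3] = repair
    return "".join(chars)


# A short cassette holding a stop codon at every reading phase; splicing it
# into a numt copy guarantees an internal stop whichever frame is read.
_STOP_CASSETTE = "TAAATAGATAA"


def _draw_length(rng, cfg: RdnaMarkerConfig) -> int:
    span = cfg.length_mean - cfg.length_min
    L = cfg.length_min + int(rng.exponential(max(span, 1.0)))
    return min(L, cfg.length_max)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _plan_taxa(config: SyntheticConfig, rng) -> tuple[
    list[tuple[str, str]],  # (species, genus) in output order
    dict[str, list[list[str]]],  # marker -> designed identical species groups
    dict[str, object],
]:
    """Assign species to genera and pick the designed special species."""
    path = config.pathologies
    special: dict[str, object] = {}
    genera: list[list[int]] = []  # lists of species indices
    groups: dict[str, list[list[int]]] = {m: [] for m in config.rdna}

    cursor = 0

    def take(n: int) -> list[int]:
        nonlocal cursor
        if cursor + n > config.n_species:
            raise GenerationError(
                "n_species too small for the configured designed groups"
            )
        out = list(range(cursor, cursor + n))
        cursor += n
        return out

    if path.shared_haplotype_pair:
        pair = take(2)
        genera.append(pair)
        special["shared_pair"] = pair
        for m in config.rdna:
            groups[m].append(pair)
    if path.rdna_identical_pair:
        pair = take(2)
        genera.append(pair)
        special["rdna_pair"] = pair
        for m in config.rdna:
            groups[m].append(pair)
    if path.deep_split_species:
        sp = take(1)
        genera.append(sp)
        special["deep_split"] = sp[0]
    for marker, sizes in config.marker_identity_groups.items():
        for size in sizes:
            grp = take(size)
            genera.append(grp)
            groups[marker].append(grp)
    if path.cross_genus_identical_pair:
        a = take(1)
        b = take(1)
        genera.append(a)
        genera.append(b)
        special["cross_pair"] = (a[0], b[0])
        groups[path.cross_genus_marker].append([a[0], b[0]])

    while cursor < config.n_species:
        size = int(rng.integers(1, config.filler_genus_max + 1))
        size = min(size, config.n_species - cursor)
        genera.append(take(size))

    taxa: list[tuple[str, str] | None] = [None] * config.n_species
    for gi, members in enumerate(genera):
        genus = f"Genus{gi + 1:02d}"
        for k, si in enumerate(members):
            taxa[si] = (f"{genus} sp{k + 1:02d}", genus)
    name_groups = {
        m: [[taxa[i][0] for i in grp] for grp in grps]
        for m, grps in groups.items()
    }
    return list(taxa), name_groups, special


def _generate_coi(config: SyntheticConfig, rng, taxa, special,
                  counts: list[int]) -> tuple[dict[int, list[str]], dict]:
    """Per-species specimen COI sequences (index -> list of residues)."""
    L = config.coi_length
    base = _sanitize_coding(_composed_sequence(rng, L, config.coi_at_bias))
    lo, hi = config.coi_founder_divergence
    founders: dict[int, str] = {}
    shared = special.get("shared_pair")
    deep = special.get("deep_split")
    for i in range(config.n_species):
        if shared and i == shared[1]:
            founders[i] = founders[shared[0]]
            continue
        d = rng.uniform(lo, hi)
        k = max(1, round(d * L))
        positions = rng.choice(L, size=k, replace=False)
        founders[i] = _sanitize_coding(_substituted(
            rng, base, positions, config.ts_tv_ratio, config.coi_at_bias))

    deep_b = None
    if deep is not None:
        k_extra = max(1, round(config.pathologies.deep_split_divergence * L))
        free = rng.choice(L, size=k_extra, replace=False)
        deep_b = _sanitize_coding(_substituted(
            rng, founders[deep], free, config.ts_tv_ratio, config.coi_at_bias))

    shared_pool = None
    if shared:
        pool = [founders[shared[0]]]
        for _ in range(2):
            pos = int(rng.integers(L))
            pool.append(_sanitize_coding(_substituted(
                rng, pool[0], [pos], config.ts_tv_ratio, config.coi_at_bias)))
        shared_pool = pool

    per_species: dict[int, list[str]] = {}
    deep_cluster: dict[int, list[int]] = {}
    for i in range(config.n_species):
        n = counts[i]
        seqs = []
        if shared and i in shared:
            seqs.append(shared_pool[0])  # the shared haplotype, in both species
            for _ in range(n - 1):
                seqs.append(shared_pool[int(rng.integers(len(shared_pool)))])
        elif deep is not None and i == deep:
            n_b = max(1, n // 2)
            clusters = [0] * (n - n_b) + [1] * n_b
            deep_cluster[i] = clusters
            for c in clusters:
                founder = founders[i] if c == 0 else deep_b
                n_mut = rng.binomial(L, rng.uniform(0, config.intraspecific_rate_max / 2))
                pos = rng.choice(L, size=n_mut, replace=False)
                seqs.append(_sanitize_coding(_substituted(
                    rng, founder, pos, config.ts_tv_ratio, config.coi_at_bias)))
        else:
            for _ in range(n):
                n_mut = rng.binomial(L, rng.uniform(0, config.intraspecific_rate_max))
                pos = rng.choice(L, size=n_mut, replace=False)
                seqs.append(_sanitize_coding(_substituted(
                    rng, founders[i], pos, config.ts_tv_ratio,
                    config.coi_at_bias)))
        per_species[i] = seqs
    return per_species, {"deep_cluster": deep_cluster, "founders": founders}


def _generate_rdna(config: SyntheticConfig, rng, taxa, special,
                   groups_idx: dict[str, list[list[int]]]) -> dict[str, dict[int, list[str]]]:
    """marker -> species index -> list of variant sequences (usually one)."""
    genus_members: dict[str, list[int]] = {}
    for i, (_, genus) in enumerate(taxa):
        genus_members.setdefault(genus, []).append(i)
    cross = special.get("cross_pair")
    cross_marker = config.pathologies.cross_genus_marker
    deep = special.get("deep_split")

    out: dict[str, dict[int, list[str]]] = {}
    for marker, mcfg in config.rdna.items():
        in_group: dict[int, int] = {}
        for gid, grp in enumerate(groups_idx.get(marker, [])):
            for i in grp:
                in_group[i] = gid
        seqs: dict[int, list[str]] = {}
        for genus, members in genus_members.items():
            L = _draw_length(rng, mcfg)
            founder = _random_sequence(rng, L)
            flank = config.rdna_flank
            interior = list(range(flank, L - flank))
            rng.shuffle(interior)
            pool_cursor = 0

            def take_positions(k: int) -> list[int]:
                nonlocal pool_cursor
                if pool_cursor + k > len(interior):
                    raise GenerationError(
                        f"{marker}/{genus}: not enough interior sites for "
                        f"the requested differences"
                    )
                got = interior[pool_cursor:pool_cursor + k]
                pool_cursor += k
                return got

            done_groups: dict[int, str] = {}
            for i in members:
                if cross and marker == cross_marker and i == cross[0]:
                    continue  # filled below, copied from partner
                gid = in_group.get(i)
                if gid is not None:
                    if gid in done_groups:
                        seqs[i] = [done_groups[gid]]
                        continue
                lo, hi = mcfg.sub_count_range
                k = int(rng.integers(lo, hi + 1))
                variant = _substituted(
                    rng, founder, take_positions(k), config.ts_tv_ratio
                )
                if gid is None and rng.random() < config.rdna_indel_prob:
                    g = min(1 + rng.geometric(0.5), config.rdna_indel_max)
                    start = flank + int(rng.integers(max(L - 2 * flank - g, 1)))
                    if rng.random() < 0.5:
                        variant = variant[:start] + variant[start + g:]
                    else:
                        insert = _random_sequence(rng, g)
                        variant = variant[:start] + insert + variant[start:]
                seqs[i] = [variant]
                if gid is not None:
                    done_groups[gid] = variant
        if cross and marker == cross_marker:
            seqs[cross[0]] = [seqs[cross[1]][0]]
        if (deep is not None and marker == "V7"
                and config.pathologies.deep_split_v7_variant):
            v1 = seqs[deep][0]
            pos = config.rdna_flank + 1
            chars = list(v1)
            _mutate_at(rng, chars, pos, config.ts_tv_ratio)
            seqs[deep] = [v1, "".join(chars)]
        out[marker] = seqs
    return out


def generate(config: SyntheticConfig) -> tuple[Dataset, SyntheticTruth]:
    """Generate a seeded dataset plus its design record, then verify it."""
    rng = np.random.default_rng(config.seed)
    taxa, name_groups, special = _plan_taxa(config, rng)

    weights = np.array([
        config.specimens_decay ** (n - config.specimens_min)
        for n in range(config.specimens_min, config.specimens_max + 1)
    ])
    weights /= weights.sum()
    counts = [
        int(rng.choice(
            np.arange(config.specimens_min, config.specimens_max + 1), p=weights
        ))
        for _ in range(config.n_species)
    ]

    groups_idx = {
        m: [[next(i for i, t in enumerate(taxa) if t[0] == name) for name in grp]
            for grp in grps]
        for m, grps in name_groups.items()
    }
    coi, coi_info = _generate_coi(config, rng, taxa, special, counts)
    rdna = _generate_rdna(config, rng, taxa, special, groups_idx)
    deep_cluster = coi_info["deep_cluster"]

    specimens: list[SpecimenRecord] = []
    sequences: dict[str, dict[str, SequenceRecord]] = {
        m: {} for m in ("COI", *config.rdna)
    }
    for i, (species, genus) in enumerate(taxa):
        for k in range(counts[i]):
            sid = f"SP{i:03d}_{k:02d}"
            seq_refs = {}
            coi_id = f"{sid}_COI"
            sequences["COI"][coi_id] = SequenceRecord(coi_id, "COI", coi[i][k])
            seq_refs["COI"] = coi_id
            for marker in config.rdna:
                variants = rdna[marker][i]
                if len(variants) > 1 and i in deep_cluster:
                    residues = variants[deep_cluster[i][k]]
                else:
                    residues = variants[0]
                ref = f"{sid}_{marker}"
                sequences[marker][ref] = SequenceRecord(ref, marker, residues)
                seq_refs[marker] = ref
            specimens.append(SpecimenRecord(sid, species, genus, "", seq_refs))

    for c in range(config.numt_copies):
        # frame-shifted COI copies for exercising the numt screen
        src = specimens[c % len(specimens)]
        residues = sequences["COI"][src.sequences["COI"]].residues
        shifted = residues[:30] + "A" + residues[30:]
        mid = len(shifted) // 2
        shifted = shifted[:mid] + _STOP_CASSETTE + shifted[mid + len(_STOP_CASSETTE):]
        nid = f"NUMT{c:02d}_COI"
        sequences["COI"][nid] = SequenceRecord(nid, "COI", shifted)

    dataset = Dataset(specimens=specimens, sequences=sequences)

    name = lambda i: taxa[i][0]
    path = config.pathologies
    unresolved: dict[str, list[str]] = {}
    for m in config.rdna:
        species = sorted({name(i) for grp in groups_idx[m] for i in grp})
        unresolved[m] = species
    both_pairs = []
    if "shared_pair" in special:
        both_pairs += [name(i) for i in special["shared_pair"]]
    if "rdna_pair" in special:
        both_pairs += [name(i) for i in special["rdna_pair"]]
    unresolved["combined"] = sorted(both_pairs)
    unresolved["COI"] = sorted(
        name(i) for i in special.get("shared_pair", [])
    )
    truth = SyntheticTruth(
        n_species=config.n_species,
        n_specimens=len(specimens),
        unresolved=unresolved,
        identity_groups={
            m: [sorted(name(i) for i in grp) for grp in groups_idx[m]]
            for m in config.rdna
        },
        shared_haplotype_pair=(
            tuple(name(i) for i in special["shared_pair"])
            if "shared_pair" in special else None
        ),
        rdna_identical_pair=(
            tuple(name(i) for i in special["rdna_pair"])
            if "rdna_pair" in special else None
        ),
        cross_genus_identical_pair=(
            tuple(name(i) for i in special["cross_pair"])
            if "cross_pair" in special else None
        ),
        cross_genus_marker=(
            path.cross_genus_marker if "cross_pair" in special else None
        ),
        deep_split_species=(
            name(special["deep_split"]) if "deep_split" in special else None
        ),
        deep_split_divergence=(
            path.deep_split_divergence if "deep_split" in special else None
        ),
    )
    verify(dataset, truth, config)
    return dataset, truth


# ---------------------------------------------------------------------------
# Brute-force verification
# ---------------------------------------------------------------------------

def verify(dataset: Dataset, truth: SyntheticTruth,
           config: SyntheticConfig | None = None) -> dict:
    """Re-check every designed property of a generated dataset by brute force.

    Raises :class:`TruthMismatchError` with a detailed message on the first
    violated design property; returns a report of measured quantities.
    """
    config = config or SyntheticConfig()
    problems: list[str] = []
    species_of = dataset.species_map()
    by_species = dataset.specimens_by_species()

    # rDNA: within-species invariance and exact identity structure
    for marker in config.rdna:
        variants: dict[str, set[str]] = {}
        for specimen, rec in dataset.marker_records(marker):
            variants.setdefault(specimen.species, set()).add(rec.degapped())
        allowed_multi = (
            {truth.deep_split_species}
            if marker == "V7" and truth.deep_split_species else set()
        )
        for sp, var in variants.items():
            if len(var) > 1 and sp not in allowed_multi:
                problems.append(f"{marker}: species {sp!r} not invariant")
        seq_to_species: dict[str, set[str]] = {}
        for sp, var in variants.items():
            for v in var:
                seq_to_species.setdefault(v, set()).add(sp)
        observed_groups = sorted(
            sorted(sps) for sps in seq_to_species.values() if len(sps) > 1
        )
        designed = sorted(sorted(g) for g in truth.identity_groups.get(marker, []))
        if observed_groups != designed:
            problems.append(
                f"{marker}: identity groups differ: observed {observed_groups} "
                f"vs designed {designed}"
            )

    # COI: haplotype sharing restricted to the designed pair
    from .distances import encode_rows
    coi_pairs = [(s, r.degapped()) for s, r in dataset.marker_records("COI")]
    ids = [s.specimen_id for s, _ in coi_pairs]
    enc = encode_rows([seq for _, seq in coi_pairs])
    n = len(ids)
    shared = set(truth.shared_haplotype_pair or ())
    deep = truth.deep_split_species
    min_inter = None
    shared_identical_seen = False
    max_intra: dict[str, int] = {}
    for i in range(n):
        diffs = (enc[i] != enc).sum(axis=1)
        for j in range(i + 1, n):
            d = int(diffs[j])
            a, b = species_of[ids[i]], species_of[ids[j]]
            if a == b:
                max_intra[a] = max(max_intra.get(a, 0), d)
                continue
            if {a, b} == shared:
                if d == 0:
                    shared_identical_seen = True
                continue
            if d == 0:
                problems.append(f"COI: undesigned identical pair {a!r}/{b!r}")
            min_inter = d if min_inter is None else min(min_inter, d)
    if truth.shared_haplotype_pair and not shared_identical_seen:
        problems.append("COI: designed shared-haplotype pair shares no haplotype")
    L = config.coi_length
    if min_inter is not None and min_inter < 0.025 * L:
        problems.append(f"COI: minimum interspecific differences {min_inter} too low")
    intra_cap = max(12, int(0.02 * L))
    for sp, d in max_intra.items():
        if sp == deep:
            designed = round((truth.deep_split_divergence or 0) * L)
            if abs(d - designed) > max(8, designed // 3):
                problems.append(
                    f"COI: deep split of {sp!r} is {d} subs, designed ~{designed}"
                )
        elif sp in shared:
            continue
        elif d > intra_cap:
            problems.append(f"COI: intraspecific spread of {sp!r} too high ({d})")

    from .distances import at_content
    at = at_content([seq for _, seq in coi_pairs])
    if n >= 50 and abs(at - config.coi_at_bias) > 0.02:
        problems.append(f"COI: A+T content {at:.3f} off target {config.coi_at_bias}")

    counts = {sp: len(v) for sp, v in by_species.items()}
    bad_counts = {
        sp: c for sp, c in counts.items()
        if not config.specimens_min <= c <= config.specimens_max
    }
    if bad_counts:
        problems.append(f"specimen counts out of range: {bad_counts}")

    if problems:
        raise TruthMismatchError("; ".join(problems))
    return {
        "n_specimens": n,
        "coi_at_content": at,
        "coi_min_interspecific_subs": min_inter,
        "coi_max_intraspecific_subs": max(max_intra.values(), default=0),
    }
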