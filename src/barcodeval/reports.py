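"""End-to-end pipeline orchestration and figure/table data exports.

``run_pipeline`` executes the whole analysis — numt screen, alignments,
distance matrices and summaries, NJ tree with bootstrap, per-marker and
combined resolution, the unresolved-pairs table, indicator-vector
classification, and the sibling-pair haplotype network — and writes every
result as plain data files (TSV/JSON/Newick/FASTA) plus a provenance
manifest.  Figures are left to downstream plotting; the exported tables
carry exactly the numbers a histogram, boxplot, heat map or network drawing
would display.

A note on tree scope: the COI tree is global, while rDNA homology exists
only within genera here, so nuclear trees/distances are computed per genus
and pooled; no global nuclear alignment is attempted.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aligner import (AlignmentParams, align_by_genus, align_coi,
                      concatenate_nuclear)
from .distances import at_content, pairwise_matrix, summarize_divergences
from .errors import ValidationError
from .klee import klee_analysis
from .resolution import (ResolutionCriterion, barcoding_gap, coi_resolution,
                         combined_resolution, deep_split_species,
                         marker_resolution, resolved_count, table1_report)
from .seqio import (NUCLEAR_MARKERS, Dataset, collapse_haplotypes,
                    screen_numts, write_table)
from .sparsnet import build_network, write_network
from .synthdata import SyntheticConfig, SyntheticTruth, generate
from .trees import bootstrap_support, write_newick

logger = logging.getLogger(__name__)


@dataclass
class BoxplotStats:
    """Within-genus interspecific p-distance statistics for one marker.

    The box is drawn at the mean and the 25th/75th percentiles, whiskers at
    the 10th/90th; the median is exported alongside.  Percentiles use
    linear interpolation between order statistics.
    """

    marker: str
    n_pairs: int
    mean: float
    median: float
    p10: float
    p25: float
    p75: float
    p90: float

    def __post_init__(self) -> None:
        if self.n_pairs and not self.p10 <= self.p25 <= self.p75 <= self.p90:
            raise ValidationError(f"{self.marker}: percentile ordering violated")


@dataclass
class PipelineConfig:
    input_dir: str | None = None          # read an existing dataset ...
    simulate: SyntheticConfig | None = None  # ... or generate one
    out_dir: str = "barcodeval_out"
    coi_metric: str = "k2p"
    rdna_metric: str = "p"
    bootstrap_replicates: int = 200
    min_differences: int = 1
    indel_counting: str = "event"
    deep_split_threshold: float = 0.02
    klee_m: int = 1
    klee_rule: str = "first"
    network_confidence: float = 0.95
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SyntheticConfig(**raw["simulate"])
        if "alignment" in raw:
            raw["alignment"] = AlignmentParams(**raw["alignment"])
        return cls(**raw)


def fragment_length_histogram(dataset: Dataset, markers=NUCLEAR_MARKERS,
                              bin_width: int = 10) -> pd.DataFrame:
    """Per-marker fragment-length stats and binned counts (long format)."""
    rows = []
    for marker in markers:
        lengths = [len(rec.degapped()) for _, rec in dataset.marker_records(marker)]
        if not lengths:
            continue
        lengths = np.array(lengths)
        lo = bin_width * (lengths.min() // bin_width)
        hi = bin_width * (lengths.max() // bin_width + 1)
        edges = np.arange(lo, hi + 1, bin_width)
        counts, edges = np.histogram(lengths, bins=edges)
        for c, e0, e1 in zip(counts, edges[:-1], edges[1:]):
            rows.append({
                "marker": marker, "bin_start": int(e0), "bin_end": int(e1),
                "count": int(c), "min": int(lengths.min()),
                "max": int(lengths.max()), "mean": float(lengths.mean()),
            })
    return pd.DataFrame(rows)


def genus_boxplot_stats(
    genus_matrices: dict[str, dict[str, object]],
    species_map: dict[str, str],
) -> dict[str, BoxplotStats]:
    """Pool within-genus heterospecific specimen pairs per marker."""
    out = {}
    for marker, per_genus in genus_matrices.items():
        pool: list[float] = []
        for matrix in per_genus.values():
            labels = matrix.labels
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    if species_map[labels[i]] != species_map[labels[j]]:
                        v = matrix.values[i, j]
                        if not math.isnan(v):
                            pool.append(float(v))
        if not pool:
            continue
        arr = np.array(pool)
        p10, p25, p50, p75, p90 = np.percentile(arr, [10, 25, 50, 75, 90])
        out[marker] = BoxplotStats(
            marker=marker, n_pairs=len(pool), mean=float(arr.mean()),
            median=float(p50), p10=float(p10), p25=float(p25),
            p75=float(p75), p90=float(p90),
        )
    return out


def _resolution_table(resolutions) -> pd.DataFrame:
    rows = []
    for r in resolutions:
        rows.append({
            "species": r.species, "marker": r.marker,
            "resolved": int(r.resolved),
            "confusions": "; ".join(
                f"{c.other_species} ({c.evidence}"
                + ("" if c.evidence == "identical sequences"
                   else f": {c.n_differences}") + ")"
                for c in r.confusions
            ),
        })
    return pd.DataFrame(rows, columns=["species", "marker", "resolved", "confusions"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute align → dist → tree → resolve → klee → network → report.

    Returns the headline numbers; writes all artefacts under ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth: SyntheticTruth | None = None
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.simulate.seed or config.seed)
        dataset, truth = generate(sim)
        dataset.write(out / "dataset")
        truth.to_json(out / "dataset" / "truth.json")
    elif config.input_dir is not None:
        dataset = Dataset.read(config.input_dir)
    else:
        raise ValidationError("pipeline config needs input_dir or simulate")

    results: dict[str, object] = {
        "n_species": len(dataset.species),
        "n_specimens": len(dataset.specimens),
    }
    criterion = ResolutionCriterion(
        min_differences=config.min_differences,
        indel_counting=config.indel_counting,
    )

    # numt screen -----------------------------------------------------------
    coi_records = [rec for _, rec in dataset.marker_records("COI")]
    numt = screen_numts(coi_records)
    write_table(pd.DataFrame([dataclasses.asdict(r) for r in numt]),
                out / "numt_screen.tsv")
    results["numt_flagged"] = sum(r.internal_stop_found for r in numt)

    # COI alignment, distances, composition ---------------------------------
    coi_aln = align_coi(
        [(s.specimen_id, rec.degapped()) for s, rec in dataset.marker_records("COI")]
    )
    species_map = dataset.species_map()
    coi_k2p = pairwise_matrix(coi_aln, config.coi_metric)
    coi_p = pairwise_matrix(coi_aln, "p")
    results["coi_mean_at"] = at_content([r.degapped() for r in coi_records])
    summaries = summarize_divergences(coi_k2p, species_map, level="species")
    inter = summaries.get("interspecific")
    intra = summaries.get("intraspecific")
    results["coi_mean_interspecific"] = inter.mean if inter else math.nan
    results["coi_min_interspecific"] = inter.minimum if inter else math.nan
    results["coi_max_intraspecific"] = intra.maximum if intra else math.nan
    # lowest distance between species that do not share haplotypes
    pair_lows = [lo for lo, _ in
                 summaries["species-level"].pair_ranges.values() if lo > 0]
    results["coi_min_interspecific_distinct"] = (
        min(pair_lows) if pair_lows else math.nan
    )
    hist = pd.DataFrame({
        "bin_start": inter.histogram_edges[:-1],
        "bin_end": inter.histogram_edges[1:],
        "count": inter.histogram_counts,
    }) if inter else pd.DataFrame()
    write_table(hist, out / "coi_interspecific_histogram.tsv")

    # COI NJ tree with bootstrap --------------------------------------------
    tree, skipped = bootstrap_support(
        coi_aln, config.coi_metric, config.bootstrap_replicates, config.seed
    )
    write_newick(tree, out / "coi_nj.nwk")
    results["bootstrap_replicates"] = config.bootstrap_replicates
    results["bootstrap_skipped"] = skipped

    # rDNA alignments, per-genus distances ----------------------------------
    rdna_alignments = {}
    genus_matrices: dict[str, dict[str, object]] = {}
    for marker in NUCLEAR_MARKERS:
        if marker not in dataset.sequences:
            continue
        rdna_alignments[marker] = align_by_genus(dataset, marker, config.alignment)
        genus_matrices[marker] = {
            genus: pairwise_matrix(aln, config.rdna_metric)
            for genus, aln in rdna_alignments[marker].items()
            if len(aln.rows) >= 2
        }
    box = genus_boxplot_stats(genus_matrices, species_map)
    write_table(pd.DataFrame([dataclasses.asdict(b) for b in box.values()]),
                out / "rdna_boxplot_stats.tsv")
    for marker, stats in box.items():
        results[f"{marker.lower()}_mean_within_genus_p"] = stats.mean
    frag = fragment_length_histogram(dataset)
    write_table(frag, out / "fragment_lengths.tsv")
    for marker in NUCLEAR_MARKERS:
        sub = frag[frag["marker"] == marker]
        if len(sub):
            results[f"{marker.lower()}_mean_length"] = float(sub["mean"].iloc[0])
            results[f"{marker.lower()}_min_length"] = int(sub["min"].iloc[0])
            results[f"{marker.lower()}_max_length"] = int(sub["max"].iloc[0])

    # resolution -------------------------------------------------------------
    rdna_res = {
        m: marker_resolution(dataset, m, rdna_alignments.get(m), criterion)
        for m in rdna_alignments
    }
    combined_res = combined_resolution(dataset, rdna_alignments, criterion)
    coi_res = coi_resolution(dataset, coi_aln, criterion)
    all_res = [r for rs in rdna_res.values() for r in rs] + combined_res + coi_res
    write_table(_resolution_table(all_res), out / "resolution.tsv")
    for m, rs in rdna_res.items():
        results[f"{m.lower()}_resolved"], results[f"{m.lower()}_total"] = resolved_count(rs)
    results["combined_resolved"], results["combined_total"] = resolved_count(combined_res)
    results["coi_resolved"], results["coi_total"] = resolved_count(coi_res)

    t1 = table1_report(dataset, coi_k2p, rdna_alignments, coi_res, rdna_res,
                       combined_res, criterion, config.alignment)
    write_table(t1, out / "unresolved_pairs.tsv")
    results["n_unresolved_pairs"] = len(t1)

    gap = barcoding_gap(coi_k2p, species_map)
    write_table(gap.per_species, out / "barcoding_gap.tsv")
    results["barcoding_gap_overlap"] = gap.overlap
    deep = deep_split_species(coi_k2p, species_map, config.deep_split_threshold)
    results["deep_split_species"] = deep

    # Klee classification ----------------------------------------------------
    klee = klee_analysis(dataset, coi_aln, config.klee_m, config.klee_rule,
                         config.seed)
    klee.correlations.to_csv(out / "klee_correlations.tsv", sep="\t")
    write_table(pd.DataFrame([
        {"test_id": t, "assigned": a or "", "true": klee.true_species[t],
         "correct": int(a == klee.true_species[t])}
        for t, a in klee.assignments.items()
    ]), out / "klee_assignments.tsv")
    results["klee_accuracy"] = klee.accuracy
    results["klee_n_test"] = klee.n_test
    results["klee_n_correct"] = klee.n_correct

    # haplotype network for the closest sibling pair -------------------------
    if truth is not None and truth.shared_haplotype_pair:
        pair = truth.shared_haplotype_pair
    else:
        pair = min(
            summaries["species-level"].pair_ranges.items(),
            key=lambda kv: kv[1][0],
        )[0]
    pair_specimens = [s for s in dataset.specimens if s.species in pair]
    pair_records = [
        dataset.sequences["COI"][s.sequences["COI"]]
        for s in pair_specimens if "COI" in s.sequences
    ]
    haplotypes = collapse_haplotypes(pair_records, pair_specimens)
    network = build_network(haplotypes, config.network_confidence)
    write_network(network, out / "network_nodes.tsv", out / "network_edges.tsv")
    results["network_pair"] = list(pair)
    results["network_components"] = len(network.components)
    results["network_connection_limit"] = network.connection_limit
    results["network_n_haplotypes"] = len(haplotypes)

    manifest = {
        "package": "barcodeval",
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "results": json.loads(json.dumps(results, default=str)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("pipeline complete: %s", out)
    return results
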