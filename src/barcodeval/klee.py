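"""Indicator-vector (Klee) classification of COI sequences.

Each aligned sequence of length L maps to a numeric vector of length 4L:
per column, four slots in the order A, C, G, T, set to 1 for the observed
base and 0 otherwise (gaps and ambiguity codes contribute an all-zero
block by default; a fractional policy splits ambiguity codes evenly over
their bases).  One reference vector per species (M sequences averaged,
M = 1 by default) spans the reference set; every remaining sequence is a
test sequence and is assigned to the species whose reference vector it
correlates with most strongly (Pearson).  The full correlation matrix is
the data behind the false-colour Klee diagram.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .seqio import Dataset

logger = logging.getLogger(__name__)

_SLOT = {"A": 0, "C": 1, "G": 2, "T": 3}
_IUPAC_SETS = {
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class KleeResult:
    correlations: pd.DataFrame  # test sequence ids × species
    assignments: dict[str, str | None]
    true_species: dict[str, str]
    accuracy: float
    species_order: list[str]
    reference_ids: dict[str, list[str]]
    n_ties: int = 0

    @property
    def n_test(self) -> int:
        return len(self.assignments)

    @property
    def n_correct(self) -> int:
        return sum(
            1 for t, a in self.assignments.items() if a == self.true_species[t]
        )


def encode(row: str, policy: str = "zero") -> np.ndarray:
    """Indicator vector of one aligned row (length 4L)."""
    out = np.zeros(4 * len(row))
    for i, ch in enumerate(row):
        k = _SLOT.get(ch)
        if k is not None:
            out[4 * i + k] = 1.0
        elif policy == "fractional" and ch in _IUPAC_SETS:
            bases = _IUPAC_SETS[ch]
            for b in bases:
                out[4 * i + _SLOT[b]] = 1.0 / len(bases)
    return out


def encode_batch(rows: list[str], policy: str = "zero") -> np.ndarray:
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValidationError(f"encode_batch: unequal row lengths {sorted(lengths)}")
    return np.stack([encode(r, policy) for r in rows])


def correlate(x: np.ndarray, y: np.ndarray, centered: bool = True) -> float:
    """Pearson correlation of two indicator vectors (NaN if degenerate)."""
    if x.shape != y.shape:
        raise ValidationError("correlate: unequal vector lengths")
    if centered:
        x = x - x.mean()
        y = y - y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        return math.nan
    return float(np.dot(x, y) / (nx * ny))


def build_reference_vectors(
    dataset: Dataset,
    alignment,
    M: int = 1,
    selection_rule: str = "first",
    seed: int | None = None,
    policy: str = "zero",
) -> tuple[dict[str, np.ndarray], dict[str, list[str]], list[tuple[str, str]]]:
    """Choose M reference sequences per species and average their encodings.

    Returns (species → reference vector, species → reference specimen ids,
    remaining (specimen_id, species) test set).  ``selection_rule`` is
    ``"first"`` (lowest specimen id, deterministic) or ``"random"`` (seeded).
    """
    species_rows: dict[str, list[tuple[str, str]]] = {}
    species_of = dataset.species_map()
    for rid, row in alignment.rows:
        species_rows.setdefault(species_of[rid], []).append((rid, row))

    short = [sp for sp, rows in species_rows.items() if len(rows) < M]
    if short:
        raise ValidationError(f"species with fewer than M={M} sequences: {sorted(short)}")

    rng = np.random.default_rng(seed)
    refs: dict[str, np.ndarray] = {}
    ref_ids: dict[str, list[str]] = {}
    test: list[tuple[str, str]] = []
    for sp, rows in species_rows.items():
        rows = sorted(rows)
        if selection_rule == "first":
            chosen = rows[:M]
        elif selection_rule == "random":
            idx = sorted(rng.choice(len(rows), size=M, replace=False))
            chosen = [rows[i] for i in idx]
        else:
            raise ValidationError(f"unknown selection_rule {selection_rule!r}")
        chosen_ids = {rid for rid, _ in chosen}
        refs[sp] = encode_batch([r for _, r in chosen], policy).mean(axis=0)
        ref_ids[sp] = sorted(chosen_ids)
        test.extend((rid, sp) for rid, _ in rows if rid not in chosen_ids)
    return refs, ref_ids, test


def classify(
    test_vectors: dict[str, np.ndarray],
    references: dict[str, np.ndarray],
    true_species: dict[str, str],
    species_order: list[str] | None = None,
    centered: bool = True,
) -> KleeResult:
    """Assign each test vector to the species of maximum correlation.

    Ties go to the lexicographically first species (and are counted);
    all-undefined rows stay unassigned and score as incorrect.
    """
    if not references:
        raise ValidationError("classify: no reference vectors")
    order = species_order or sorted(references)
    ref_mat = np.stack([references[sp] for sp in order])
    test_ids = list(test_vectors)
    test_mat = np.stack([test_vectors[t] for t in test_ids])

    tc = test_mat - test_mat.mean(axis=1, keepdims=True) if centered else test_mat
    rc = ref_mat - ref_mat.mean(axis=1, keepdims=True) if centered else ref_mat
    tn = np.linalg.norm(tc, axis=1)
    rn = np.linalg.norm(rc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (tc @ rc.T) / np.outer(tn, rn)
    corr[:, rn == 0.0] = np.nan
    corr[tn == 0.0, :] = np.nan

    assignments: dict[str, str | None] = {}
    n_ties = 0
    for r, tid in enumerate(test_ids):
        row = corr[r]
        if np.isnan(row).all():
            assignments[tid] = None
            continue
        best = np.nanmax(row)
        winners = [order[k] for k in range(len(order)) if row[k] == best]
        if len(winners) > 1:
            n_ties += 1
        assignments[tid] = sorted(winners)[0]
    if n_ties:
        logger.info("classify: %d argmax ties broken lexicographically", n_ties)

    correct = sum(1 for t, a in assignments.items() if a == true_species[t])
    accuracy = correct / len(test_ids) if test_ids else math.nan
    return KleeResult(
        correlations=pd.DataFrame(corr, index=test_ids, columns=order),
        assignments=assignments,
        true_species=dict(true_species),
        accuracy=accuracy,
        species_order=order,
        reference_ids={},
        n_ties=n_ties,
    )


def klee_analysis(
    dataset: Dataset,
    alignment,
    M: int = 1,
    selection_rule: str = "first",
    seed: int | None = None,
    species_order: list[str] | None = None,
    policy: str = "zero",
    centered: bool = True,
) -> KleeResult:
    """Reference selection, encoding and max-correlation classification."""
    refs, ref_ids, test = build_reference_vectors(
        dataset, alignment, M, selection_rule, seed, policy
    )
    row_of = dict(alignment.rows)
    test_vectors = {rid: encode(row_of[rid], policy) for rid, _ in test}
    result = classify(
        test_vectors, refs, dict(test), species_order, centered=centered
    )
    result.reference_ids = ref_ids
    return result


def mean_accuracy_over_draws(
    dataset: Dataset,
    alignment,
    M: int = 1,
    draws: int = 10,
    seed: int = 0,
) -> float:
    """Mean classification accuracy over seeded random reference draws."""
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(draws):
        sub = int(rng.integers(0, 2**31 - 1))
        accs.append(
            klee_analysis(dataset, alignment, M, "random", sub).accuracy
        )
    return float(np.mean(accs))
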