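"""Statistical-parsimony haplotype networks (TCS-style).

Distinct haplotypes are connected in order of increasing mutational
distance; a pair k > 1 steps apart is joined through k − 1 inferred
intermediate nodes, and pairs beyond the parsimony connection limit stay in
separate components.  Every edge represents exactly one mutational change.

The connection limit is the largest number of steps whose probability of
parsimony still exceeds the confidence level (default 95%).  The estimate
implemented here models the number of mutations per site as Poisson with
rate fitted by a Jukes-Cantor correction of the observed difference
fraction, and asks that no site mutated more than once, conditional on the
observed pattern: for two sequences differing at j of m sites,

    lambda = -(3/4) * ln(1 - 4j/(3m))
    a = P(one hit | site differs)  = lambda*e^-lambda / ((3/4)(1-e^(-4*lambda/3)))
    b = P(no hit  | site matches)  = e^-lambda / (1/4 + (3/4) e^(-4*lambda/3))
    P_parsimony(j, m) = a^j * b^(m-j)

which is monotone non-increasing in j, non-decreasing in m, and gives the
familiar single-digit-percent step limits for barcode-length fragments.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .errors import NetworkError
from .seqio import Haplotype

logger = logging.getLogger(__name__)

_BASES = set("ACGT")


def mutational_distance(a: str, b: str) -> int:
    """Hamming distance over unambiguous columns of two equal-length
    gap-free haplotypes; ambiguity codes are treated as missing."""
    if len(a) != len(b):
        raise NetworkError(f"length mismatch: {len(a)} vs {len(b)}")
    skipped = 0
    d = 0
    for x, y in zip(a, b):
        if x in _BASES and y in _BASES:
            if x != y:
                d += 1
        else:
            skipped += 1
    if skipped:
        logger.debug("mutational_distance: %d ambiguous columns ignored", skipped)
    return d


def parsimony_probability(j: int, m: int, *, _exp=math.exp, _log=math.log) -> float:
    """Probability that j observed differences over m sites are parsimonious."""
    if j == 0:
        return 1.0
    if j < 0 or m < 1 or j > m:
        raise NetworkError(f"invalid (j={j}, m={m})")
    frac = 4.0 * j / (3.0 * m)
    if frac >= 1.0:
        return 0.0
    lam = -0.75 * _log(1.0 - frac)
    e_l = _exp(-lam)
    e_43 = _exp(-4.0 * lam / 3.0)
    a = (lam * e_l) / (0.75 * (1.0 - e_43))
    b = e_l / (0.25 + 0.75 * e_43)
    return (a ** j) * (b ** (m - j))


def parsimony_limit(sequence_length: int, confidence: float = 0.95) -> int:
    """Largest step count whose parsimony probability exceeds ``confidence``."""
    if sequence_length < 1:
        raise NetworkError("sequence_length must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise NetworkError("confidence must be in (0, 1)")
    limit = 0
    for j in range(1, sequence_length + 1):
        if parsimony_probability(j, sequence_length) > confidence:
            limit = j
        else:
            break
    return limit


@dataclass
class HaplotypeNetwork:
    """Single-mutation haplotype graph with inferred intermediates.

    Observed nodes are named ``H0, H1, ...`` in input order and carry
    ``count`` and ``species_counts``; inferred nodes are ``x0, x1, ...``
    with count 0.
    """

    graph: nx.Graph
    connection_limit: int
    haplotypes: list[Haplotype] = field(default_factory=list)

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["inferred"]]

    @property
    def inferred_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["inferred"]]


def build_network(
    haplotypes: list[Haplotype] | list[str],
    confidence: float = 0.95,
    connection_limit: int | None = None,
) -> HaplotypeNetwork:
    """Connect distinct haplotypes up to the parsimony connection limit.

    Pairs are processed in order of increasing mutational distance (ties by
    input index); a pair already reachable by a path no longer than its
    distance is left as is, otherwise a chain of distance − 1 inferred
    intermediates joins it.
    """
    if not haplotypes:
        raise NetworkError("build_network: no haplotypes")
    haps = [
        h if isinstance(h, Haplotype)
        else Haplotype(residues=h, members=[f"seq{i}"], species_counts={"?": 1})
        for i, h in enumerate(haplotypes)
    ]
    seqs = [h.residues for h in haps]
    if len(set(seqs)) != len(seqs):
        raise NetworkError("build_network: haplotypes must be distinct")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise NetworkError(f"build_network: unequal lengths {sorted(lengths)}")
    m = lengths.pop()
    limit = parsimony_limit(m, confidence) if connection_limit is None else connection_limit

    g = nx.Graph()
    for i, h in enumerate(haps):
        g.add_node(
            f"H{i}", inferred=False, count=len(h.members),
            species_counts=dict(h.species_counts),
        )
    pairs = sorted(
        ((mutational_distance(seqs[i], seqs[j]), i, j)
         for i, j in itertools.combinations(range(len(seqs)), 2)),
    )
    n_inferred = 0
    for d, i, j in pairs:
        if d > limit:
            continue
        a, b = f"H{i}", f"H{j}"
        try:
            if nx.shortest_path_length(g, a, b) <= d:
                continue
        except nx.NetworkXNoPath:
            pass
        prev = a
        for _ in range(d - 1):
            node = f"x{n_inferred}"
            n_inferred += 1
            g.add_node(node, inferred=True, count=0, species_counts={})
            g.add_edge(prev, node)
            prev = node
        g.add_edge(prev, b)
    return HaplotypeNetwork(graph=g, connection_limit=limit, haplotypes=haps)


def write_network(network: HaplotypeNetwork, nodes_path, edges_path) -> None:
    """Tab-separated node attributes and edge list."""
    import pandas as pd

    node_rows = [
        {
            "node": n,
            "inferred": int(d["inferred"]),
            "count": d["count"],
            "species_counts": ";".join(
                f"{sp}:{c}" for sp, c in sorted(d["species_counts"].items())
            ),
        }
        for n, d in network.graph.nodes(data=True)
    ]
    pd.DataFrame(node_rows).to_csv(nodes_path, sep="\t", index=False)
    edge_rows = [{"source": u, "target": v} for u, v in network.graph.edges()]
    pd.DataFrame(edge_rows, columns=["source", "target"]).to_csv(
        edges_path, sep="\t", index=False
    )
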