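"""Reciprocal-best-hit graph construction and ortholog-cluster formation.

Proteins of different genomes are connected when each is the other's top
scoring hit (a reciprocal best hit, RBH).  Clusters are groups with exactly
one member per genome whose induced RBH subgraph is well connected: at
least two members linked to all other members, and every member linked to
all but at most one.  For the canonical four-genome case that is the quad
rule "(>= 2 nodes of degree 3, minimum degree 2)".

The degree rule generalises to G genomes as (>= 2 members of degree G-1,
all members of degree >= G-2); at G = 4 it reduces to the quad rule.
Overlapping candidate groups within a connected component are resolved by a
deterministic greedy: candidates are accepted in order of induced edge
count (descending), summed edge score (descending), then lexicographic
member ids, subject to member disjointness.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx

from .sequence_io import SimilarityHit

logger = logging.getLogger(__name__)

#: Enumeration guard: components whose one-per-genome candidate product
#: exceeds this are truncated (logged); RBH degree limits keep real
#: components far below it.
MAX_CANDIDATES_PER_COMPONENT = 100_000


@dataclass
class COGCluster:
    """One ortholog cluster: exactly one protein per genome."""

    cluster_id: str
    members: dict[str, str]  # genome_id -> protein_id
    n_edges: int
    total_score: float

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.members.values()))


def best_hit_map(hits: list[SimilarityHit]) -> dict[str, str]:
    """Top subject per query: best bitscore, ties by lower e-value then
    lexicographic subject id.  Queries without hits are absent."""
    best: dict[str, SimilarityHit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None or (-hit.bitscore, hit.evalue, hit.subject_id) < (
            -cur.bitscore,
            cur.evalue,
            cur.subject_id,
        ):
            best[hit.query_id] = hit
    return {q: h.subject_id for q, h in best.items()}


def reciprocal_best_hits(
    map_ab: dict[str, str], map_ba: dict[str, str]
) -> list[tuple[str, str]]:
    """Edges (a, b) with map_ab[a] == b and map_ba[b] == a, deduplicated."""
    return [(a, b) for a, b in map_ab.items() if map_ba.get(b) == a]


def build_rbh_graph(
    genomes: dict[str, list[str]],
    hit_tables: dict[tuple[str, str], list[SimilarityHit]],
    bitscores: dict[tuple[str, str], float] | None = None,
) -> nx.Graph:
    """Union of reciprocal best hits over all unordered genome pairs.

    ``genomes`` maps genome id to its protein ids (defining node tags);
    ``hit_tables`` must contain every ordered genome pair.  Edge attribute
    ``score`` is the mean bitscore of the two supporting hits.
    """
    graph = nx.Graph()
    genome_of: dict[str, str] = {}
    for gid, prot_ids in genomes.items():
        for pid in prot_ids:
            if pid in genome_of:
                raise ValueError(f"protein id {pid!r} appears in more than one genome")
            genome_of[pid] = gid
            graph.add_node(pid, genome=gid)
    order = list(genomes)
    for ga, gb in itertools.combinations(order, 2):
        for pair in ((ga, gb), (gb, ga)):
            if pair not in hit_tables:
                raise ValueError(f"missing hit table for genome pair {pair[0]} vs {pair[1]}")
        score_of: dict[tuple[str, str], float] = {}
        for pair in ((ga, gb), (gb, ga)):
            for hit in hit_tables[pair]:
                key = (hit.query_id, hit.subject_id)
                if key not in score_of or hit.bitscore > score_of[key]:
                    score_of[key] = hit.bitscore
        m_ab = best_hit_map(hit_tables[(ga, gb)])
        m_ba = best_hit_map(hit_tables[(gb, ga)])
        for a, b in reciprocal_best_hits(m_ab, m_ba):
            mean_score = 0.5 * (score_of[(a, b)] + score_of[(b, a)])
            graph.add_edge(a, b, score=mean_score)
    return graph


def quad_valid(members: list[str], graph: nx.Graph, n_genomes: int = 4) -> bool:
    """Connectivity rule for a candidate one-per-genome group.

    True iff, in the induced subgraph, at least two members have degree
    ``n_genomes - 1`` (connected to every other member) and every member
    has degree at least ``n_genomes - 2``.
    """
    if len(members) != n_genomes:
        raise ValueError(f"expected {n_genomes} members, got {len(members)}")
    genomes = [graph.nodes[m]["genome"] for m in members]
    if len(set(genomes)) != n_genomes:
        raise ValueError("members must come from distinct genomes")
    sub = graph.subgraph(members)
    degrees = [sub.degree(m) for m in members]
    return sum(d == n_genomes - 1 for d in degrees) >= 2 and min(degrees) >= n_genomes - 2


def _candidate_key(members: tuple[str, ...], graph: nx.Graph) -> tuple:
    sub = graph.subgraph(members)
    n_edges = sub.number_of_edges()
    total = sum(d["score"] for _, _, d in sub.edges(data=True))
    return (-n_edges, -total, tuple(sorted(members)))


def form_clusters(graph: nx.Graph, n_genomes: int = 4) -> list[COGCluster]:
    """Enumerate valid one-per-genome groups and accept them greedily.

    Within each connected component every one-per-genome combination is
    tested against :func:`quad_valid`; valid candidates across the whole
    graph are ranked by (induced edge count desc, summed edge score desc,
    lexicographic member ids) and accepted subject to member disjointness.
    """
    candidates: list[tuple[tuple, tuple[str, ...]]] = []
    for component in nx.connected_components(graph):
        by_genome: dict[str, list[str]] = {}
        for node in component:
            by_genome.setdefault(graph.nodes[node]["genome"], []).append(node)
        if len(by_genome) < n_genomes:
            continue
        pools = [sorted(by_genome[g]) for g in sorted(by_genome)]
        n_combos = 1
        for pool in pools:
            n_combos *= len(pool)
        if n_combos > MAX_CANDIDATES_PER_COMPONENT:
            logger.warning(
                "component with %d nodes yields %d candidate groups; truncating",
                len(component),
                n_combos,
            )
        produced = 0
        found = False
        for combo in itertools.product(*pools):
            produced += 1
            if produced > MAX_CANDIDATES_PER_COMPONENT:
                break
            if quad_valid(list(combo), graph, n_genomes):
                candidates.append((_candidate_key(combo, graph), combo))
                found = True
        if not found:
            logger.info("component of %d nodes yields no valid cluster", len(component))
    candidates.sort(key=lambda item: item[0])
    used: set[str] = set()
    clusters: list[COGCluster] = []
    for key, combo in candidates:
        if any(m in used for m in combo):
            continue
        used.update(combo)
        members = {graph.nodes[m]["genome"]: m for m in combo}
        clusters.append(
            COGCluster(
                cluster_id=f"COG{len(clusters) + 1:05d}",
                members=members,
                n_edges=-key[0],
                total_score=-key[1],
            )
        )
    return clusters


def write_clusters(
    clusters: list[COGCluster], genome_order: list[str], path
) -> None:
    """TSV: cluster_id then one member column per genome (in given order)."""
    with open(path, "w") as fh:
        fh.write("cluster_id\t" + "\t".join(genome_order) + "\n")
        for cl in clusters:
            fh.write(
                cl.cluster_id
                + "\t"
                + "\t".join(cl.members.get(g, "-") for g in genome_order)
                + "\n"
            )
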