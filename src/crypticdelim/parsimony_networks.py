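"""Statistical-parsimony haplotype network membership.

Identical sequences are collapsed into haplotypes; haplotypes within the
parsimony connection limit (a maximum number of mutational steps) are
joined; the connected components of that graph are the "networks".
Gaps count as a fifth character state, so a base-vs-gap column is one
step; positions missing in either sequence contribute nothing.

The connection limit is derived from a probability-of-parsimony model
in the tradition of Templeton, Crandall & Sing (1992): for two sequences
of length L differing at j sites, the per-site number of substitutions
along the connecting path is modelled as Poisson with mean
lambda = -ln(1 - j/L) (the divergence that would produce a fraction j/L
of visibly different sites if any hit changes the site), and the
probability that a differing site experienced exactly one hit is
lambda e^-lambda / (1 - e^-lambda).  The probability that a j-step
connection is fully parsimonious is that quantity to the j-th power,
and the connection limit j_max is the largest j whose probability still
meets the chosen limit (98% for slow loci here, 90% for the fast one).
A ``fixed_steps`` override bypasses the model entirely.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import alphabet
from .distances import Partition
from .io_formats import Alignment


# ---------------------------------------------------------------------------
# Haplotype collapsing
# ---------------------------------------------------------------------------

@dataclass
class Haplotype:
    hap_id: str
    sequence: str          # representative: member with most resolved sites
    members: list[str]

    @property
    def multiplicity(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeSet:
    locus: str
    columns: int
    haplotypes: list[Haplotype]

    @property
    def specimen_to_hap(self) -> dict[str, str]:
        return {m: h.hap_id for h in self.haplotypes for m in h.members}

    def by_id(self, hap_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.hap_id == hap_id:
                return h
        raise KeyError(hap_id)


def _rows_match(chars_a, chars_b, miss_a, miss_b) -> bool:
    return bool(np.all(miss_a | miss_b | (chars_a == chars_b)))


def collapse_haplotypes(aln: Alignment,
                        missing_matches_any: bool = True) -> HaplotypeSet:
    """Merge identical sequences into haplotypes.

    Under the default policy a missing position matches any state, so a
    partial sequence joins the haplotype(s) it is compatible with; the
    match relation is closed transitively (connected components), since
    wildcard matching alone is not transitive.  Gap is a real state and
    must match exactly; ambiguity codes must match literally.
    """
    n = aln.n_specimens
    chars = aln.states
    miss = aln.masks == 0
    if not missing_matches_any:
        miss = np.zeros_like(miss)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n - 1):
        for j in range(i + 1, n):
            ri, rj = find(i), find(j)
            if ri == rj:
                continue
            if _rows_match(chars[i], chars[j], miss[i], miss[j]):
                parent[max(ri, rj)] = min(ri, rj)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    haplotypes = []
    resolved_counts = (~miss).sum(axis=1)
    for k, root in enumerate(sorted(clusters), start=1):
        members = clusters[root]
        rep = max(members, key=lambda i: (resolved_counts[i], -i))
        haplotypes.append(Haplotype(
            hap_id=f"H{k}",
            sequence="".join(chars[rep]),
            members=[aln.specimen_ids[i] for i in members]))
    return HaplotypeSet(aln.locus_name, aln.columns, haplotypes)


# ---------------------------------------------------------------------------
# Step distance (gaps as fifth state)
# ---------------------------------------------------------------------------

def step_distance(seq_a: str, seq_b: str) -> int:
    """Mutational steps between two aligned sequences.

    Counts columns whose states differ, with ``-`` as a fifth state
    (base vs gap = 1 step, gap vs gap = 0); columns missing in either
    sequence are excluded; overlapping ambiguity codes do not count as
    a step.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    ma = alphabet.masks(np.array(list(seq_a), dtype="<U1"))
    mb = alphabet.masks(np.array(list(seq_b), dtype="<U1"))
    both = (ma > 0) & (mb > 0)
    return int((both & ((ma & mb) == 0)).sum())


# ---------------------------------------------------------------------------
# Connection limit
# ---------------------------------------------------------------------------

@dataclass
class ConnectionLimit:
    length: int
    prob_limit: float
    j_max: int
    probs: list[float]   # P_1 .. P_{j_max + 1}, for audit


def parsimony_probability(length: int, j: int) -> float:
    """Probability that a connection of ``j`` steps is fully parsimonious
    for sequences of ``length`` sites (see module docstring)."""
    if j == 0:
        return 1.0
    if j >= length:
        return 0.0
    p = j / length
    lam = -math.log1p(-p)
    single = lam * math.exp(-lam) / (-math.expm1(-lam))
    return single ** j


def connection_limit_steps(length: int, prob_limit: float) -> ConnectionLimit:
    """Largest step count whose parsimony probability meets ``prob_limit``."""
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    if not 0 < prob_limit < 1:
        raise ValueError("prob_limit must be in (0, 1)")
    probs: list[float] = []
    j = 0
    while True:
        p_next = parsimony_probability(length, j + 1)
        probs.append(p_next)
        if p_next < prob_limit:
            break
        j += 1
    return ConnectionLimit(length, prob_limit, j, probs)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeNetworkSet:
    """Connected components of haplotypes under a connection limit.

    Each component is one "network"; singleton haplotypes count as
    networks of their own.  ``step_matrix`` holds all pairwise step
    distances between haplotypes (by list position in ``haplotypes``).
    """

    locus: str
    haplotypes: HaplotypeSet
    limit: ConnectionLimit
    components: list[list[str]]          # lists of hap ids
    step_matrix: np.ndarray

    @property
    def n_networks(self) -> int:
        return len(self.components)

    def component_of(self, hap_id: str) -> int:
        for k, comp in enumerate(self.components):
            if hap_id in comp:
                return k
        raise KeyError(hap_id)

    def steps(self, hap_a: str, hap_b: str) -> int:
        ids = [h.hap_id for h in self.haplotypes.haplotypes]
        return int(self.step_matrix[ids.index(hap_a), ids.index(hap_b)])


def build_networks(haps: HaplotypeSet,
                   limit: ConnectionLimit | None = None,
                   fixed_steps: int | None = None) -> HaplotypeNetworkSet:
    """Join haplotypes within the connection limit; enumerate components."""
    if (limit is None) == (fixed_steps is None):
        raise ValueError("provide exactly one of limit or fixed_steps")
    if fixed_steps is not None:
        limit = ConnectionLimit(haps.columns, float("nan"),
                                int(fixed_steps), [])
    k = len(haps.haplotypes)
    steps = np.zeros((k, k), dtype=np.int64)
    seqs = [h.sequence for h in haps.haplotypes]
    for i in range(k - 1):
        for j in range(i + 1, k):
            d = step_distance(seqs[i], seqs[j])
            steps[i, j] = steps[j, i] = d
    graph = nx.Graph()
    hap_ids = [h.hap_id for h in haps.haplotypes]
    graph.add_nodes_from(hap_ids)
    for i in range(k - 1):
        for j in range(i + 1, k):
            if steps[i, j] <= limit.j_max:
                graph.add_edge(hap_ids[i], hap_ids[j],
                               steps=int(steps[i, j]))
    comps = [sorted(c, key=hap_ids.index)
             for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), hap_ids.index(c[0])))
    return HaplotypeNetworkSet(haps.locus, haps, limit, comps, steps)


@dataclass
class SeparationReport:
    """Whether a group occupies haplotype networks exclusively.

    ``n_networks_spanned`` > 1 with ``is_separate`` True is the
    "recovered in more than one network" (asterisk) case;
    ``min_steps_to_nonmember`` is reported when a network is shared with
    non-members (0 when they share a haplotype).
    """

    group: str
    locus: str
    has_data: bool
    is_separate: bool = False
    n_networks_spanned: int = 0
    min_steps_to_nonmember: int | None = None


def network_separation(nets: HaplotypeNetworkSet, partition: Partition,
                       group: str) -> SeparationReport:
    """Assess whether ``group`` is separated from all other *partitioned*
    specimens; specimens carrying no group assignment (e.g. excluded
    from discovery at another locus) are neutral, not counter-evidence."""
    hap_ids = [h.hap_id for h in nets.haplotypes.haplotypes]
    members = {s for s, g in partition.items() if g == group}
    foreign = {s for s, g in partition.items() if g != group}
    hap_members: dict[str, set[str]] = {
        h.hap_id: set(h.members) for h in nets.haplotypes.haplotypes}
    member_haps = [h for h in hap_ids if hap_members[h] & members]
    if not member_haps:
        return SeparationReport(group, nets.locus, has_data=False)
    nonmember_haps = {h for h in hap_ids if hap_members[h] & foreign}
    spanned = sorted({nets.component_of(h) for h in member_haps})
    min_steps: int | None = None
    for ci in spanned:
        comp = set(nets.components[ci])
        shared_nonmembers = comp & nonmember_haps
        if not shared_nonmembers:
            continue
        for hm in member_haps:
            if hm not in comp:
                continue
            if hap_members[hm] & foreign:
                min_steps = 0
            for hn in shared_nonmembers:
                d = nets.steps(hm, hn) if hn != hm else 0
                if min_steps is None or d < min_steps:
                    min_steps = d
    return SeparationReport(group, nets.locus, has_data=True,
                            is_separate=min_steps is None,
                            n_networks_spanned=len(spanned),
                            min_steps_to_nonmember=min_steps)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_membership_tsv(nets: HaplotypeNetworkSet,
                         path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tnetwork_id\thaplotype_id\tspecimen_ids\n")
        for k, comp in enumerate(nets.components, start=1):
            for hap_id in comp:
                members = ",".join(nets.haplotypes.by_id(hap_id).members)
                fh.write(f"{nets.locus}\tN{k}\t{hap_id}\t{members}\n")


def export_graph(nets: HaplotypeNetworkSet, path: str | os.PathLike,
                 fmt: str = "graphml") -> None:
    graph = nx.Graph()
    for h in nets.haplotypes.haplotypes:
        graph.add_node(h.hap_id, multiplicity=h.multiplicity,
                       members=",".join(h.members))
    hap_ids = [h.hap_id for h in nets.haplotypes.haplotypes]
    for i in range(len(hap_ids) - 1):
        for j in range(i + 1, len(hap_ids)):
            if nets.step_matrix[i, j] <= nets.limit.j_max:
                graph.add_edge(hap_ids[i], hap_ids[j],
                               steps=int(nets.step_matrix[i, j]))
    if fmt == "graphml":
        nx.write_graphml(graph, os.fspath(path))
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write("graph networks {\n")
            for nd in graph.nodes:
                fh.write(f'  "{nd}";\n')
            for a, b, data in graph.edges(data=True):
                fh.write(f'  "{a}" -- "{b}" [label={data["steps"]}];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
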