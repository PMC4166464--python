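"""Multilocus sequence simulator with known species structure.

Emulates the shape of a multi-marker cryptic-species dataset: a handful
of species-level groups sequenced for three loci of contrasting rates
(a slow and a medium ribosomal-like marker, and a short fast-saturating
protein-coding-like marker), with indels, scattered missing data and a
few heavily truncated (partial) sequences.

Species relationships follow a random ultrametric species tree whose
split times are bounded away from the present, specimens within a
species coalesce on a much shorter timescale, and sequences evolve
column-independently under JC or HKY along the resulting gene trees.
With the defaults this yields between-species divergence at least ten
times the within-species divergence at the non-saturated loci, so the
true partition is recoverable and every pipeline stage has ground truth
(:class:`SimTruth`) to be scored against.  Everything is driven by one
integer seed; identical seeds give byte-identical datasets.
"""

from __future__ import annotations

import copy
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (Alignment, MultiLocusDataset, SpecimenTable,
                         SupportTree, assemble_dataset, parse_tree,
                         write_alignment, write_specimen_table, write_tree)

_BASES = np.array(list("ACGT"), dtype="<U1")
_TRANSITION_PARTNER = {0: 2, 1: 3, 2: 0, 3: 1}  # A<->G, C<->T


@dataclass
class LocusConfig:
    """One simulated marker.

    ``rate`` is in expected substitutions per site per unit of tree
    time; ``indel_rate`` is the expected number of indel events per
    locus; ``truncation_fraction`` of specimens keep only a partial
    sequence (the rest replaced by ``?``), exercising coverage
    filtering downstream.
    """

    name: str
    length: int
    rate: float
    model: str = "JC"
    kappa: float = 2.0
    indel_rate: float = 2.0
    missing_fraction: float = 0.002
    truncation_fraction: float = 0.05


def default_loci() -> list[LocusConfig]:
    return [
        LocusConfig("lsu_like", 2009, 0.02),
        LocusConfig("ssu_like", 1502, 0.01),
        LocusConfig("h3_like", 328, 0.5, indel_rate=0.0),
    ]


@dataclass
class SimConfig:
    n_species: int = 6
    specimens_per_species: int | list[int] = 8
    loci: list[LocusConfig] = field(default_factory=default_loci)
    species_depth: float = 1.0
    min_split_depth: float = 0.3
    coalescent_depth: float = 0.02
    seed: int = 0
    # internal knob used by hard-case scenarios: force the first two
    # species to split at this time instead of >= min_split_depth
    forced_pair_time: float | None = None

    def counts(self) -> list[int]:
        if isinstance(self.specimens_per_species, int):
            return [self.specimens_per_species] * self.n_species
        if len(self.specimens_per_species) != self.n_species:
            raise ValueError("specimens_per_species length != n_species")
        return list(self.specimens_per_species)


@dataclass
class SimTruth:
    partition: dict[str, str]
    gene_trees: dict[str, SupportTree]
    split_times: list[float]
    expected_divergence: dict[str, dict[str, float]]


class _Node:
    __slots__ = ("time", "children", "name")

    def __init__(self, time: float, children=None, name: str | None = None):
        self.time = time
        self.children = children or []
        self.name = name

    def leaves(self) -> list["_Node"]:
        if not self.children:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def newick(self, rate: float) -> str:
        def rec(nd: "_Node", parent_time: float) -> str:
            bl = (parent_time - nd.time) * rate
            if not nd.children:
                return f"{nd.name}:{bl:.8f}"
            inner = ",".join(rec(ch, nd.time) for ch in nd.children)
            return f"({inner})100:{bl:.8f}"
        inner = ",".join(rec(ch, self.time) for ch in self.children)
        return f"({inner})100;"


# ---------------------------------------------------------------------------
# Genealogies
# ---------------------------------------------------------------------------

def _species_tree(config: SimConfig, rng: np.random.Generator) -> _Node:
    n = config.n_species
    leaves = [_Node(0.0, name=f"sp{i + 1:02d}") for i in range(n)]
    if n == 1:
        return leaves[0]
    lineages = list(leaves)
    lo = config.min_split_depth
    hi = 0.9 * config.species_depth
    if config.forced_pair_time is not None:
        b = lineages.pop(1)
        a = lineages.pop(0)
        lineages.append(_Node(config.forced_pair_time, [a, b]))
    k = len(lineages)
    if k == 1:
        return lineages[0]
    inner = sorted(rng.uniform(lo, hi, size=max(k - 2, 0)))
    times = list(inner) + [config.species_depth]
    for t in times:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        lineages.append(_Node(t, [a, b]))
    assert len(lineages) == 1
    return lineages[0]


def _parent_times(root: _Node) -> dict[str, float]:
    out: dict[str, float] = {}

    def rec(nd: _Node, parent_time: float | None) -> None:
        if not nd.children:
            out[nd.name] = (parent_time if parent_time is not None
                            else float("inf"))
        for ch in nd.children:
            rec(ch, nd.time)
    rec(root, None)
    return out


def _coalescent(ids: list[str], two_n: float, cap: float,
                rng: np.random.Generator) -> _Node:
    nodes = [_Node(0.0, name=sid) for sid in ids]
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(two_n / (k * (k - 1) / 2))
        t_used = min(t, cap)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(_Node(t_used, [a, b]))
    return nodes[0]


def _gene_tree(species_node: _Node,
               subtrees: dict[str, _Node]) -> _Node:
    if not species_node.children:
        return subtrees[species_node.name]
    children = [_gene_tree(ch, subtrees) for ch in species_node.children]
    return _Node(species_node.time, children)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _hky_matrix(t_subs: float, kappa: float) -> np.ndarray:
    from scipy.linalg import expm
    pi = np.full(4, 0.25)
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = pi[j] * (kappa if _TRANSITION_PARTNER[i] == j else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    return expm(Q / scale * t_subs)


def _evolve_branch(seq: np.ndarray, t_subs: float, locus: LocusConfig,
                   rng: np.random.Generator) -> np.ndarray:
    if t_subs <= 0:
        return seq.copy()
    if locus.model == "JC":
        p_diff = 0.75 * -np.expm1(-4.0 / 3.0 * t_subs)
        changed = rng.random(seq.shape[0]) < p_diff
        out = seq.copy()
        out[changed] = (seq[changed]
                        + rng.integers(1, 4, changed.sum())) % 4
        return out
    if locus.model == "HKY":
        P = _hky_matrix(t_subs, locus.kappa)
        cum = np.cumsum(P, axis=1)
        u = rng.random(seq.shape[0])
        return (u[:, None] > cum[seq]).sum(axis=1).astype(seq.dtype)
    raise ValueError(f"unknown model {locus.model!r}")


def _simulate_sequences(root: _Node, locus: LocusConfig,
                        rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Evolve integer-coded sequences down the gene tree; returns
    leaf name -> base index array."""
    L = locus.length
    out: dict[str, np.ndarray] = {}
    root_seq = rng.integers(0, 4, size=L)
    stack = [(root, root_seq, root.time)]
    while stack:
        nd, seq, parent_time = stack.pop()
        if not nd.children:
            out[nd.name] = seq
            continue
        for ch in nd.children:
            t_subs = (nd.time - ch.time) * locus.rate
            stack.append((ch, _evolve_branch(seq, t_subs, locus, rng),
                          ch.time))
    return out


def _node_list(root: _Node) -> list[_Node]:
    out: list[_Node] = []
    stack = [root]
    while stack:
        nd = stack.pop()
        for ch in nd.children:
            out.append(ch)
            stack.extend([ch])
    return out


def _apply_indels(chars: np.ndarray, ids: list[str], root: _Node,
                  locus: LocusConfig, rng: np.random.Generator) -> None:
    """Single-event gap blocks of geometric length: a deletion gaps the
    chosen subtree's specimens; an insertion gaps everyone else (the
    subtree uniquely carries sequence there)."""
    n_events = rng.poisson(locus.indel_rate)
    if n_events == 0:
        return
    nodes = _node_list(root)
    index = {sid: k for k, sid in enumerate(ids)}
    for _ in range(n_events):
        nd = nodes[rng.integers(len(nodes))]
        length = int(min(1 + rng.geometric(0.35), 12, locus.length))
        start = int(rng.integers(0, locus.length - length + 1))
        members = [index[lf.name] for lf in nd.leaves()]
        if rng.random() < 0.5:
            rows = members                                 # deletion
        else:
            rows = [k for k in range(len(ids)) if k not in members]
        chars[np.ix_(rows, range(start, start + length))] = "-"


def _apply_missing_and_truncation(chars: np.ndarray, ids: list[str],
                                  locus: LocusConfig,
                                  rng: np.random.Generator) -> None:
    n, L = chars.shape
    if locus.missing_fraction > 0:
        mask = rng.random((n, L)) < locus.missing_fraction
        chars[mask] = "N"
    n_trunc = int(round(locus.truncation_fraction * n))
    if n_trunc:
        rows = rng.choice(n, size=n_trunc, replace=False)
        for r in rows:
            keep = rng.uniform(0.2, 0.45)
            cut = int(round(keep * L))
            if rng.random() < 0.5:
                chars[r, cut:] = "?"
            else:
                chars[r, :L - cut] = "?"


# ---------------------------------------------------------------------------
# Top-level simulation
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig,
                     ) -> tuple[MultiLocusDataset, SimTruth]:
    """Simulate a multilocus dataset plus its ground truth."""
    if config.n_species < 1:
        raise ValueError("n_species must be >= 1")
    counts = config.counts()
    if any(c < 1 for c in counts):
        raise ValueError("every species needs >= 1 specimen")
    rng = np.random.default_rng(config.seed)

    sp_tree = _species_tree(config, rng)
    parent_times = _parent_times(sp_tree)
    species = [f"sp{i + 1:02d}" for i in range(config.n_species)]
    specimen_ids = {s: [f"{s}_{k + 1:02d}" for k in range(c)]
                    for s, c in zip(species, counts)}
    all_ids = [sid for s in species for sid in specimen_ids[s]]
    partition = {sid: s for s in species for sid in specimen_ids[s]}

    alignments: dict[str, Alignment] = {}
    gene_trees: dict[str, SupportTree] = {}
    expected: dict[str, dict[str, float]] = {}
    split_times = sorted(nd.time for nd in _node_list(sp_tree)
                         if nd.children) + ([sp_tree.time]
                                            if sp_tree.children else [])
    for locus in config.loci:
        subtrees = {}
        for s in species:
            cap = min(parent_times[s], config.species_depth) * 0.9
            subtrees[s] = _coalescent(specimen_ids[s],
                                      config.coalescent_depth, cap, rng)
        gtree = _gene_tree(sp_tree, subtrees)
        seqs = _simulate_sequences(gtree, locus, rng)
        chars = np.array([list(_BASES[seqs[sid]]) for sid in all_ids],
                         dtype="<U1")
        _apply_indels(chars, all_ids, gtree, locus, rng)
        _apply_missing_and_truncation(chars, all_ids, locus, rng)
        alignments[locus.name] = Alignment(locus.name, list(all_ids), chars)
        gene_trees[locus.name] = parse_tree(gtree.newick(locus.rate),
                                            "bootstrap_percent",
                                            name=f"{locus.name}.true")
        mean_split = float(np.mean(split_times)) if split_times else 0.0
        expected[locus.name] = {
            "between_p": 0.75 * -np.expm1(-8.0 / 3.0 * locus.rate
                                          * mean_split),
            "within_p": 0.75 * -np.expm1(-8.0 / 3.0 * locus.rate
                                         * config.coalescent_depth),
        }

    rows = []
    localities = ["loc_a", "loc_b", "loc_c"]
    for si, s in enumerate(species):
        for k, sid in enumerate(specimen_ids[s]):
            rows.append({"specimen_id": sid, "clade": s,
                         "locality": localities[(si + k) % 3],
                         "outgroup": False,
                         "type_status": "holotype" if k == 0 else "none"})
    table = SpecimenTable(pd.DataFrame(rows))
    dataset = assemble_dataset(alignments, table,
                               {ln: {"true": gt}
                                for ln, gt in gene_trees.items()})
    truth = SimTruth(partition, gene_trees, split_times, expected)
    return dataset, truth


# ---------------------------------------------------------------------------
# Hard cases
# ---------------------------------------------------------------------------

SCENARIOS = ("shallow_split", "saturated_locus", "singleton_species",
             "shared_haplotype")


def make_hard_case(config: SimConfig, scenario: str,
                   ) -> tuple[MultiLocusDataset, SimTruth, dict]:
    """Engineer a dataset that triggers a known failure mode.

    Returns (dataset, truth, expectations); ``expectations`` annotates
    the behaviour the pipeline should show on this input.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; "
                         f"choose from {SCENARIOS}")
    cfg = copy.deepcopy(config)
    loci_by_rate = sorted(cfg.loci, key=lambda l: l.rate)
    slow, fast = loci_by_rate[0], loci_by_rate[-1]
    expectations: dict[str, object] = {"scenario": scenario,
                                       "slow_locus": slow.name,
                                       "fast_locus": fast.name}
    if scenario == "shallow_split":
        cfg.forced_pair_time = 0.05
        expectations.update(merged_pair=("sp01", "sp02"),
                            note="pair too recent for the slow locus; "
                                 "the fast locus still splits it")
    elif scenario == "shared_haplotype":
        cfg.forced_pair_time = 0.05
        cfg.coalescent_depth = 0.005
        for k, l in enumerate(cfg.loci):
            if l.name == slow.name:
                cfg.loci[k] = replace(l, rate=0.0003, indel_rate=0.0,
                                      missing_fraction=0.0,
                                      truncation_fraction=0.0)
        expectations.update(merged_pair=("sp01", "sp02"),
                            note="pair shares slow-locus haplotypes but is "
                                 "split by the fast locus")
    elif scenario == "singleton_species":
        counts = cfg.counts()
        counts[0] = 1
        cfg.specimens_per_species = counts
        expectations.update(singleton="sp01",
                            note="intra-distance undefined; status candidate")
    elif scenario == "saturated_locus":
        for k, l in enumerate(cfg.loci):
            if l.name == fast.name:
                cfg.loci[k] = replace(l, rate=l.rate * 3)
        expectations.update(note="fast-locus p-vs-patristic slope below "
                                 "the slow locus")
    dataset, truth = simulate_dataset(cfg)
    return dataset, truth, expectations


# ---------------------------------------------------------------------------
# On-disk round trip
# ---------------------------------------------------------------------------

def write_dataset(dataset: MultiLocusDataset, outdir: str | os.PathLike,
                  ) -> None:
    """Write the exact input formats the pipeline consumes: one FASTA
    per locus, one Newick per locus/method, and the specimen TSV."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    for name, aln in dataset.loci.items():
        write_alignment(aln, os.path.join(outdir, f"{name}.fasta"))
    for locus, by_method in dataset.trees.items():
        for method, stree in by_method.items():
            write_tree(stree, os.path.join(outdir,
                                           f"{locus}.{method}.nwk"))
    write_specimen_table(dataset.specimens,
                         os.path.join(outdir, "specimens.tsv"))
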