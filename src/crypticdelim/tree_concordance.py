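"""Per-clade monophyly and support across gene trees.

A candidate clade is assessed in each gene tree as a bipartition of the
tree's own leaf set: specimens absent from a tree are ignored for that
tree, and a clade is monophyletic when some edge splits the members
present from everything else (rooting via declared outgroups is then
implicit).  A tree "passes" for a clade when the clade is monophyletic
and the subtending support meets the threshold; a locus is concordant
when any of its trees (ML or Bayesian) passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io_formats import SupportTree

DEFAULT_BOOTSTRAP_THRESHOLD = 70.0
DEFAULT_POSTERIOR_THRESHOLD = 0.95


@dataclass
class TreeAssessment:
    """Outcome for one clade in one tree."""

    tree_name: str
    assessable: bool
    monophyletic: bool = False
    support: float | None = None     # None = unsupported node
    passes: bool = False


@dataclass
class CladeAssessment:
    """Per-tree outcomes for one clade plus the concordant-locus count."""

    clade: frozenset[str]
    per_tree: dict[tuple[str, str], TreeAssessment]
    per_locus_pass: dict[str, bool]
    concordant_locus_count: int
    n_assessable_loci: int

    @property
    def assessed(self) -> bool:
        return self.n_assessable_loci > 0


def _support_threshold(stree: SupportTree,
                       bootstrap_threshold: float,
                       posterior_threshold: float) -> float:
    if stree.support_kind == "bootstrap_percent":
        return bootstrap_threshold
    return posterior_threshold


def clade_in_tree(stree: SupportTree, clade: Iterable[str],
                  bootstrap_threshold: float = DEFAULT_BOOTSTRAP_THRESHOLD,
                  posterior_threshold: float = DEFAULT_POSTERIOR_THRESHOLD,
                  restrict_to: Iterable[str] | None = None,
                  ) -> TreeAssessment:
    """Assess one clade in one tree.

    Fewer than 2 clade members present -> "not assessable" (not a
    failure).  Monophyly is a bipartition test, so it is invariant to
    how the Newick happened to be rooted or rotated; the support comes
    from the edge realising the bipartition (a clade realised only by a
    terminal edge of its complement is monophyletic but unsupported).
    ``restrict_to`` limits the assessment to those leaves (specimens
    outside it — e.g. excluded from the analysis — are ignored, as if
    pruned).
    """
    clade = set(clade)
    taxa = stree.leaf_labels
    if restrict_to is not None:
        taxa = taxa & set(restrict_to)
    present = clade & taxa
    if len(present) < 2:
        return TreeAssessment(stree.name, assessable=False)
    complement = taxa - present
    threshold = _support_threshold(stree, bootstrap_threshold,
                                   posterior_threshold)

    # leaf sets per node, postorder; a rooted-bifurcating tree realises
    # each root bipartition on both root-child edges, so collect every
    # matching edge and prefer one that carries a support label
    supports: list[float | None] = []
    monophyletic = False
    leafsets: dict[int, set[str]] = {}
    for nd in stree.tree.postorder_node_iter():
        if nd.is_leaf():
            ls = {nd.taxon.label}
        else:
            ls = set()
            for ch in nd.child_nodes():
                ls |= leafsets[id(ch)]
        leafsets[id(nd)] = ls
        if nd is stree.tree.seed_node:
            continue
        ls = ls & taxa
        if not ls or ls == taxa:
            continue
        if ls == present or ls == complement:
            # the clade side, or the same bipartition seen from the
            # other end of the edge
            monophyletic = True
            supports.append(None if nd.is_leaf()
                            else getattr(nd, "support_value", None))
    if not monophyletic and not complement:
        # clade equals the full leaf set: trivially monophyletic
        monophyletic = True
    support = next((s for s in supports if s is not None), None)
    passes = monophyletic and support is not None and support >= threshold
    return TreeAssessment(stree.name, True, monophyletic, support, passes)


def concordance_count(trees: Mapping[str, Mapping[str, SupportTree]],
                      clade: Iterable[str],
                      bootstrap_threshold: float = DEFAULT_BOOTSTRAP_THRESHOLD,
                      posterior_threshold: float = DEFAULT_POSTERIOR_THRESHOLD,
                      require_all_methods: bool = False,
                      restrict_to: Iterable[str] | None = None,
                      ) -> CladeAssessment:
    """Count loci whose gene trees recover the clade.

    ``trees`` maps locus -> method -> tree.  By default a locus counts
    as concordant when *any* of its trees passes (``require_all_methods``
    switches to the strict conjunction).
    """
    clade = frozenset(clade)
    per_tree: dict[tuple[str, str], TreeAssessment] = {}
    per_locus_pass: dict[str, bool] = {}
    n_assessable = 0
    for locus, by_method in trees.items():
        outcomes = []
        for method, stree in by_method.items():
            ta = clade_in_tree(stree, clade, bootstrap_threshold,
                               posterior_threshold, restrict_to)
            per_tree[(locus, method)] = ta
            outcomes.append(ta)
        assessable = [o for o in outcomes if o.assessable]
        if not assessable:
            per_locus_pass[locus] = False
            continue
        n_assessable += 1
        if require_all_methods:
            per_locus_pass[locus] = all(o.passes for o in assessable)
        else:
            per_locus_pass[locus] = any(o.passes for o in assessable)
    count = sum(per_locus_pass.values())
    return CladeAssessment(clade, per_tree, per_locus_pass, count,
                           n_assessable)
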