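"""Uncorrected p-distances and the relative-threshold (2x) discovery test.

Distances use pairwise deletion: for each pair of sequences only columns
at which *both* have a non-gap, non-missing state are compared, and the
distance is mismatches / comparable sites.  IUPAC ambiguity codes match
any overlapping state (R vs A is a match), which is conservative for
within-group distances.  A pair with zero comparable sites has an
*undefined* distance (NaN + flag), never 0.

Group discovery implements the relative threshold criterion: a group is
accepted when its smallest mean between-group distance is at least twice
its mean within-group distance.  Distances are stored as fractions; the
reports print percentages to one decimal.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import alphabet
from .io_formats import Alignment

#: A partition maps specimen id -> group label.
Partition = Mapping[str, str]

RATIO_THRESHOLD = 2.0  # "at least twice", inclusive


def partition_groups(partition: Partition) -> dict[str, list[str]]:
    """Invert a partition into label -> sorted member list."""
    groups: dict[str, list[str]] = {}
    for sid, label in partition.items():
        groups.setdefault(label, []).append(sid)
    return {g: sorted(ms) for g, ms in sorted(groups.items())}


# ---------------------------------------------------------------------------
# Coverage filtering and trimming
# ---------------------------------------------------------------------------

def coverage_filter(aln: Alignment, min_fraction: float = 0.5,
                    ) -> tuple[Alignment, list[str]]:
    """Drop specimens resolved at fewer than ``min_fraction`` of columns.

    A column counts as resolved when the state is neither gap nor
    missing.  Returns the filtered alignment and the excluded ids.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    m = aln.masks
    resolved = ((m > 0) & (m < alphabet.GAP_BIT)).sum(axis=1)
    keep = resolved >= min_fraction * aln.columns
    excluded = [sid for sid, k in zip(aln.specimen_ids, keep) if not k]
    if not keep.any():
        raise ValueError(
            f"coverage_filter: all specimens excluded at locus "
            f"{aln.locus_name!r} (min_fraction={min_fraction})")
    kept_ids = [sid for sid, k in zip(aln.specimen_ids, keep) if k]
    return Alignment(aln.locus_name, kept_ids, aln.states[keep]), excluded


def trim_alignment(aln: Alignment, start: int, end: int) -> Alignment:
    """Keep columns ``start``..``end`` (1-based, inclusive)."""
    if not (1 <= start <= end <= aln.columns):
        raise ValueError(
            f"trim interval [{start}, {end}] invalid for "
            f"{aln.columns}-column alignment")
    return Alignment(aln.locus_name, list(aln.specimen_ids),
                     aln.states[:, start - 1:end])


# ---------------------------------------------------------------------------
# Pairwise distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric uncorrected p-distance matrix with per-pair denominators.

    ``values[i, j]`` is NaN when the pair shares no comparable site.
    """

    specimen_ids: list[str]
    values: np.ndarray
    comparable_sites: np.ndarray

    def index_of(self, sid: str) -> int:
        return self.specimen_ids.index(sid)

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def submatrix(self, ids: Iterable[str]) -> "DistanceMatrix":
        """Restriction to ``ids``, in the order given."""
        keep = [s for s in ids if s in self.specimen_ids]
        idx = np.array([self.index_of(s) for s in keep], dtype=int)
        return DistanceMatrix(keep, self.values[np.ix_(idx, idx)],
                              self.comparable_sites[np.ix_(idx, idx)])

    def to_long_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("id_a\tid_b\tdistance\tcomparable_sites\n")
            n = len(self.specimen_ids)
            for i in range(n):
                for j in range(i + 1, n):
                    d = self.values[i, j]
                    fh.write(f"{self.specimen_ids[i]}\t{self.specimen_ids[j]}"
                             f"\t{'NA' if math.isnan(d) else f'{d:.6f}'}"
                             f"\t{int(self.comparable_sites[i, j])}\n")

    def to_phylip(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.specimen_ids)}\n")
            for sid, row in zip(self.specimen_ids, self.values):
                cells = " ".join("NA" if math.isnan(v) else f"{v:.6f}"
                                 for v in row)
                fh.write(f"{sid}  {cells}\n")


def pairwise_p_distance(aln: Alignment) -> DistanceMatrix:
    """Uncorrected p-distance under pairwise deletion.

    Comparable sites exclude positions where either sequence is gap or
    missing; overlapping ambiguity codes count as matches.
    """
    if aln.n_specimens < 2:
        raise ValueError("pairwise_p_distance needs >= 2 specimens")
    m = aln.masks.astype(np.uint8)
    resolved = (m > 0) & (m < alphabet.GAP_BIT)
    n = aln.n_specimens
    values = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        both = resolved[i] & resolved[i + 1:]
        mism = both & ((m[i] & m[i + 1:]) == 0)
        c = both.sum(axis=1)
        d = mism.sum(axis=1)
        with np.errstate(invalid="ignore"):
            frac = np.where(c > 0, d / np.maximum(c, 1), np.nan)
        values[i, i + 1:] = frac
        values[i + 1:, i] = frac
        comp[i, i + 1:] = c
        comp[i + 1:, i] = c
    return DistanceMatrix(list(aln.specimen_ids), values, comp)


# ---------------------------------------------------------------------------
# Group summaries and the 2x test
# ---------------------------------------------------------------------------

@dataclass
class GroupDistanceSummary:
    """Mean within- and between-group distances for a partition.

    ``mean_intra[g]`` is NaN for singleton groups (undefined, flagged
    via :meth:`intra_defined`), ``mean_inter[(g, h)]`` is symmetric, and
    ``min_mean_inter[g]`` is the distance to ``nearest_group[g]``.
    """

    groups: list[str]
    mean_intra: dict[str, float]
    mean_inter: dict[tuple[str, str], float]
    nearest_group: dict[str, str | None]
    min_mean_inter: dict[str, float]

    def intra_defined(self, group: str) -> bool:
        return not math.isnan(self.mean_intra[group])


def group_summary(dm: DistanceMatrix, partition: Partition,
                  ) -> GroupDistanceSummary:
    """Arithmetic means of defined pairwise distances within/between groups."""
    unassigned = [s for s in dm.specimen_ids if s not in partition]
    if unassigned:
        raise ValueError(f"specimens without group assignment: {unassigned}")
    groups = partition_groups({s: partition[s] for s in dm.specimen_ids})
    labels = list(groups)
    idx = {g: np.array([dm.index_of(s) for s in ms], dtype=int)
           for g, ms in groups.items()}

    def _mean(block: np.ndarray) -> float:
        vals = block[~np.isnan(block)]
        return float(vals.mean()) if vals.size else float("nan")

    mean_intra: dict[str, float] = {}
    for g, gi in idx.items():
        if len(gi) < 2:
            mean_intra[g] = float("nan")
        else:
            iu = np.triu_indices(len(gi), k=1)
            mean_intra[g] = _mean(dm.values[np.ix_(gi, gi)][iu])
    mean_inter: dict[tuple[str, str], float] = {}
    for a_i, g in enumerate(labels):
        for h in labels[a_i + 1:]:
            v = _mean(dm.values[np.ix_(idx[g], idx[h])])
            mean_inter[(g, h)] = v
            mean_inter[(h, g)] = v
    nearest: dict[str, str | None] = {}
    min_inter: dict[str, float] = {}
    for g in labels:
        cands = [(mean_inter[(g, h)], h) for h in labels if h != g
                 and not math.isnan(mean_inter[(g, h)])]
        if cands:
            best = min(cands)
            min_inter[g], nearest[g] = best[0], best[1]
        else:
            min_inter[g], nearest[g] = float("nan"), None
    return GroupDistanceSummary(labels, mean_intra, mean_inter,
                                nearest, min_inter)


@dataclass
class EvidenceRatio:
    """Outcome of the relative-threshold (2x) test for one group/locus."""

    group: str
    locus: str
    ratio: float  # inf when intra is 0 or undefined
    passes: bool
    intra_undefined: bool = False

    def __str__(self) -> str:
        r = "inf" if math.isinf(self.ratio) else f"{self.ratio:.2f}"
        return f"{self.group}@{self.locus}: R={r} " \
               f"({'pass' if self.passes else 'fail'})"


def relative_threshold_test(summary: GroupDistanceSummary, group: str,
                            locus: str = "",
                            threshold: float = RATIO_THRESHOLD,
                            ) -> EvidenceRatio:
    """Test min mean inter-group / mean intra-group >= threshold (inclusive).

    Singleton groups and groups with zero intra-group distance pass with
    an explicit ``intra_undefined`` / infinite-ratio flag rather than
    being dropped.
    """
    if group not in summary.mean_intra:
        raise KeyError(f"group {group!r} not in summary")
    intra = summary.mean_intra[group]
    inter = summary.min_mean_inter[group]
    if math.isnan(intra):
        return EvidenceRatio(group, locus, float("inf"), True,
                             intra_undefined=True)
    if math.isnan(inter):
        # no other group to compare against: vacuous, flagged via ratio NaN
        return EvidenceRatio(group, locus, float("nan"), False)
    if intra == 0:
        return EvidenceRatio(group, locus, float("inf"), True)
    ratio = inter / intra
    return EvidenceRatio(group, locus, ratio, ratio >= threshold)


# ---------------------------------------------------------------------------
# De novo discovery
# ---------------------------------------------------------------------------

def _canonical_labels(partition: dict[str, str]) -> dict[str, str]:
    """Relabel groups by their lexicographically smallest member, so the
    result is invariant to input order and original labelling."""
    groups = partition_groups(partition)
    return {sid: f"grp_{min(ms)}" for g, ms in groups.items() for sid in ms}


def _positive_intra_groups_pass(dm: DistanceMatrix,
                                partition: dict[str, str],
                                threshold: float) -> bool:
    """Every group with a defined positive within-group mean must pass
    the relative-threshold test; singletons and identical-sequence
    groups pass with their flag, as in the a-priori evaluation."""
    summary = group_summary(dm, partition)
    return all(relative_threshold_test(summary, g, threshold=threshold).passes
               for g in summary.groups)


def discover_distance_groups(dm: DistanceMatrix,
                             threshold: float = RATIO_THRESHOLD,
                             ) -> dict[str, str]:
    """Partition specimens so every group passes the relative-threshold test.

    Builds an average-linkage dendrogram on the distance matrix and
    scans every cut height.  A cut is a candidate when all groups with
    positive within-group divergence pass the 2x criterion (singletons
    and identical-sequence groups carry their pass-with-flag status).
    Among candidates the chosen cut maximises the dendrogram gap margin

        s(t) - threshold * w(t)

    where w(t) is the largest merge height at or below the cut (the
    within-group scale) and s(t) the smallest merge height above it
    (the separation); this is the "between at least twice within"
    criterion applied to the linkage tree itself and prevents the
    degenerate all-singletons solution that a naive "finest passing
    cut" rule produces.  Ties break toward more groups.  Undefined
    pairwise distances are imputed at just above the largest defined
    distance for clustering only.  If no cut has a positive margin, the
    single-group partition is returned with a warning.
    """
    ids = sorted(dm.specimen_ids)
    sub = dm.submatrix(ids)
    vals = sub.values.copy()
    if np.isnan(vals).any():
        finite_max = np.nanmax(vals) if np.isfinite(np.nanmax(vals)) else 1.0
        vals[np.isnan(vals)] = finite_max * 1.05 + 1e-6
    np.fill_diagonal(vals, 0.0)
    vals = (vals + vals.T) / 2
    condensed = squareform(vals, checks=False)
    Z = linkage(condensed, method="average")
    merge_heights = sorted(set(float(h) for h in Z[:, 2]))
    if not merge_heights or merge_heights[-1] == 0.0:
        # no positive divergence anywhere: one group, trivially
        return _canonical_labels({sid: "all" for sid in ids})

    best: tuple[float, int, dict[str, str]] | None = None
    cuts = [0.0] + merge_heights[:-1]   # cutting at/above the last merge
    seen: set[tuple[int, ...]] = set()  # leaves a single group
    for t in cuts:
        flat = fcluster(Z, t=t, criterion="distance")
        key = tuple(flat)
        if key in seen:
            continue
        seen.add(key)
        w = max((h for h in merge_heights if h <= t), default=0.0)
        s = min(h for h in merge_heights if h > t)
        margin = s - threshold * w
        if margin <= 0:
            continue
        counts = np.bincount(flat)
        if counts[counts > 0].max() == 1:
            # every specimen its own group: the criterion is vacuous
            # there (no within-group divergence to compare against)
            continue
        part = {sid: f"c{c}" for sid, c in zip(ids, flat)}
        if not _positive_intra_groups_pass(sub, part, threshold):
            continue
        n_groups = len(set(flat))
        if best is None or (margin, n_groups) > (best[0], best[1]):
            best = (margin, n_groups, part)
    if best is None:
        warnings.warn("discover_distance_groups: no partition satisfies "
                      "the relative-threshold criterion; returning a "
                      "single group", stacklevel=2)
        return _canonical_labels({sid: "all" for sid in ids})
    return _canonical_labels(best[2])
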