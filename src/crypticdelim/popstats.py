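"""Tajima's D and substitution-saturation diagnostics.

Tajima's D contrasts mean pairwise nucleotide diversity (pi) with the
Watterson estimate from segregating sites (S / a1); under neutral,
constant-size evolution the normalized difference is near zero.  The
default *complete deletion* policy drops every column containing a gap,
missing or ambiguous state before counting, matching the common default
of distance-based packages; a pairwise-deletion variant is available
for the diversity component.

Saturation is assessed as the paired scatter of uncorrected p-distance
against patristic (tree-path) distance: a saturating locus shows a
flattened relationship, summarised by the least-squares slope through
the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import alphabet
from .distances import pairwise_p_distance
from .io_formats import Alignment, SupportTree


@dataclass
class TajimaResult:
    n: int
    sites_used: int
    S: int
    pi: float                  # mean pairwise differences (count)
    theta_w: float             # S / a1
    D: float                   # NaN when S == 0 (undefined, flagged)
    defined: bool
    constants: dict[str, float]


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(aln: Alignment, deletion: str = "complete") -> TajimaResult:
    """Tajima's D for one alignment.

    ``deletion="complete"`` keeps only columns where every sequence has
    an unambiguous base; ``"pairwise"`` computes pi from
    pairwise-deleted difference counts while S is still taken from the
    completely resolved columns.  Requires n >= 4; S = 0 yields an
    undefined (flagged) D, not 0.
    """
    n = aln.n_specimens
    if n < 4:
        raise ValueError(f"Tajima's D needs >= 4 sequences, got {n}")
    if deletion not in ("complete", "pairwise"):
        raise ValueError(f"unknown deletion policy {deletion!r}")
    m = aln.masks
    plain_base = np.isin(m, (alphabet.A, alphabet.C, alphabet.G, alphabet.T))
    full_cols = plain_base.all(axis=0)
    sites_used = int(full_cols.sum())
    sub = aln.states[:, full_cols]

    S = 0
    pair_diff_total = 0.0
    n_pairs = n * (n - 1) / 2
    for col in range(sub.shape[1]):
        _, counts = np.unique(sub[:, col], return_counts=True)
        if len(counts) > 1:
            S += 1
            pair_diff_total += n_pairs - sum(c * (c - 1) / 2 for c in counts)
    if deletion == "pairwise":
        dm = pairwise_p_distance(aln)
        diffs = [dm.values[i, j] * dm.comparable_sites[i, j]
                 for i, j in combinations(range(n), 2)
                 if not math.isnan(dm.values[i, j])]
        pi = float(np.mean(diffs)) if diffs else 0.0
    else:
        pi = pair_diff_total / n_pairs

    const = _tajima_constants(n)
    theta_w = S / const["a1"]
    if S == 0:
        return TajimaResult(n, sites_used, 0, pi, 0.0, float("nan"),
                            False, const)
    var = const["e1"] * S + const["e2"] * S * (S - 1)
    D = (pi - theta_w) / math.sqrt(var)
    return TajimaResult(n, sites_used, S, pi, theta_w, D, True, const)


# ---------------------------------------------------------------------------
# Saturation
# ---------------------------------------------------------------------------

@dataclass
class SaturationData:
    locus: str
    points: pd.DataFrame      # id_a, id_b, p_distance, tree_distance
    slope: float              # least squares through the origin


def saturation_points(aln: Alignment, stree: SupportTree) -> SaturationData:
    """Pairs of (uncorrected p-distance, patristic distance).

    The tree must have branch lengths; only specimens present in both
    the alignment and the tree contribute, and pairs with undefined
    p-distance are dropped.
    """
    if not stree.has_branch_lengths():
        raise ValueError("tree has no branch lengths; cannot compute "
                         "patristic distances")
    common = sorted(set(aln.specimen_ids) & stree.leaf_labels)
    if len(common) < 2:
        raise ValueError("fewer than 2 specimens shared between alignment "
                         "and tree")
    pdm = stree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in stree.tree.taxon_namespace}
    dm = pairwise_p_distance(aln.subset(common))
    rows = []
    for a, b in combinations(common, 2):
        p = dm.value(a, b)
        if math.isnan(p):
            continue
        t = pdm.patristic_distance(taxa[a], taxa[b])
        rows.append((a, b, p, float(t)))
    df = pd.DataFrame(rows, columns=["id_a", "id_b", "p_distance",
                                     "tree_distance"])
    x = df["tree_distance"].to_numpy()
    y = df["p_distance"].to_numpy()
    denom = float((x * x).sum())
    slope = float((x * y).sum() / denom) if denom > 0 else float("nan")
    return SaturationData(aln.locus_name, df, slope)


def plot_saturation(data: SaturationData, path: str) -> None:
    """Scatter of p-distance vs patristic distance (optional figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(data.points["tree_distance"], data.points["p_distance"],
               s=8, alpha=0.5)
    xmax = max(data.points["tree_distance"].max(), 1e-9)
    ax.plot([0, xmax], [0, data.slope * xmax], color="firebrick",
            label=f"slope {data.slope:.3f}")
    ax.set_xlabel("patristic distance (subs/site)")
    ax.set_ylabel("uncorrected p-distance")
    ax.set_title(f"Saturation: {data.locus}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
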