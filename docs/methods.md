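# Methods

This note records the models, defaults and design choices behind
`crypticdelim`, and what the synthetic tests do and do not demonstrate.

## Distances and the relative threshold

Distances are uncorrected p-distances under **pairwise deletion**: each
pair is compared over the columns where both sequences carry a non-gap,
non-missing state, and the denominator (comparable sites) is stored
alongside every value. Pairs with no comparable sites are *undefined*
(NaN), never zero. IUPAC ambiguity codes are kept as composite states
and count as matches when their base sets overlap; this is conservative
in the direction that matters (it cannot inflate within-group
distances). No model correction (JC/K2P) is applied anywhere — the
method is built on observed differences. Reports print percentages to
one decimal; internal values are fractions.

The species criterion is the **relative threshold (2× rule)**: a
group's smallest mean between-group distance must be at least twice its
mean within-group distance, inclusive at exactly 2.0. Singleton groups
and groups of identical sequences cannot furnish a within-group scale;
in *a-priori* evaluation they pass with an explicit `intra-undefined`
(or infinite-ratio) flag, so legitimately monotypic putative species
are retained rather than dropped.

### De-novo discovery

The criterion alone does not define a search. We cluster the distance
matrix by average linkage and scan every cut height. A literal "finest
partition in which every group passes" rule is degenerate: the
flag-pass for singletons means the all-singletons cut always passes.
Instead, a cut at height *t* is a candidate when every group with
positive within-group divergence passes the 2× test, and among
candidates we select the cut maximising the dendrogram gap margin
`s(t) − 2·w(t)`, where `w(t)` is the largest merge height at or below
the cut (the within-group scale the cut implies) and `s(t)` the
smallest merge height above it (the separation it claims). This is the
same "between at least twice within" idea applied to the linkage tree
itself; it returns two groups for two separated clusters of identical
sequences, one group for structureless data (with a warning), and is
deterministic and invariant to input order. Undefined distances are
imputed just above the largest observed distance for clustering only.

One caveat, verified by the property tests: with arithmetic-mean group
distances, *merging* two well-separated sister groups does not always
produce a group that fails the 2× test — the merged within-group mean
is diluted by the original within-group pairs. Merging always weakens
the evidence ratio below both constituents', but distance evidence
alone cannot refute every lumping; that is precisely why the pipeline
requires concordant gene trees and network separation as well.

## Statistical-parsimony networks

Sequences collapse to haplotypes under exact identity, with missing
positions acting as wildcards by default so partial sequences are not
artifactually isolated; because wildcard identity is not transitive,
haplotypes are the connected components of the match relation (a
strict mode disables the wildcard). Mutational steps between
haplotypes count differing columns with the gap as a **fifth state**
(base↔gap = 1 step, gap↔gap = 0) and missing excluded.

The connection limit follows the probability-of-parsimony logic of
statistical parsimony (Templeton, Crandall & Sing 1992), in a
self-contained single-hit form: if two sequences of length *L* differ
at *j* sites, take λ = −ln(1 − j/L) as the per-site substitution
intensity that would make a fraction j/L of sites visibly different,
so the probability that a differing site experienced exactly one hit
is λe^(−λ)/(1 − e^(−λ)), and

P_j = [λe^(−λ)/(1 − e^(−λ))]^j

is the probability that a j-step connection is fully parsimonious.
The limit j_max is the largest j with P_j ≥ the chosen probability
(0.98 for slow loci, 0.90 for the fast one, mirroring the practice of
relaxing the limit for rapidly evolving markers). P_j is strictly
decreasing in j and increasing in L, so relaxing the probability never
reduces j_max and longer loci connect more steps — the two properties
the downstream counts rely on. The exact variant used inside the
original TCS binary is not recoverable from the literature it cites;
a `fixed_steps` override bypasses the model entirely for users who
want to pin the limit. Networks are the connected components of the
graph joining sampled haplotypes within j_max steps; unsampled
intermediate haplotypes are not reconstructed, because all downstream
use is co-membership and counts, not topology. Singleton networks
count toward network totals.

## Gene-tree concordance

Monophyly is a bipartition test on the tree's own leaf set, restricted
to the specimens under analysis: leaves absent from a gene tree, or
excluded upstream (coverage filter), are ignored rather than counted
as conflict. The test is therefore invariant to how the Newick happens
to be rooted or rotated; support is read from the edge realising the
bipartition (for a degree-2 root, both root edges are the same
bipartition and either label is accepted). Thresholds default to
bootstrap ≥ 70 and posterior ≥ 0.95 — the conventional "well supported"
cutoffs, configurable because reasonable analyses differ — and a locus
counts as concordant when *any* of its trees (ML or Bayesian) recovers
the clade, with a strict all-trees mode available.

## The combined decision rule

`described_candidate` requires: ≥ 3 specimens, ≥ 2 concordant loci,
the 2× distance test passed at ≥ 1 locus, exclusive haplotype networks
at ≥ `min_separate_loci` loci (default 1 — real species are sometimes
network-exclusive at only one locus, so an AND across all loci would
be self-defeating), and validation. Validation is consumed, not
computed: a clade is validated when ≥ 2 of its supplied posteriors are
≥ 0.95; clades never tested may still be described because
`allow_unvalidated` defaults to true (set it false to require
validation). Clades with ≤ 2 specimens are always `candidate` — too
poorly known for formal description regardless of other evidence — as
are clades whose concordance was never assessed (no trees supplied) or
that carry a free-text veto (e.g. missing documentation for a formal
description). Everything else with failing evidence is `unresolved`.

For the monotonicity contract (strengthening one evidence stream never
demotes), statuses rank `described_candidate` above both others, and
`candidate`/`unresolved` as equal: moving from 2 to 3 specimens can
legitimately turn a `candidate` into an `unresolved` (the evidence now
counts and conflicts), which is a change of kind, not a demotion.
A failed validation ranks below *untested*: a failed test is negative
evidence, absence of a test is not.

## Nucleotide diagnoses

A diagnostic substitution is a column where every focal sequence
carries the same base and no compared sequence resolved at that column
carries a compatible state — non-focal gaps count as a fifth state (so
base-vs-gap contrasts diagnose), non-focal ambiguity codes block any
base they could contain, and columns with missing or ambiguous focal
states are excluded outright (strict policy). A maximal run of columns
where all focal sequences carry bases and all compared sequences carry
gaps is one diagnostic *insert* with its concatenated state string.
Positions are reported 1-based in two coordinate systems: the
alignment column and the position in the designated reference (type)
specimen's ungapped sequence. Diagnostics are relative to the compared
species set — stated in every report header — and adding non-focal
sequences can only remove them. A post-hoc soundness scan re-verifies
every reported character against every sequence.

## Tajima's D and saturation

Tajima's D is computed from the 1989 formulas with all constants
(a1…e2) retained on the result for audit. The default deletion policy
is *complete*: columns containing any gap, missing or ambiguous state
are dropped before counting segregating sites and mean pairwise
differences (a pairwise-deletion variant recomputes the diversity
component per pair). S = 0 yields an undefined, flagged D — never 0 —
and n < 4 is an error. Note that D is only asymptotically centred on
zero: with n ≈ 20 its mean under strict neutrality sits near −0.08
because the variance in the denominator is itself estimated from S.
The neutral-calibration test accounts for this by checking the mean of
a fixed replicate set against the 2-standard-error band.

Saturation is reported as data, not a test statistic: all pairwise
(p-distance, patristic distance) points plus the least-squares slope
through the origin. A saturating locus shows a flattened cloud and a
visibly smaller slope than a slow locus. On simulated data the true
trees carry realized — not expected — substitution histories, so
slow-locus slopes scatter around 1 by roughly ±15–20% (shared Poisson
noise on internal branches); the fast locus sits near 0.6 and the
contrast is unambiguous.

## Synthetic data

The simulator emulates the structure of a multi-marker cryptic-species
study: `n_species` (default 6) on a random ultrametric species tree of
depth 1.0 whose split times are bounded below by 0.3 (so between-
species divergence is well away from the coalescent scale),
`specimens_per_species` (default 8) coalescing within species on a
2N = 0.02 timescale, and three loci echoing a slow/medium/fast design:
2009 bp at rate 0.02, 1502 bp at rate 0.01, and a 328 bp fast locus at
rate 0.5 substitutions/site/time — the last saturating over
between-species depths exactly as short protein-coding markers do.
With these defaults the between/within divergence ratio at the
non-saturated loci is ≥ 10. Sequences evolve column-independently
under JC (HKY with κ available); indels are single-event geometric gap
blocks assigned to a random subtree (deletion) or its complement
(insertion — producing the diagnostic-insert pattern); a small fraction
of sites become missing and ~5% of specimens per locus are truncated
below the 50% coverage threshold to exercise the filter. True gene
trees (support 100, branch lengths in substitutions/site) and the true
partition are returned alongside the data, and one integer seed fully
determines the output.

Hard-case scenarios engineer known failure modes: a species pair
splitting at 0.05 (`shallow_split`: lumped by slow-locus distances,
split by the fast locus), the same pair with a near-zero slow-locus
rate (`shared_haplotype`: one slow network contains both species, the
fast locus separates them), a monotypic species
(`singleton_species`: intra-undefined flag, status capped at
candidate), and a tripled fast rate (`saturated_locus`).

What the simulator does *not* emulate — incomplete lineage sorting
(one lineage per species enters the species tree, so gene trees never
conflict with the species tree), recombination, rate variation across
sites, alignment error, or contamination. Passing tests therefore
demonstrate correctness of the machinery and the decision rules under
clean, well-separated conditions, not robustness to discordant gene
histories; on real data the concordance and validation criteria are
doing work the simulator never challenges.

## Numerical and procedural choices

- Alignment coordinates are 1-based inclusive everywhere, including in
  every written report.
- `N` and `?` are both missing; `U` folds to `T`; all states are kept
  uppercase; unknown characters are format errors, never silently
  dropped.
- The coverage filter (default: ≥ 50% of columns resolved) runs before
  everything else; excluded specimens are listed per locus and carry
  no group label downstream (they are ignored, not counted as
  conflict).
- Discovery ties break toward more groups; group labels are canonical
  (`grp_<smallest member id>`), so results are invariant to input
  order and prior labels.
- The evidence table is a pure function of its inputs; pipeline
  outputs carry a provenance header (config JSON + per-locus input
  checksums) and rerunning a config byte-identically reproduces them.
- Problem sizes in the test and acceptance runs — 48 specimens ×
  3 loci for recovery, 100-instance oracle sweeps at ≤ 30 sequences ×
  ≤ 50 columns, 200 neutral replicates at n = 20 × 2 kb — were chosen
  to exercise every code path at the scale of a typical single-marker
  study table while keeping a full run in seconds.

## Known limitations

- The parsimony-probability model is one defensible operationalisation
  of the cited theory; absolute j_max values may differ from the
  original TCS binary (use `fixed_steps` to pin them). All comparative
  statements (98% vs 90%, slow vs fast loci) are invariant to this
  choice.
- Mean-based distance evidence cannot always refute lumping two
  well-separated sister species (see above).
- Haplotype wildcard matching can chain very partial sequences into
  one haplotype; strict mode trades that for isolating them.
- BP&P-style validation is an input; the package takes no position on
  guide trees or priors beyond recording the posteriors it is given.
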