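"""Combine the evidence streams into per-clade species hypotheses.

A clade becomes a ``described_candidate`` when it has at least three
specimens, is recovered (monophyletic and supported) in at least two
loci, passes the 2x relative-distance test in at least one locus, is
separated in the haplotype networks of at least ``min_separate_loci``
loci, and is either validated by external multilocus posteriors or
untested with the explicit allow-unvalidated override.  Clades with two
or fewer specimens are always plain ``candidate`` (too poorly known);
clades that were assessed and failed are ``unresolved``.  Every
criterion outcome is retained on the hypothesis for audit.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .distances import (EvidenceRatio, Partition, group_summary,
                        pairwise_p_distance, partition_groups,
                        relative_threshold_test)
from .io_formats import MultiLocusDataset
from .parsimony_networks import (HaplotypeNetworkSet, SeparationReport,
                                 network_separation)
from .tree_concordance import CladeAssessment, concordance_count

DESCRIBED = "described_candidate"
CANDIDATE = "candidate"
UNRESOLVED = "unresolved"

#: Rank used by the monotonicity contract: a described candidate
#: outranks everything else; candidate and unresolved are both simply
#: "not described" (a clade can move between them when specimen counts
#: change, which is not a demotion of the species hypothesis).
STATUS_RANK = {DESCRIBED: 1, CANDIDATE: 0, UNRESOLVED: 0}


@dataclass
class DelimitationConfig:
    min_specimens: int = 3
    ratio_threshold: float = 2.0
    min_concordant_loci: int = 2
    min_separate_loci: int = 1
    bootstrap_threshold: float = 70.0
    posterior_threshold: float = 0.95
    validation_pp_threshold: float = 0.95
    validation_min_analyses: int = 2
    allow_unvalidated: bool = True


@dataclass
class ValidationResult:
    """External multilocus (BP&P-style) posteriors for one clade."""

    clade: str
    posteriors: list[float]

    def verdict(self, config: DelimitationConfig) -> str:
        if not self.posteriors:
            return "untested"
        n_pass = sum(p >= config.validation_pp_threshold
                     for p in self.posteriors)
        return "yes" if n_pass >= min(config.validation_min_analyses,
                                      len(self.posteriors)) else "no"


def read_validations(path: str | os.PathLike) -> dict[str, ValidationResult]:
    """Read a `clade pp_prior1 pp_prior2 pp_prior3` TSV (missing cells
    allowed)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, ValidationResult] = {}
    for _, row in df.iterrows():
        pps = [float(v) for v in row.iloc[1:] if v not in ("", "-", "NA")]
        out[str(row.iloc[0])] = ValidationResult(str(row.iloc[0]), pps)
    return out


@dataclass
class SpeciesHypothesis:
    label: str
    specimen_ids: list[str]
    ratios: dict[str, EvidenceRatio]
    separations: dict[str, SeparationReport]
    assessment: CladeAssessment | None
    validation: ValidationResult | None
    validated: str                      # yes / no / untested
    status: str
    veto: str | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def n_specimens(self) -> int:
        return len(self.specimen_ids)


def evaluate_clade(label: str, specimen_ids: list[str],
                   ratios: Mapping[str, EvidenceRatio],
                   separations: Mapping[str, SeparationReport],
                   assessment: CladeAssessment | None,
                   validation: ValidationResult | None,
                   config: DelimitationConfig,
                   veto: str | None = None) -> SpeciesHypothesis:
    """Apply the combined decision rule to one clade's evidence bundle."""
    ratios = dict(ratios)
    separations = dict(separations)
    has_evidence = (ratios or
                    any(s.has_data for s in separations.values()) or
                    (assessment is not None and assessment.assessed))
    if not has_evidence:
        raise ValueError(f"clade {label!r}: no evidence at any locus")

    n = len(specimen_ids)
    notes: list[str] = []
    dist_pass = any(r.passes for r in ratios.values())
    if any(r.intra_undefined for r in ratios.values()):
        notes.append("intra-undefined")
    sep_count = sum(1 for s in separations.values()
                    if s.has_data and s.is_separate)
    concordant = assessment.concordant_locus_count if assessment else 0
    validated = validation.verdict(config) if validation else "untested"
    validation_ok = (validated == "yes"
                     or (validated == "untested" and config.allow_unvalidated))

    if n <= 2:
        status = CANDIDATE
    elif assessment is None:
        status = CANDIDATE
        notes.append("concordance not assessed")
    elif veto:
        status = CANDIDATE
        notes.append(f"veto: {veto}")
    elif (n >= config.min_specimens
          and concordant >= config.min_concordant_loci
          and dist_pass
          and sep_count >= config.min_separate_loci
          and validation_ok):
        status = DESCRIBED
    else:
        status = UNRESOLVED
    return SpeciesHypothesis(label, list(specimen_ids), ratios, separations,
                             assessment, validation, validated, status,
                             veto, notes)


# ---------------------------------------------------------------------------
# Evidence table
# ---------------------------------------------------------------------------

def _fmt_pct(x: float) -> str:
    return "-" if math.isnan(x) else f"{100 * x:.1f}"


def _fmt_dist(summary, group) -> str:
    if group not in summary.mean_intra:
        return "-"
    return f"{_fmt_pct(summary.min_mean_inter[group])}/" \
           f"{_fmt_pct(summary.mean_intra[group])}"


def _fmt_sep(rep: SeparationReport) -> str:
    if not rep.has_data:
        return "-"
    if rep.is_separate:
        return ("yes" if rep.n_networks_spanned == 1
                else f"yes*{rep.n_networks_spanned}")
    return str(rep.min_steps_to_nonmember)


def _fmt_trees(assessment: CladeAssessment | None, locus: str) -> str:
    if assessment is None:
        return "-"
    cells = []
    for (loc, method), ta in sorted(assessment.per_tree.items()):
        if loc != locus:
            continue
        if not ta.assessable:
            cells.append("-")
        elif not ta.monophyletic:
            cells.append("#")
        elif ta.support is None:
            cells.append("ns")
        else:
            cells.append(format(ta.support, "g"))
    return "/".join(cells) if cells else "-"


def evidence_table(dataset: MultiLocusDataset, partition: Partition,
                   networks: Mapping[str, HaplotypeNetworkSet],
                   validations: Mapping[str, ValidationResult] | None = None,
                   config: DelimitationConfig | None = None,
                   vetoes: Mapping[str, str] | None = None,
                   ) -> tuple[pd.DataFrame, dict[str, SpeciesHypothesis]]:
    """One row per clade: counts, distances, network separation, tree
    support and the combined status.  Pure function of its inputs."""
    config = config or DelimitationConfig()
    validations = dict(validations or {})
    vetoes = dict(vetoes or {})
    groups = partition_groups(partition)
    loci = list(dataset.loci)

    summaries = {}
    for locus, aln in dataset.loci.items():
        ids = [s for s in aln.specimen_ids if s in partition]
        if len(ids) >= 2 and len({partition[s] for s in ids}) >= 1:
            dm = pairwise_p_distance(aln.subset(ids))
            summaries[locus] = group_summary(
                dm, {s: partition[s] for s in ids})

    rows = []
    hypotheses: dict[str, SpeciesHypothesis] = {}
    trees_present = any(dataset.trees.get(locus) for locus in loci)
    for label, members in groups.items():
        ratios: dict[str, EvidenceRatio] = {}
        seps: dict[str, SeparationReport] = {}
        for locus in loci:
            if locus in summaries and label in summaries[locus].mean_intra:
                ratios[locus] = relative_threshold_test(
                    summaries[locus], label, locus,
                    threshold=config.ratio_threshold)
            if locus in networks:
                seps[locus] = network_separation(networks[locus],
                                                 partition, label)
        assessment = None
        if trees_present:
            assessment = concordance_count(
                dataset.trees, members,
                bootstrap_threshold=config.bootstrap_threshold,
                posterior_threshold=config.posterior_threshold,
                restrict_to=set(partition))
        hyp = evaluate_clade(label, members, ratios, seps, assessment,
                             validations.get(label), config,
                             veto=vetoes.get(label))
        hypotheses[label] = hyp
        row: dict[str, object] = {"clade": label,
                                  "n_specimens": len(members)}
        for locus in loci:
            present = [s for s in members
                       if s in dataset.loci[locus].specimen_ids]
            row[f"n_{locus}"] = len(present)
            row[f"dist_{locus}"] = (_fmt_dist(summaries[locus], label)
                                    if locus in summaries else "-")
            row[f"net_{locus}"] = (_fmt_sep(seps[locus])
                                   if locus in seps else "-")
            row[f"trees_{locus}"] = _fmt_trees(assessment, locus)
        row["validation"] = ("/".join(format(p, "g") for p in
                                      hyp.validation.posteriors)
                             if hyp.validation else "-")
        row["validated"] = hyp.validated
        row["status"] = hyp.status
        row["notes"] = ";".join(hyp.notes)
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("clade").reset_index(drop=True)
    return df, hypotheses


def write_evidence_table(df: pd.DataFrame, path: str | os.PathLike,
                         header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("# Evidence table; alignment coordinates 1-based inclusive;"
                 " distances are percentages (min mean inter/mean intra)\n")
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_markdown_report(df: pd.DataFrame, path: str | os.PathLike,
                          title: str = "Species delimitation evidence",
                          ) -> None:
    cols = list(df.columns)
    with open(path, "w") as fh:
        fh.write(f"# {title}\n\n")
        fh.write("| " + " | ".join(cols) + " |\n")
        fh.write("|" + "|".join("---" for _ in cols) + "|\n")
        for _, row in df.iterrows():
            fh.write("| " + " | ".join(str(row[c]) for c in cols) + " |\n")
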