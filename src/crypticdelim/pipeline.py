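"""End-to-end orchestration: filter -> distances -> networks ->
concordance -> delimitation -> diagnostics -> popstats.

The library entry point is :func:`run_pipeline`; the command-line
wrapper in :mod:`crypticdelim.cli` only handles file discovery and exit
codes.  Given the same configuration and inputs the run is fully
deterministic and every written artifact carries a provenance header
(configuration plus input checksums).
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping

import pandas as pd

from .delimitation import (DelimitationConfig, SpeciesHypothesis,
                           ValidationResult, evidence_table,
                           write_evidence_table, write_markdown_report)
from .diagnostics import (DiagnosticSet, diagnostic_positions,
                          verify_diagnostics, write_diagnostics_tsv)
from .distances import (Partition, coverage_filter, discover_distance_groups,
                        pairwise_p_distance, partition_groups)
from .io_formats import MultiLocusDataset
from .parsimony_networks import (HaplotypeNetworkSet, build_networks,
                                 collapse_haplotypes, connection_limit_steps,
                                 write_membership_tsv)
from .popstats import SaturationData, TajimaResult, saturation_points, tajimas_d

DEFAULT_SLOW_LIMIT = 0.98
DEFAULT_FAST_LIMIT = 0.90


@dataclass
class PipelineConfig:
    """Thresholds for a full run; defaults mirror the analysis design:
    half-length coverage cutoff, inclusive 2x distance ratio, 98%
    connection limit for slow loci and 90% for a locus named as fast."""

    min_fraction: float = 0.5
    connection_limits: dict[str, float] = field(default_factory=dict)
    default_connection_limit: float = DEFAULT_SLOW_LIMIT
    fixed_steps: dict[str, int] = field(default_factory=dict)
    use_a_priori_partition: bool = True
    discovery_locus: str | None = None   # default: first locus
    delimitation: DelimitationConfig = field(
        default_factory=DelimitationConfig)

    def limit_for(self, locus: str) -> float:
        return self.connection_limits.get(locus,
                                          self.default_connection_limit)


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: MultiLocusDataset            # after coverage filtering
    excluded: dict[str, list[str]]
    partition: dict[str, str]
    partition_source: str                 # "a_priori" | "discovered"
    networks: dict[str, HaplotypeNetworkSet]
    evidence: pd.DataFrame
    hypotheses: dict[str, SpeciesHypothesis]
    diagnostics: DiagnosticSet
    tajima: dict[str, TajimaResult]
    saturation: dict[str, SaturationData]


def _checksums(dataset: MultiLocusDataset) -> dict[str, str]:
    out = {}
    for name, aln in dataset.loci.items():
        h = hashlib.sha256()
        for sid, row in zip(aln.specimen_ids, aln.states):
            h.update(sid.encode())
            h.update("".join(row).encode())
        out[name] = h.hexdigest()[:12]
    return out


def run_pipeline(dataset: MultiLocusDataset,
                 config: PipelineConfig | None = None,
                 validations: Mapping[str, ValidationResult] | None = None,
                 vetoes: Mapping[str, str] | None = None,
                 outdir: str | os.PathLike | None = None) -> PipelineResult:
    """Run every stage on an assembled dataset and optionally write the
    full set of reports to ``outdir``."""
    config = config or PipelineConfig()

    # 1. coverage filtering per locus
    filtered = {}
    excluded: dict[str, list[str]] = {}
    for name, aln in dataset.loci.items():
        falns, exc = coverage_filter(aln, config.min_fraction)
        filtered[name] = falns
        excluded[name] = exc
    dataset = MultiLocusDataset(filtered, dataset.specimens, dataset.trees,
                                dataset.missing_by_locus, dataset.unannotated)

    # 2. partition: a-priori clade labels, else distance-based discovery
    a_priori = dataset.specimens.clade_partition()
    loci_names = list(dataset.loci)
    if config.use_a_priori_partition and a_priori:
        partition = {s: g for s, g in a_priori.items()
                     if any(s in dataset.loci[ln].specimen_ids
                            for ln in loci_names)}
        source = "a_priori"
    else:
        disc_locus = config.discovery_locus or loci_names[0]
        dm = pairwise_p_distance(dataset.loci[disc_locus])
        partition = discover_distance_groups(dm)
        source = "discovered"

    # 3. parsimony networks per locus
    networks: dict[str, HaplotypeNetworkSet] = {}
    for name, aln in dataset.loci.items():
        haps = collapse_haplotypes(aln)
        if name in config.fixed_steps:
            networks[name] = build_networks(
                haps, fixed_steps=config.fixed_steps[name])
        else:
            limit = connection_limit_steps(aln.columns,
                                           config.limit_for(name))
            networks[name] = build_networks(haps, limit)

    # 4-5. concordance + combined decision rule
    evidence, hypotheses = evidence_table(dataset, partition, networks,
                                          validations, config.delimitation,
                                          vetoes)

    # 6. diagnostics per clade, reference = type specimen when declared
    groups = partition_groups(partition)
    characters: dict[str, dict[str, list]] = {}
    references: dict[str, str] = {}
    for label, members in groups.items():
        ref = dataset.specimens.type_specimen(label)
        by_locus = {}
        for name, aln in dataset.loci.items():
            present = [s for s in members if s in aln.specimen_ids]
            if not present:
                continue
            ref_here = ref if ref in present else present[0]
            part_here = {s: g for s, g in partition.items()
                         if s in aln.specimen_ids}
            by_locus[name] = diagnostic_positions(aln, part_here, label,
                                                  ref_here)
            references.setdefault(label, ref_here)
        characters[label] = by_locus
    diagnostics = DiagnosticSet(characters, references)

    # 7. popstats per locus
    tajima: dict[str, TajimaResult] = {}
    saturation: dict[str, SaturationData] = {}
    for name, aln in dataset.loci.items():
        if aln.n_specimens >= 4:
            tajima[name] = tajimas_d(aln)
        for stree in dataset.trees.get(name, {}).values():
            if stree.has_branch_lengths():
                saturation[name] = saturation_points(aln, stree)
                break

    result = PipelineResult(config, dataset, excluded, partition, source,
                            networks, evidence, hypotheses, diagnostics,
                            tajima, saturation)
    if outdir is not None:
        write_reports(result, outdir)
    return result


def write_reports(result: PipelineResult, outdir: str | os.PathLike) -> None:
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    cfg = asdict(result.config)
    header = [f"config: {json.dumps(cfg, sort_keys=True)}",
              f"input checksums: {json.dumps(_checksums(result.dataset))}",
              f"partition source: {result.partition_source}"]
    write_evidence_table(result.evidence,
                         os.path.join(outdir, "evidence.tsv"), header)
    write_markdown_report(result.evidence,
                          os.path.join(outdir, "evidence.md"))
    for name, aln in result.dataset.loci.items():
        if aln.n_specimens >= 2:
            pairwise_p_distance(aln).to_long_tsv(
                os.path.join(outdir, f"distances_{name}.tsv"))
    for name, nets in result.networks.items():
        write_membership_tsv(nets, os.path.join(outdir,
                                                f"networks_{name}.tsv"))
    write_diagnostics_tsv(result.diagnostics,
                          os.path.join(outdir, "diagnostics.tsv"))
    with open(os.path.join(outdir, "popstats.tsv"), "w") as fh:
        fh.write("locus\tn\tsites_used\tS\tpi\ttheta_w\ttajimas_D"
                 "\tsaturation_slope\n")
        for name in result.dataset.loci:
            tj = result.tajima.get(name)
            sat = result.saturation.get(name)
            cells = [name]
            if tj is not None:
                d = "undefined" if not tj.defined else f"{tj.D:.6f}"
                cells += [str(tj.n), str(tj.sites_used), str(tj.S),
                          f"{tj.pi:.4f}", f"{tj.theta_w:.4f}", d]
            else:
                cells += ["-"] * 6
            cells.append(f"{sat.slope:.4f}" if sat is not None else "-")
            fh.write("\t".join(cells) + "\n")
    with open(os.path.join(outdir, "excluded_specimens.tsv"), "w") as fh:
        fh.write("locus\tspecimen_id\n")
        for name, ids in result.excluded.items():
            for sid in ids:
                fh.write(f"{name}\t{sid}\n")
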