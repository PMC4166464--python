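"""Nucleotide-based species diagnoses.

A *diagnostic* column is fixed for one state in every sequence of the
focal species and shows no compatible state in any other compared
sequence resolved at that column — the "pure" diagnostic class of
character-based DNA taxonomy.  Gaps in non-focal sequences count as a
fifth state, so a base-vs-gap contrast can diagnose; a maximal run of
columns where all focal sequences carry bases and all non-focal
sequences carry gaps is reported as a single *insert* with its
alignment-column range.

Positions are reported in two coordinate systems, both 1-based: the
alignment column, and the position in the ungapped sequence of a
designated reference (type) specimen.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from . import alphabet
from .distances import Partition
from .io_formats import Alignment


@dataclass(frozen=True)
class DiagnosticCharacter:
    species: str
    locus: str
    aln_start: int           # 1-based inclusive
    aln_end: int
    ref_start: int           # position in reference specimen's ungapped seq
    ref_end: int
    state: str
    kind: str                # "substitution" | "insert"

    @property
    def aln_pos(self) -> str:
        if self.aln_start == self.aln_end:
            return str(self.aln_start)
        return f"{self.aln_start}-{self.aln_end}"

    @property
    def ref_pos(self) -> str:
        if self.ref_start == self.ref_end:
            return str(self.ref_start)
        return f"{self.ref_start}-{self.ref_end}"


@dataclass
class DiagnosticSet:
    """Per-species, per-locus diagnostic characters with the reference
    specimen used for sequence coordinates.  Empty lists are legitimate
    (a species may lack diagnostics at a locus)."""

    characters: dict[str, dict[str, list[DiagnosticCharacter]]]
    reference_ids: dict[str, str]


def map_alignment_to_sequence_position(aln: Alignment, specimen_id: str,
                                       aln_pos: int) -> int:
    """Map a 1-based alignment column to the 1-based position in the
    specimen's ungapped sequence (count of non-gap characters through
    that column).  A gap at the column has no sequence coordinate."""
    if not 1 <= aln_pos <= aln.columns:
        raise ValueError(f"alignment position {aln_pos} out of range "
                         f"[1, {aln.columns}]")
    row = aln.states[aln.index_of(specimen_id)]
    if row[aln_pos - 1] == alphabet.GAP_CHAR:
        raise ValueError(f"{specimen_id} has a gap at column {aln_pos}: "
                         "no sequence coordinate")
    return int((row[:aln_pos] != alphabet.GAP_CHAR).sum())


def _column_class(focal_chars: np.ndarray, other_chars: np.ndarray,
                  other_masks: np.ndarray) -> tuple[str | None, str]:
    """Classify one column: ('sub', state), ('ins', state) or (None, '')."""
    fset = set(focal_chars.tolist())
    if fset & alphabet.MISSING_CHARS or fset & alphabet.AMBIGUITY_CHARS:
        return None, ""       # strict policy: unresolved focal blocks
    if len(fset) != 1:
        return None, ""       # polymorphic in focal
    state = focal_chars[0]
    if state == alphabet.GAP_CHAR:
        return None, ""       # focal gaps never diagnose (deletions skipped)
    resolved = [(ch, mk) for ch, mk in zip(other_chars.tolist(), other_masks)
                if ch not in alphabet.MISSING_CHARS]
    if not resolved:
        return None, ""       # nothing to contrast against
    if all(ch == alphabet.GAP_CHAR for ch, _ in resolved):
        return "ins", str(state)
    smask = alphabet.CHAR_TO_MASK[state]
    # gap (fifth state) never overlaps a base mask; ambiguity overlap
    # means the state could be present -> not diagnostic
    if any(int(mk) & smask for _, mk in resolved):
        return None, ""
    return "sub", str(state)


def diagnostic_positions(aln: Alignment, partition: Partition,
                         focal_species: str, ref_id: str,
                         compare_species: Iterable[str] | None = None,
                         ) -> list[DiagnosticCharacter]:
    """All pure diagnostic substitutions and inserts for one species.

    ``compare_species`` restricts the contrast set (e.g. to congeners);
    by default every other partitioned species in the alignment is
    compared.
    """
    if partition.get(ref_id) != focal_species:
        raise ValueError(f"reference {ref_id!r} does not belong to "
                         f"focal species {focal_species!r}")
    ids = [s for s in aln.specimen_ids if s in partition]
    focal_ids = [s for s in ids if partition[s] == focal_species]
    if not focal_ids:
        raise ValueError(f"{focal_species!r} has no sequence at locus "
                         f"{aln.locus_name!r}")
    if compare_species is None:
        other_ids = [s for s in ids if partition[s] != focal_species]
    else:
        allowed = set(compare_species)
        other_ids = [s for s in ids if partition[s] in allowed]
    if ref_id not in aln.specimen_ids:
        raise ValueError(f"reference {ref_id!r} not in alignment")

    focal = aln.states[[aln.index_of(s) for s in focal_ids]]
    others = aln.states[[aln.index_of(s) for s in other_ids]]
    other_masks = alphabet.masks(others) if len(other_ids) else \
        np.zeros((0, aln.columns), dtype=np.uint8)

    ref_row = aln.states[aln.index_of(ref_id)]
    ref_cum = np.cumsum(ref_row != alphabet.GAP_CHAR)

    out: list[DiagnosticCharacter] = []
    ins_run: list[tuple[int, str]] = []

    def _flush_run() -> None:
        if not ins_run:
            return
        start_col, end_col = ins_run[0][0], ins_run[-1][0]
        state = "".join(s for _, s in ins_run)
        out.append(DiagnosticCharacter(
            focal_species, aln.locus_name, start_col, end_col,
            int(ref_cum[start_col - 1]), int(ref_cum[end_col - 1]),
            state, "insert"))
        ins_run.clear()

    for col in range(1, aln.columns + 1):
        kind, state = _column_class(focal[:, col - 1], others[:, col - 1],
                                    other_masks[:, col - 1])
        if kind == "ins":
            if ins_run and ins_run[-1][0] != col - 1:
                _flush_run()
            ins_run.append((col, state))
            continue
        _flush_run()
        if kind == "sub":
            out.append(DiagnosticCharacter(
                focal_species, aln.locus_name, col, col,
                int(ref_cum[col - 1]), int(ref_cum[col - 1]),
                state, "substitution"))
    _flush_run()
    out.sort(key=lambda d: d.aln_start)
    return out


def verify_diagnostics(aln: Alignment, partition: Partition,
                       characters: Iterable[DiagnosticCharacter],
                       ) -> list[str]:
    """Post-hoc soundness re-scan: confirm every reported character
    against every sequence.  Returns human-readable violations (empty
    when sound)."""
    violations: list[str] = []
    for ch in characters:
        cols = range(ch.aln_start - 1, ch.aln_end)
        for sid in aln.specimen_ids:
            if sid not in partition:
                continue
            row = aln.states[aln.index_of(sid)]
            is_focal = partition[sid] == ch.species
            if ch.kind == "substitution":
                col = ch.aln_start - 1
                st = row[col]
                if is_focal and st != ch.state:
                    violations.append(
                        f"{ch.species} col {ch.aln_start}: focal {sid} "
                        f"has {st}, expected {ch.state}")
                if (not is_focal and st not in alphabet.MISSING_CHARS
                        and alphabet.CHAR_TO_MASK[st]
                        & alphabet.CHAR_TO_MASK[ch.state]):
                    violations.append(
                        f"{ch.species} col {ch.aln_start}: non-focal {sid} "
                        f"shows compatible state {st}")
            else:  # insert
                states = [row[c] for c in cols]
                if is_focal and any(s == alphabet.GAP_CHAR for s in states):
                    violations.append(
                        f"{ch.species} insert {ch.aln_pos}: focal {sid} "
                        "has a gap inside the insert")
                if (not is_focal
                        and not all(s == alphabet.GAP_CHAR or
                                    s in alphabet.MISSING_CHARS
                                    for s in states)):
                    violations.append(
                        f"{ch.species} insert {ch.aln_pos}: non-focal "
                        f"{sid} carries sequence in the insert")
    return violations


def write_diagnostics_tsv(diag: DiagnosticSet,
                          path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# positions 1-based inclusive; ref_pos in the reference "
                 "(type) specimen's ungapped sequence; diagnostics are "
                 "relative to the compared species set\n")
        fh.write("species\tlocus\taln_pos\tref_pos\tstate\tkind\n")
        for species, by_locus in diag.characters.items():
            for locus, chars in by_locus.items():
                if not chars:
                    fh.write(f"{species}\t{locus}\t-\t-\t-\t-\n")
                for ch in chars:
                    fh.write(f"{species}\t{locus}\t{ch.aln_pos}\t"
                             f"{ch.ref_pos}\t{ch.state}\t{ch.kind}\n")
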