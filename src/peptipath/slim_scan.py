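"""Short-linear-motif (SLiM) scanning of regulated peptide sequences.

Each motif's regex is scanned against a peptide with overlapping occurrences
enumerated: after each match the scan restarts one residue after the previous
match start, so every distinct start position is reported.  Coordinates are
1-based inclusive, peptide-local.

Downstream over-representation consumes the deduplicated SLiM *set*
(presence/absence per analysis), after the class/taxon selection filter:
by default only motifs of the docking (DOC) and ligand (LIG) classes carrying
an annotated Mus musculus instance are retained.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_model import MotifDefinition, PeptideRecord, ValidationError

#: Default motif-class filter: docking and ligand-binding SLiMs.
DEFAULT_CLASSES: frozenset[str] = frozenset({"DOC", "LIG"})

#: Default annotated-instance taxon filter.
DEFAULT_TAXON = "Mus musculus"


@dataclass(frozen=True)
class MotifMatch:
    """One occurrence of a motif in a peptide (1-based inclusive coords)."""

    motif_id: str
    peptide_sequence: str
    start: int
    end: int
    matched_subsequence: str

    def __post_init__(self) -> None:
        n = len(self.peptide_sequence)
        if not (1 <= self.start <= self.end <= n):
            raise ValidationError(
                f"match {self.motif_id!r} coords [{self.start},{self.end}] out of 1..{n}"
            )
        if self.peptide_sequence[self.start - 1 : self.end] != self.matched_subsequence:
            raise ValidationError(
                f"match {self.motif_id!r}: subsequence does not equal the peptide slice"
            )


def scan_peptide(
    peptide: PeptideRecord, motifs: Sequence[MotifDefinition]
) -> list[MotifMatch]:
    """All motif occurrences in one peptide, overlapping starts included.

    Output is sorted by (motif_id, start).  Scanning is pure: identical
    inputs give identical outputs.
    """
    seq = peptide.sequence
    matches: list[MotifMatch] = []
    for motif in motifs:
        pat = motif.compiled
        pos = 0
        while pos <= len(seq):
            m = pat.search(seq, pos)
            if m is None:
                break
            if m.end() == m.start():  # zero-width match: advance without recording
                pos = m.start() + 1
                continue
            matches.append(
                MotifMatch(
                    motif_id=motif.motif_id,
                    peptide_sequence=seq,
                    start=m.start() + 1,
                    end=m.end(),
                    matched_subsequence=m.group(0),
                )
            )
            pos = m.start() + 1
    matches.sort(key=lambda x: (x.motif_id, x.start))
    return matches


def scan_peptides(
    peptides: Iterable[PeptideRecord], motifs: Sequence[MotifDefinition]
) -> list[MotifMatch]:
    """Scan a pool of peptides (e.g. all regulated in one comparison)."""
    out: list[MotifMatch] = []
    for pep in peptides:
        out.extend(scan_peptide(pep, motifs))
    return out


def select_slims(
    matches: Iterable[MotifMatch],
    motifs: Sequence[MotifDefinition],
    classes: frozenset[str] | set[str] = DEFAULT_CLASSES,
    taxon: str = DEFAULT_TAXON,
) -> set[str]:
    """Apply the class/taxon selection filter to matched motifs.

    Keeps motif ids whose class is in ``classes``, that carry an annotated
    instance in ``taxon``, and that matched at least one peptide.  The result
    is a set — each SLiM counts once per analysis regardless of how many
    times or in how many peptides it matched.
    """
    by_id = {m.motif_id: m for m in motifs}
    matched_ids = {m.motif_id for m in matches}
    selected: set[str] = set()
    for mid in matched_ids:
        motif = by_id.get(mid)
        if motif is None:
            continue
        if motif.class_code in classes and taxon in motif.instance_taxa:
            selected.add(mid)
    return selected


def matches_to_frame(
    matches: Sequence[MotifMatch],
    motifs: Sequence[MotifDefinition],
    selected: set[str],
) -> pd.DataFrame:
    """Tabular match report with the selection flag per row."""
    by_id = {m.motif_id: m for m in motifs}
    rows = [
        {
            "motif_id": m.motif_id,
            "class": by_id[m.motif_id].class_code if m.motif_id in by_id else "",
            "peptide": m.peptide_sequence,
            "start": m.start,
            "end": m.end,
            "matched_subsequence": m.matched_subsequence,
            "selected": m.motif_id in selected,
        }
        for m in matches
    ]
    columns = ["motif_id", "class", "peptide", "start", "end", "matched_subsequence", "selected"]
    return pd.DataFrame(rows, columns=columns)
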