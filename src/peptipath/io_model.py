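"""Domain types, validation, and readers/writers for pipeline file formats.

The pipeline consumes four kinds of input, all plain text:

* a peptide ratio table (TSV) — per-run isotopic-label ratios of endogenous
  plasma peptides in each post-induction group versus the reference control;
* an ELM-style motif database (TSV or JSON) — short linear motif (SLiM)
  classes with regex patterns, annotated-instance taxa and pathway-term links;
* gene sets in GMT format (the standard gene-set exchange format);
* a protein-interaction network as a two-column TSV edge list or 3-column SIF.

Ratios are stored as given (treatment/control); the control group is implicit
with ratio 1 and never appears as a group row.  Identifiers (terms, genes)
are opaque strings — no online ID mapping is attempted.
"""
from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Post-induction sampling groups, compared against the implicit control.
VALID_GROUPS: tuple[str, ...] = ("1h", "3h", "6h", "12h", "24h")

#: Standard 20 amino-acid one-letter codes.
AA_ALPHABET: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: ELM motif class codes (ligand, docking, modification, degron, targeting, cleavage).
MOTIF_CLASSES: tuple[str, ...] = ("LIG", "DOC", "MOD", "DEG", "TRG", "CLV")


class FormatError(ValueError):
    """A file does not conform to its documented format."""


class ValidationError(ValueError):
    """Well-formed input violating a semantic invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeptideRecord:
    """A peptide sequence with its source protein / gene identity.

    Sequences are uppercased on construction; I/L ambiguity is NOT collapsed
    (distinct I/L-containing sequences are distinct peptides).
    """

    sequence: str
    protein_id: str
    gene_symbol: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ValidationError("peptide sequence must be non-empty")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.sequence!r} contains non-amino-acid symbols {sorted(bad)}"
            )
        if not self.protein_id or not self.gene_symbol:
            raise ValidationError(
                f"peptide {self.sequence!r}: protein_id and gene_symbol must be non-empty"
            )


@dataclass(frozen=True)
class RatioObservation:
    """One per-run quantification ratio of a peptide in a group vs. control.

    ``ratio`` is the treatment/control channel ratio and must be positive when
    ``identified`` is true; unidentified rows carry presence/absence
    information for the run-frequency statistic only and contribute no ratio.
    """

    peptide_sequence: str
    group: str
    run_id: str
    ratio: float | None
    identified: bool

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r}; expected one of {VALID_GROUPS}"
            )
        if self.identified:
            if self.ratio is None or not self.ratio > 0:
                raise ValidationError(
                    f"identified observation of {self.peptide_sequence!r} in run "
                    f"{self.run_id!r} must have a positive ratio, got {self.ratio!r}"
                )


@dataclass(frozen=True)
class RegulationCall:
    """Per-peptide, per-group differential-regulation verdict."""

    peptide_sequence: str
    group: str
    direction: str  # "up" | "down" | "unchanged"
    p_value: float
    median_ratio: float
    n_obs: int
    frequency_pct: float
    protein_id: str = ""
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "unchanged"):
            raise ValidationError(f"invalid direction {self.direction!r}")
        if not 0.0 <= self.frequency_pct <= 100.0:
            raise ValidationError(f"frequency_pct out of [0,100]: {self.frequency_pct}")

    @property
    def regulated(self) -> bool:
        return self.direction in ("up", "down")


@dataclass(frozen=True)
class MotifDefinition:
    """An ELM-style short linear motif: regex pattern plus annotations.

    ``class_code`` must be the prefix of ``motif_id`` before the first
    underscore (ELM naming convention, e.g. ``LIG_SH3_1`` is class LIG).
    """

    motif_id: str
    class_code: str
    pattern: str
    instance_taxa: frozenset[str]
    term_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.class_code not in MOTIF_CLASSES:
            raise ValidationError(
                f"motif {self.motif_id!r}: unknown class code {self.class_code!r}"
            )
        prefix = self.motif_id.split("_", 1)[0]
        if prefix != self.class_code:
            raise ValidationError(
                f"motif {self.motif_id!r}: id prefix {prefix!r} does not match "
                f"class code {self.class_code!r}"
            )
        try:
            re.compile(self.pattern)
        except re.error as exc:
            raise FormatError(
                f"motif {self.motif_id!r}: invalid regex {self.pattern!r} ({exc})"
            ) from exc

    @property
    def compiled(self) -> re.Pattern[str]:
        return _compile_cached(self.pattern)


def _compile_cached(pattern: str, _cache: dict[str, re.Pattern[str]] = {}) -> re.Pattern[str]:
    pat = _cache.get(pattern)
    if pat is None:
        pat = _cache[pattern] = re.compile(pattern)
    return pat


@dataclass(frozen=True)
class GeneSet:
    """A pathway term with its member gene symbols."""

    term_id: str
    term_name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.term_id!r} has no genes")


@dataclass(frozen=True)
class EnrichmentResult:
    """A pathway term with its enrichment p-value and magnitude.

    ``magnitude`` is the odds ratio for SLiM over-representation and the fold
    enrichment for the subnetwork stage.  ``support_count`` equals the number
    of contributing member ids.
    """

    term_id: str
    term_name: str
    p_value: float
    magnitude: float
    support_count: int
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.support_count != len(self.member_ids):
            raise ValidationError(
                f"term {self.term_id!r}: support_count {self.support_count} != "
                f"|member_ids| {len(self.member_ids)}"
            )


# ---------------------------------------------------------------------------
# Ratio table I/O
# ---------------------------------------------------------------------------

RATIO_COLUMNS = ("peptide", "protein_id", "gene_symbol", "group", "run_id", "ratio", "identified")

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _parse_bool(token: str, row: int) -> bool:
    low = token.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise FormatError(f"row {row}: cannot parse boolean {token!r}")


def read_ratio_table(path: str | Path) -> tuple[list[RatioObservation], list[PeptideRecord]]:
    """Read the peptide ratio table TSV.

    Returns the per-run observations plus one :class:`PeptideRecord` per
    distinct peptide.  The peptide -> (protein_id, gene_symbol) mapping must be
    consistent across rows.  Row numbers in error messages count the header as
    line 1.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in RATIO_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    observations: list[RatioObservation] = []
    identity: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        seq = str(row.peptide).upper()
        identified = _parse_bool(str(row.identified), i)
        ratio_token = str(row.ratio).strip()
        ratio: float | None
        if ratio_token in ("", "NA", "nan", "None"):
            ratio = None
        else:
            try:
                ratio = float(ratio_token)
            except ValueError as exc:
                raise FormatError(f"row {i}: cannot parse ratio {ratio_token!r}") from exc
        if identified and (ratio is None or ratio <= 0):
            raise ValidationError(
                f"row {i}: identified observation must have a positive ratio, got {ratio!r}"
            )
        try:
            obs = RatioObservation(
                peptide_sequence=seq,
                group=str(row.group),
                run_id=str(row.run_id),
                ratio=ratio if identified else None,
                identified=identified,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        observations.append(obs)
        ident = (str(row.protein_id), str(row.gene_symbol))
        if seq in identity:
            if identity[seq] != ident:
                raise ValidationError(
                    f"row {i}: peptide {seq!r} maps to {ident} but previously to "
                    f"{identity[seq]}"
                )
        else:
            identity[seq] = ident
            order.append(seq)

    peptides = [
        PeptideRecord(sequence=s, protein_id=identity[s][0], gene_symbol=identity[s][1])
        for s in order
    ]
    return observations, peptides


def write_ratio_table(
    observations: Sequence[RatioObservation],
    peptides: Sequence[PeptideRecord],
    path: str | Path,
) -> None:
    """Write observations back out in the ratio-table TSV format."""
    identity = {p.sequence: (p.protein_id, p.gene_symbol) for p in peptides}
    rows = []
    for o in observations:
        prot, gene = identity[o.peptide_sequence]
        rows.append(
            {
                "peptide": o.peptide_sequence,
                "protein_id": prot,
                "gene_symbol": gene,
                "group": o.group,
                "run_id": o.run_id,
                "ratio": "" if o.ratio is None else repr(float(o.ratio)),
                "identified": "true" if o.identified else "false",
            }
        )
    pd.DataFrame(rows, columns=list(RATIO_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (term_id, description, genes...)."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(fields)}")
            term_id, term_name = fields[0], fields[1]
            if term_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            seen.add(term_id)
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {term_id!r} has no genes")
            sets.append(GeneSet(term_id=term_id, term_name=term_name, genes=genes))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.term_id, gs.term_name, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Interaction network
# ---------------------------------------------------------------------------

def read_network(path: str | Path) -> nx.Graph:
    """Read an undirected simple interaction network.

    Accepts a two-column TSV edge list or a three-column SIF (the middle
    interaction-type column is ignored).  Self-loops are dropped with a
    warning; duplicate edges collapse silently.
    """
    graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = re.split(r"[\t ]+", line.strip())
            if len(fields) == 2:
                u, v = fields
            elif len(fields) == 3:
                u, _, v = fields
            else:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 (TSV) or 3 (SIF) fields, got {len(fields)}"
                )
            if u == v:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, u)
                graph.add_node(u)
                continue
            graph.add_edge(u, v)
    return graph


def write_network(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# Motif database
# ---------------------------------------------------------------------------

MOTIF_COLUMNS = ("motif_id", "class_code", "pattern", "instance_taxa", "term_ids")


def _split_tokens(raw: str) -> frozenset[str]:
    return frozenset(t.strip() for t in raw.split(",") if t.strip())


def read_motif_db(path: str | Path) -> list[MotifDefinition]:
    """Read an ELM-style motif database (TSV, or JSON list of objects).

    TSV set-valued fields (``instance_taxa``, ``term_ids``) are comma-joined
    tokens.  Malformed regex patterns are rejected naming the motif.
    """
    path = Path(path)
    records: list[dict] = []
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        for entry in data:
            records.append(
                {
                    "motif_id": entry["motif_id"],
                    "class_code": entry["class_code"],
                    "pattern": entry["pattern"],
                    "instance_taxa": frozenset(entry.get("instance_taxa", [])),
                    "term_ids": frozenset(entry.get("term_ids", [])),
                }
            )
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in MOTIF_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        for row in df.itertuples(index=False):
            records.append(
                {
                    "motif_id": row.motif_id,
                    "class_code": row.class_code,
                    "pattern": row.pattern,
                    "instance_taxa": _split_tokens(str(row.instance_taxa)),
                    "term_ids": _split_tokens(str(row.term_ids)),
                }
            )
    motifs = [MotifDefinition(**rec) for rec in records]
    for m in motifs:
        m.compiled  # compile and cache eagerly; FormatError already raised on bad regex
    return motifs


def write_motif_db(motifs: Sequence[MotifDefinition], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = [
            {
                "motif_id": m.motif_id,
                "class_code": m.class_code,
                "pattern": m.pattern,
                "instance_taxa": sorted(m.instance_taxa),
                "term_ids": sorted(m.term_ids),
            }
            for m in motifs
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
    else:
        rows = [
            {
                "motif_id": m.motif_id,
                "class_code": m.class_code,
                "pattern": m.pattern,
                "instance_taxa": ",".join(sorted(m.instance_taxa)),
                "term_ids": ",".join(sorted(m.term_ids)),
            }
            for m in motifs
        ]
        pd.DataFrame(rows, columns=list(MOTIF_COLUMNS)).to_csv(path, sep="\t", index=False)
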