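"""Synthetic generators for every input the pipeline consumes.

The raw study data are label-based LC-MS/MS ratio measurements; this module
emulates their statistical shape so every stage is testable offline:

* per-run peptide ratios with log-normal multiplicative noise around a
  direction-dependent median (the standard noise model for MS ratio data),
  following a planted (peptide, group) -> up/down/unchanged direction pattern;
* ELM-style motif databases where planted motifs are literal substrings of
  their target peptides (guaranteed hits) among random-pattern decoys;
* gene-set collections and protein-interaction networks with a planted,
  fully connected module attached to an Erdos-Renyi background.

The packaged direction pattern reproduces the observed study surface: ten
plasma peptides from eight source proteins, with per-group regulated counts
1 (1h), 1 (3h), 4 (6h), 8 (12h) and 4 (24h).  Generator defaults (10 runs
per group, up/down medians 4.0 / 0.25, log-sigma 0.15) are chosen so a
planted direction is essentially always recovered by the screen: with five
tie-free same-sign observations the exact two-sided signed-rank minimum is
p = 0.0625 > 0.05, so significant calls require more observations per group
than animals — multiple MS runs/labels per animal — hence the default of 10.

All generators are pure functions of their spec: a fixed seed gives
bitwise-identical output.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_model import (
    VALID_GROUPS,
    MotifDefinition,
    PeptideRecord,
    RatioObservation,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class GenerationError(ValueError):
    """A planted structure cannot be realised from the given inputs."""


# ---------------------------------------------------------------------------
# Packaged fixture: the observed peptide table
# ---------------------------------------------------------------------------

def _load_fixture_frame() -> pd.DataFrame:
    ref = importlib.resources.files("peptipath").joinpath("data/table1_fixture.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype=str)


def table1_fixture() -> tuple[
    list[PeptideRecord], dict[tuple[str, str], str], dict[str, float]
]:
    """The packaged observed-peptide fixture.

    Returns the ten peptide records (eight distinct source proteins), the
    per-(peptide, group) direction pattern, and the mean identification
    frequency (percent of MS runs) per peptide.
    """
    df = _load_fixture_frame()
    peptides = []
    pattern: dict[tuple[str, str], str] = {}
    frequency: dict[str, float] = {}
    for _, row in df.iterrows():
        peptides.append(
            PeptideRecord(
                sequence=row["peptide"],
                protein_id=row["protein_id"],
                gene_symbol=row["gene_symbol"],
            )
        )
        for group in VALID_GROUPS:
            pattern[(row["peptide"], group)] = row[group]
        frequency[row["peptide"]] = float(row["freq_mean"])
    return peptides, pattern, frequency


# ---------------------------------------------------------------------------
# Ratio dataset generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the planted ratio-replicate generator.

    ``direction_pattern`` maps (peptide_sequence, group) to up/down/unchanged;
    peptides and pattern default to the packaged fixture.  Medians are on the
    ratio scale; noise is log-normal with standard deviation ``log_sigma`` on
    the natural-log scale.
    """

    seed: int
    n_runs_per_group: int = 10
    up_median: float = 4.0
    down_median: float = 0.25
    null_median: float = 1.0
    log_sigma: float = 0.15
    peptides: tuple[PeptideRecord, ...] = ()
    direction_pattern: Mapping[tuple[str, str], str] | None = None

    def __post_init__(self) -> None:
        if self.n_runs_per_group < 1:
            raise GenerationError("n_runs_per_group must be >= 1")
        if not (self.down_median < 1.0 < self.up_median):
            raise GenerationError("need down_median < 1 < up_median")
        if not self.log_sigma > 0:
            raise GenerationError("log_sigma must be positive")
        if not self.peptides or self.direction_pattern is None:
            peptides, pattern, _ = table1_fixture()
            if not self.peptides:
                object.__setattr__(self, "peptides", tuple(peptides))
            if self.direction_pattern is None:
                object.__setattr__(self, "direction_pattern", pattern)


def generate_ratio_dataset(spec: GeneratorSpec) -> list[RatioObservation]:
    """Per-run ratio replicates following the spec's direction pattern.

    Each (peptide, group) cell receives ``n_runs_per_group`` identified
    observations with ratio = median_direction * exp(N(0, log_sigma)).
    Iteration order (group, peptide, run) and a fresh PCG64 stream make the
    output bitwise-reproducible per seed.
    """
    rng = np.random.default_rng(spec.seed)
    medians = {
        "up": spec.up_median,
        "down": spec.down_median,
        "unchanged": spec.null_median,
    }
    observations: list[RatioObservation] = []
    for group in VALID_GROUPS:
        for pep in spec.peptides:
            direction = spec.direction_pattern.get((pep.sequence, group), "unchanged")
            center = medians[direction]
            noise = rng.normal(0.0, spec.log_sigma, size=spec.n_runs_per_group)
            for i in range(spec.n_runs_per_group):
                observations.append(
                    RatioObservation(
                        peptide_sequence=pep.sequence,
                        group=group,
                        run_id=f"{group}_run{i + 1:02d}",
                        ratio=float(center * np.exp(noise[i])),
                        identified=True,
                    )
                )
    return observations


def emulate_frequencies(
    observations: Sequence[RatioObservation],
    frequency_pct: Mapping[str, float],
    seed: int,
) -> list[RatioObservation]:
    """Subsample identified flags so per-peptide run frequencies match targets.

    For each (peptide, group) cell, round(frequency/100 * n_runs) runs stay
    identified; the rest become unidentified presence rows (no ratio).  Which
    runs are kept is drawn from the seeded stream.
    """
    rng = np.random.default_rng(seed)
    cells: dict[tuple[str, str], list[RatioObservation]] = {}
    for o in observations:
        cells.setdefault((o.peptide_sequence, o.group), []).append(o)
    out: list[RatioObservation] = []
    for o in observations:
        cell = cells[(o.peptide_sequence, o.group)]
        if o is cell[0]:  # decide the whole cell once, on first encounter
            target = frequency_pct.get(o.peptide_sequence, 100.0)
            n_keep = int(round(target / 100.0 * len(cell)))
            keep_idx = set(rng.choice(len(cell), size=n_keep, replace=False).tolist())
            for j, obs in enumerate(cell):
                if j in keep_idx:
                    out.append(obs)
                else:
                    out.append(
                        RatioObservation(
                            peptide_sequence=obs.peptide_sequence,
                            group=obs.group,
                            run_id=obs.run_id,
                            ratio=None,
                            identified=False,
                        )
                    )
    return out


# ---------------------------------------------------------------------------
# Motif database generator
# ---------------------------------------------------------------------------

def generate_motif_db(
    seed: int,
    n_motifs: int,
    planted: Mapping[str, tuple[Sequence[str], Sequence[str]]],
    *,
    taxon: str = "Mus musculus",
    decoy_term_pool: Sequence[str] = (),
    planted_length: int = 6,
) -> list[MotifDefinition]:
    """ELM-style motif DB with guaranteed-hit planted motifs among decoys.

    ``planted`` maps motif_id -> (target peptide sequences, term_ids); each
    planted pattern is a literal substring of its first target (length
    ``planted_length``) and must occur in every target, else GenerationError.
    Planted ids must carry a DOC or LIG prefix so the default selection
    filter keeps them; decoys are random literal 5-mers (per-peptide hit
    probability well under 5%), mostly filter-passing with a minority of
    off-class / off-taxon entries to exercise the filters.
    """
    rng = np.random.default_rng(seed)
    motifs: list[MotifDefinition] = []
    for motif_id, (targets, term_ids) in sorted(planted.items()):
        if not targets:
            raise GenerationError(f"planted motif {motif_id!r} has no target peptides")
        first = targets[0].upper()
        length = min(planted_length, len(first))
        start = int(rng.integers(0, len(first) - length + 1))
        pattern = first[start : start + length]
        for t in targets:
            if pattern not in t.upper():
                raise GenerationError(
                    f"planted motif {motif_id!r}: substring {pattern!r} absent from "
                    f"target {t!r}"
                )
        class_code = motif_id.split("_", 1)[0]
        if class_code not in ("DOC", "LIG"):
            raise GenerationError(
                f"planted motif id {motif_id!r} must use a DOC_ or LIG_ prefix to "
                "survive the default class filter"
            )
        motifs.append(
            MotifDefinition(
                motif_id=motif_id,
                class_code=class_code,
                pattern=pattern,
                instance_taxa=frozenset({taxon}),
                term_ids=frozenset(term_ids),
            )
        )
    n_decoys = n_motifs - len(motifs)
    if n_decoys < 0:
        raise GenerationError(f"n_motifs={n_motifs} smaller than planted set {len(motifs)}")
    decoy_terms = list(decoy_term_pool) or [f"term_decoy_{i:02d}" for i in range(8)]
    for i in range(n_decoys):
        pattern = "".join(rng.choice(list(AMINO_ACIDS), size=5))
        r = rng.random()
        if r < 0.8:  # filter-passing decoys populate the reference universe
            class_code = "LIG" if rng.random() < 0.5 else "DOC"
            taxa = frozenset({taxon})
        elif r < 0.9:
            class_code = "MOD"
            taxa = frozenset({taxon})
        else:
            class_code = "LIG"
            taxa = frozenset({"Homo sapiens"})
        terms = frozenset(
            rng.choice(decoy_terms, size=min(2, len(decoy_terms)), replace=False).tolist()
        )
        motifs.append(
            MotifDefinition(
                motif_id=f"{class_code}_DECOY_{i:03d}",
                class_code=class_code,
                pattern=pattern,
                instance_taxa=taxa,
                term_ids=terms,
            )
        )
    return motifs


# ---------------------------------------------------------------------------
# Network generator
# ---------------------------------------------------------------------------

def generate_network(
    seed: int,
    n_nodes: int,
    planted_module: Sequence[str] = (),
    *,
    edge_prob: float = 0.05,
) -> nx.Graph:
    """Erdos-Renyi background with a planted fully connected module.

    The module genes form a clique; remaining nodes are named G001, G002, ...
    Connectivity is guaranteed by linking consecutive components after the
    random edges are drawn (spanning-tree augmentation), so the graph is
    always simple, undirected and connected.
    """
    module = list(dict.fromkeys(planted_module))
    if len(module) > n_nodes:
        raise GenerationError("planted module larger than the network")
    rng = np.random.default_rng(seed)
    background = [f"G{i:03d}" for i in range(1, n_nodes - len(module) + 1)]
    nodes = module + background
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if rng.random() < edge_prob:
                graph.add_edge(nodes[i], nodes[j])
    for i in range(len(module)):
        for j in range(i + 1, len(module)):
            graph.add_edge(module[i], module[j])
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: c[0])
    for prev, cur in zip(components, components[1:]):
        graph.add_edge(prev[0], cur[0])
    return graph
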