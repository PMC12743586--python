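"""End-to-end orchestration: screen -> scan -> ORA -> subnetwork per comparison.

This is the library behind the command-line interface: it validates a
:class:`PipelineConfig`, runs each stage for every post-induction comparison
group, and writes the stage TSVs plus a ``summary.json`` describing counts,
parameters and the seed.  Re-running with an identical config and seed
reproduces byte-identical outputs.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .io_model import (
    VALID_GROUPS,
    RegulationCall,
    ValidationError,
    read_gmt,
    read_motif_db,
    read_network,
    read_ratio_table,
)
from .ora import build_reference_universe, ora_per_term, ora_to_frame
from .screening import ScreeningConfig, calls_to_frame, regulated_counts, screen_dataset
from .slim_scan import DEFAULT_CLASSES, DEFAULT_TAXON, matches_to_frame, scan_peptides, select_slims
from .subnetwork import (
    enrich_subnetworks,
    enrichment_to_frame,
    find_subnetworks,
    genes_from_calls,
    subnetworks_to_frame,
)


@dataclass
class PipelineConfig:
    """Paths and options of a full pipeline run."""

    ratio_table: Path
    motif_db: Path
    gene_sets: Path
    network: Path
    out_dir: Path
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    slim_classes: frozenset[str] = DEFAULT_CLASSES
    slim_taxon: str = DEFAULT_TAXON
    ora_alpha: float = 0.05
    ora_top_k: int = 5
    ora_alternative: str = "greater"
    min_term_genes: int = 2
    background_size: int | None = None  # default: number of PIN nodes
    seed: int = 0

    def validate(self) -> None:
        for name in ("ratio_table", "motif_db", "gene_sets", "network"):
            path = getattr(self, name)
            if not Path(path).is_file():
                raise ValidationError(f"--{name.replace('_', '-')}: no such file {path}")
        if not (0.0 < self.ora_alpha < 1.0):
            raise ValidationError(f"--alpha must be in (0,1) exclusive, got {self.ora_alpha}")
        if self.ora_top_k < 1:
            raise ValidationError(f"--top-k must be >= 1, got {self.ora_top_k}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle; returns the summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    observations, peptides = read_ratio_table(config.ratio_table)
    motifs = read_motif_db(config.motif_db)
    gene_sets = read_gmt(config.gene_sets)
    network = read_network(config.network)
    background = config.background_size or network.number_of_nodes()

    # Stage 1: differential-regulation screen
    calls = screen_dataset(observations, peptides, config.screening)
    calls_to_frame(calls).to_csv(out / "regulation_calls.tsv", sep="\t", index=False)
    counts = regulated_counts(calls)
    counts.to_csv(out / "regulated_counts.tsv", sep="\t", index=False)
    volcano_table(calls).to_csv(out / "volcano.tsv", sep="\t", index=False)

    peptide_by_seq = {p.sequence: p for p in peptides}
    universe = build_reference_universe(motifs, config.slim_classes, config.slim_taxon)
    term_names = {gs.term_id: gs.term_name for gs in gene_sets}

    match_frames, ora_frames, subnet_frames, subnet_enrich_frames = [], [], [], []
    summary_groups = {}
    for group in VALID_GROUPS:
        group_calls = [c for c in calls if c.group == group]
        regulated = [c for c in group_calls if c.regulated]
        reg_peptides = [peptide_by_seq[c.peptide_sequence] for c in regulated]

        # Stage 2: SLiM scan of the comparison's regulated peptides
        matches = scan_peptides(reg_peptides, motifs)
        selected = select_slims(matches, motifs, config.slim_classes, config.slim_taxon)
        mf = matches_to_frame(matches, motifs, selected)
        mf.insert(0, "comparison", group)
        match_frames.append(mf)

        # Stage 3: SLiM over-representation per pathway term
        ora_results = ora_per_term(
            selected & universe,
            motifs,
            universe,
            alpha=config.ora_alpha,
            top_k=config.ora_top_k,
            alternative=config.ora_alternative,
            comparison=group,
            term_names=term_names,
        )
        ora_frames.append(ora_to_frame(ora_results))

        # Stage 4: active subnetworks seeded by regulated-peptide genes
        scores = genes_from_calls(group_calls)
        subnets = find_subnetworks(network, scores, alpha=config.screening.alpha)
        sf = subnetworks_to_frame(subnets, scores, alpha=config.screening.alpha)
        sf.insert(0, "comparison", group)
        subnet_frames.append(sf)
        enrich = enrich_subnetworks(
            subnets,
            gene_sets,
            background,
            input_genes={s.gene_symbol for s in scores},
            min_term_genes=config.min_term_genes,
            comparison=group,
        )
        subnet_enrich_frames.append(enrichment_to_frame(enrich))

        summary_groups[group] = {
            "n_regulated_peptides": len(regulated),
            "n_selected_slims": len(selected),
            "n_significant_ora_terms": sum(r.significant for r in ora_results),
            "n_subnetworks": len(subnets),
            "n_enriched_subnet_terms": sum(e.p_value <= config.ora_alpha for e in enrich),
        }

    _concat(match_frames).to_csv(out / "slim_matches.tsv", sep="\t", index=False)
    _concat(ora_frames).to_csv(out / "slim_ora.tsv", sep="\t", index=False)
    _concat(subnet_frames).to_csv(out / "subnetworks.tsv", sep="\t", index=False)
    _concat(subnet_enrich_frames).to_csv(out / "subnet_enrichment.tsv", sep="\t", index=False)

    summary = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "fold_up": config.screening.fold_up,
            "fold_down": config.screening.fold_down,
            "alpha": config.screening.alpha,
            "test_scale": config.screening.test_scale,
            "zero_policy": config.screening.zero_policy,
            "slim_classes": sorted(config.slim_classes),
            "slim_taxon": config.slim_taxon,
            "ora_alpha": config.ora_alpha,
            "ora_top_k": config.ora_top_k,
            "min_term_genes": config.min_term_genes,
            "background_size": background,
        },
        "regulated_counts": {
            row.group: int(row.n_total) for row in counts.itertuples(index=False)
        },
        "groups": summary_groups,
        "universe_size": len(universe),
        "n_peptides": len(peptides),
        "n_observations": len(observations),
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary


def _concat(frames: list[pd.DataFrame]) -> pd.DataFrame:
    # keep the header of the first frame even when every group is empty
    nonempty = [f for f in frames if not f.empty]
    return pd.concat(nonempty, ignore_index=True) if nonempty else frames[0]


def volcano_table(calls: Sequence[RegulationCall]) -> pd.DataFrame:
    """Frequency vs. -log10(p) per peptide/group with direction colour labels.

    Colours follow the convention red = significantly increased, green =
    significantly decreased, gray = unchanged.
    """
    colour = {"up": "red", "down": "green", "unchanged": "gray"}
    rows = [
        {
            "peptide": c.peptide_sequence,
            "group": c.group,
            "frequency_pct": c.frequency_pct,
            "neg_log10_p": -math.log10(c.p_value),
            "color": colour[c.direction],
        }
        for c in calls
    ]
    columns = ["peptide", "group", "frequency_pct", "neg_log10_p", "color"]
    return pd.DataFrame(rows, columns=columns)
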