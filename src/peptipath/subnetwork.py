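"""Active-subnetwork identification and pathway enrichment on a PIN.

Genes encoding the source proteins of differentially regulated peptides seed
a deterministic greedy search on the protein-interaction network (PIN): each
significant gene starts a subnetwork that repeatedly absorbs the neighbouring
gene maximising the aggregate score sum(z)/sqrt(k), stopping when no single
addition strictly improves it.  Node scores are z = Phi^-1(1 - p) (one-sided,
clamped to |z| <= 10); genes absent from the input get z = 0.  This replaces
the genetic / simulated-annealing search of interactive active-subnetwork
tools with a reproducible, exhaustively testable greedy — adequate at the
scale of a handful of seed genes, and deliberately so.

The union of subnetwork genes is then tested per pathway term with the
hypergeometric upper tail; the magnitude is the fold enrichment
(k/n)/(K/N), and terms overlapping fewer than two genes are dropped.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

from .io_model import EnrichmentResult, GeneSet, RegulationCall, ValidationError

#: Clamp for node z-scores, avoiding infinities as p -> 0.
Z_CLAMP = 10.0


@dataclass(frozen=True)
class GeneScore:
    """A seed gene with its best peptide p-value and derived node score."""

    gene_symbol: str
    p_value: float
    z: float


@dataclass(frozen=True)
class Subnetwork:
    """A connected gene set with its aggregate score sum(z)/sqrt(k)."""

    genes: frozenset[str]
    score: float


def z_from_p(p: float) -> float:
    """One-sided node score Phi^-1(1 - p), clamped to [-Z_CLAMP, Z_CLAMP]."""
    z = float(stats.norm.ppf(1.0 - p))
    return max(-Z_CLAMP, min(Z_CLAMP, z))


def genes_from_calls(calls: Iterable[RegulationCall]) -> list[GeneScore]:
    """Seed genes for one comparison: genes with >= 1 regulated peptide.

    A gene's p-value is the minimum p among its regulated (up or down)
    peptides; multiple regulated peptides of one protein collapse to one
    entry.  Returns an empty list when nothing is regulated.
    """
    best: dict[str, float] = {}
    for c in calls:
        if not c.regulated:
            continue
        if not c.gene_symbol:
            raise ValidationError(
                f"regulated peptide {c.peptide_sequence!r} carries no gene symbol"
            )
        prev = best.get(c.gene_symbol)
        if prev is None or c.p_value < prev:
            best[c.gene_symbol] = c.p_value
    return [
        GeneScore(gene_symbol=g, p_value=p, z=z_from_p(p))
        for g, p in sorted(best.items())
    ]


def subnetwork_score(genes: Iterable[str], zmap: Mapping[str, float]) -> float:
    """Aggregate score sum(z_i)/sqrt(k) of a gene set."""
    genes = list(genes)
    if not genes:
        raise ValueError("cannot score an empty gene set")
    return sum(zmap.get(g, 0.0) for g in genes) / math.sqrt(len(genes))


def greedy_active_subnetwork(
    network: nx.Graph, zmap: Mapping[str, float], seed_gene: str
) -> Subnetwork:
    """Greedy seed-and-grow: absorb the best-scoring neighbour until stuck.

    Ties between candidate neighbours are broken by higher z, then by
    lexicographic gene symbol, making the search fully deterministic.  The
    score never decreases during growth and the result induces a connected
    subgraph by construction.
    """
    if seed_gene not in network:
        raise ValueError(f"seed gene {seed_gene!r} is not in the network")
    members: set[str] = {seed_gene}
    score = subnetwork_score(members, zmap)
    frontier: set[str] = set(network[seed_gene]) - members
    while True:
        if not frontier:
            break
        best_gene = max(
            frontier,
            key=lambda g: (
                subnetwork_score(members | {g}, zmap),
                zmap.get(g, 0.0),
                _LexDesc(g),
            ),
        )
        new_score = subnetwork_score(members | {best_gene}, zmap)
        if new_score <= score:
            break
        members.add(best_gene)
        score = new_score
        frontier |= set(network[best_gene])
        frontier -= members
    return Subnetwork(genes=frozenset(members), score=score)


class _LexDesc:
    """Reverse-order wrapper so max() prefers the lexicographically smaller symbol."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_LexDesc") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _LexDesc) and self.s == other.s


def find_subnetworks(
    network: nx.Graph,
    scores: Sequence[GeneScore],
    *,
    alpha: float = 0.05,
    min_sig_genes: int = 1,
) -> list[Subnetwork]:
    """One greedy run per significant input gene present in the network.

    Resulting subnetworks are deduplicated by gene set, required to contain
    at least ``min_sig_genes`` significant input genes, and sorted by score
    descending (ties by sorted gene tuple).
    """
    zmap = {s.gene_symbol: s.z for s in scores}
    significant = sorted(
        s.gene_symbol for s in scores if s.p_value <= alpha and s.gene_symbol in network
    )
    seen: set[frozenset[str]] = set()
    out: list[Subnetwork] = []
    for seed in significant:
        sub = greedy_active_subnetwork(network, zmap, seed)
        if sub.genes in seen:
            continue
        seen.add(sub.genes)
        if len(sub.genes & set(significant)) >= min_sig_genes:
            out.append(sub)
    out.sort(key=lambda s: (-s.score, tuple(sorted(s.genes))))
    return out


@dataclass(frozen=True)
class SubnetTermEnrichment:
    """One term's subnetwork enrichment (hypergeometric, fold enrichment)."""

    comparison: str
    term_id: str
    term_name: str
    k: int  # query genes in the term
    n: int  # query (subnetwork-union) size
    K: int  # term genes in the background
    N: int  # background size
    p_value: float
    fold_enrichment: float
    support_count: int  # input (regulated-peptide) genes in the term
    member_ids: tuple[str, ...]

    def as_enrichment_result(self) -> EnrichmentResult:
        return EnrichmentResult(
            term_id=self.term_id,
            term_name=self.term_name,
            p_value=self.p_value,
            magnitude=self.fold_enrichment,
            support_count=len(self.member_ids),
            member_ids=self.member_ids,
        )


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N, K, n)."""
    return float(min(1.0, max(stats.hypergeom.sf(k - 1, N, K, n), 0.0)))


def enrich_subnetworks(
    subnets: Sequence[Subnetwork],
    gene_sets: Sequence[GeneSet],
    background_size: int,
    *,
    input_genes: set[str] | None = None,
    min_term_genes: int = 2,
    comparison: str = "",
) -> list[SubnetTermEnrichment]:
    """Hypergeometric term enrichment of the pooled subnetwork genes.

    The query is the union of all subnetwork genes (n); per term of size K in
    a background of N genes, the overlap k is tested with the upper tail and
    the fold enrichment is (k/n)/(K/N).  Terms with k < ``min_term_genes``
    are dropped.  ``support_count`` reports how many of the original
    regulated-peptide input genes fall in the term (defaults to the overlap
    when ``input_genes`` is not given).
    """
    union_genes = frozenset().union(*(s.genes for s in subnets)) if subnets else frozenset()
    all_term_genes = frozenset().union(*(gs.genes for gs in gene_sets)) if gene_sets else frozenset()
    if background_size < len(all_term_genes):
        raise ValidationError(
            f"background_size {background_size} smaller than the union of gene-set "
            f"genes ({len(all_term_genes)})"
        )
    n = len(union_genes)
    results: list[SubnetTermEnrichment] = []
    if n == 0:
        return results
    for gs in gene_sets:
        overlap = sorted(union_genes & gs.genes)
        k = len(overlap)
        if k < min_term_genes:
            continue
        K = len(gs.genes)
        N = background_size
        p = hypergeom_upper_tail(k, N, K, n)
        fold = (k / n) / (K / N)
        support = overlap if input_genes is None else sorted(input_genes & gs.genes)
        results.append(
            SubnetTermEnrichment(
                comparison=comparison,
                term_id=gs.term_id,
                term_name=gs.term_name,
                k=k, n=n, K=K, N=N,
                p_value=p,
                fold_enrichment=fold,
                support_count=len(support),
                member_ids=tuple(overlap),
            )
        )
    results.sort(key=lambda r: (r.p_value, -r.fold_enrichment, r.term_id))
    return results


def subnetworks_to_frame(subnets: Sequence[Subnetwork], scores: Sequence[GeneScore],
                         alpha: float = 0.05) -> pd.DataFrame:
    significant = {s.gene_symbol for s in scores if s.p_value <= alpha}
    rows = [
        {
            "genes": ",".join(sorted(s.genes)),
            "score": s.score,
            "n_significant": len(s.genes & significant),
        }
        for s in subnets
    ]
    return pd.DataFrame(rows, columns=["genes", "score", "n_significant"])


def enrichment_to_frame(results: Sequence[SubnetTermEnrichment]) -> pd.DataFrame:
    rows = [
        {
            "comparison": r.comparison,
            "term_id": r.term_id,
            "term_name": r.term_name,
            "k": r.k, "n": r.n, "K": r.K, "N": r.N,
            "p_value": r.p_value,
            "fold_enrichment": r.fold_enrichment,
            "support_count": r.support_count,
        }
        for r in results
    ]
    columns = ["comparison", "term_id", "term_name", "k", "n", "K", "N",
               "p_value", "fold_enrichment", "support_count"]
    return pd.DataFrame(rows, columns=columns)
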