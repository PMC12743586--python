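"""Over-representation analysis (ORA) of selected SLiMs per pathway term.

For each pathway term the selected SLiM set is cross-tabulated against the
reference universe (all class/taxon-filtered motifs annotated to at least one
term) and tested with Fisher's exact test, one-sided for enrichment by
default.  The sample odds ratio (a*d)/(b*c) is the magnitude of enrichment;
zero cells receive the Haldane-Anscombe +0.5 correction (flagged) so
magnitudes stay finite.

Reporting mirrors a bubble-plot surface: raw p <= alpha marks significance
(no multiple-testing correction by default; Benjamini-Hochberg optional) and,
per comparison, the five terms with the lowest significant p-values are
flagged ``top5`` (ties broken by larger odds ratio, then term id).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .io_model import EnrichmentResult, MotifDefinition, ValidationError
from .slim_scan import DEFAULT_CLASSES, DEFAULT_TAXON


class ConfigurationError(ValueError):
    """The analysis cannot be set up from the given inputs."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of selected vs. term-annotated SLiM counts.

    a: selected & annotated, b: selected & not, c: not selected & annotated,
    d: neither.  a+b is the selected set size, a+c the term's reference SLiMs,
    a+b+c+d the reference universe.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError(f"negative cell in contingency table {self}")


def build_reference_universe(
    motifs: Sequence[MotifDefinition],
    classes: frozenset[str] | set[str] = DEFAULT_CLASSES,
    taxon: str = DEFAULT_TAXON,
) -> set[str]:
    """Reference universe: filtered motifs annotated to >= 1 pathway term.

    Independent of any selected set.  An empty universe means the motif
    database cannot support the analysis and raises ConfigurationError.
    """
    universe = {
        m.motif_id
        for m in motifs
        if m.class_code in classes and taxon in m.instance_taxa and m.term_ids
    }
    if not universe:
        raise ConfigurationError(
            f"no motif passes the class ({sorted(classes)}) / taxon ({taxon!r}) filter "
            "with at least one pathway-term annotation"
        )
    return universe


def make_contingency(
    selected: set[str], term_motifs: set[str], universe: set[str]
) -> ContingencyTable:
    """Cross-tabulate a selected SLiM set against one term inside the universe."""
    if not selected <= universe:
        raise ValidationError("selected set must be a subset of the universe")
    a = len(selected & term_motifs)
    b = len(selected) - a
    c = len(term_motifs & universe) - a
    d = len(universe) - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def fisher_exact_enrichment(table: ContingencyTable, alternative: str = "greater") -> float:
    """Fisher's exact p-value; 'greater' gives the enrichment upper tail.

    One-sided enrichment p = sum_{k >= a} P[K = k] for K hypergeometric with
    the table's margins.
    """
    _, p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative=alternative
    )
    return float(min(1.0, max(p, 0.0)))


def odds_ratio(table: ContingencyTable) -> tuple[float, bool]:
    """Sample odds ratio (a*d)/(b*c); Haldane-Anscombe corrected on zero cells.

    Returns (odds_ratio, corrected) — corrected is True when +0.5 was added
    to every cell to keep the ratio finite and positive.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c), True
    return (a * d) / (b * c), False


@dataclass(frozen=True)
class SlimTermEnrichment:
    """One term's SLiM over-representation result for one comparison."""

    comparison: str
    term_id: str
    term_name: str
    a: int
    b: int
    c: int
    d: int
    p_value: float
    odds_ratio: float
    corrected: bool
    support_count: int
    member_ids: tuple[str, ...]
    significant: bool
    top5: bool

    def as_enrichment_result(self) -> EnrichmentResult:
        return EnrichmentResult(
            term_id=self.term_id,
            term_name=self.term_name,
            p_value=self.p_value,
            magnitude=self.odds_ratio,
            support_count=self.support_count,
            member_ids=self.member_ids,
        )


def ora_per_term(
    selected: set[str],
    motifs: Sequence[MotifDefinition],
    universe: set[str],
    *,
    alpha: float = 0.05,
    top_k: int = 5,
    alternative: str = "greater",
    comparison: str = "",
    term_names: Mapping[str, str] | None = None,
    multiple_testing: str = "none",
) -> list[SlimTermEnrichment]:
    """Fisher ORA over every term with at least one selected SLiM.

    Terms are taken from the universe motifs' annotations.  Results are
    sorted by (p, -odds_ratio, term_id); after the significance filter the
    ``top_k`` lowest-p terms of the comparison are flagged ``top5``.
    """
    if not selected <= universe:
        raise ValidationError("selected set must be a subset of the universe")
    if multiple_testing not in ("none", "bh"):
        raise ValueError(f"unknown multiple_testing {multiple_testing!r}")
    term_names = term_names or {}
    by_id = {m.motif_id: m for m in motifs}
    term_to_motifs: dict[str, set[str]] = {}
    for mid in universe:
        for tid in by_id[mid].term_ids:
            term_to_motifs.setdefault(tid, set()).add(mid)

    raw: list[tuple[str, ContingencyTable, float, float, bool, tuple[str, ...]]] = []
    for tid in sorted(term_to_motifs):
        members = tuple(sorted(selected & term_to_motifs[tid]))
        if not members:
            continue
        table = make_contingency(selected, term_to_motifs[tid], universe)
        p = fisher_exact_enrichment(table, alternative=alternative)
        orat, corr = odds_ratio(table)
        raw.append((tid, table, p, orat, corr, members))

    if multiple_testing == "bh" and raw:
        qs = stats.false_discovery_control([r[2] for r in raw], method="bh")
        raw = [
            (tid, tab, float(min(1.0, q)), orat, corr, mem)
            for (tid, tab, _, orat, corr, mem), q in zip(raw, qs)
        ]

    raw.sort(key=lambda r: (r[2], -r[3], r[0]))
    top_ids = {tid for tid, *_ in
               [r for r in raw if r[2] <= alpha][:top_k]}

    results = [
        SlimTermEnrichment(
            comparison=comparison,
            term_id=tid,
            term_name=term_names.get(tid, tid),
            a=tab.a, b=tab.b, c=tab.c, d=tab.d,
            p_value=p,
            odds_ratio=orat,
            corrected=corr,
            support_count=len(mem),
            member_ids=mem,
            significant=p <= alpha,
            top5=tid in top_ids,
        )
        for tid, tab, p, orat, corr, mem in raw
    ]
    return results


def ora_to_frame(results: Sequence[SlimTermEnrichment]) -> pd.DataFrame:
    """Tabular ORA report (the data behind a term-by-comparison bubble plot)."""
    rows = [
        {
            "comparison": r.comparison,
            "term_id": r.term_id,
            "term_name": r.term_name,
            "a": r.a, "b": r.b, "c": r.c, "d": r.d,
            "p_value": r.p_value,
            "odds_ratio": r.odds_ratio,
            "corrected": r.corrected,
            "n_slims": r.support_count,
            "top5": r.top5,
        }
        for r in results
    ]
    columns = [
        "comparison", "term_id", "term_name", "a", "b", "c", "d",
        "p_value", "odds_ratio", "corrected", "n_slims", "top5",
    ]
    return pd.DataFrame(rows, columns=columns)
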