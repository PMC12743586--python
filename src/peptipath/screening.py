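"""Differential-regulation screening of peptide ratios.

For every (peptide, group) cell the stage combines

* a fold-change filter on the group's central ratio — keep increases of 2x or
  more, or decreases to 0.5x or less, both thresholds inclusive — with
* a one-sample Wilcoxon signed-rank test of the per-run ratios against the
  null effect of 1, significant at p <= 0.05, and
* the run-frequency statistic: the percentage of the group's MS runs in which
  the peptide sequence was identified.

The test operates on log-ratios by default: multiplicative ratio data are
symmetric around 1 on the log scale, making the null exactly location-zero
and giving the exact r -> 1/r up/down symmetry.  On the log scale the group
center is the geometric median (exp of the median log-ratio; for even n the
geometric midpoint of the two central order statistics), on the raw ratio
scale the plain sample median.

No multiple-testing correction is applied by default (raw p <= 0.05);
Benjamini-Hochberg is available per group via ``multiple_testing="bh"``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import (
    VALID_GROUPS,
    PeptideRecord,
    RatioObservation,
    RegulationCall,
    ValidationError,
)

#: Largest effective sample size for which the exact signed-rank null is used.
EXACT_LIMIT = 25

_P_FLOOR = 1e-300  # keep p in (0, 1] even when the normal tail underflows


@dataclass(frozen=True)
class ScreeningConfig:
    """Thresholds and numerical conventions of the screening stage.

    fold_up / fold_down
        Inclusive fold-change gates on the group median ratio (defaults 2.0
        and 0.5 — a doubling or a halving versus control).
    alpha
        Significance level for the signed-rank p-value (default 0.05).
    test_scale
        ``"log_ratio"`` (default) tests log(ratio) against log(1) = 0;
        ``"ratio"`` tests the raw ratios against 1.
    zero_policy
        ``"drop"`` (default) removes exact-null observations before ranking
        (classic Wilcoxon); ``"pratt"`` keeps them in the ranking.
    """

    fold_up: float = 2.0
    fold_down: float = 0.5
    alpha: float = 0.05
    test_scale: str = "log_ratio"
    zero_policy: str = "drop"

    def __post_init__(self) -> None:
        if not (self.fold_down < 1.0 < self.fold_up):
            raise ValidationError(
                f"need fold_down < 1 < fold_up, got {self.fold_down}, {self.fold_up}"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.test_scale not in ("ratio", "log_ratio"):
            raise ValidationError(f"unknown test_scale {self.test_scale!r}")
        if self.zero_policy not in ("drop", "pratt"):
            raise ValidationError(f"unknown zero_policy {self.zero_policy!r}")


class WilcoxonResult(NamedTuple):
    p_value: float
    n_effective: int
    method: str  # "exact" | "approx" | "degenerate"


def wilcoxon_signed_rank_one_sample(
    values: Sequence[float],
    mu: float = 1.0,
    *,
    test_scale: str = "log_ratio",
    zero_policy: str = "drop",
) -> WilcoxonResult:
    """Two-sided one-sample Wilcoxon signed-rank test against ``mu``.

    Deviations are taken on the configured scale (log_ratio: log(v) - log(mu)).
    The exact null distribution (equivalent to enumerating all 2^n sign
    assignments) is used when, after zero handling, n <= 25 and the absolute
    deviations are tie-free; otherwise the normal approximation with tie and
    continuity correction.  All deviations zero yields p = 1 with
    ``n_effective = 0``.
    """
    if len(values) == 0:
        raise ValueError("values must be non-empty")
    if not mu > 0:
        raise ValueError(f"mu must be positive, got {mu}")
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("values must be positive ratios")
    if test_scale == "log_ratio":
        d = np.log(arr) - math.log(mu)
    elif test_scale == "ratio":
        d = arr - mu
    else:
        raise ValueError(f"unknown test_scale {test_scale!r}")

    if zero_policy == "drop":
        d = d[d != 0.0]
        zero_method = "wilcox"
    elif zero_policy == "pratt":
        zero_method = "pratt"
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")

    if d.size == 0 or np.all(d == 0.0):
        return WilcoxonResult(p_value=1.0, n_effective=0, method="degenerate")

    nonzero = d[d != 0.0]
    has_zeros = nonzero.size < d.size
    if d.size <= EXACT_LIMIT and not has_zeros:
        p = _exact_signed_rank_p(d)
        return WilcoxonResult(p_value=p, n_effective=int(nonzero.size), method="exact")
    res = stats.wilcoxon(
        d, zero_method=zero_method, correction=True,
        alternative="two-sided", method="approx",
    )
    p = float(min(1.0, max(res.pvalue, _P_FLOOR)))
    return WilcoxonResult(p_value=p, n_effective=int(nonzero.size), method="approx")


def _exact_signed_rank_p(d: np.ndarray) -> float:
    """Exact two-sided p over all 2^n sign assignments, ties allowed.

    Ranks tied absolute deviations by midranks; doubling makes every rank an
    integer, so the null distribution of the positive-rank sum is the subset-
    sum polynomial of the doubled ranks — identical to full enumeration but
    O(n * sum(ranks)) instead of O(2^n).
    """
    ranks2 = np.round(2.0 * stats.rankdata(np.abs(d))).astype(np.int64)
    w2_obs = int(ranks2[d > 0].sum())
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks2:
        counts[r:] += counts[:-r].copy()
    denom = 2.0 ** d.size
    cnt_ge = counts[w2_obs:].sum()
    cnt_le = counts[: w2_obs + 1].sum()
    return float(min(1.0, 2.0 * min(cnt_ge, cnt_le) / denom))


class GroupSummary(NamedTuple):
    median_ratio: float  # nan when no identified observation
    n_obs: int
    frequency_pct: float


def summarize_group(
    observations: Sequence[RatioObservation],
    total_runs: int,
    *,
    scale: str = "log_ratio",
) -> GroupSummary:
    """Median ratio, observation count and run frequency for one peptide+group.

    Under the default log scale the median is geometric — exp of the median
    log-ratio, i.e. the geometric midpoint of the two central order statistics
    for even n (median([2, 8]) = 4).  ``frequency_pct`` is 100 x the number of
    runs identifying the peptide over the group's total runs.  With no
    identified observation the median is NaN (cell not evaluable).
    """
    if total_runs < 1:
        raise ValueError(f"total_runs must be >= 1, got {total_runs}")
    identified = [o for o in observations if o.identified]
    n_obs = len(identified)
    runs = {o.run_id for o in identified}
    frequency_pct = 100.0 * len(runs) / total_runs
    if n_obs == 0:
        return GroupSummary(median_ratio=float("nan"), n_obs=0, frequency_pct=frequency_pct)
    ratios = np.asarray([o.ratio for o in identified], dtype=float)
    if scale == "log_ratio":
        med = float(np.exp(np.median(np.log(ratios))))
    else:
        med = float(np.median(ratios))
    return GroupSummary(median_ratio=med, n_obs=n_obs, frequency_pct=frequency_pct)


def call_regulation(median_ratio: float, p_value: float, config: ScreeningConfig) -> str:
    """Fold-change + significance gate: 'up', 'down' or 'unchanged'."""
    if math.isnan(median_ratio):
        return "unchanged"
    if p_value <= config.alpha:
        if median_ratio >= config.fold_up:
            return "up"
        if median_ratio <= config.fold_down:
            return "down"
    return "unchanged"


def screen_dataset(
    observations: Sequence[RatioObservation],
    peptides: Sequence[PeptideRecord],
    config: ScreeningConfig | None = None,
    *,
    multiple_testing: str = "none",
) -> list[RegulationCall]:
    """Screen every (peptide, group) cell with >= 1 identified observation.

    The total run count of a group is the number of distinct run ids observed
    in that group across all peptides.  With ``multiple_testing="bh"`` the
    p-values are Benjamini-Hochberg adjusted within each group before the
    significance gate.
    """
    config = config or ScreeningConfig()
    if multiple_testing not in ("none", "bh"):
        raise ValueError(f"unknown multiple_testing {multiple_testing!r}")
    identity = {p.sequence: p for p in peptides}

    runs_per_group: dict[str, set[str]] = {}
    cells: dict[tuple[str, str], list[RatioObservation]] = {}
    for o in observations:
        runs_per_group.setdefault(o.group, set()).add(o.run_id)
        cells.setdefault((o.peptide_sequence, o.group), []).append(o)

    raw: list[tuple[str, str, GroupSummary, float]] = []
    for (seq, group), obs in cells.items():
        summary = summarize_group(obs, len(runs_per_group[group]), scale=config.test_scale)
        if summary.n_obs == 0:
            continue
        ratios = [o.ratio for o in obs if o.identified]
        wres = wilcoxon_signed_rank_one_sample(
            ratios, 1.0, test_scale=config.test_scale, zero_policy=config.zero_policy
        )
        raw.append((seq, group, summary, wres.p_value))

    if multiple_testing == "bh":
        adjusted: dict[tuple[str, str], float] = {}
        for group in VALID_GROUPS:
            grp = [(seq, p) for seq, g, _, p in raw if g == group]
            if not grp:
                continue
            qs = stats.false_discovery_control([p for _, p in grp], method="bh")
            for (seq, _), q in zip(grp, qs):
                adjusted[(seq, group)] = float(min(1.0, q))
        raw = [(seq, g, s, adjusted[(seq, g)]) for seq, g, s, _ in raw]

    group_order = {g: i for i, g in enumerate(VALID_GROUPS)}
    peptide_order = {p.sequence: i for i, p in enumerate(peptides)}
    raw.sort(key=lambda t: (group_order[t[1]], peptide_order.get(t[0], len(peptide_order)), t[0]))

    calls: list[RegulationCall] = []
    for seq, group, summary, p in raw:
        rec = identity.get(seq)
        calls.append(
            RegulationCall(
                peptide_sequence=seq,
                group=group,
                direction=call_regulation(summary.median_ratio, p, config),
                p_value=p,
                median_ratio=summary.median_ratio,
                n_obs=summary.n_obs,
                frequency_pct=summary.frequency_pct,
                protein_id=rec.protein_id if rec else "",
                gene_symbol=rec.gene_symbol if rec else "",
            )
        )
    return calls


def regulated_counts(calls: Iterable[RegulationCall]) -> pd.DataFrame:
    """Per-group counts of up/down-regulated peptides (the Figure-1 summary)."""
    counts = {g: {"n_up": 0, "n_down": 0} for g in VALID_GROUPS}
    for c in calls:
        if c.direction == "up":
            counts[c.group]["n_up"] += 1
        elif c.direction == "down":
            counts[c.group]["n_down"] += 1
    rows = [
        {"group": g, "n_up": v["n_up"], "n_down": v["n_down"], "n_total": v["n_up"] + v["n_down"]}
        for g, v in counts.items()
    ]
    return pd.DataFrame(rows, columns=["group", "n_up", "n_down", "n_total"])


def calls_to_frame(calls: Sequence[RegulationCall]) -> pd.DataFrame:
    """Machine-readable regulation-call table (one row per peptide x group)."""
    rows = [
        {
            "peptide": c.peptide_sequence,
            "protein_id": c.protein_id,
            "gene_symbol": c.gene_symbol,
            "group": c.group,
            "n_obs": c.n_obs,
            "frequency_pct": c.frequency_pct,
            "median_ratio": c.median_ratio,
            "p_value": c.p_value,
            "direction": c.direction,
        }
        for c in calls
    ]
    columns = [
        "peptide", "protein_id", "gene_symbol", "group",
        "n_obs", "frequency_pct", "median_ratio", "p_value", "direction",
    ]
    return pd.DataFrame(rows, columns=columns)


def calls_from_frame(df: pd.DataFrame) -> list[RegulationCall]:
    """Inverse of :func:`calls_to_frame` (round-trips a calls TSV)."""
    return [
        RegulationCall(
            peptide_sequence=str(row.peptide),
            group=str(row.group),
            direction=str(row.direction),
            p_value=float(row.p_value),
            median_ratio=float(row.median_ratio),
            n_obs=int(row.n_obs),
            frequency_pct=float(row.frequency_pct),
            protein_id=str(row.protein_id),
            gene_symbol=str(row.gene_symbol),
        )
        for row in df.itertuples(index=False)
    ]
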