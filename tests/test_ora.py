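"""SLiM over-representation: Fisher test, odds ratio, universe, reporting."""
import numpy as np
import pytest

from _oracles import fisher_greater_exact
from peptipath.io_model import MotifDefinition
from peptipath.ora import (
    ConfigurationError,
    ContingencyTable,
    build_reference_universe,
    fisher_exact_enrichment,
    make_contingency,
    odds_ratio,
    ora_per_term,
    ora_to_frame,
)


def _motif(motif_id, terms, pattern="AA", taxa=("Mus musculus",)):
    return MotifDefinition(
        motif_id=motif_id,
        class_code=motif_id.split("_", 1)[0],
        pattern=pattern,
        instance_taxa=frozenset(taxa),
        term_ids=frozenset(terms),
    )


class TestFisher:
    def test_worked_table(self):
        p = fisher_exact_enrichment(ContingencyTable(3, 2, 5, 40))
        assert p == pytest.approx(fisher_greater_exact(3, 2, 5, 40), abs=1e-12)

    def test_zero_overlap_tail_is_one(self):
        assert fisher_exact_enrichment(ContingencyTable(0, 5, 5, 40)) == 1.0

    def test_selected_equals_universe_is_uninformative(self):
        assert fisher_exact_enrichment(ContingencyTable(4, 0, 6, 0)) == 1.0

    def test_matches_hypergeometric_tail_oracle_on_random_tables(self):
        """Fisher 'greater' p equals the exact tail sum to 1e-12, N <= 60."""
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(400):
            N = int(rng.integers(1, 61))
            sel = int(rng.integers(0, N + 1))
            ann = int(rng.integers(0, N + 1))
            a = int(rng.integers(max(0, sel + ann - N), min(sel, ann) + 1))
            table = ContingencyTable(a, sel - a, ann - a, N - sel - ann + a)
            got = fisher_exact_enrichment(table)
            want = fisher_greater_exact(table.a, table.b, table.c, table.d)
            assert got == pytest.approx(want, abs=1e-12)
            checked += 1
        assert checked == 400

    def test_exhaustive_small_margins(self):
        for N in range(1, 13):
            for sel in range(N + 1):
                for ann in range(N + 1):
                    for a in range(max(0, sel + ann - N), min(sel, ann) + 1):
                        t = ContingencyTable(a, sel - a, ann - a, N - sel - ann + a)
                        assert fisher_exact_enrichment(t) == pytest.approx(
                            fisher_greater_exact(t.a, t.b, t.c, t.d), abs=1e-12
                        )

    def test_p_antimonotone_in_overlap(self):
        """With fixed margins, a larger overlap never increases the p-value."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            N = int(rng.integers(4, 61))
            sel = int(rng.integers(1, N))
            ann = int(rng.integers(1, N))
            lo, hi = max(0, sel + ann - N), min(sel, ann)
            ps = [
                fisher_exact_enrichment(
                    ContingencyTable(a, sel - a, ann - a, N - sel - ann + a)
                )
                for a in range(lo, hi + 1)
            ]
            assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(ps, ps[1:]))


class TestOddsRatio:
    def test_plain_table(self):
        assert odds_ratio(ContingencyTable(3, 2, 5, 40)) == (12.0, False)

    def test_uniform_table(self):
        assert odds_ratio(ContingencyTable(1, 1, 1, 1)) == (1.0, False)

    def test_haldane_anscombe_on_zero_cell(self):
        orat, corrected = odds_ratio(ContingencyTable(2, 0, 3, 10))
        assert corrected and orat == pytest.approx((2.5 * 10.5) / (0.5 * 3.5))

    def test_enriched_tables_have_or_above_one(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            N = int(rng.integers(8, 60))
            sel = int(rng.integers(2, N - 2))
            ann = int(rng.integers(2, N - 2))
            lo, hi = max(0, sel + ann - N), min(sel, ann)
            a = int(rng.integers(lo, hi + 1))
            t = ContingencyTable(a, sel - a, ann - a, N - sel - ann + a)
            if min(t.a, t.b, t.c, t.d) == 0:
                continue
            if fisher_exact_enrichment(t) < 0.5:
                assert odds_ratio(t)[0] > 1.0


class TestUniverseAndOra:
    def _db(self, n_term_motifs=5, n_other=55):
        motifs = [
            _motif(f"LIG_T_{i}", ["termT"]) for i in range(n_term_motifs)
        ] + [
            _motif(f"DOC_O_{i}", [f"term{i % 7}"]) for i in range(n_other)
        ]
        return motifs

    def test_universe_counts_filter_passing_annotated_motifs(self):
        motifs = self._db() + [
            _motif("MOD_X_1", ["termT"]),                      # wrong class
            _motif("LIG_Y_1", ["termT"], taxa=("Homo sapiens",)),  # wrong taxon
            _motif("LIG_Z_1", []),                              # no annotation
        ]
        universe = build_reference_universe(motifs)
        assert len(universe) == 60
        assert {"MOD_X_1", "LIG_Y_1", "LIG_Z_1"}.isdisjoint(universe)

    def test_empty_universe_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            build_reference_universe([_motif("LIG_Z_1", [])])

    def test_contingency_margins(self):
        motifs = self._db()
        universe = build_reference_universe(motifs)
        selected = {f"LIG_T_{i}" for i in range(5)} | {"DOC_O_0"}
        table = make_contingency(selected, {f"LIG_T_{i}" for i in range(5)}, universe)
        assert (table.a, table.b) == (5, 1)
        assert table.a + table.b + table.c + table.d == len(universe)

    def test_planted_term_has_smallest_p(self):
        motifs = self._db()
        universe = build_reference_universe(motifs)
        selected = {f"LIG_T_{i}" for i in range(5)} | {"DOC_O_0"}
        results = ora_per_term(selected, motifs, universe, comparison="6h")
        assert results[0].term_id == "termT"
        assert results[0].p_value == min(r.p_value for r in results)
        assert results[0].support_count == 5 and results[0].top5

    def test_empty_selection_empty_results(self):
        motifs = self._db()
        universe = build_reference_universe(motifs)
        assert ora_per_term(set(), motifs, universe) == []

    def test_identical_annotation_sets_tie_exactly(self):
        motifs = [
            _motif("LIG_A_1", ["t1", "t2"]),
            _motif("LIG_A_2", ["t1", "t2"]),
            _motif("DOC_B_1", ["t3"]),
            _motif("DOC_B_2", ["t3"]),
        ]
        universe = build_reference_universe(motifs)
        results = ora_per_term({"LIG_A_1", "LIG_A_2"}, motifs, universe)
        by_term = {r.term_id: r for r in results}
        assert by_term["t1"].p_value == by_term["t2"].p_value
        assert by_term["t1"].odds_ratio == by_term["t2"].odds_ratio

    def test_top5_flag_limited_to_five_significant_terms(self):
        motifs = [_motif(f"LIG_M_{i}", [f"t{i}"]) for i in range(8)]
        motifs += [_motif(f"DOC_F_{i}", ["tbg"]) for i in range(40)]
        universe = build_reference_universe(motifs)
        selected = {f"LIG_M_{i}" for i in range(8)}
        results = ora_per_term(selected, motifs, universe, top_k=5)
        flagged = [r for r in results if r.top5]
        assert len(flagged) <= 5
        assert all(r.significant for r in flagged)
        df = ora_to_frame(results)
        assert int(df["top5"].sum()) == len(flagged)
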