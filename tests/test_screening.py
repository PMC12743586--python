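"""Differential-regulation screening: the signed-rank test, summaries, calls."""
import math

import numpy as np
import pytest

from _oracles import wilcoxon_enum_p
from peptipath.io_model import RatioObservation
from peptipath.screening import (
    ScreeningConfig,
    call_regulation,
    calls_from_frame,
    calls_to_frame,
    regulated_counts,
    screen_dataset,
    summarize_group,
    wilcoxon_signed_rank_one_sample,
)
from peptipath.synthetic_data import GeneratorSpec, generate_ratio_dataset


def _obs(ratios, group="6h", identified=True):
    return [
        RatioObservation("SAPFSSDSEQGNA", group, f"r{i}", r if identified else None, identified)
        for i, r in enumerate(ratios)
    ]


class TestWilcoxon:
    def test_five_same_sign_deviations(self):
        res = wilcoxon_signed_rank_one_sample([2.1, 2.3, 1.8, 2.9, 2.2], 1.0)
        assert res.p_value == pytest.approx(0.0625, abs=0)
        assert res.method == "exact"

    def test_all_at_null_gives_p_one_zero_effective(self):
        res = wilcoxon_signed_rank_one_sample([1.0, 1.0, 1.0], 1.0)
        assert res.p_value == 1.0 and res.n_effective == 0

    def test_tie_symmetric_pair_is_null(self):
        res = wilcoxon_signed_rank_one_sample([3.0, 1 / 3], 1.0, test_scale="log_ratio")
        assert res.p_value == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank_one_sample([], 1.0)

    @pytest.mark.parametrize("scale", ["log_ratio", "ratio"])
    def test_exact_p_matches_sign_enumeration(self, scale):
        """Exact p equals brute-force 2^n enumeration for random n <= 12."""
        rng = np.random.default_rng(1234)
        for _ in range(60):
            n = int(rng.integers(1, 13))
            values = np.exp(rng.normal(0.4, 0.8, size=n))
            got = wilcoxon_signed_rank_one_sample(values, 1.0, test_scale=scale)
            want = wilcoxon_enum_p(values, 1.0, scale)
            assert got.p_value == pytest.approx(want, abs=1e-12)

    def test_exact_p_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            n = int(rng.integers(2, 11))
            values = rng.choice([0.25, 0.5, 1.5, 2.0, 4.0], size=n)
            got = wilcoxon_signed_rank_one_sample(values, 1.0)
            assert got.p_value == pytest.approx(wilcoxon_enum_p(values), abs=1e-12)

    def test_observation_at_mu_dropped_without_changing_p(self):
        values = [2.1, 2.3, 1.8, 2.9, 2.2]
        base = wilcoxon_signed_rank_one_sample(values, 1.0, zero_policy="drop")
        plus = wilcoxon_signed_rank_one_sample(values + [1.0], 1.0, zero_policy="drop")
        assert plus.p_value == base.p_value and plus.n_effective == base.n_effective

    def test_reciprocal_ratios_preserve_p_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            values = np.exp(rng.normal(0.5, 0.6, size=int(rng.integers(2, 10))))
            p_fwd = wilcoxon_signed_rank_one_sample(values, 1.0).p_value
            p_rev = wilcoxon_signed_rank_one_sample(1.0 / values, 1.0).p_value
            assert p_fwd == p_rev

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(11)
        res = wilcoxon_signed_rank_one_sample(np.exp(rng.normal(0.5, 0.3, 40)), 1.0)
        assert res.method == "approx" and 0 < res.p_value <= 1


class TestSummarizeGroup:
    def test_even_n_geometric_midpoint(self):
        s = summarize_group(_obs([2.0, 8.0]), total_runs=4)
        assert s.median_ratio == pytest.approx(4.0) and s.frequency_pct == 50.0

    def test_no_identified_runs_not_evaluable(self):
        s = summarize_group(_obs([1.0] * 3, identified=False), total_runs=5)
        assert s.frequency_pct == 0.0 and s.n_obs == 0 and math.isnan(s.median_ratio)

    def test_single_observation_identity(self):
        s = summarize_group(_obs([4.2]), total_runs=1)
        assert s.median_ratio == pytest.approx(4.2) and s.frequency_pct == 100.0


class TestCallRegulation:
    @pytest.mark.parametrize(
        "median, p, expected",
        [
            (2.0, 0.01, "up"),        # threshold "2 or higher" is inclusive
            (0.5, 0.01, "down"),      # "0.5 or lower" is inclusive
            (4.0, 0.20, "unchanged"),  # significance gate
            (1.5, 0.01, "unchanged"),  # fold gate
            (float("nan"), 0.01, "unchanged"),
        ],
    )
    def test_fold_and_significance_gates(self, median, p, expected):
        assert call_regulation(median, p, ScreeningConfig()) == expected

    def test_config_invariants_enforced(self):
        with pytest.raises(Exception):
            ScreeningConfig(fold_up=0.9)
        with pytest.raises(Exception):
            ScreeningConfig(alpha=1.0)


class TestScreenDataset:
    def test_planted_pattern_recovers_observed_counts(self, planted_dataset):
        observations, peptides = planted_dataset
        calls = screen_dataset(observations, peptides)
        counts = regulated_counts(calls).set_index("group")["n_total"].to_dict()
        assert counts == {"1h": 1, "3h": 1, "6h": 4, "12h": 8, "24h": 4}

    def test_null_dataset_has_no_regulation(self, fixture_bundle):
        peptides, pattern, _ = fixture_bundle
        null_pattern = {k: "unchanged" for k in pattern}
        spec = GeneratorSpec(seed=3, direction_pattern=null_pattern,
                             peptides=tuple(peptides))
        calls = screen_dataset(generate_ratio_dataset(spec), peptides)
        assert regulated_counts(calls)["n_total"].sum() == 0

    def test_constant_upshift_has_exact_enumeration_p(self, fixture_bundle):
        peptides, _, _ = fixture_bundle
        obs = _obs([4.0] * 8, group="12h")
        calls = screen_dataset(obs, peptides[:1])
        (call,) = calls
        assert call.direction == "up"
        assert call.p_value == pytest.approx(2 / 2 ** 8, abs=1e-15)

    def test_reciprocal_dataset_flips_directions(self, fixture_bundle):
        """Replacing every ratio r by 1/r swaps up<->down at identical p."""
        peptides, _, _ = fixture_bundle
        spec = GeneratorSpec(seed=21)
        obs = generate_ratio_dataset(spec)
        flipped = [
            RatioObservation(o.peptide_sequence, o.group, o.run_id, 1.0 / o.ratio, True)
            for o in obs
        ]
        swap = {"up": "down", "down": "up", "unchanged": "unchanged"}
        fwd = {(c.peptide_sequence, c.group): c for c in screen_dataset(obs, peptides)}
        rev = {(c.peptide_sequence, c.group): c for c in screen_dataset(flipped, peptides)}
        assert fwd.keys() == rev.keys()
        for key, c in fwd.items():
            assert rev[key].direction == swap[c.direction]
            assert rev[key].p_value == c.p_value

    def test_bh_adjustment_is_conservative(self, planted_dataset):
        observations, peptides = planted_dataset
        raw = screen_dataset(observations, peptides)
        adj = screen_dataset(observations, peptides, multiple_testing="bh")
        raw_p = {(c.peptide_sequence, c.group): c.p_value for c in raw}
        for c in adj:
            assert c.p_value >= raw_p[(c.peptide_sequence, c.group)] - 1e-15

    def test_calls_frame_round_trip(self, planted_dataset):
        observations, peptides = planted_dataset
        calls = screen_dataset(observations, peptides)
        assert calls_from_frame(calls_to_frame(calls)) == calls
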