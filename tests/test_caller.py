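"""Cleavage ratios, the unpaired t-test, and three-criterion calling."""

import numpy as np
import pytest
from scipy import stats

from hacseq.caller import (
    CallingConfig,
    band_cleavage_ratio,
    call_sites,
    called_sites,
    cleavage_ratio_profile,
    evaluations_to_frame,
    read_calls_tsv,
    ttest_unpaired,
    write_calls_tsv,
)
from hacseq.coverage import GROUPS, CoverageProfile
from hacseq.refio import Transcript, TranscriptSet


class TestCleavageRatio:
    def test_direct_arithmetic(self):
        # site i=1 reads position 2: starts 5 of depth 10 -> 0.5
        p = CoverageProfile("t", np.array([0, 5, 0]), np.array([10, 10, 10]))
        r = cleavage_ratio_profile(p)
        assert r[0] == 0.5
        assert r[1] == 0.0

    def test_zero_depth_is_undefined_not_error(self):
        p = CoverageProfile("t", np.array([0, 0]), np.array([3, 0]))
        assert np.isnan(cleavage_ratio_profile(p)[0])

    def test_last_position_has_no_ratio(self):
        p = CoverageProfile("t", np.zeros(5, int), np.ones(5, int))
        assert cleavage_ratio_profile(p).size == 4

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(2)
        depth = rng.integers(0, 50, size=40)
        starts = np.minimum(rng.integers(0, 50, size=40), depth)
        r = cleavage_ratio_profile(CoverageProfile("t", starts, depth))
        defined = r[~np.isnan(r)]
        assert ((defined >= 0) & (defined <= 1)).all()


class TestTTest:
    def test_identical_groups_give_p_one(self):
        assert ttest_unpaired([0.5, 0.5], [0.5, 0.5]) == 1.0

    def test_zero_variance_different_means_give_p_zero(self):
        assert ttest_unpaired([0.8, 0.8], [0.1, 0.1]) == 0.0

    def test_textbook_pooled_t_with_two_df(self):
        # hand-derived: a={0.8,0.9}, b={0.1,0.2}; pooled s^2=0.005,
        # t = 0.7/sqrt(0.005) = 9.8995, df=2 -> p = 2*sf(t, 2)
        p = ttest_unpaired([0.8, 0.9], [0.1, 0.2])
        t_hand = 0.7 / np.sqrt(0.005)
        assert p == pytest.approx(2 * stats.t.sf(t_hand, 2), abs=1e-12)

    def test_matches_scipy_reference_on_random_samples(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = rng.normal(0, 1, size=int(rng.integers(2, 8)))
            b = rng.normal(0.3, 1.2, size=int(rng.integers(2, 8)))
            expected = stats.ttest_ind(a, b, equal_var=True).pvalue
            assert ttest_unpaired(a, b) == pytest.approx(expected, abs=1e-9)

    def test_too_few_values_is_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            ttest_unpaired([0.5], [0.1, 0.2])


class TestBandRatio:
    @pytest.mark.parametrize(
        "cleaved,uncleaved,expected", [(1, 1, 0.5), (0, 7, 0.0), (3, 1, 0.75)]
    )
    def test_examples(self, cleaved, uncleaved, expected):
        assert band_cleavage_ratio(cleaved, uncleaved) == expected

    def test_no_signal_is_error(self):
        with pytest.raises(ValueError, match="no signal"):
            band_cleavage_ratio(0, 0)


def make_profiles(ratio_spec, L=6, depth=100, seq=None):
    """Build three-arm profiles where site 2 (position 3) has the given
    per-replicate ratios and everything else is quiet.

    ratio_spec: {group: [r_rep1, r_rep2, ...]}.
    """
    ts = TranscriptSet([Transcript("t", seq or "ACCGUA")])
    profiles = {}
    for g, ratios in ratio_spec.items():
        for rep, r in enumerate(ratios, start=1):
            starts = np.zeros(L, int)
            d = np.full(L, depth, int)
            starts[2] = int(round(r * depth))  # position 3 -> site 2
            profiles[(g, rep)] = {
                "t": CoverageProfile("t", starts, d, group=g, replicate=rep)
            }
    return ts, profiles


def site(evals, tid, pos):
    return next(e for e in evals if e.transcript_id == tid and e.position == pos)


class TestCallSites:
    def test_strong_site_passes_all_three_criteria(self):
        ts, profiles = make_profiles(
            {"Ctrl": [0.02, 0.03], "HAC": [0.80, 0.82], "DM-HAC": [0.02, 0.04]}
        )
        evals = call_sites(profiles, CallingConfig(), ts)
        e = site(evals, "t", 2)
        assert e.c1 and e.c2 and e.c3 and e.called
        assert e.ref_base == "C"
        assert e.hac_mean == pytest.approx(0.81)
        assert [x.called for x in evals if x.position != 2] == [False] * 4

    def test_low_ratio_fails_only_the_absolute_cutoff(self):
        """A site cleaving at ~35% with clean contrasts mirrors the
        low-stoichiometry exclusion: criterion (i) alone rejects it."""
        ts, profiles = make_profiles(
            {"Ctrl": [0.02, 0.03], "HAC": [0.34, 0.36], "DM-HAC": [0.02, 0.04]}
        )
        e = site(call_sites(profiles, CallingConfig(), ts), "t", 2)
        assert not e.c1 and e.c2 and e.c3
        assert not e.called

    def test_demethylase_resistant_site_fails_only_criterion_three(self):
        """Cleavage that AlkB pre-treatment does not diminish is rejected
        as non-methylation even though it is strong and reproducible."""
        ts, profiles = make_profiles(
            {"Ctrl": [0.02, 0.03], "HAC": [0.80, 0.82], "DM-HAC": [0.75, 0.78]}
        )
        e = site(call_sites(profiles, CallingConfig(), ts), "t", 2)
        assert e.c1 and e.c2 and not e.c3
        assert not e.called
        assert e.fold_decrease < 2.5

    def test_zero_control_passes_fold_component(self):
        ts, profiles = make_profiles(
            {"Ctrl": [0.0, 0.0], "HAC": [0.80, 0.82], "DM-HAC": [0.0, 0.0]}
        )
        e = site(call_sites(profiles, CallingConfig(), ts), "t", 2)
        assert np.isinf(e.fold_increase)
        assert e.called

    def test_insufficient_depth_reported_untestable(self):
        ts, profiles = make_profiles(
            {"Ctrl": [0.0, 0.0], "HAC": [0.9, 0.9], "DM-HAC": [0.0, 0.0]}, depth=10
        )
        e = site(call_sites(profiles, CallingConfig(min_depth=20), ts), "t", 2)
        assert e.reason == "low_depth" and not e.called

    def test_n_base_never_callable(self):
        ts, profiles = make_profiles(
            {"Ctrl": [0.0, 0.0], "HAC": [0.9, 0.9], "DM-HAC": [0.0, 0.0]},
            seq="ANCGUA",
        )
        e = site(call_sites(profiles, CallingConfig(), ts), "t", 2)
        assert e.reason == "N_base" and not e.called

    def test_base_filter_restricts_to_cytidine(self):
        ts, profiles = make_profiles(
            {"Ctrl": [0.0, 0.0], "HAC": [0.9, 0.9], "DM-HAC": [0.0, 0.0]},
            seq="AUCGUA",
        )
        assert site(call_sites(profiles, CallingConfig(), ts), "t", 2).called
        e = site(call_sites(profiles, CallingConfig(base_filter=True), ts), "t", 2)
        assert e.reason == "non_C_base" and not e.called

    def test_missing_group_and_unequal_replicates_rejected(self):
        ts, profiles = make_profiles({"Ctrl": [0.0, 0.0], "HAC": [0.9, 0.9]})
        with pytest.raises(ValueError, match="DM-HAC"):
            call_sites(profiles, CallingConfig(), ts)
        ts, profiles = make_profiles(
            {"Ctrl": [0.0, 0.0], "HAC": [0.9, 0.9], "DM-HAC": [0.0]}
        )
        with pytest.raises(ValueError, match="replicate"):
            call_sites(profiles, CallingConfig(), ts)

    def test_single_replicate_rejected(self):
        ts, profiles = make_profiles(
            {"Ctrl": [0.0], "HAC": [0.9], "DM-HAC": [0.0]}
        )
        with pytest.raises(ValueError, match="2 replicates"):
            call_sites(profiles, CallingConfig(), ts)

    def test_replicate_order_invariance(self):
        ts, profiles = make_profiles(
            {"Ctrl": [0.02, 0.05], "HAC": [0.7, 0.9], "DM-HAC": [0.01, 0.06]}
        )
        swapped = {
            (g, {1: 2, 2: 1}[r]): profs for (g, r), profs in profiles.items()
        }
        a = call_sites(profiles, CallingConfig(), ts)
        b = call_sites(swapped, CallingConfig(), ts)
        assert [(e.transcript_id, e.position, e.called) for e in a] == [
            (e.transcript_id, e.position, e.called) for e in b
        ]

    def test_threshold_monotonicity(self):
        """Raising any threshold (or lowering alpha) never grows the call
        set."""
        rng = np.random.default_rng(19)
        ts = TranscriptSet([Transcript("t", "".join(rng.choice(list("ACGU"), 40)))])
        profiles = {}
        for g in GROUPS:
            scale = {"Ctrl": 0.05, "HAC": 0.5, "DM-HAC": 0.1}[g]
            for rep in (1, 2):
                depth = rng.integers(30, 200, size=40)
                starts = np.minimum(
                    rng.binomial(depth, scale), depth
                )
                profiles[(g, rep)] = {
                    "t": CoverageProfile("t", starts, depth, group=g, replicate=rep)
                }
        base = {
            (e.transcript_id, e.position)
            for e in called_sites(call_sites(profiles, CallingConfig(), ts))
        }
        for cfg in (
            CallingConfig(r_min=0.7),
            CallingConfig(fold_min=4.0),
            CallingConfig(alpha=0.01),
            CallingConfig(min_depth=60),
            CallingConfig(p_adjust="BH"),
        ):
            strict = {
                (e.transcript_id, e.position)
                for e in called_sites(call_sites(profiles, cfg, ts))
            }
            assert strict <= base

    def test_calls_tsv_roundtrip(self, tmp_path):
        ts, profiles = make_profiles(
            {"Ctrl": [0.02, 0.03], "HAC": [0.80, 0.82], "DM-HAC": [0.02, 0.04]}
        )
        evals = call_sites(profiles, CallingConfig(), ts)
        path = tmp_path / "calls.tsv"
        write_calls_tsv(evals, path)
        back = read_calls_tsv(path)
        import pandas.testing as pdt

        pdt.assert_frame_equal(
            evaluations_to_frame(back), evaluations_to_frame(evals)
        )

    def test_frame_has_one_row_per_site(self):
        ts, profiles = make_profiles(
            {"Ctrl": [0.0, 0.0], "HAC": [0.9, 0.9], "DM-HAC": [0.0, 0.0]}
        )
        frame = evaluations_to_frame(call_sites(profiles, CallingConfig(), ts))
        assert len(frame) == 5  # L-1 sites for L=6


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            CallingConfig(r_min=1.5)
        with pytest.raises(ValueError):
            CallingConfig(fold_min=0.5)
        with pytest.raises(ValueError):
            CallingConfig(p_adjust="bonferroni")

    def test_from_mapping_rejects_unknown_keys(self):
        with pytest.raises(ValueError, match="unknown"):
            CallingConfig.from_mapping({"r_min": 0.4, "bogus": 1})
        cfg = CallingConfig.from_mapping({"r_min": 0.4, "min_depth": 5})
        assert cfg.r_min == 0.4 and cfg.min_depth == 5
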