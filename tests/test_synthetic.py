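"""Synthetic cohort generator: determinism, planted structure, fixtures."""

import numpy as np
import pytest

from dynhub.connectivity import pearson_fc, sliding_windows
from dynhub.graphs import ThresholdSpec, hub_probability
from dynhub.synthetic import (ConfigError, CovariateModel, ScoreSpec,
                              SimulationConfig, StateSpec, expected_hub_prob,
                              fixed_fixture, generate_cohort, null_config,
                              planted_shift_config, study_config)


def tiny_covariates():
    return CovariateModel(
        age_mean={"NC": 64, "SCD": 65}, age_sd={"NC": 8, "SCD": 8},
        female_frac={"NC": 0.5, "SCD": 0.5},
        education_mean={"NC": 11, "SCD": 11},
        education_sd={"NC": 4, "SCD": 4},
    )


def tiny_config(states, **kw):
    defaults = dict(
        states=states,
        scores=(ScoreSpec("S", {"NC": 0.0, "SCD": 0.0}, 1.0),),
        covariates=tiny_covariates(),
        n_nc=2, n_scd=2, n_regions=20, n_volumes=120,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestDeterminism:
    def test_same_config_and_seed_bit_identical(self):
        cfg = null_config(seed=5, n_per_group=2)
        cfg.n_volumes = 50
        a_cohort, a_phen, a_gt = generate_cohort(cfg)
        b_cohort, b_phen, b_gt = generate_cohort(cfg)
        for a, b in zip(a_cohort, b_cohort):
            assert np.array_equal(a.data, b.data)
        assert a_phen.equals(b_phen)
        assert np.array_equal(a_gt["true_hub_prob"], b_gt["true_hub_prob"])
        assert np.array_equal(a_gt["state_sequences"], b_gt["state_sequences"])

    def test_different_seeds_differ(self):
        cfg1 = null_config(seed=5, n_per_group=2)
        cfg2 = null_config(seed=6, n_per_group=2)
        cfg1.n_volumes = cfg2.n_volumes = 50
        a, _, _ = generate_cohort(cfg1)
        b, _, _ = generate_cohort(cfg2)
        assert not np.array_equal(a[0].data, b[0].data)


class TestPlantedStructure:
    def test_single_hubless_state_has_no_systematic_hubs(self):
        # identity covariance: no region's full-scan correlations dominate
        cfg = tiny_config(
            (StateSpec("flat", (), {"NC": 1.0, "SCD": 1.0}),),
            background_strength=0.0, n_volumes=800,
        )
        cohort, _, gt = generate_cohort(cfg)
        fc = pearson_fc(cohort[0]).values
        off = fc[~np.eye(20, dtype=bool)]
        assert np.abs(off).mean() < 0.1  # sample noise at T=800
        assert gt["true_hub_prob"].sum() == 0

    def test_single_hub_dominates_every_window(self):
        # region 1 correlates 0.8 with everything, others ~0.64 through the
        # shared factor: its window degree should be maximal essentially always
        cfg = tiny_config(
            (StateSpec("one", (1,), {"NC": 1.0, "SCD": 1.0}),),
            hub_strength=0.8, background_strength=0.64, hub_coherence=1.0,
            n_volumes=200,
        )
        cohort, _, _ = generate_cohort(cfg)
        fc = pearson_fc(cohort[0]).values
        assert fc[0, 1:].mean() > fc[1:, 1:][~np.eye(19, dtype=bool)].mean()
        ws = sliding_windows(cohort[0], window_length=25)
        degs = np.array([
            (w.values > 0.7).sum(axis=1) for w in ws
        ])
        assert (degs.argmax(axis=1) == 0).mean() > 0.9

    def test_two_equal_dwell_states_split_hub_probability(self):
        set_a, set_b = (1, 2, 3, 4, 5), (6, 7, 8, 9, 10)
        cfg = tiny_config(
            (StateSpec("a", set_a, {"NC": 0.5, "SCD": 0.5}),
             StateSpec("b", set_b, {"NC": 0.5, "SCD": 0.5})),
            n_regions=30, n_volumes=230, n_nc=3, n_scd=3,
            dwell_mean=100.0,  # windows mostly fall within one state
            occupancy_concentration=500.0,  # minimal subject jitter
            seed=11,
        )
        cohort, _, _ = generate_cohort(cfg)
        spec = ThresholdSpec("absolute", 0.25)
        probs = np.mean([
            hub_probability(sliding_windows(ts), spec).prob for ts in cohort
        ], axis=0)  # averaged over 6 subjects x 206 windows
        for r in set_a + set_b:
            assert probs[r - 1] == pytest.approx(0.5, abs=0.1)

    def test_true_hub_prob_matches_state_sequence(self):
        cfg = null_config(seed=3, n_per_group=2)
        cfg.n_volumes = 60
        _, _, gt = generate_cohort(cfg)
        seq = gt["state_sequences"][0]
        hubs_by_state = list(gt["state_hubs"].values())
        expected = np.zeros(90)
        for s in seq:
            for r in hubs_by_state[s]:
                expected[r - 1] += 1
        assert np.allclose(gt["true_hub_prob"][0], expected / len(seq))

    def test_expected_hub_prob_reflects_occupancy_and_overlay(self):
        cfg = planted_shift_config(region=7, shift=0.2)
        p_nc = expected_hub_prob(cfg, "NC")
        p_scd = expected_hub_prob(cfg, "SCD")
        assert p_nc[6] == 0.0
        assert p_scd[6] == pytest.approx(0.2)
        occ = cfg.occupancies("NC")
        assert p_nc[22] == pytest.approx(occ[0])  # region 23, first state hub
        assert abs(p_scd - p_nc).sum() == pytest.approx(0.2)

    def test_scores_couple_to_true_hub_probability(self):
        cfg = study_config(seed=9)
        cfg.n_nc, cfg.n_scd = 40, 0
        cfg.scores = (ScoreSpec("S", {"NC": 0.0, "SCD": 0.0}, 0.01,
                                ((28, 5.0),)),)
        cfg.n_scd = 1  # generator requires both groups
        _, phen, gt = generate_cohort(cfg)
        nc = phen["group"] == "NC"
        r = np.corrcoef(phen.loc[nc, "S"], gt["true_hub_prob"][nc.to_numpy(), 27])[0, 1]
        assert r > 0.95


class TestValidation:
    def test_infeasible_hub_strength_rejected_at_validation(self):
        cfg = tiny_config(
            (StateSpec("bad", (1, 2, 3), {"NC": 1.0, "SCD": 1.0}),),
            hub_strength=0.9, background_strength=0.01,
        )
        with pytest.raises(ConfigError, match="positive definite"):
            cfg.validate()

    def test_out_of_range_planted_region_rejected(self):
        cfg = tiny_config((StateSpec("a", (1,), {"NC": 1.0, "SCD": 1.0}),),
                          planted_group_effect=((99, 0.2),))
        with pytest.raises(ConfigError, match="outside"):
            cfg.validate()

    def test_zero_occupancy_group_rejected(self):
        cfg = tiny_config((StateSpec("a", (1,), {"NC": 1.0, "SCD": 0.0}),))
        with pytest.raises(ConfigError, match="occupanc"):
            cfg.validate()


class TestFixedFixtures:
    def test_toy5_has_duplicate_and_antipodal_columns(self, toy5):
        assert toy5.data.shape == (30, 5)
        assert np.array_equal(toy5.data[:, 0], toy5.data[:, 1])
        assert np.allclose(toy5.data[:, 3], -toy5.data[:, 2] + 2.0)

    def test_toy5_is_bit_identical_across_calls(self):
        assert np.array_equal(fixed_fixture("toy5").data,
                              fixed_fixture("toy5").data)

    def test_table1_summaries_contents(self):
        t1 = fixed_fixture("table1_summaries")
        assert t1["n"] == {"NC": 53, "SCD": 40}
        assert t1["rows"]["age"]["NC"] == [63.50, 8.25]
        assert t1["rows"]["MMSE"]["p_reported"] == 0.750

    def test_results_selections_totals(self, selections):
        totals = {(m, g): len(selections[m][g]["selected"])
                  for m in ("dynamic", "static") for g in ("NC", "SCD")}
        assert totals == {("dynamic", "NC"): 24, ("dynamic", "SCD"): 23,
                          ("static", "NC"): 17, ("static", "SCD"): 23}

    def test_unknown_fixture_rejected(self):
        with pytest.raises(KeyError):
            fixed_fixture("nope")
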