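"""Partitioning, candidate evaluation, selection, final models, thresholding."""
import numpy as np
import pandas as pd
import pytest

from enmpipe.calibrate import (
    CandidateSpec,
    EvalConfig,
    InsufficientRecordsError,
    aicc,
    average_models,
    bootstrap_final,
    checkerboard_bin,
    enumerate_candidates,
    evaluate_candidates,
    jackknife_importance,
    make_partitions,
    omission_rate,
    partial_roc,
    pick_final,
    select_candidates,
    threshold_map,
)
from enmpipe.grid import EnvStack, GridSpec
from enmpipe.maxent import MaxentModel, fit_maxent, train_maxent, training_gain
from enmpipe.synth import PREDICTOR_SETS, sample_presences


def test_checkerboard_matches_hand_parity_table():
    """4x4 grid with aggregation factors (1, 2) against a hand-derived table."""
    rows, cols = np.meshgrid(np.arange(4), np.arange(4), indexing="ij")
    got = checkerboard_bin(rows.ravel(), cols.ravel(), factors=(1, 2)).reshape(4, 4)
    expected = np.array([
        [0, 1, 2, 3],
        [1, 0, 3, 2],
        [2, 3, 0, 1],
        [3, 2, 1, 0],
    ])
    assert np.array_equal(got, expected)


class TestPartitions:
    @pytest.fixture()
    def env(self, rng):
        spec = GridSpec(20, 20, 0.0, 0.0, 0.5)
        return EnvStack(spec, {"a": rng.uniform(size=(20, 20))})

    def points(self, env, n, seed):
        r = np.random.default_rng(seed)
        return (r.uniform(env.spec.xll, env.spec.xur, n),
                r.uniform(env.spec.yll, env.spec.yur, n))

    def test_same_seed_identical_different_seed_differs(self, env):
        lons, lats = self.points(env, 200, 0)
        a = make_partitions(lons, lats, env, seed=5)
        b = make_partitions(lons, lats, env, seed=5)
        assert np.array_equal(a.independent_idx, b.independent_idx)
        assert np.array_equal(a.spatial_bin, b.spatial_bin)
        assert np.array_equal(a.background_rc, b.background_rc)
        c = make_partitions(lons, lats, env, seed=6)
        assert not np.array_equal(a.independent_idx, c.independent_idx)

    def test_partition_is_a_disjoint_cover(self, env):
        lons, lats = self.points(env, 200, 1)
        parts = make_partitions(lons, lats, env, seed=2)
        groups = [set(parts.independent_idx), set(parts.train_idx), set(parts.test_idx)]
        assert sum(len(g) for g in groups) == 200
        assert set().union(*groups) == set(range(200))

    def test_sixty_records_trigger_fallback(self, env):
        lons, lats = self.points(env, 60, 3)
        parts = make_partitions(lons, lats, env, seed=0)
        assert parts.independent_idx.size == 3  # 5% of 60
        assert parts.fallback

    def test_too_few_records_instruct_skip(self, env):
        lons, lats = self.points(env, 8, 4)
        with pytest.raises(InsufficientRecordsError, match="skip"):
            make_partitions(lons, lats, env, seed=0)

    def test_background_sampled_from_valid_cells(self, rng):
        spec = GridSpec(10, 10, 0.0, 0.0, 1.0)
        layer = rng.uniform(size=(10, 10))
        layer[:, :5] = np.nan
        env = EnvStack(spec, {"a": layer})
        lons = rng.uniform(5.0, 10.0, 50)
        lats = rng.uniform(0.0, 10.0, 50)
        parts = make_partitions(lons, lats, env, seed=1,
                                config=EvalConfig(n_background=30))
        assert env.mask[parts.background_rc[:, 0], parts.background_rc[:, 1]].all()


class TestEnumerate:
    def test_cartesian_size_and_rm_major_order(self):
        out = enumerate_candidates([1, 2], ["l", "lq", "h"], ["bio"])
        assert len(out) == 6
        assert [c.rm for c in out] == [1, 1, 1, 2, 2, 2]

    def test_full_grid_size(self):
        out = enumerate_candidates()
        assert len(out) == 17 * 29 * 3 == 1479

    def test_duplicate_rm_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_candidates([1, 1], ["l"], ["bio"])


class TestPartialRoc:
    def test_noise_predictions_ratio_near_one(self):
        ratios, ps = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            ratio, p = partial_roc(r.uniform(size=30), r.uniform(size=1000),
                                   replicates=200, seed=seed)
            ratios.append(ratio)
            ps.append(p)
        assert 0.9 <= np.mean(ratios) <= 1.1
        assert sum(p > 0.05 for p in ps) >= 18

    def test_strong_model_ratio_above_1p5(self, rng):
        bg = rng.uniform(size=2000)
        test = np.quantile(bg, 0.95) + rng.uniform(0, 0.05, size=40)
        ratio, p = partial_roc(test, bg, seed=0)
        assert ratio > 1.5 and p < 0.05

    @pytest.mark.parametrize("seed", range(5))
    def test_ratio_bounded_zero_two(self, seed):
        r = np.random.default_rng(seed)
        ratio, _ = partial_roc(r.normal(size=15), r.normal(size=500),
                               replicates=100, seed=seed)
        assert 0.0 <= ratio <= 2.0

    def test_constant_predictions_null(self):
        ratio, p = partial_roc(np.ones(10), np.ones(100))
        assert ratio == 1.0 and p == 1.0


class TestOmissionRate:
    def test_self_evaluation_bounded_by_E(self, rng):
        cal = rng.uniform(size=40)
        assert omission_rate(cal, cal, E=0.05) <= 0.05

    def test_all_above_calibration_max_is_zero(self, rng):
        cal = rng.uniform(0, 1, size=30)
        assert omission_rate(cal, cal.max() + rng.uniform(0, 1, 10)) == 0.0

    def test_hand_built_example_matches_enumeration(self):
        cal = np.arange(1.0, 21.0)          # 20 calibration presences
        ev = np.array([0.5, 1.5, 2.0, 3.0, 10.0])
        # oracle from the definition: discard floor(0.05*20)=1 lowest, T=2.0
        T = np.sort(cal)[1]
        expected = np.mean(ev < T)
        assert omission_rate(cal, ev, E=0.05) == pytest.approx(expected) == 0.4


class TestAicc:
    def worked_model(self, k=1):
        lam = np.zeros(k)
        lam[0] = np.log(4)
        return MaxentModel(lam=lam, feature_names=[f"f{i}" for i in range(k)],
                           rm=1.0, n_presence=10, Z=1.0, H=0.5)

    def test_two_cell_worked_example(self):
        """10 presences in the 0.8-raw cell, k=1: AICc = 2 - 2*10*ln(0.8) + 4/8."""
        got = aicc(self.worked_model(), np.full(10, 0.8))
        assert got == pytest.approx(2 - 2 * 10 * np.log(0.8) + 0.5, abs=1e-9)
        assert got == pytest.approx(6.963, abs=1e-3)

    def test_zero_weight_feature_does_not_count(self):
        a = aicc(self.worked_model(k=1), np.full(10, 0.8))
        b = aicc(self.worked_model(k=3), np.full(10, 0.8))  # two zero weights
        assert a == b

    def test_more_parameters_worse_at_equal_fit(self):
        m2 = self.worked_model(k=2)
        m2.lam[1] = 0.5
        assert aicc(m2, np.full(10, 0.8)) > aicc(self.worked_model(), np.full(10, 0.8))

    def test_undefined_when_too_few_presences(self):
        assert np.isnan(aicc(self.worked_model(), np.full(2, 0.8)))


class TestSelectCandidates:
    def metrics(self, rows):
        base = {"rm": 1.0, "classes": "lq", "predictor_set": "bio", "converged": True,
                "n_nonzero": 2}
        return pd.DataFrame([{**base, **r} for r in rows])

    def test_single_significant_low_or_retained(self):
        m = self.metrics([{"p": 0.0, "omission_rate": 0.02, "auc_ratio": 1.5, "aicc": 10.0}])
        kept, info = select_candidates(m)
        assert len(kept) == 1 and not info["or_fallback"]

    def test_min_or_fallback_when_none_below_threshold(self):
        m = self.metrics([
            {"p": 0.0, "omission_rate": 0.08, "auc_ratio": 1.5, "aicc": 10.0},
            {"p": 0.0, "omission_rate": 0.12, "auc_ratio": 1.6, "aicc": 9.0},
        ])
        kept, info = select_candidates(m)
        assert info["or_fallback"]
        assert kept["omission_rate"].tolist() == [0.08]

    def test_delta_aicc_filter(self):
        m = self.metrics([
            {"p": 0.0, "omission_rate": 0.01, "auc_ratio": 1.5, "aicc": 100.0},
            {"p": 0.0, "omission_rate": 0.01, "auc_ratio": 1.5, "aicc": 101.9},
            {"p": 0.0, "omission_rate": 0.01, "auc_ratio": 1.5, "aicc": 102.5},
        ])
        kept, _ = select_candidates(m)
        assert sorted(kept["aicc"]) == [100.0, 101.9]

    def test_no_significant_model_signalled(self):
        m = self.metrics([{"p": 0.5, "omission_rate": 0.01, "auc_ratio": 1.0, "aicc": 5.0}])
        kept, info = select_candidates(m)
        assert kept.empty and info["no_significant"]

    def test_output_subset_of_input_and_bounds_hold(self):
        rng = np.random.default_rng(0)
        m = self.metrics([{"p": float(p), "omission_rate": float(o),
                           "auc_ratio": 1.2, "aicc": float(a)}
                          for p, o, a in zip(rng.uniform(0, 0.2, 30),
                                             rng.uniform(0, 0.2, 30),
                                             rng.uniform(50, 60, 30))])
        kept, info = select_candidates(m)
        assert kept.index.isin(m.index).all()
        if not info["or_fallback"] and not kept.empty:
            assert (kept["omission_rate"] < 0.05).all()
            assert (kept["aicc"] - kept["aicc"].min() <= 2.0 + 1e-12).all()


@pytest.fixture(scope="module")
def modeling_setup(world1):
    pres = sample_presences(world1, 200, seed=21)
    parts = make_partitions(pres[:, 0], pres[:, 1], world1.env, seed=22)
    return world1.env, pres, parts


class TestFinalModels:
    def test_bootstrap_deterministic_and_gain_consistent(self, modeling_setup):
        env, pres, parts = modeling_setup
        spec = CandidateSpec(1.0, "lq", "bioclimatic")
        cfg = EvalConfig(proc_replicates=100)
        models_a, met_a = bootstrap_final(spec, env, PREDICTOR_SETS, pres, parts,
                                          cfg, seed=3)
        models_b, met_b = bootstrap_final(spec, env, PREDICTOR_SETS, pres, parts,
                                          cfg, seed=3)
        assert met_a == met_b
        assert all(np.array_equal(a.lam, b.lam) for a, b in zip(models_a, models_b))

        # replicate-mean training gain close to the plain (non-bootstrap) fit
        variables = PREDICTOR_SETS["bioclimatic"]
        fit_idx = parts.non_independent_idx
        Xp = env.values_at(pres[fit_idx, 0], pres[fit_idx, 1], variables)
        Xb = env.table(variables)
        plain = train_maxent(Xp, Xb, variables, classes="lq", rm=1.0)
        Fp, Fb = plain.expander.transform(Xp), plain.expander.transform(Xb)
        gains = [training_gain(m, m.expander.transform(Xp),
                               m.expander.transform(Xb)) for m in models_a]
        spread = max(2 * np.std(gains), 0.05)
        assert abs(np.mean(gains) - training_gain(plain, Fp, Fb)) < spread

    def test_jackknife_driver_beats_noise(self, modeling_setup):
        env, pres, parts = modeling_setup
        spec = CandidateSpec(1.0, "lq", "combination")
        jk = jackknife_importance(env, PREDICTOR_SETS, spec, pres,
                                  parts.non_independent_idx)
        jk = jk.set_index("variable")
        assert jk.loc["bio1", "gain_only"] > jk.loc["bio3", "gain_only"]
        # full-model gain at least the best single-variable gain (minus slack)
        variables = PREDICTOR_SETS["combination"]
        Xp = env.values_at(pres[parts.non_independent_idx, 0],
                           pres[parts.non_independent_idx, 1], variables)
        Xb = env.table(variables)
        full = train_maxent(Xp, Xb, variables, classes="lq")
        g_full = training_gain(full, full.expander.transform(Xp),
                               full.expander.transform(Xb))
        assert g_full >= jk["gain_only"].max() - 1e-6

    def test_jackknife_identical_variables_redundant(self, rng):
        spec_g = GridSpec(12, 12, 0.0, 0.0, 0.5)
        a = rng.uniform(size=(12, 12))
        env = EnvStack(spec_g, {"dup1": a, "dup2": a.copy()})
        lon, lat = spec_g.cell_centers()
        order = np.argsort(a.ravel())[::-1][:40]
        pres = np.column_stack([lon.ravel()[order], lat.ravel()[order]])
        sets = {"dups": ["dup1", "dup2"]}
        jk = jackknife_importance(env, sets, CandidateSpec(1.0, "l", "dups"),
                                  pres, np.arange(40))
        full = train_maxent(env.values_at(pres[:, 0], pres[:, 1], sets["dups"]),
                            env.table(sets["dups"]), sets["dups"], classes="l")
        g_full = training_gain(full, full.expander.transform(
            env.values_at(pres[:, 0], pres[:, 1], sets["dups"])),
            full.expander.transform(env.table(sets["dups"])))
        for _, row in jk.iterrows():
            assert row["gain_without"] == pytest.approx(g_full, abs=1e-3)

    def test_average_models_identity_and_envelope(self, modeling_setup):
        env, pres, parts = modeling_setup
        variables = PREDICTOR_SETS["bioclimatic"]
        sub = env.subset(variables)
        idx = parts.non_independent_idx
        Xp = env.values_at(pres[idx, 0], pres[idx, 1], variables)
        m1 = train_maxent(Xp, sub.table(), variables, classes="lq", rm=0.5)
        m2 = train_maxent(Xp, sub.table(), variables, classes="lq", rm=5.0)
        single = average_models([m1], sub)
        assert np.allclose(single, average_models([m1], sub), equal_nan=True)
        avg = average_models([m1, m2], sub)
        lo = np.minimum(average_models([m1], sub), average_models([m2], sub))
        hi = np.maximum(average_models([m1], sub), average_models([m2], sub))
        ok = ~np.isnan(avg)
        assert (avg[ok] >= lo[ok] - 1e-12).all() and (avg[ok] <= hi[ok] + 1e-12).all()


class TestPickFinal:
    def test_minimal_or_wins_regardless_of_auc(self):
        winners = {"a": {"omission_rate": 0.00, "auc_ratio": 1.1, "n_nonzero": 5},
                   "b": {"omission_rate": 0.04, "auc_ratio": 1.9, "n_nonzero": 2},
                   "c": {"omission_rate": 0.12, "auc_ratio": 1.9, "n_nonzero": 2}}
        assert pick_final(winners) == "a"

    def test_or_tie_broken_by_auc_ratio(self):
        winners = {"a": {"omission_rate": 0.0, "auc_ratio": 1.4, "n_nonzero": 2},
                   "b": {"omission_rate": 0.0, "auc_ratio": 1.6, "n_nonzero": 2}}
        assert pick_final(winners) == "b"

    def test_single_winner_is_itself(self):
        assert pick_final({"only": {"omission_rate": 0.1, "auc_ratio": 1.0}}) == "only"


class TestThresholdMap:
    def test_hundred_value_percentile_example(self, rng):
        suits = np.arange(0.01, 1.005, 0.01)  # 0.01 .. 1.00
        surface = rng.uniform(size=(10, 10))
        binary, T = threshold_map(surface, suits, percentile=10)
        assert np.sum(suits < T) == 10
        assert set(np.unique(binary)) <= {0.0, 1.0}

    def test_percentile_zero_keeps_all_presence_cells(self, rng):
        suits = rng.uniform(0.2, 0.9, size=30)
        surface = suits.reshape(5, 6)
        binary, T = threshold_map(surface, suits, percentile=0)
        assert binary.sum() == surface.size

    def test_raising_percentile_never_adds_cells(self, rng):
        suits = rng.uniform(size=50)
        surface = rng.uniform(size=(8, 8))
        prev = None
        for pct in (0, 10, 25, 50):
            binary, _ = threshold_map(surface, suits, percentile=pct)
            if prev is not None:
                assert not ((binary == 1) & (prev == 0)).any()
            prev = binary

    def test_strictly_below_fraction_bounded(self):
        # n=15 distinct values: plain linear interpolation would leave 2/15
        # (13.3%) strictly below; the stepped-down threshold must not
        suits = np.linspace(0.1, 0.9, 15)
        _, T = threshold_map(np.zeros((2, 2)), suits, percentile=10)
        assert np.sum(suits < T) <= 0.10 * suits.size + 1e-9

    def test_empty_presences_rejected(self):
        with pytest.raises(ValueError):
            threshold_map(np.zeros((2, 2)), np.array([]))


def test_evaluate_candidates_rows_and_determinism(modeling_setup):
    env, pres, parts = modeling_setup
    cands = enumerate_candidates([1.0], ["lq", "h"], ["bioclimatic"])
    cfg = EvalConfig(proc_replicates=100)
    a = evaluate_candidates(cands, env, PREDICTOR_SETS, pres, parts, cfg, seed=7)
    b = evaluate_candidates(cands, env, PREDICTOR_SETS, pres, parts, cfg, seed=7)
    assert len(a) == 2
    pd.testing.assert_frame_equal(a, b)
    assert a["converged"].all()
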