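import math

import numpy as np
import pandas as pd
import pytest

from lanchester_abc import (
    ALL_MODELS,
    ABCConfig,
    Battle,
    BattleDataset,
    HyperDraw,
    Model,
    Posterior,
    SimOutcome,
    SynthConfig,
    accept_at,
    battle_distance,
    bayes_factors,
    generate_dataset,
    load_records,
    pool_records,
    run_distance,
    run_rejection,
    save_records,
)
from lanchester_abc.simulate import Termination


def mk_battle(size_blue, size_red, cas_blue, cas_red):
    return Battle(
        id="t", year=1700, size_blue=size_blue, size_red=size_red, cas_blue=cas_blue, cas_red=cas_red
    )


def mk_sim(cb, cr):
    return SimOutcome(sim_cas_blue=cb, sim_cas_red=cr, steps=1, termination=Termination.HISTORICAL)


def hand_records(distances, models=None):
    n = len(distances)
    return pd.DataFrame(
        {
            "run_index": np.arange(n),
            "model": models if models is not None else ["fatigue"] * n,
            "mu": np.linspace(1, 2, n),
            "sigma": np.linspace(0.1, 0.5, n),
            "distance": distances,
            "accepted": False,
        }
    )


class TestBattleDistance:
    def test_hand_example(self):
        # hist (3000, 1000), sim (3300, 1000): (0.1 + 0)/2
        d = battle_distance(mk_sim(3300, 1000), mk_battle(15000, 10000, 3000, 1000))
        assert d == pytest.approx(0.05)

    def test_exact_match_is_zero(self):
        assert battle_distance(mk_sim(3000, 1000), mk_battle(15000, 10000, 3000, 1000)) == 0.0

    def test_relabelling_matches_lower_ratio_sides(self):
        # simulated ratios reversed relative to history: the simulated
        # lower-ratio side is compared against historical red
        b = mk_battle(10000, 10000, 2000, 1000)
        d = battle_distance(mk_sim(900, 2100), b)
        assert d == pytest.approx(0.5 * (100 / 2000 + 100 / 1000))

    def test_invariant_to_simulated_side_ordering(self):
        b = mk_battle(10000, 10000, 2000, 1000)
        assert battle_distance(mk_sim(900, 2100), b) == pytest.approx(
            battle_distance(mk_sim(2100, 900), b)
        )


class TestRunDistance:
    def test_single_battle_equals_battle_distance(self):
        from lanchester_abc import simulate_to_casualties

        b = mk_battle(15000, 10000, 2000, 1100)
        h = HyperDraw.from_moments(1.8, 0.0)  # deterministic P
        d = run_distance(Model.SQUARED, h, BattleDataset([b]))
        out = simulate_to_casualties(Model.SQUARED, b, 1.8)
        assert d == pytest.approx(battle_distance(out, b))

    def test_duplicated_battles_leave_mean_unchanged(self):
        ds, _ = generate_dataset(SynthConfig(n_battles=10, seed=3))
        h = HyperDraw.from_moments(2.0, 0.0)
        d1 = run_distance(Model.FATIGUE, h, ds)
        d2 = run_distance(Model.FATIGUE, h, BattleDataset(list(ds) + list(ds)))
        assert d2 == pytest.approx(d1, rel=1e-12)

    def test_exact_generating_replay_is_zero(self):
        # deterministic ground truth: replaying the generating model with
        # the generating P reproduces every battle exactly
        cfg = SynthConfig(true_model=Model.SQUARED, true_mu=1.8, true_sigma=0.0, n_battles=15, seed=9)
        ds, truth = generate_dataset(cfg)
        h = HyperDraw.from_moments(1.8, 0.0)
        assert run_distance(Model.SQUARED, h, ds) == pytest.approx(0.0, abs=1e-9)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            run_distance(Model.SQUARED, HyperDraw.from_moments(1, 0), BattleDataset([]))


class TestAcceptance:
    def test_hand_sorted_cut(self):
        rec = hand_records([0.1, 0.2, 0.05, 0.4])
        post = accept_at(rec, 0.5)
        assert sorted(post.accepted["run_index"]) == [0, 2]

    def test_tau_one_accepts_everything(self):
        rec = hand_records([0.3, 0.1, 0.2])
        assert accept_at(rec, 1.0).n_accepted == 3

    def test_tie_break_by_run_index(self):
        rec = hand_records([0.2, 0.1, 0.1, 0.1])
        post = accept_at(rec, 0.5)
        assert sorted(post.accepted["run_index"]) == [1, 2]

    def test_nested_tolerances(self):
        rng = np.random.default_rng(0)
        rec = hand_records(rng.uniform(size=10_000))
        sets = [set(accept_at(rec, t).accepted["run_index"]) for t in (0.05, 0.005, 0.0005)]
        assert sets[2] <= sets[1] <= sets[0]
        assert [len(s) for s in sets] == [500, 50, 5]

    def test_tau_too_small_errors(self):
        with pytest.raises(ValueError):
            accept_at(hand_records([0.1, 0.2]), 0.1)

    def test_posterior_size_invariant(self):
        rng = np.random.default_rng(1)
        rec = hand_records(rng.uniform(size=1000))
        for tau in (0.5, 0.123, 0.01):
            post = accept_at(rec, tau)
            assert post.n_accepted == math.floor(tau * 1000)
            rejected = rec.loc[~rec["run_index"].isin(post.accepted["run_index"]), "distance"]
            assert post.accepted["distance"].max() <= rejected.min() + 1e-15


@pytest.fixture(scope="module")
def tiny_experiment():
    ds, _ = generate_dataset(SynthConfig(n_battles=8, seed=5))
    cfg = ABCConfig(n_runs=200, tau=0.1, seed=2, mode="hierarchical")
    return ds, cfg, run_rejection(ds, cfg)


class TestRunRejection:
    def test_record_count_and_acceptance_size(self, tiny_experiment):
        _, cfg, rec = tiny_experiment
        assert len(rec) == 200
        assert rec["accepted"].sum() == 20

    def test_brute_force_sort_oracle(self, tiny_experiment):
        # accepted set must equal a full sort of all distances
        _, cfg, rec = tiny_experiment
        k = math.floor(cfg.tau * cfg.n_runs)
        expected = set(rec.sort_values(["distance", "run_index"]).head(k)["run_index"])
        assert set(rec.loc[rec["accepted"], "run_index"]) == expected

    def test_chunking_does_not_change_records(self, tiny_experiment):
        ds, cfg, rec = tiny_experiment
        rec2 = run_rejection(ds, cfg, chunk_runs=7)
        pd.testing.assert_frame_equal(rec, rec2)

    def test_accept_at_reproduces_run_rejection_flags(self, tiny_experiment):
        _, cfg, rec = tiny_experiment
        post = accept_at(rec, cfg.tau)
        assert set(post.accepted["run_index"]) == set(rec.loc[rec["accepted"], "run_index"])

    def test_hierarchical_samples_all_models(self, tiny_experiment):
        _, _, rec = tiny_experiment
        counts = rec["model"].value_counts()
        assert set(counts.index) == {m.label for m in ALL_MODELS}
        # uniform model prior: no model grossly over-represented
        assert counts.min() > 200 / 4 * 0.5

    def test_single_model_mode(self):
        ds, _ = generate_dataset(SynthConfig(n_battles=5, seed=5))
        cfg = ABCConfig(n_runs=50, tau=0.1, seed=2, mode="single_model", models=(Model.LINEAR,))
        rec = run_rejection(ds, cfg)
        assert (rec["model"] == "linear").all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ABCConfig(n_runs=100, tau=0.001)  # keeps no runs
        with pytest.raises(ValueError):
            ABCConfig(n_runs=100, tau=0.5, mode="single_model")  # needs 1 model
        with pytest.raises(ValueError):
            ABCConfig(n_runs=0, tau=0.5)

    def test_record_store_round_trip(self, tiny_experiment, tmp_path):
        _, _, rec = tiny_experiment
        path = tmp_path / "records.csv"
        save_records(rec, path)
        back = load_records(path)
        pd.testing.assert_frame_equal(back, rec, check_dtype=False)


class TestBayesFactors:
    def _posterior(self, counts):
        rows = []
        i = 0
        for label, c in counts.items():
            for _ in range(c):
                rows.append({"run_index": i, "model": label, "mu": 2.0, "sigma": 0.5,
                             "distance": 0.01 * i, "accepted": True})
                i += 1
        return Posterior(
            accepted=pd.DataFrame(rows), tau=0.01, n_runs=100 * max(1, i), model_set=ALL_MODELS
        )

    def test_count_ratios(self):
        post = self._posterior({"fatigue": 400, "logarithmic": 100, "linear": 0, "squared": 0})
        bf, props = bayes_factors(post)
        assert props.loc["fatigue"] == pytest.approx(0.8)
        assert props.loc["logarithmic"] == pytest.approx(0.2)
        assert bf.loc["fatigue", "logarithmic"] == pytest.approx(4.0)
        assert np.isinf(bf.loc["fatigue", "linear"])
        assert props.sum() == pytest.approx(1.0)

    def test_equal_counts_give_unit_factors(self):
        post = self._posterior({m.label: 25 for m in ALL_MODELS})
        bf, props = bayes_factors(post)
        assert np.allclose(bf.to_numpy(), 1.0)
        assert np.allclose(props.to_numpy(), 0.25)

    def test_single_model_posterior_rejected(self):
        post = Posterior(
            accepted=pd.DataFrame({"run_index": [0], "model": ["fatigue"], "mu": [2.0],
                                   "sigma": [0.5], "distance": [0.1], "accepted": [True]}),
            tau=0.1, n_runs=10, model_set=(Model.FATIGUE,),
        )
        with pytest.raises(ValueError):
            bayes_factors(post)


def test_pool_records_reindexes_and_cuts_globally():
    a = hand_records([0.5, 0.01], models=["linear", "linear"])
    b = hand_records([0.02, 0.6], models=["fatigue", "fatigue"])
    pooled = pool_records([a, b])
    assert list(pooled["run_index"]) == [0, 1, 2, 3]
    post = accept_at(pooled, 0.5)
    assert sorted(post.accepted["model"]) == ["fatigue", "linear"]
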