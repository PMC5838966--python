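"""Petri net execution semantics: enabling, firing, degradation, blocks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphopetri.netmodel import (
    PHOSPHORYLATION,
    DE_PHOSPHORYLATION,
    WITH_PHOSPHORYLATION,
    WITHOUT_PHOSPHORYLATION,
    Interaction,
    PhosphoNetwork,
)
from phosphopetri.simulator import (
    Perturbation,
    SimulationConfig,
    apply_perturbation,
    degrade,
    derive_seed,
    fire,
    is_enabled,
    run_block,
    simulate,
    simulate_final,
    simulate_state,
)
from phosphopetri.synthdata import SynthSpec, generate_network


class TestEnabling:
    @pytest.mark.parametrize(
        "tokens,activation,expected",
        [
            (36, WITH_PHOSPHORYLATION, True),
            (34, WITH_PHOSPHORYLATION, False),
            (34, WITHOUT_PHOSPHORYLATION, True),
            (36, WITHOUT_PHOSPHORYLATION, False),
            # counts exactly at the threshold enable nothing in either regime
            (35, WITH_PHOSPHORYLATION, False),
            (35, WITHOUT_PHOSPHORYLATION, False),
            (0, WITHOUT_PHOSPHORYLATION, True),
            (0, WITH_PHOSPHORYLATION, False),
        ],
    )
    def test_strict_threshold_rule(self, tokens, activation, expected):
        assert is_enabled(tokens, activation, 35) is expected

    def test_negative_tokens_rejected(self):
        with pytest.raises(ValueError):
            is_enabled(-1, WITH_PHOSPHORYLATION, 35)


class TestFire:
    def test_phosphorylation_adds_one_enzyme_untouched(self):
        marking = {"K": 40, "S": 10}
        out = fire(Interaction("K", "S", PHOSPHORYLATION), marking)
        assert out == {"K": 40, "S": 11}
        assert marking == {"K": 40, "S": 10}  # pure

    def test_dephosphorylation_removes_one(self):
        out = fire(Interaction("F", "S", DE_PHOSPHORYLATION), {"F": 40, "S": 10})
        assert out["S"] == 9

    def test_dephosphorylation_clamps_at_zero(self):
        out = fire(Interaction("F", "S", DE_PHOSPHORYLATION), {"F": 40, "S": 0})
        assert out["S"] == 0

    @given(st.integers(0, 200), st.integers(0, 200))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_total_token_delta_is_unit_or_clamped(self, e, s):
        marking = {"E": e, "S": s}
        plus = fire(Interaction("E", "S", PHOSPHORYLATION), marking)
        assert sum(plus.values()) - sum(marking.values()) == 1
        minus = fire(Interaction("E", "S", DE_PHOSPHORYLATION), marking)
        expected = -1 if s > 0 else 0
        assert sum(minus.values()) - sum(marking.values()) == expected
        assert plus["E"] == e and minus["E"] == e


class TestDegrade:
    @pytest.mark.parametrize("n,rate,expected", [(10, 0.1, 9), (35, 0.1, 31), (0, 0.1, 0)])
    def test_floor_rule(self, n, rate, expected):
        assert degrade({"p": n}, rate) == {"p": expected}

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_strict_decay_and_integrality(self, n):
        out = degrade({"p": n}, 0.1)["p"]
        assert isinstance(out, int) and 0 <= out <= n
        if n >= 1:
            assert out < n  # every positive count strictly decreases

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            degrade({"p": 1}, 1.0)


class TestPerturbation:
    def test_clamp_high(self):
        p = Perturbation(clamp_high={"A"}, high_value=70)
        assert apply_perturbation({"A": 12, "B": 3}, p) == {"A": 70, "B": 3}

    def test_inhibit_zeroes(self):
        p = Perturbation(inhibit={"G"})
        assert apply_perturbation({"G": 55, "B": 3}, p) == {"G": 0, "B": 3}

    def test_empty_perturbation_is_identity(self):
        assert apply_perturbation({"A": 5}, Perturbation()) == {"A": 5}

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            Perturbation(clamp_high={"A"}, inhibit={"A"})

    def test_default_high_value_is_twice_threshold(self):
        p = Perturbation(clamp_high={"A"})
        assert apply_perturbation({"A": 0}, p, threshold=35) == {"A": 70}

    def test_unknown_place_rejected_at_simulation(self, tiny_network):
        cfg = SimulationConfig(blocks=1, iterations=1, seed=0)
        with pytest.raises(ValueError, match="unknown place"):
            simulate(tiny_network, cfg, Perturbation(clamp_high={"NOPE"}))


class TestRunBlock:
    def test_zero_transition_network_only_degrades(self):
        net = PhosphoNetwork()
        from phosphopetri.netmodel import ProteinNode, SUBSTRATE_ONLY

        net.nodes["S"] = ProteinNode("S", SUBSTRATE_ONLY)
        rng = np.random.default_rng(0)
        out = run_block(net, {"S": 10}, None, 35, rng)
        assert out == {"S": 9}

    def test_all_zero_marking_stays_zero_for_with_phosphorylation_net(self, tiny_network):
        # K2 is without-phosphorylation, so silence it via inhibition and
        # check the remaining with-phosphorylation net is absorbing at zero
        rng = np.random.default_rng(1)
        zero = {p: 0 for p in tiny_network.places}
        out = run_block(tiny_network, zero, Perturbation(inhibit={"K2"}), 35, rng)
        assert out == zero

    def test_fixed_seed_reproducible(self, tiny_network):
        marking = {p: 40 for p in tiny_network.places}
        a = run_block(tiny_network, marking, None, 35, np.random.default_rng(7))
        b = run_block(tiny_network, marking, None, 35, np.random.default_rng(7))
        assert a == b


class TestSimulate:
    def test_degradation_only_trajectory(self, tiny_network):
        cfg = SimulationConfig(blocks=1, iterations=1, seed=0)
        init = {p: 10 for p in tiny_network.places}
        # K2 (without-phosphorylation, 10 < 35) would fire; inhibit it so the
        # only change in the block is the 10% degradation
        traj = simulate(tiny_network, cfg, Perturbation(inhibit={"K2"}),
                        initial_marking=init)
        assert traj.loc[1, "S1"] == 9 and traj.loc[1, "K1"] == 9
        assert traj.loc[1, "K2"] == 0  # inhibited place reads zero

    def test_same_seed_identical_trajectory(self, tiny_network):
        cfg = SimulationConfig(blocks=20, seed=42)
        t1 = simulate(tiny_network, cfg)
        t2 = simulate(tiny_network, cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_inhibited_place_trajectory_constantly_zero(self, tiny_network):
        cfg = SimulationConfig(blocks=30, seed=3)
        traj = simulate(tiny_network, cfg, Perturbation(inhibit={"K1"}))
        assert (traj["K1"] == 0).all()

    def test_trajectory_counts_are_nonnegative_integers(self, tiny_network):
        cfg = SimulationConfig(blocks=50, seed=5)
        traj = simulate(tiny_network, cfg, Perturbation(clamp_high={"K1"}))
        assert (traj.dtypes == np.int64).all() or all(
            np.issubdtype(dt, np.integer) for dt in traj.dtypes
        )
        assert (traj.to_numpy() >= 0).all()


class TestSimulateState:
    def test_mean_of_final_markings(self, chain_network):
        cfg = SimulationConfig(blocks=1, iterations=2, seed=0)
        # compute the two finals by hand using the same derived sub-seeds
        finals = []
        for i in range(2):
            rng = np.random.default_rng(derive_seed(0, "iteration", i))
            finals.append(simulate_final(chain_network, cfg, None, rng=rng))
        status = simulate_state(chain_network, cfg, None)
        for p in chain_network.places:
            assert status[p] == pytest.approx((finals[0][p] + finals[1][p]) / 2)

    def test_inhibited_gene_status_is_zero(self, chain_network):
        cfg = SimulationConfig(blocks=10, iterations=3, seed=1)
        status = simulate_state(
            chain_network, cfg, Perturbation.gene_inhibition((), "K1")
        )
        assert status["K1"] == 0.0

    def test_clamped_stimulus_raises_downstream_status(self, chain_network):
        cfg = SimulationConfig(blocks=100, iterations=5, seed=2)
        ref = simulate_state(chain_network, cfg, None)
        stim = simulate_state(
            chain_network, cfg, Perturbation.stimulus({"K1"}), seed=cfg.seed
        )
        assert stim["M"] > ref["M"]
        assert ref["M"] == 0.0  # unfed places fully decay over 100 blocks

    def test_bit_reproducible(self, tiny_network):
        cfg = SimulationConfig(blocks=30, iterations=4, seed=9)
        a = simulate_state(tiny_network, cfg, Perturbation(clamp_high={"K1"}))
        b = simulate_state(tiny_network, cfg, Perturbation(clamp_high={"K1"}))
        assert a == b

    def test_iteration_prefix_stability(self, tiny_network):
        """Raising the iteration count must not perturb earlier iterations'
        sub-seeds: the 5-iteration mean is recoverable from the runs that a
        10-iteration campaign performs."""
        cfg5 = SimulationConfig(blocks=10, iterations=5, seed=4)
        finals = []
        for i in range(5):
            rng = np.random.default_rng(derive_seed(4, "iteration", i))
            finals.append(simulate_final(tiny_network, cfg5, None, rng=rng))
        status5 = simulate_state(tiny_network, cfg5, None)
        for p in tiny_network.places:
            assert status5[p] == pytest.approx(sum(f[p] for f in finals) / 5)


class TestConfig:
    def test_defaults_follow_threshold(self):
        cfg = SimulationConfig()
        assert cfg.threshold == 35
        assert cfg.effective_init_max == 70
        assert cfg.blocks == 100 and cfg.iterations == 10
        assert cfg.degradation_rate == pytest.approx(0.10)

    def test_file_roundtrip(self, tmp_path):
        cfg = SimulationConfig(threshold=20, blocks=50, seed=123)
        cfg.to_file(tmp_path / "c.cfg")
        again = SimulationConfig.from_file(tmp_path / "c.cfg")
        assert again.threshold == 20 and again.blocks == 50 and again.seed == 123
        assert again.effective_init_max == 40

    @pytest.mark.parametrize(
        "kwargs", [{"threshold": 0}, {"degradation_rate": 0.0},
                   {"degradation_rate": 1.0}, {"iterations": 0}, {"blocks": 0}]
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestInvariantsOnSyntheticNetworks:
    """Structural invariants of whole trajectories on generated networks."""

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_trajectories_nonnegative_integral_and_bounded(self, seed):
        spec = SynthSpec(plant_relay=True, seed=seed)
        net, scen = generate_network(spec)
        cfg = SimulationConfig(blocks=100, iterations=1, seed=seed)
        pert = Perturbation.stimulus(scen.stimulus_targets)
        traj = simulate(net, cfg, pert)
        arr = traj.to_numpy()
        assert np.issubdtype(arr.dtype, np.integer)
        assert (arr >= 0).all()
        indeg = {p: 0 for p in net.places}
        for it in net.interactions:
            indeg[it.substrate_id] += 1
        bound = {
            p: max(cfg.effective_init_max, 10 * indeg[p] + 10) for p in net.places
        }
        for p in net.places:
            assert (traj[p] <= bound[p]).all(), p

    def test_with_phosphorylation_only_network_absorbs_at_zero(self):
        spec = SynthSpec(frac_without_phosph=0.0, seed=6)
        net, _ = generate_network(spec)
        cfg = SimulationConfig(blocks=20, iterations=1, seed=6)
        zero = {p: 0 for p in net.places}
        traj = simulate(net, cfg, None, initial_marking=zero)
        assert (traj.to_numpy() == 0).all()


class TestSeedDerivation:
    def test_distinct_streams(self):
        seen = {derive_seed(1, "iteration", i) for i in range(50)}
        assert len(seen) == 50
        assert derive_seed(1, "a") != derive_seed(2, "a")

    def test_stable_and_31_bit(self):
        s = derive_seed(12345, "inhibit", "K001", 2)
        assert s == derive_seed(12345, "inhibit", "K001", 2)
        assert 0 <= s < 2**31
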