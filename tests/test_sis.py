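"""Discrete-time SIS simulation, protection semantics and the mean-field ODE."""

import numpy as np
import pytest

from multiplexshield import (
    EpidemicConfig,
    EpidemicState,
    LayerRates,
    MultiplexGraph,
    ProtectionSet,
    apply_protection,
    build_supra_adjacency,
    generate_er_multiplex,
    mean_field_sis,
    monte_carlo,
    run_simulation,
    seed_attack,
    sis_step,
)


def flat_rates(L, beta, delta):
    return LayerRates(beta=np.full(L, float(beta)), delta=np.full(L, float(delta)))


def path_graph(n):
    return MultiplexGraph(num_nodes=n, num_layers=1,
                          edges=[[(i, i + 1, 1.0) for i in range(n - 1)]])


class TestApplyProtection:
    def test_empty_set_unchanged(self, tiny_supra):
        s = ProtectionSet(members=(), k=0, scheme="multiplex", method="none")
        pruned, mask = apply_protection(tiny_supra, s)
        assert not mask.any()
        np.testing.assert_array_equal(pruned.matrix.toarray(),
                                      tiny_supra.matrix.toarray())

    def test_multiplex_isolates_all_copies(self, tiny_supra):
        """Protecting node 1 removes both copies' incident edges: intra edges
        (0,1),(1,2) in layer 0 plus the coupling pair, i.e. 3 of 6 edges."""
        s = ProtectionSet(members=(1,), k=1, scheme="multiplex", method="t")
        pruned, mask = apply_protection(tiny_supra, s)
        assert mask.tolist() == [False, True, False, False, True, False]
        assert pruned.num_supra_edges == 3
        A = pruned.matrix.toarray()
        assert A[1].sum() == 0 and A[:, 1].sum() == 0
        assert A[4].sum() == 0 and A[:, 4].sum() == 0

    def test_layer_scheme_keeps_sibling(self, tiny_supra):
        s = ProtectionSet(members=(0,), k=1, scheme="layer", method="t")
        pruned, mask = apply_protection(tiny_supra, s)
        assert mask.tolist() == [True, False, False, False, False, False]
        A = pruned.matrix.toarray()
        assert A[0].sum() == 0
        assert A[3, 5] == 1.0  # copy (0, layer 1) keeps its intra edge


class TestSeedAttack:
    def make_state(self, graph, protected=None):
        N = graph.num_nodes * graph.num_layers
        mask = np.zeros(N, dtype=bool)
        if protected is not None:
            mask[list(protected)] = True
        return EpidemicState.initial(N, mask)

    def test_phi_zero(self, tiny_graph):
        st = seed_attack(self.make_state(tiny_graph), tiny_graph, 0)
        assert not st.infected.any()

    def test_targeted_star_hits_hub(self):
        g = MultiplexGraph(num_nodes=4, num_layers=1,
                           edges=[[(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)]])
        st = seed_attack(self.make_state(g), g, 1, attack="targeted")
        assert st.infected.tolist() == [True, False, False, False]

    def test_equal_allocation_remainder_low_layers(self):
        g = MultiplexGraph(num_nodes=4, num_layers=2,
                           edges=[[(0, 1, 1.0)], [(2, 3, 1.0)]])
        st = seed_attack(self.make_state(g), g, 3, attack="targeted", seed=0)
        per_layer = st.infected.reshape(2, 4).sum(axis=1)
        assert per_layer.tolist() == [2, 1]

    def test_only_unprotected_seeded(self, tiny_graph):
        mask_ids = (0, 1, 2)  # all copies in layer 0 protected
        st = self.make_state(tiny_graph, protected=mask_ids)
        st = seed_attack(st, tiny_graph, 3, attack="random", seed=1)
        assert not st.infected[list(mask_ids)].any()
        assert st.infected.sum() == 3

    def test_phi_too_large(self, tiny_graph):
        with pytest.raises(ValueError, match="phi"):
            seed_attack(self.make_state(tiny_graph), tiny_graph, 7)


class TestSisStep:
    def test_beta_zero_only_shrinks(self):
        g = path_graph(6)
        supra = build_supra_adjacency(g)
        st = EpidemicState.initial(6, np.zeros(6, dtype=bool))
        st.infected[:3] = True
        st.ever_infected[:3] = True
        rng = np.random.default_rng(0)
        for _ in range(5):
            before = st.ever_infected.copy()
            sis_step(st, supra, flat_rates(1, 0.0, 0.5), rng)
            np.testing.assert_array_equal(st.ever_infected, before)
        assert st.infected.sum() <= 3

    def test_flooding_deterministic(self):
        g = path_graph(8)
        supra = build_supra_adjacency(g)
        st = EpidemicState.initial(8, np.zeros(8, dtype=bool))
        st.infected[0] = st.ever_infected[0] = True
        rng = np.random.default_rng(0)
        for _ in range(8):
            sis_step(st, supra, flat_rates(1, 1.0, 0.0), rng)
        assert st.ever_infected.all()

    def test_single_edge_transmission_frequency(self):
        g = path_graph(2)
        supra = build_supra_adjacency(g)
        rates = flat_rates(1, 0.5, 0.5)
        hits = 0
        for s in range(10_000):
            st = EpidemicState.initial(2, np.zeros(2, dtype=bool))
            st.infected[0] = st.ever_infected[0] = True
            sis_step(st, supra, rates, np.random.default_rng(s))
            hits += bool(st.infected[1])
        sigma = np.sqrt(0.25 / 10_000)
        assert abs(hits / 10_000 - 0.5) < 5 * sigma

    def test_coupling_transmission_toggle(self):
        g = MultiplexGraph(num_nodes=2, num_layers=2)  # coupling edges only
        supra = build_supra_adjacency(g)
        rates = flat_rates(2, 1.0, 0.0)
        st = EpidemicState.initial(4, np.zeros(4, dtype=bool))
        st.infected[0] = st.ever_infected[0] = True
        sis_step(st, supra, rates, np.random.default_rng(0),
                 coupling_transmission=False)
        assert st.infected.sum() == 1
        sis_step(st, supra, rates, np.random.default_rng(0),
                 coupling_transmission=True)
        assert st.infected[2]  # sibling copy infected through coupling

    def test_protected_never_infected_and_conservation(self):
        g = generate_er_multiplex(20, 60, 2, seed=6)
        supra = build_supra_adjacency(g)
        protection = ProtectionSet(members=(0, 1, 2, 3, 4), k=5,
                                   scheme="multiplex", method="t")
        pruned, mask = apply_protection(supra, protection)
        st = EpidemicState.initial(40, mask)
        seed_attack(st, g, 5, seed=3)
        rng = np.random.default_rng(4)
        for _ in range(30):
            sis_step(st, pruned, flat_rates(2, 0.8, 0.3), rng)
            assert not st.ever_infected[mask].any()
            # susceptible + infected = N at every step
            assert st.infected.sum() + (~st.infected).sum() == 40

    def test_ever_infected_monotone(self):
        g = generate_er_multiplex(15, 40, 2, seed=1)
        supra = build_supra_adjacency(g)
        st = EpidemicState.initial(30, np.zeros(30, dtype=bool))
        seed_attack(st, g, 4, seed=0)
        rng = np.random.default_rng(2)
        prev = st.ever_infected.copy()
        for _ in range(25):
            sis_step(st, supra, flat_rates(2, 0.6, 0.6), rng)
            assert (st.ever_infected | prev == st.ever_infected).all()
            prev = st.ever_infected.copy()


class TestRunSimulation:
    def test_beta_zero_exact_theta(self, tiny_graph):
        cfg = EpidemicConfig(rates=flat_rates(2, 0.0, 0.5), phi=2, runs=1)
        summary = run_simulation(tiny_graph, None, cfg, seed=0)
        assert summary.survived_pct == 100.0 * (6 - 2) / 6
        assert summary.survived_count == 4

    def test_phi_zero_full_survival(self, tiny_graph):
        cfg = EpidemicConfig(rates=flat_rates(2, 0.9, 0.5), phi=0)
        assert run_simulation(tiny_graph, None, cfg, seed=0).survived_pct == 100.0

    def test_flooding_theta_zero(self):
        g = path_graph(10)
        cfg = EpidemicConfig(rates=flat_rates(1, 1.0, 0.0), phi=1, horizon=20)
        assert run_simulation(g, None, cfg, seed=0).survived_pct == 0.0

    def test_protected_copies_count_as_survived(self):
        g = path_graph(6)
        s = ProtectionSet(members=(2, 3), k=2, scheme="multiplex", method="t")
        cfg = EpidemicConfig(rates=flat_rates(1, 1.0, 0.0), phi=1, horizon=20)
        summary = run_simulation(g, s, cfg, seed=1)
        # the flood is contained on one side of the protected cut
        assert summary.survived_count >= 2
        assert summary.survived_pct == 100.0 * summary.survived_count / 6

    def test_theta_is_exact_ratio(self):
        g = generate_er_multiplex(12, 30, 2, seed=2)
        cfg = EpidemicConfig(rates=flat_rates(2, 0.7, 0.5), phi=3, horizon=50)
        summary = run_simulation(g, None, cfg, seed=5)
        assert summary.survived_pct == 100.0 * summary.survived_count / 24


class TestMonteCarlo:
    def test_single_run_convention(self, tiny_graph):
        cfg = EpidemicConfig(rates=flat_rates(2, 0.5, 0.5), phi=1, runs=1)
        summary = monte_carlo(tiny_graph, "none", 0, cfg)
        assert summary.theta_std == 0.0
        assert summary.theta_ave == summary.thetas[0]

    def test_beta_zero_zero_variance(self, tiny_graph):
        cfg = EpidemicConfig(rates=flat_rates(2, 0.0, 0.5), phi=2, runs=10)
        summary = monte_carlo(tiny_graph, "random", 1, cfg)
        assert summary.theta_ave == 100.0 * (6 - 2) / 6
        assert summary.theta_std == 0.0

    def test_reproducible(self):
        g = generate_er_multiplex(15, 40, 2, seed=9)
        cfg = EpidemicConfig(rates=flat_rates(2, 0.6, 0.6), phi=3, runs=8,
                             seed=17)
        a = monte_carlo(g, "av", 4, cfg)
        b = monte_carlo(g, "av", 4, cfg)
        np.testing.assert_array_equal(a.thetas, b.thetas)
        assert a.theta_ave == b.theta_ave and a.theta_std == b.theta_std

    def test_unknown_method(self, tiny_graph):
        cfg = EpidemicConfig(rates=flat_rates(2, 0.5, 0.5), phi=1)
        with pytest.raises(ValueError, match="unknown method"):
            monte_carlo(tiny_graph, "tinfoil", 1, cfg)


class TestMeanField:
    def test_endemic_level(self):
        traj = mean_field_sis(0.8, 0.4, 0.01, T=500)
        assert abs(traj.i[-1] - 0.5) < 1e-4

    def test_subcritical_dies_out(self):
        traj = mean_field_sis(0.5, 0.7, 0.2, T=200)
        assert traj.i[-1] < 1e-4

    def test_absorbing_zero(self):
        traj = mean_field_sis(0.9, 0.1, 0.0, T=50)
        assert (traj.i == 0).all()

    def test_s_plus_i_is_one(self):
        traj = mean_field_sis(0.7, 0.5, 0.05, T=100)
        np.testing.assert_allclose(traj.s + traj.i, 1.0)
        assert ((traj.i >= 0) & (traj.i <= 1)).all()
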