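"""Engine semantics: probability components, state ladder, determinism, and
exact Markov-chain validation on tiny graphs."""

import numpy as np
import pytest

import campaignsim as cs
from _markov_oracle import exact_adoption_pmf, exact_distribution
from campaignsim import dynamics as dyn
from campaignsim import networks as nw
from conftest import make_toy_population


def _agent(a=(0.8, 0.2, 0.1), b_step=0.1454, klass=1):
    post = np.zeros(6)
    post[klass - 1] = 1.0
    return cs.AgentProfile(id=0, class_modal=klass, class_posterior=post,
                           a=np.asarray(a, float), b_step=b_step,
                           degree_target=4, task="vaccination")


def test_awareness_probability_control_scenario():
    spec = cs.get_scenario("vaccination", "A")
    p = dyn.awareness_probability(_agent(), spec, cs.ModelParams(), 0.0)
    assert p == pytest.approx(0.12)
    spec_s = cs.get_scenario("screening", "A")
    p = dyn.awareness_probability(_agent(), spec_s,
                                  cs.ModelParams(w_bg=0.10), 0.0)
    assert p == pytest.approx(0.10)


def test_awareness_probability_hand_value_and_clipping():
    spec = cs.get_scenario("vaccination", "B")
    params = cs.ModelParams(w_bg=0.12, omega_a=0.3)
    # 0.12 + 0.10*0.8 + 0.3*0.5 = 0.35
    p = dyn.awareness_probability(_agent(a=(0.8, 0, 0)), spec, params, 0.5)
    assert p == pytest.approx(0.35)
    big = cs.ModelParams(w_bg=1.0, omega_a=1.0)
    assert dyn.awareness_probability(_agent(a=(1, 1, 1)), spec, big, 1.0) == 1.0


def test_adoption_probability_threshold_and_hand_value():
    spec = cs.get_scenario("vaccination", "B")
    params = cs.ModelParams(alpha=1.15, beta_m=1.0, beta_s=0.2, tau=2)
    ag = _agent(a=(0.8, 0, 0), b_step=0.1454)
    # below threshold: reinforcement exactly 0
    p1 = dyn.adoption_probability(ag, spec, params, 1, 1 / 6)
    assert p1 == pytest.approx(1.15 * 0.1454 + 0.08)
    # 3 of 6 adopted: clip(0.16721 + 0.08 + 0.2*0.5) = 0.34721
    p2 = dyn.adoption_probability(ag, spec, params, 3, 0.5)
    assert p2 == pytest.approx(1.15 * 0.1454 + 0.08 + 0.1)
    # zero media, zero neighbors -> scaled baseline
    spec_a = cs.get_scenario("vaccination", "A")
    p3 = dyn.adoption_probability(ag, spec_a, params, 0, 0.0)
    assert p3 == pytest.approx(1.15 * 0.1454)


def test_logistic_link_anchoring():
    # agrees with the clipped-linear link at L = 0.5 by construction
    spec = cs.get_scenario("vaccination", "A")
    params = cs.ModelParams(w_bg=0.5, omega_a=0.0, link="logistic")
    p = dyn.awareness_probability(_agent(), spec, params, 0.0)
    assert p == pytest.approx(0.5)


def test_absorbing_states_fixed_point(toy_pop):
    net = nw.build_layered(toy_pop.degree_targets, seed=0)
    spec = cs.get_scenario("vaccination", "A")
    params = cs.ModelParams()
    sim = dyn.SimState.initial(toy_pop.n)
    sim.state[:] = 2
    before = sim.state.copy()
    dyn.step(sim, toy_pop, net, spec, params, np.random.default_rng(0))
    assert np.array_equal(sim.state, before)


def test_no_inputs_no_awareness(toy_pop):
    net = nw.build_layered(toy_pop.degree_targets, seed=0)
    spec = cs.get_scenario("vaccination", "A")
    params = cs.ModelParams(w_bg=0.0, omega_a=0.0)
    res = dyn.run_simulation(toy_pop, net, spec, params, seed=1)
    assert np.all(res.state == 0)
    assert np.all(res.t_aware == 0) and np.all(res.t_adopt == 0)


def test_saturated_probabilities_adopt_at_step_one():
    pop = make_toy_population(50, seed=1, b_annual=0.0)
    pop.b_step[:] = 1.0
    net = nw.build_layered(pop.degree_targets, seed=0)
    spec = cs.get_scenario("vaccination", "A")
    params = cs.ModelParams(alpha=1.0, w_bg=1.0)
    res = dyn.run_simulation(pop, net, spec, params, seed=2)
    assert np.all(res.state == 2)
    assert np.all(res.t_aware == 1) and np.all(res.t_adopt == 1)


def test_state_ladder_invariants(pop_vacc):
    net = nw.build_layered(pop_vacc.degree_targets, seed=3)
    spec = cs.get_scenario("vaccination", "E")
    res = dyn.run_simulation(pop_vacc, net, spec, cs.ModelParams(), seed=4)
    adopters = res.t_adopt > 0
    assert np.all(res.t_aware[adopters] > 0)
    assert np.all(res.t_adopt[adopters] >= res.t_aware[adopters])
    assert np.all((res.t_adopt >= 0) & (res.t_adopt <= 12))
    assert np.all((res.state == 2) == adopters)


def test_seed_determinism(toy_pop):
    net = nw.build_layered(toy_pop.degree_targets, seed=5)
    spec = cs.get_scenario("vaccination", "B")
    r1 = dyn.run_simulation(toy_pop, net, spec, cs.ModelParams(), seed=99)
    r2 = dyn.run_simulation(toy_pop, net, spec, cs.ModelParams(), seed=99)
    assert np.array_equal(r1.state, r2.state)
    assert np.array_equal(r1.t_adopt, r2.t_adopt)


def test_framing_at_unit_multiplier_equals_base_scenario(toy_pop):
    # M with k_neg=1 resolves to B's weights: identical runs seed-for-seed
    net = nw.build_layered(toy_pop.degree_targets, seed=6)
    b = cs.get_scenario("vaccination", "B")
    m = cs.get_scenario("vaccination", "M").with_kneg(1.0)
    params = cs.ModelParams()
    rb = dyn.run_simulation(toy_pop, net, b, params, seed=7)
    rm = dyn.run_simulation(toy_pop, net, m, params, seed=7)
    assert np.array_equal(rb.state, rm.state)


@pytest.mark.parametrize("knob", ["w_tv", "k_neg", "alpha", "w_bg"])
def test_stochastic_monotonicity(knob):
    """Increasing media weight, framing, baseline multiplier, or background
    exposure weakly increases mean final adoption (>=50 CRN seeds)."""
    pop = make_toy_population(250, seed=8, b_annual=0.4)
    net = nw.build_layered(pop.degree_targets, seed=8)
    lo_spec = cs.get_scenario("vaccination", "B")
    hi_spec = lo_spec
    lo_p = hi_p = cs.ModelParams(alpha=0.8, w_bg=0.06)
    if knob == "w_tv":
        lo_spec = cs.get_scenario("vaccination", "I")   # 0.025 TV+DG
        hi_spec = cs.get_scenario("vaccination", "J")   # 0.200 TV+DG
    elif knob == "k_neg":
        lo_spec = cs.get_scenario("vaccination", "M").with_kneg(0.95)
        hi_spec = cs.get_scenario("vaccination", "M").with_kneg(1.10)
    elif knob == "alpha":
        hi_p = lo_p.replace(alpha=1.3)
    elif knob == "w_bg":
        hi_p = lo_p.replace(w_bg=0.15)
    lo = np.mean([cs.final_adoption(dyn.run_simulation(pop, net, lo_spec, lo_p, s))
                  for s in range(50)])
    hi = np.mean([cs.final_adoption(dyn.run_simulation(pop, net, hi_spec, hi_p, s))
                  for s in range(50)])
    assert hi >= lo


# ---------------------------------------------------------------------------
# exact Markov-chain validation


def _two_agent_setup():
    post = np.eye(6)[[0, 0]]
    pop = dyn.ArrayPopulation(posterior=post, modal_class=np.array([1, 1]),
                              a=np.array([[0.6, 0.2, 0.0], [0.3, 0.5, 0.0]]),
                              b_step=np.array([0.12, 0.2]))
    net = nw.LayeredNetwork(2, {(0, 1)}, set())
    return pop, net


def _three_agent_setup():
    post = np.eye(6)[[0, 0, 0]]
    pop = dyn.ArrayPopulation(
        posterior=post, modal_class=np.array([1, 1, 1]),
        a=np.array([[0.6, 0.2, 0.0], [0.3, 0.5, 0.0], [0.9, 0.1, 0.0]]),
        b_step=np.array([0.12, 0.2, 0.08]))
    net = nw.LayeredNetwork(3, {(0, 1), (1, 2)}, {(0, 2)})
    return pop, net


@pytest.mark.parametrize("setup, tau", [(_two_agent_setup, 1),
                                        (_two_agent_setup, 2),
                                        (_three_agent_setup, 2)])
def test_kernel_matches_exact_markov_chain(setup, tau):
    """12-step adoption-count distribution from the compiled kernel matches
    exhaustive enumeration of the two-phase chain within 3 MC s.e. at
    50,000 replications."""
    pop, net = setup()
    n = pop.n
    spec = cs.get_scenario("vaccination", "B")
    params = cs.ModelParams(alpha=1.0, w_bg=0.05, omega_a=0.3, beta_s=0.25,
                            tau=tau)
    media = dyn.resolve_exposure_terms(pop, spec, params)
    adj = [sorted(net.union_neighbors(i)) for i in range(n)]
    dist = exact_distribution(adj, params.w_bg + media,
                              params.alpha * pop.b_step + media,
                              params.omega_a, params.beta_s, tau, T=12)
    pmf = exact_adoption_pmf(dist, n)
    assert pmf.sum() == pytest.approx(1.0, abs=1e-9)

    reps = 50_000
    counts = np.zeros(n + 1)
    for s in range(reps):
        res = dyn.run_simulation(pop, net, spec, params, seed=s)
        counts[int(np.sum(res.state == 2))] += 1
    freq = counts / reps
    for k in range(n + 1):
        se = max(np.sqrt(pmf[k] * (1 - pmf[k]) / reps), 1e-4)
        assert abs(freq[k] - pmf[k]) <= 3 * se, (
            f"count {k}: MC {freq[k]:.4f} vs exact {pmf[k]:.4f}")


def test_reference_path_matches_exact_chain_too():
    """The pure NumPy step() path agrees with the same enumeration."""
    pop, net = _two_agent_setup()
    spec = cs.get_scenario("vaccination", "A")
    params = cs.ModelParams(alpha=1.0, w_bg=0.15, omega_a=0.4, beta_s=0.3,
                            tau=1, T=6)
    media = dyn.resolve_exposure_terms(pop, spec, params)
    adj = [sorted(net.union_neighbors(i)) for i in range(2)]
    dist = exact_distribution(adj, params.w_bg + media,
                              params.alpha * pop.b_step + media,
                              params.omega_a, params.beta_s, 1, T=6)
    pmf = exact_adoption_pmf(dist, 2)
    reps = 8000
    counts = np.zeros(3)
    for s in range(reps):
        res = dyn.run_simulation_reference(pop, net, spec, params, seed=s)
        counts[int(np.sum(res.state == 2))] += 1
    freq = counts / reps
    for k in range(3):
        se = max(np.sqrt(pmf[k] * (1 - pmf[k]) / reps), 1e-4)
        assert abs(freq[k] - pmf[k]) <= 4 * se


def test_step_past_horizon_raises(toy_pop):
    net = nw.build_layered(toy_pop.degree_targets, seed=0)
    spec = cs.get_scenario("vaccination", "A")
    params = cs.ModelParams(T=1)
    sim = dyn.SimState.initial(toy_pop.n)
    rng = np.random.default_rng(0)
    dyn.step(sim, toy_pop, net, spec, params, rng)
    with pytest.raises(RuntimeError):
        dyn.step(sim, toy_pop, net, spec, params, rng)
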