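"""Synthetic surveys, Gower matching, hazard conversion, agent assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import campaignsim as cs
from campaignsim import synthpop as sp


# ---------------------------------------------------------------------------
# Gower distance


SPEC2 = {"x": ("numeric", (0.0, 10.0)), "c": ("categorical", None)}


def test_gower_identical_records_zero():
    r = {"age": 70.0, "sex": 1, "education": 2, "income": 3, "region": 1}
    assert sp.gower_distance(r, dict(r)) == 0.0


def test_gower_all_binary_mismatch_is_one():
    spec = {f"c{i}": ("categorical", None) for i in range(4)}
    x = {f"c{i}": 0 for i in range(4)}
    y = {f"c{i}": 1 for i in range(4)}
    assert sp.gower_distance(x, y, spec) == 1.0


def test_gower_hand_example():
    # numeric |2-7|/10 = 0.5, equal categorical 0 -> mean 0.25
    assert sp.gower_distance({"x": 2, "c": "a"}, {"x": 7, "c": "a"},
                             SPEC2) == pytest.approx(0.25)


def test_gower_errors():
    with pytest.raises(KeyError):
        sp.gower_distance({"x": 1}, {"x": 2}, SPEC2)
    bad = {"x": ("numeric", (5.0, 5.0))}
    with pytest.raises(ValueError):
        sp.gower_distance({"x": 1}, {"x": 2}, bad)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.floats(0, 10), st.integers(0, 3)),
                min_size=2, max_size=2))
def test_gower_symmetry_and_bounds(recs):
    x = {"x": recs[0][0], "c": recs[0][1]}
    y = {"x": recs[1][0], "c": recs[1][1]}
    d = sp.gower_distance(x, y, SPEC2)
    assert 0.0 <= d <= 1.0
    assert d == pytest.approx(sp.gower_distance(y, x, SPEC2))


# ---------------------------------------------------------------------------
# matching


def _random_tables(rng, n_r, n_d):
    def tab(n, start):
        return pd.DataFrame({
            "id": np.arange(start, start + n),
            "age": rng.uniform(55, 95, n).round(1),
            "sex": rng.integers(1, 3, n),
            "education": rng.integers(1, 5, n),
            "income": rng.integers(1, 6, n),
            "region": rng.integers(1, 4, n),
        })
    return tab(n_r, 0), tab(n_d, 1000)


def test_match_single_donor_maps_everyone():
    rng = np.random.default_rng(0)
    recips, donors = _random_tables(rng, 10, 1)
    mapping = sp.match_donors(recips, donors)
    assert (mapping == donors["id"].iloc[0]).all()


def test_match_exact_duplicate_wins():
    rng = np.random.default_rng(1)
    recips, donors = _random_tables(rng, 1, 50)
    # plant an exact copy of the recipient as donor id 1007
    for c in ("age", "sex", "education", "income", "region"):
        donors.loc[7, c] = recips[c].iloc[0]
    mapping = sp.match_donors(recips, donors)
    assert mapping.iloc[0] == donors["id"].iloc[7]


def test_match_equals_exhaustive_argmin():
    rng = np.random.default_rng(2)
    recips, donors = _random_tables(rng, 20, 30)
    mapping = sp.match_donors(recips, donors)
    for i in range(len(recips)):
        dists = np.array([sp.gower_distance(recips.iloc[i], donors.iloc[j])
                          for j in range(len(donors))])
        best = dists.min()
        # tie rule: lowest donor id among minimizers
        expect = donors["id"].iloc[np.flatnonzero(dists <= best + 1e-12).min()]
        assert mapping.iloc[i] == expect


def test_match_empty_pool_errors():
    rng = np.random.default_rng(3)
    recips, donors = _random_tables(rng, 5, 5)
    with pytest.raises(ValueError):
        sp.match_donors(recips, donors.iloc[:0])


# ---------------------------------------------------------------------------
# generator


def test_generator_sizes_and_determinism():
    d1, r1, t1 = sp.generate_synthetic_survey(seed=9)
    d2, r2, t2 = sp.generate_synthetic_survey(seed=9)
    assert len(r1) == 2405
    counts = np.bincount(t1, minlength=7)[1:]
    assert tuple(counts) == sp.CLASS_SIZES_DEFAULT
    pd.testing.assert_frame_equal(d1, d2)
    pd.testing.assert_frame_equal(r1, r2)


def test_generator_class_conditional_means():
    donors, recips, _ = sp.generate_synthetic_survey(seed=4)
    cfg = sp.PopulationConfig()
    for k, prof in enumerate(cfg.profiles, start=1):
        blk = donors[donors["true_class"] == k]
        for ch, col in (("tv", "a_tv"), ("dg", "a_dg"), ("pr", "a_pr")):
            a, b = prof.media[ch]
            mean, sd = a / (a + b), np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
            band = max(0.02, 3 * sd / np.sqrt(len(blk)))
            assert abs(blk[col].mean() - mean) < band
    # media-profile ordering: 1 and 5 TV-dominant, 6 digital-dominant
    for k in (1, 5):
        blk = donors[donors["true_class"] == k]
        assert blk["a_tv"].mean() > blk["a_dg"].mean()
    blk6 = donors[donors["true_class"] == 6]
    assert blk6["a_dg"].mean() > blk6["a_tv"].mean()


def test_generator_population_uptake_means():
    _, recips, _ = sp.generate_synthetic_survey(seed=5)
    assert abs(recips["q_vaccination"].mean() - 0.848) < 0.02
    assert abs(recips["q_screening"].mean() - 0.744) < 0.02


def test_generator_config_validation():
    good = sp._default_profiles()
    from dataclasses import replace
    bad = (replace(good[0], size=600),) + good[1:]
    with pytest.raises(ValueError):
        sp.PopulationConfig(profiles=bad)


# ---------------------------------------------------------------------------
# hazard conversion


@pytest.mark.parametrize("q, T, expected", [
    (0.0, 12, 0.0),
    (0.848, 12, 0.145279),   # closed form 1-(1-q)^(1/12)
    (0.3, 1, 0.3),
])
def test_annual_to_step_hazard_values(q, T, expected):
    assert sp.annual_to_step_hazard(q, T) == pytest.approx(expected, abs=1e-5)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.floats(0, 0.999), st.integers(1, 60))
def test_hazard_round_trip(q, T):
    h = sp.annual_to_step_hazard(q, T)
    assert 1 - (1 - h) ** T == pytest.approx(q, abs=1e-12)


def test_hazard_domain_error():
    with pytest.raises(ValueError):
        sp.annual_to_step_hazard(1.0, 12)


# ---------------------------------------------------------------------------
# agent assembly and the full pipeline


def test_pipeline_agents(pop_vacc):
    assert pop_vacc.n == 2405
    ids = [a.id for a in pop_vacc.agents]
    assert len(set(ids)) == 2405
    assert np.allclose(pop_vacc.posterior.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(pop_vacc.b_step >= 0) and np.all(pop_vacc.b_step <= 1)
    assert np.all(pop_vacc.degree_targets >= 1)
    # degree mapping: social activity 5 -> degree 10
    freq = pop_vacc.matched_table["social_activity"].to_numpy()
    assert np.all(pop_vacc.degree_targets[freq == 5] == 10)
    # hazard consistency with the annual propensity
    assert np.allclose(1 - (1 - pop_vacc.b_step) ** 12, pop_vacc.q_annual,
                       atol=1e-9)


def test_pipeline_screening_drops_nonresponse(pop_scr):
    assert pop_scr.n == 2400


def test_pipeline_class_designations(pop_vacc, pop_scr):
    """Matched modal classes preserve the media/baseline structure that the
    personalization scenarios assume."""
    for k in (1, 5):
        m = pop_vacc.modal_class == k
        assert pop_vacc.a[m, 0].mean() > pop_vacc.a[m, 1].mean()
    m6 = pop_vacc.modal_class == 6
    assert pop_vacc.a[m6, 1].mean() > pop_vacc.a[m6, 0].mean()
    # lowest-baseline designations
    qv = [pop_vacc.q_annual[pop_vacc.modal_class == k].mean()
          for k in range(1, 7)]
    assert int(np.argmin(qv)) + 1 == 6
    qs = [pop_scr.q_annual[pop_scr.modal_class == k].mean()
          for k in range(1, 7)]
    assert int(np.argmin(qs)) + 1 == 1


def test_build_agents_row_mismatch():
    from campaignsim import latent_class as lca
    tab = pd.DataFrame({"id": [0, 1], "q_vaccination": [0.5, 0.6],
                        "a_tv": [0.5, 0.5], "a_dg": [0.5, 0.5],
                        "a_pr": [0.5, 0.5], "social_activity": [3, 3]})
    bad = lca.ClassAssignment(posterior=np.ones((3, 1)),
                              modal_class=np.ones(3, int))
    with pytest.raises(ValueError):
        sp.build_agents(tab, bad, "vaccination")


def test_zero_channel_use_zero_media_exposure():
    from campaignsim import dynamics
    pop = cs.dynamics.ArrayPopulation(
        posterior=np.eye(6)[[0, 1, 2]], modal_class=np.array([1, 2, 3]),
        a=np.zeros((3, 3)), b_step=np.full(3, 0.1))
    for sid in "ABJKL":
        spec = cs.get_scenario("vaccination", sid)
        terms = dynamics.resolve_exposure_terms(pop, spec, cs.ModelParams())
        assert np.all(terms == 0.0)
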