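"""Sheaf layer: restriction, gluing, obstruction, consensus dynamics."""

import numpy as np
import pytest

from protentia.categorical import Categorical, FiniteSet, StochasticMap, ValidationError
from protentia.engine import GenerativeModel
from protentia.fixtures import make_shared_world, make_tmaze, perturb_sections
from protentia.sheaf import (
    Cover,
    GluingError,
    Section,
    check_gluing,
    consensus_step,
    disagreement,
    glue,
    restrict,
    run_consensus,
    validate_spatial_model,
)

SUP = FiniteSet(["h", "t"])


def sec(agent, **site_probs):
    return Section(agent, {site: Categorical(SUP, p) for site, p in site_probs.items()})


@pytest.fixture
def one_site_pair():
    """Two agents sharing a single site with maximal disagreement."""
    cover = Cover(FiniteSet(["x"]), {"a": ["x"], "b": ["x"]})
    return cover, [sec("a", x=[1, 0]), sec("b", x=[0, 1])]


class TestCover:
    def test_union_must_equal_base(self):
        with pytest.raises(ValidationError):
            Cover(FiniteSet(["x", "y"]), {"a": ["x"]})

    def test_empty_patch_rejected(self):
        with pytest.raises(ValidationError):
            Cover(FiniteSet(["x"]), {"a": []})

    def test_overlaps_in_base_order(self):
        cover = Cover(FiniteSet(["x", "y", "z"]),
                      {"a": ["y", "x"], "b": ["z", "y", "x"]})
        assert cover.overlaps()[("a", "b")] == ("x", "y")


class TestRestrict:
    def test_full_patch_is_identity(self):
        s = sec("a", x=[0.5, 0.5], y=[0.2, 0.8])
        assert restrict(s, ["x", "y"]).data == s.data

    def test_functoriality(self):
        s = sec("a", x=[0.5, 0.5], y=[0.2, 0.8], z=[0.9, 0.1])
        twice = restrict(restrict(s, ["x", "y"]), ["x"])
        once = restrict(s, ["x"])
        assert twice.data.keys() == once.data.keys()
        assert np.array_equal(twice.data["x"].probs, once.data["x"].probs)

    def test_single_site(self):
        s = sec("a", x=[0.5, 0.5], y=[0.2, 0.8])
        r = restrict(s, ["y"])
        assert r.sites == ("y",)

    def test_outside_patch_rejected(self):
        with pytest.raises(ValidationError):
            restrict(sec("a", x=[0.5, 0.5]), ["nope"])


class TestDisagreement:
    def test_identical_sections_have_zero_energy(self):
        cover = Cover(FiniteSet(["x", "y"]), {"a": ["x", "y"], "b": ["x"]})
        secs = [sec("a", x=[0.3, 0.7], y=[0.5, 0.5]), sec("b", x=[0.3, 0.7])]
        rep = disagreement(secs, cover)
        assert rep.energy == 0.0 and rep.max_discrepancy == 0.0

    def test_opposed_point_masses_have_energy_two(self, one_site_pair):
        cover, secs = one_site_pair
        rep = disagreement(secs, cover)
        assert rep.energy == pytest.approx(2.0)
        assert rep.pairwise[("a", "b")]["x"] == pytest.approx(2.0)
        assert rep.max_discrepancy == pytest.approx(1.0)  # total variation

    def test_disjoint_patches_vacuously_glueable(self):
        cover = Cover(FiniteSet(["x", "y"]), {"a": ["x"], "b": ["y"]})
        rep = disagreement([sec("a", x=[1, 0]), sec("b", y=[0, 1])], cover)
        assert rep.energy == 0.0 and rep.vacuous


class TestGluing:
    def test_consistent_fixture_glues(self):
        b = make_shared_world(epsilon=0.0, seed=3)
        ok, rep = check_gluing(list(b.sections), b.cover, tol=1e-12)
        assert ok and rep.energy == pytest.approx(0.0, abs=1e-24)

    def test_perturbed_fixture_fails_below_epsilon(self):
        b = make_shared_world(epsilon=0.2, seed=3)
        ok, rep = check_gluing(list(b.sections), b.cover, tol=0.1)
        assert not ok
        assert rep.max_discrepancy == pytest.approx(0.2, abs=1e-12)
        # the perturbed overlap is identified in the report
        assert any(d > 0 for per_site in rep.pairwise.values() for d in per_site.values())

    def test_infinite_tolerance_always_glues(self, one_site_pair):
        cover, secs = one_site_pair
        ok, _ = check_gluing(secs, cover, tol=float("inf"))
        assert ok

    def test_single_agent_glues_to_its_own_section(self):
        cover = Cover(FiniteSet(["x", "y"]), {"a": ["x", "y"]})
        s = sec("a", x=[0.3, 0.7], y=[0.9, 0.1])
        g = glue([s], cover)
        assert np.allclose(g.data["x"].probs, [0.3, 0.7])
        assert np.allclose(g.data["y"].probs, [0.9, 0.1])

    def test_exact_agreement_glues_to_shared_vector(self):
        cover = Cover(FiniteSet(["x"]), {"a": ["x"], "b": ["x"]})
        g = glue([sec("a", x=[0.25, 0.75]), sec("b", x=[0.25, 0.75])], cover)
        assert np.allclose(g.data["x"].probs, [0.25, 0.75])

    def test_three_patch_restriction_round_trip(self):
        b = make_shared_world(n_agents=3, n_sites=7, overlap=1, epsilon=0.0, seed=8)
        g = glue(list(b.sections), b.cover, tol=1e-12)
        for s in b.sections:
            for site, vec in s.data.items():
                assert np.max(np.abs(g.data[site].probs - vec.probs)) < 1e-12

    def test_failed_gluing_raises_with_report(self, one_site_pair):
        cover, secs = one_site_pair
        with pytest.raises(GluingError) as exc:
            glue(secs, cover, tol=1e-6)
        assert exc.value.report.energy == pytest.approx(2.0)


class TestConsensus:
    def test_consistent_sections_are_a_fixed_point(self):
        b = make_shared_world(epsilon=0.0, seed=5)
        stepped = consensus_step(list(b.sections), b.cover, eta=0.7)
        for before, after in zip(b.sections, stepped):
            for site in before.data:
                assert np.allclose(before.data[site].probs, after.data[site].probs,
                                   atol=1e-15)

    def test_eta_one_takes_midpoint(self, one_site_pair):
        cover, secs = one_site_pair
        stepped = consensus_step(secs, cover, eta=1.0)
        for s in stepped:
            assert np.allclose(s.data["x"].probs, [0.5, 0.5])

    def test_eta_zero_rejected(self, one_site_pair):
        cover, secs = one_site_pair
        with pytest.raises(ValidationError):
            consensus_step(secs, cover, eta=0.0)

    def test_two_agent_geometric_decay_matches_closed_form(self, one_site_pair):
        """Differences contract by (1-eta); energy by (1-eta)^2 per step."""
        cover, secs = one_site_pair
        res = run_consensus(secs, cover, eta=0.5, tol=1e-6, max_iter=25)
        assert res.converged and res.iterations <= 25
        for e_prev, e_next in zip(res.energies, res.energies[1:]):
            assert e_next == pytest.approx(0.25 * e_prev, rel=1e-9)
        # limit is the renormalized mean of the initial vectors
        for s in res.sections:
            assert np.allclose(s.data["x"].probs, [0.5, 0.5], atol=1e-3)

    def test_consistent_input_zero_iterations(self):
        b = make_shared_world(epsilon=0.0, seed=2)
        res = run_consensus(list(b.sections), b.cover, tol=1e-12)
        assert res.iterations == 0 and res.energies == (0.0,)

    def test_energy_trace_non_increasing_on_seeded_scenarios(self):
        for seed in range(50):
            b = make_shared_world(n_agents=3, n_sites=7, overlap=1, seed=seed)
            secs = perturb_sections(list(b.sections), 0.5, seed=seed)
            res = run_consensus(secs, b.cover, eta=0.7, max_iter=40)
            diffs = np.diff(res.energies)
            assert np.all(diffs <= 1e-12), seed

    def test_non_convergence_flagged(self, one_site_pair):
        cover, secs = one_site_pair
        res = run_consensus(secs, cover, eta=0.5, tol=1e-30, max_iter=3)
        assert not res.converged and res.iterations == 3


class TestSpatialValidation:
    def test_everything_admissible_passes(self, identity_model):
        chk = validate_spatial_model(identity_model,
                                     {"s1": "here", "s2": "here"},
                                     {"here": ["o1", "o2"]})
        assert chk.passed and not chk.violations

    def test_tmaze_cue_admissible_only_at_cue_site(self, tmaze):
        chk = validate_spatial_model(tmaze.agents[0].model,
                                     tmaze.metadata["site_assignment"],
                                     tmaze.metadata["admissibility"])
        assert chk.passed

    def test_corrupt_likelihood_detected_and_localized(self, tmaze):
        m = tmaze.agents[0].model
        bad = m.A.table.copy()
        j = m.states.index("center:reward-left")
        bad[:, j] = 0.0
        bad[m.observations.index("o-cue-left"), j] = 0.1  # forbidden at center
        bad[m.observations.index("o-center"), j] = 0.9
        m2 = GenerativeModel(states=m.states, observations=m.observations,
                             actions=m.actions, A=StochasticMap(m.states, m.observations, bad),
                             B=m.B, C=m.C, D=m.D, E=m.E, gamma=m.gamma)
        chk = validate_spatial_model(m2, tmaze.metadata["site_assignment"],
                                     tmaze.metadata["admissibility"])
        assert not chk.passed
        assert ("center:reward-left", "center", "o-cue-left", pytest.approx(0.1)) \
            in [tuple(v) for v in chk.violations]

    def test_missing_site_assignment_rejected(self, identity_model):
        with pytest.raises(ValidationError):
            validate_spatial_model(identity_model, {"s1": "here"}, {"here": ["o1", "o2"]})
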