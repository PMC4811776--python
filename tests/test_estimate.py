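"""Estimator: priors, MAP recovery, evidence behavior, group inference."""

import numpy as np
import pandas as pd
import pytest

from conftest import TWO_NODE_SPEC, two_node_params, two_node_timeline
from hierdcm.design import InputTimeline
from hierdcm.estimate import (
    DCMEstimator,
    ParameterMap,
    PriorSpec,
    default_priors,
    fit_dcm,
    group_parameter_inference,
    log_evidence,
    parameter_table,
)
from hierdcm.modelspace import ModelSpec, default_winning_structure
from hierdcm.simulate import DCMParameters, HemodynamicParams, simulate_dataset


class TestPriors:
    def test_offdiag_prior_mean_zero(self):
        priors = default_priors(TWO_NODE_SPEC)
        assert priors.a_offdiag[0] == 0.0

    def test_self_parameterization_identity(self):
        pmap = ParameterMap(TWO_NODE_SPEC, ("u1", "u2"), ())
        theta = np.zeros(pmap.n_total)
        A, _, _, _ = pmap.unpack(theta)
        assert np.allclose(np.diag(A), -0.5)

    def test_free_parameter_counts_default_network(self):
        """9 bidirectional edges, 3 inputs and 8 modulated edges give
        18 + 3 + 8 neural parameters plus self and noise terms."""
        spec = default_winning_structure()
        pmap = ParameterMap(spec)
        assert pmap.n_a == 18
        assert pmap.n_c == 3
        assert pmap.n_b == 8
        assert pmap.n_neural == 18 + 6 + 8 + 3
        assert pmap.n_total == pmap.n_neural + 6

    def test_nonpositive_prior_variance(self):
        with pytest.raises(ValueError):
            PriorSpec(b=(0.0, 0.0))


class TestFit:
    def test_prior_only_returns_prior_mean(self, rng):
        tl = two_node_timeline(rng, 40)
        data = simulate_dataset(two_node_params(0.2, 0.1), timeline=tl, noise_sd=0.1, seed=0)
        est = DCMEstimator(spec=TWO_NODE_SPEC, likelihood_weight=0.0, restarts=1).fit(data, tl)
        pmap = est.pmap_
        mu, _ = pmap.prior_vectors(default_priors(TWO_NODE_SPEC))
        assert np.allclose(est.theta_, mu, atol=1e-6)

    def test_analytic_gradient_matches_finite_differences(self, rng):
        tl = two_node_timeline(rng, 40)
        Y = simulate_dataset(two_node_params(0.2, 0.1), timeline=tl, noise_sd=0.1, seed=1).data
        pmap = ParameterMap(TWO_NODE_SPEC, tl.drive_names, tl.mod_names)
        mu, var = pmap.prior_vectors(default_priors(TWO_NODE_SPEC))
        theta = mu + 0.1 * np.sqrt(var) * rng.standard_normal(mu.size)
        hemo = HemodynamicParams()
        fa, _ = DCMEstimator(spec=TWO_NODE_SPEC, gradient="analytic")._objective_factory(
            Y, tl, pmap, mu, 1 / var, hemo, 4)
        ff, _ = DCMEstimator(spec=TWO_NODE_SPEC, gradient="fd", fd_step=1e-6)._objective_factory(
            Y, tl, pmap, mu, 1 / var, hemo, 4)
        va, ga = fa(theta)
        vf, gf = ff(theta)
        assert va == pytest.approx(vf, abs=1e-8)
        assert np.max(np.abs(ga - gf) / (np.abs(gf) + 1e-3)) < 1e-3

    def test_planted_negative_modulation_recovered(self, rng):
        """A strongly inhibitory planted modulation comes back negative."""
        dt = 0.5
        spt = 4
        n_scans = 300
        T = n_scans * spt
        drive = np.zeros((T, 2))
        mod = np.zeros((T, 1))
        for tr in range(n_scans):
            drive[tr * spt, rng.integers(2)] = 1.0
        mod[: T // 2, 0] = 1.0
        tl = InputTimeline(dt=dt, drive=drive, mod=mod, drive_names=("u1", "u2"), mod_names=("m1",))
        spec = ModelSpec(regions=("R1", "R2"), edges=(("R1", "R2"),),
                         drive_targets=(("u1", "R1"), ("u2", "R2")),
                         modulations=(("m1", (("R1", "R2"),)),))
        A = np.array([[-0.5, 0.2], [0.4, -0.5]])
        B = {"m1": np.array([[0.0, 0.0], [-0.35, 0.0]])}
        params = DCMParameters(("R1", "R2"), A, B, np.eye(2))
        data = simulate_dataset(params, timeline=tl, noise_sd=0.1, seed=5)
        fit = fit_dcm(data, tl, spec, options={"restarts": 2, "seed": 0})
        assert fit.B["m1"][1, 0] < -0.1

    def test_dimension_mismatch_errors(self, rng):
        tl = two_node_timeline(rng, 40)
        data = simulate_dataset(two_node_params(0.2, 0.1), timeline=tl, noise_sd=0.1, seed=0)
        with pytest.raises(ValueError):
            DCMEstimator(spec=TWO_NODE_SPEC).fit(data.data[:, :1], tl)
        with pytest.raises(ValueError):
            DCMEstimator(spec=TWO_NODE_SPEC).fit(data.data[:-5], tl)


class TestEvidence:
    def _fit_ev(self, data, tl, spec, seed=0):
        return fit_dcm(data, tl, spec, options={"restarts": 1, "seed": seed}).log_evidence

    def test_generative_model_beats_scrambled_edges(self):
        """Across seeded replicates the generating structure wins the
        evidence comparison against a same-size scrambled edge set."""
        regions = ("R1", "R2", "R3")
        true_spec = ModelSpec(regions=regions, edges=(("R1", "R2"), ("R2", "R3")),
                              drive_targets=(("u1", "R1"), ("u2", "R2")), modulations=())
        scrambled = ModelSpec(regions=regions, edges=(("R1", "R3"), ("R1", "R2")),
                              drive_targets=(("u1", "R1"), ("u2", "R2")), modulations=())
        A = np.array([[-0.5, 0.15, 0.0], [0.35, -0.5, 0.1], [0.0, 0.4, -0.5]])
        C = np.zeros((3, 2))
        C[0, 0] = 1.0
        C[1, 1] = 1.0
        params = DCMParameters(regions, A, {}, C)
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(500 + rep)
            spt = 4
            T = 150 * spt
            drive = np.zeros((T, 2))
            for tr in range(150):
                drive[tr * spt, rng.integers(2)] = 1.0
            tl = InputTimeline(dt=0.5, drive=drive, mod=np.zeros((T, 0)),
                               drive_names=("u1", "u2"), mod_names=())
            data = simulate_dataset(params, timeline=tl, noise_sd=0.1, seed=600 + rep)
            if self._fit_ev(data, tl, true_spec, rep) > self._fit_ev(data, tl, scrambled, rep):
                wins += 1
        assert wins >= int(0.9 * n_rep)

    def test_spurious_modulation_penalized_on_null_data(self, rng):
        """On data without any modulation effect, freeing a modulation
        lowers the evidence (complexity penalty)."""
        spt = 4
        n_scans = 200
        T = n_scans * spt
        drive = np.zeros((T, 2))
        mod = np.zeros((T, 1))
        for tr in range(n_scans):
            drive[tr * spt, rng.integers(2)] = 1.0
        mod[: T // 2, 0] = 1.0
        tl = InputTimeline(dt=0.5, drive=drive, mod=mod, drive_names=("u1", "u2"), mod_names=("m1",))
        params = two_node_params(0.2, 0.1)
        data = simulate_dataset(params, timeline=tl, noise_sd=0.3, seed=11)
        plain = TWO_NODE_SPEC
        spurious = ModelSpec(regions=("R1", "R2"), edges=(("R1", "R2"),),
                             drive_targets=(("u1", "R1"), ("u2", "R2")),
                             modulations=(("m1", (("R1", "R2"), ("R2", "R1"))),))
        assert self._fit_ev(data, tl, plain) > self._fit_ev(data, tl, spurious)

    def test_evidence_deterministic(self, rng):
        tl = two_node_timeline(rng, 60)
        data = simulate_dataset(two_node_params(0.2, 0.1), timeline=tl, noise_sd=0.1, seed=0)
        f1 = fit_dcm(data, tl, TWO_NODE_SPEC, options={"restarts": 2, "seed": 7})
        f2 = fit_dcm(data, tl, TWO_NODE_SPEC, options={"restarts": 2, "seed": 7})
        assert log_evidence(f1) == log_evidence(f2)
        assert np.array_equal(f1.theta, f2.theta)

    def test_ranking_invariant_to_data_scaling(self, rng):
        """Scaling the data rescales noise estimates but not which model
        has higher evidence."""
        tl = two_node_timeline(rng, 120)
        data = simulate_dataset(two_node_params(0.3, 0.05), timeline=tl, noise_sd=0.1, seed=3)
        swapped = ModelSpec(regions=("R1", "R2"), edges=(("R1", "R2"),),
                            drive_targets=(("u1", "R2"), ("u2", "R1")), modulations=())
        for k in (1.0, 3.0):
            e_true = self._fit_ev(k * data.data, tl, TWO_NODE_SPEC)
            e_swap = self._fit_ev(k * data.data, tl, swapped)
            assert e_true > e_swap


class TestGroupInference:
    def test_planted_mean_detected_and_null_spared(self, rng):
        n = 24
        table = pd.DataFrame({
            "effect": 0.3 + 0.15 * rng.standard_normal(n),
            "null1": 0.15 * rng.standard_normal(n),
            "null2": 0.15 * rng.standard_normal(n),
        })
        res = group_parameter_inference(table)
        assert res.loc["effect", "q"] < 0.05
        assert res.loc["effect", "t"] > 4

    def test_constant_nonzero_parameter_flagged(self):
        table = pd.DataFrame({"const": np.full(10, 0.4), "noise": np.linspace(-1, 1, 10)})
        res = group_parameter_inference(table)
        assert np.isinf(res.loc["const", "t"])
        assert res.loc["const", "q"] == res["q"].min()
        assert bool(res.loc["const", "degenerate"])

    def test_mixed_specs_error(self, rng):
        tl = two_node_timeline(rng, 40)
        data = simulate_dataset(two_node_params(0.2, 0.1), timeline=tl, noise_sd=0.2, seed=0)
        f1 = fit_dcm(data, tl, TWO_NODE_SPEC, options={"restarts": 1})
        swapped = ModelSpec(regions=("R1", "R2"), edges=(("R1", "R2"),),
                            drive_targets=(("u1", "R2"), ("u2", "R1")), modulations=())
        f2 = fit_dcm(data, tl, swapped, options={"restarts": 1})
        with pytest.raises(ValueError):
            parameter_table([f1, f2])

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            group_parameter_inference(pd.DataFrame({"a": [1.0, 2.0]}))
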