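"""Corner sampling, the Hit-and-Run baseline, and summary statistics."""

import numpy as np
import pytest

from conftest import bound_violation, steady_state_residual
from fluxcorners import (draw_objective, make_fixture, run_fva, sample_corners,
                         sample_hit_and_run, summarize)
from fluxcorners.fixtures import enumerate_vertices, nearest_vertex_distance
from fluxcorners.model import apply_condition
from fluxcorners.sampling import FluxSampleSet


class TestDrawObjective:
    def test_weights_normalized_by_fva_magnitude(self, diamond_fx):
        # reactions with 100x smaller FVA range get ~100x larger weights
        m = apply_condition(diamond_fx.model, diamond_fx.condition)
        fva = run_fva(m)
        mags = {r: max(abs(lo), abs(hi))
                for r, lo, hi in zip(fva.reaction_ids, fva.min_flux, fva.max_flux)}
        rng = np.random.default_rng(0)
        sums = {r: 0.0 for r in m.reaction_ids}
        counts = {r: 0 for r in m.reaction_ids}
        for _ in range(4000):
            for rxn, w in draw_objective(m, fva, set(), rng).terms:
                sums[rxn] += w
                counts[rxn] += 1
        # E[w] = 0.5 / magnitude
        for rxn in m.reaction_ids:
            assert sums[rxn] / counts[rxn] == pytest.approx(0.5 / mags[rxn], rel=0.15)

    def test_all_loop_flagged_is_error(self, diamond_fx):
        m = apply_condition(diamond_fx.model, diamond_fx.condition)
        fva = run_fva(m)
        with pytest.raises(ValueError, match="eligible"):
            draw_objective(m, fva, set(m.reaction_ids), np.random.default_rng(0))

    def test_fixed_rng_is_deterministic(self, diamond_fx):
        m = apply_condition(diamond_fx.model, diamond_fx.condition)
        fva = run_fva(m)
        a = draw_objective(m, fva, set(), np.random.default_rng(42))
        b = draw_objective(m, fva, set(), np.random.default_rng(42))
        assert a.terms == b.terms

    def test_loop_reactions_never_drawn(self, cycle_fx):
        m = apply_condition(cycle_fx.model, cycle_fx.condition)
        fva = run_fva(m)
        rng = np.random.default_rng(3)
        loops = {"C1", "C2", "C3"}
        for _ in range(200):
            obj = draw_objective(m, fva, loops, rng)
            assert not loops & {r for r, _ in obj.terms}


class TestSampleCorners:
    def test_one_dof_samples_are_endpoints(self, interval_fx):
        ss = sample_corners(interval_fx.model, interval_fx.condition, n=300, seed=11)
        j = ss.reaction_ids.index("b1")
        col = ss.samples[:, j]
        assert np.all((np.abs(col) < 1e-8) | (np.abs(col - 10.0) < 1e-8))
        # both endpoints are reached and the split is roughly even
        assert ss.means[j] == pytest.approx(5.0, abs=1.8)
        assert ss.variances[j] == pytest.approx(25.0, abs=7.0)

    def test_fully_determined_chain_zero_variance(self, chain_fx):
        ss = sample_corners(chain_fx.model, chain_fx.condition, n=20, seed=5)
        assert np.max(ss.variances) <= 1e-18
        assert np.max(np.abs(ss.samples - ss.samples[0])) <= 1e-12

    def test_same_seed_bitwise_identical(self, diamond_fx):
        a = sample_corners(diamond_fx.model, diamond_fx.condition, n=40, seed=9)
        b = sample_corners(diamond_fx.model, diamond_fx.condition, n=40, seed=9)
        assert np.array_equal(a.samples, b.samples)

    @pytest.mark.parametrize("kind, params", [
        ("diamond", {}),
        ("diamond", {"cap_branch1": 0.4}),
        ("interval", {}),
        ("simplex", {"n_branches": 3}),
        ("simplex", {"n_branches": 4}),
    ])
    def test_every_sample_is_a_brute_force_vertex(self, kind, params):
        fx = make_fixture(kind, **params)
        verts = enumerate_vertices(fx.model, fx.condition)
        ss = sample_corners(fx.model, fx.condition, n=120, seed=2)
        worst = max(nearest_vertex_distance(row, verts) for row in ss.samples)
        assert worst <= 1e-8

    def test_samples_respect_constraints(self, simplex_fx):
        ss = sample_corners(simplex_fx.model, simplex_fx.condition, n=100, seed=4)
        m = apply_condition(simplex_fx.model, simplex_fx.condition)
        for row in ss.samples:
            scale = max(1.0, np.max(np.abs(row)))
            assert steady_state_residual(m, row) <= 1e-9 * scale
            assert bound_violation(m, row) <= 1e-6
        j = ss.reaction_ids.index("EX_A")
        assert np.all(ss.samples[:, j] == -1.0)  # fixed flux held exactly

    def test_loop_bounded_model_samples(self, cycle_fx):
        ss = sample_corners(cycle_fx.model, cycle_fx.condition, n=30, seed=6)
        assert ss.loop_set == {"C1", "C2", "C3"}
        assert ss.loop_bound == pytest.approx(0.1)
        for c in ("C1", "C2", "C3"):
            assert np.all(np.abs(ss.samples[:, ss.reaction_ids.index(c)]) <= 0.1 + 1e-9)

    def test_fva_brackets_all_samples(self, diamond_fx):
        m = apply_condition(diamond_fx.model, diamond_fx.condition)
        fva = run_fva(m)
        ss = sample_corners(diamond_fx.model, diamond_fx.condition, n=80, seed=7)
        for k, rxn in enumerate(fva.reaction_ids):
            j = ss.reaction_ids.index(rxn)
            assert np.all(ss.samples[:, j] >= fva.min_flux[k] - 1e-8)
            assert np.all(ss.samples[:, j] <= fva.max_flux[k] + 1e-8)


class TestHitAndRun:
    def test_interval_uniform_moments(self, interval_fx):
        ss = sample_hit_and_run(interval_fx.model, interval_fx.condition,
                                n=4000, seed=12)
        j = ss.reaction_ids.index("b1")
        assert ss.means[j] == pytest.approx(5.0, abs=0.4)
        assert ss.variances[j] == pytest.approx(100.0 / 12.0, rel=0.15)

    def test_simplex_dirichlet_moments(self, simplex_fx):
        ss = sample_hit_and_run(simplex_fx.model, simplex_fx.condition,
                                n=4000, seed=13)
        for b in ("b1", "b2", "b3"):
            j = ss.reaction_ids.index(b)
            assert ss.means[j] == pytest.approx(1.0 / 3.0, abs=0.04)
            assert ss.variances[j] == pytest.approx(1.0 / 18.0, rel=0.25)

    def test_degenerate_polytope_warns_identical(self, chain_fx):
        with pytest.warns(UserWarning, match="0 degrees of freedom"):
            ss = sample_hit_and_run(chain_fx.model, chain_fx.condition, n=5, seed=1)
        assert np.max(np.abs(ss.samples - ss.samples[0])) <= 1e-12

    def test_zero_samples_errors_on_summarize(self, interval_fx):
        ss = sample_hit_and_run(interval_fx.model, interval_fx.condition, n=0, seed=1)
        assert ss.n_samples == 0
        with pytest.raises(ValueError, match="at least 2"):
            summarize(ss)

    def test_samples_respect_constraints(self, simplex_fx):
        ss = sample_hit_and_run(simplex_fx.model, simplex_fx.condition, n=200, seed=14)
        m = apply_condition(simplex_fx.model, simplex_fx.condition)
        for row in ss.samples:
            assert steady_state_residual(m, row) <= 1e-8
            assert bound_violation(m, row) <= 1e-6


class TestSummaryStatistics:
    def test_two_point_summary(self):
        samples = np.array([[0.0], [10.0], [0.0], [10.0]])
        ss = FluxSampleSet("c", ["r"], samples, "CB", seed=0)
        df = summarize(ss)
        assert df.at["r", "mean"] == pytest.approx(5.0)
        assert df.at["r", "variance"] == pytest.approx(25.0)

    def test_constant_column_zero_variance(self):
        ss = FluxSampleSet("c", ["r"], np.full((7, 1), 3.3), "CB", seed=0)
        assert summarize(ss).at["r", "variance"] <= 1e-24

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(99)
        x = rng.normal(size=(50, 4))
        ss = FluxSampleSet("c", list("abcd"), x, "HR", seed=0)
        df = summarize(ss)
        for j, r in enumerate("abcd"):
            mean = sum(x[:, j]) / 50.0
            var = sum((x[:, j] - mean) ** 2) / 50.0
            assert abs(df.at[r, "mean"] - mean) < 1e-12
            assert abs(df.at[r, "variance"] - var) < 1e-12


class TestCBvsHR:
    def test_cb_variance_at_least_hr_variance(self, interval_fx, simplex_fx):
        # corners spread wider than the uniform interior: the method's
        # central qualitative claim
        for fx, branches in ((interval_fx, ("b1", "b2")),
                             (simplex_fx, ("b1", "b2", "b3"))):
            cb = sample_corners(fx.model, fx.condition, n=300, seed=21)
            hr = sample_hit_and_run(fx.model, fx.condition, n=1500, seed=22)
            for b in branches:
                j = cb.reaction_ids.index(b)
                assert cb.variances[j] >= hr.variances[j]

    def test_cb_and_hr_means_agree(self, simplex_fx):
        cb = sample_corners(simplex_fx.model, simplex_fx.condition, n=400, seed=23)
        hr = sample_hit_and_run(simplex_fx.model, simplex_fx.condition,
                                n=2000, seed=24)
        for b in ("b1", "b2", "b3"):
            j = cb.reaction_ids.index(b)
            assert abs(cb.means[j] - hr.means[j]) <= 0.15

    def test_tsv_serialization_roundtrip(self, diamond_fx, tmp_path):
        ss = sample_corners(diamond_fx.model, diamond_fx.condition, n=25, seed=8)
        tsv, meta = tmp_path / "s.tsv", tmp_path / "s.json"
        ss.write_tsv(tsv, meta)
        import json

        import pandas as pd
        back = pd.read_csv(tsv, sep="\t")
        assert list(back.columns) == ss.reaction_ids
        np.testing.assert_allclose(back.to_numpy(), ss.samples, atol=1e-9)
        info = json.loads(meta.read_text())
        assert info["sampler"] == "CB" and info["n_samples"] == 25
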