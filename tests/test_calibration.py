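"""Objective function, constraint penalties and the genetic algorithm."""

import numpy as np
import pandas as pd
import pytest

from pykmet import calibration as cal
from pykmet.calibration import (
    Condition,
    ConstraintPenalty,
    ExperimentalDataset,
    GAConfig,
    cost_J,
    ga_fit,
    objective_M,
    random_neighborhood_assessment,
)
from pykmet.model import ParameterSet
from pykmet.simulate import Stimulus, simulate
from pykmet.synth import TimecourseConfig, synth_timecourses

from conftest import TOY_TRUTH


def _stub_dataset(obs, sd, cond="c"):
    rec = pd.DataFrame(
        {
            "readout": "pERK",
            "time_h": np.arange(1.0, len(obs) + 1),
            "condition": cond,
            "mean": obs,
            "sd": sd,
        }
    )
    return ExperimentalDataset(rec, {cond: Condition(cond)})


class TestCostJ:
    def test_hand_computed_chi_square(self, ref_model, monkeypatch):
        """obs (1, 2, 3), model (1.1, 1.8, 3.0), sd 0.1 -> J = 5."""
        ds = _stub_dataset([1.0, 2.0, 3.0], [0.1, 0.1, 0.1])
        sims = {"pERK": np.array([1.1, 1.8, 3.0])}
        monkeypatch.setattr(
            cal, "simulate_condition", lambda *a, **k: sims
        )
        assert cost_J(ref_model, ref_model.params, ds) == pytest.approx(5.0)

    def test_scale_invariance(self, ref_model, monkeypatch):
        """J is unchanged when obs, model and sd are jointly rescaled."""
        c = 7.3
        base = _stub_dataset([1.0, 2.0, 3.0], [0.1, 0.1, 0.1])
        scaled = _stub_dataset([c, 2 * c, 3 * c], [0.1 * c] * 3)
        sims = {"pERK": np.array([1.1, 1.8, 3.0])}
        monkeypatch.setattr(cal, "simulate_condition", lambda *a, **k: sims)
        j1 = cost_J(ref_model, ref_model.params, base)
        monkeypatch.setattr(
            cal, "simulate_condition", lambda *a, **k: {"pERK": sims["pERK"] * c}
        )
        j2 = cost_J(ref_model, ref_model.params, scaled)
        assert j2 == pytest.approx(j1, rel=1e-12)

    def test_self_consistent_data_gives_zero(self, ref_model):
        ds = synth_timecourses(ref_model, config=TimecourseConfig(seed=0, sigma=0.0))
        assert cost_J(ref_model, ref_model.params, ds) == pytest.approx(0.0, abs=1e-8)

    def test_adding_a_record_cannot_decrease_J(self, ref_model, monkeypatch):
        monkeypatch.setattr(
            cal, "simulate_condition",
            lambda sys, cond, readouts, times:
                {"pERK": np.array([1.1, 1.8, 3.0])[: len(times)]},
        )
        j2 = cost_J(ref_model, ref_model.params,
                    _stub_dataset([1.0, 2.0], [0.1, 0.1]))
        j3 = cost_J(ref_model, ref_model.params,
                    _stub_dataset([1.0, 2.0, 3.5], [0.1, 0.1, 0.1]))
        assert j3 >= j2

    def test_positive_sd_required(self):
        with pytest.raises(ValueError, match="SD"):
            _stub_dataset([1.0], [0.0])


class TestObjectiveM:
    def test_equals_J_when_constraints_satisfied(self, ref_model):
        """The calibrated model satisfies all three qualitative constraints."""
        ds = synth_timecourses(ref_model, config=TimecourseConfig(seed=0, sigma=0.0))
        j = cost_J(ref_model, ref_model.params, ds)
        m = objective_M(ref_model, ref_model.params, ds, cal.default_constraints())
        assert m == pytest.approx(j, abs=1e-9)

    def test_quadratic_penalty_shape(self):
        pen = ConstraintPenalty("t", "margin equals feature", lambda f: f["m"], 1e3)
        assert pen.penalty({"m": 0.0}) == 0.0
        assert pen.penalty({"m": 0.2}) == pytest.approx(1e3 * 0.04)
        assert pen.penalty({"m": -1.0}) == 0.0  # satisfied side clamps to zero


def _quadratic_objective(truth):
    keys = sorted(truth)

    def f(params: ParameterSet) -> float:
        return sum((np.log10(params[k]) - np.log10(truth[k])) ** 2 for k in keys)

    return f


class TestGeneticAlgorithm:
    BOUNDS = {"k1": (0.02, 200.0), "k2": (0.015, 150.0), "k3": (0.008, 80.0)}

    def test_deterministic_under_seed(self):
        obj = _quadratic_objective({"k1": 2.0, "k2": 1.5, "k3": 0.8})
        base = ParameterSet(TOY_TRUTH)
        cfg = GAConfig(population=20, generations=15, seed=5)
        r1 = ga_fit(obj, base, self.BOUNDS, cfg)
        r2 = ga_fit(obj, base, self.BOUNDS, cfg)
        assert r1.objective == r2.objective
        assert dict(r1.best_params) == dict(r2.best_params)

    def test_elitism_never_worse_than_seeded_truth(self):
        truth = {"k1": 2.0, "k2": 1.5, "k3": 0.8}
        obj = _quadratic_objective(truth)
        base = ParameterSet(TOY_TRUTH)
        res = ga_fit(
            obj, base, self.BOUNDS,
            GAConfig(population=12, generations=5, seed=1),
            initial_guesses=[truth],
        )
        assert res.objective <= obj(base.updated(**truth)) + 1e-12

    def test_population_floor(self):
        with pytest.raises(ValueError, match="population"):
            ga_fit(lambda p: 0.0, ParameterSet(TOY_TRUTH), self.BOUNDS,
                   GAConfig(population=5))

    def test_all_infeasible_population_reported(self):
        def bad(params):
            raise RuntimeError("no")

        with pytest.raises(RuntimeError, match="widen"):
            ga_fit(bad, ParameterSet(TOY_TRUTH), self.BOUNDS,
                   GAConfig(population=10, generations=1, seed=0))


class TestNeighborhood:
    def test_degenerate_fold_range_keeps_objective(self):
        obj = _quadratic_objective({"k1": 2.0})
        best = ParameterSet(TOY_TRUTH).updated(k1=2.0)
        tab = random_neighborhood_assessment(
            obj, best, free_names=["k1"], fold_ranges=[1.0], n=20, seed=0
        )
        assert np.allclose(tab["M"], obj(best))

    def test_table_shape(self):
        obj = _quadratic_objective({"k1": 2.0})
        best = ParameterSet(TOY_TRUTH).updated(k1=2.0)
        tab = random_neighborhood_assessment(
            obj, best, free_names=["k1"], fold_ranges=[2.0, 5.0], n=30, seed=0
        )
        assert len(tab) == 60
        assert set(tab["fold_range"]) == {2.0, 5.0}
        # the exact optimum beats every perturbed draw
        assert tab["exceeds_best"].all()
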