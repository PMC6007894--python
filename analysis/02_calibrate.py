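"""Calibration demonstration on synthetic training data.

Generates the noisy training design from the reference model, evaluates
the chi-square cost and the constrained objective at the true parameters,
runs the genetic-algorithm recovery harness on a reduced problem (four
free kinetic parameters of the toy phospho-cycle), and performs the
randomised neighbourhood assessment of the reference fit (200 draws per
fold range, reduced from 1000 for runtime).

Run:  python analysis/02_calibrate.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from pykmet import calibration as cal
from pykmet import synth
from pykmet.calibration import GAConfig, ga_fit, random_neighborhood_assessment
from pykmet.model import ModelDefinition, ParameterSet, Reaction, build_model
from pykmet.reference import reference_model
from pykmet.simulate import simulate

OUT = Path(__file__).resolve().parents[1] / "results" / "calibration"
OUT.mkdir(parents=True, exist_ok=True)

TOY_TRUTH = {"k0": 0.05, "k1": 2.0, "Km1": 0.5, "k2": 1.5, "Km2": 0.4,
             "k3": 0.8, "ks_b": 0.6}


def toy_definition() -> ModelDefinition:
    rxns = {
        "act": Reaction("act", "(k0 + k1 * u) * A / (Km1 + A)"),
        "deact": Reaction("deact", "k2 * pA / (Km2 + pA)"),
        "prod": Reaction("prod", "ks_b + 0 * B", kind="mass-action"),
        "deg": Reaction("deg", "k3 * pA * B", kind="mass-action"),
    }
    stoich = {"act": {"A": -1, "pA": 1}, "deact": {"pA": -1, "A": 1},
              "prod": {"B": 1}, "deg": {"B": -1}}
    return ModelDefinition(species=["A", "pA", "B"], reactions=rxns,
                           stoichiometry=stoich, inputs=["u"],
                           conserved={"A_total": {"A": 1, "pA": 1}})


def main(seed: int) -> None:
    model = reference_model()
    dataset = synth.synth_timecourses(
        model, config=synth.TimecourseConfig(seed=seed, sigma=0.15))
    dataset.to_csv(OUT / "training_data.csv")
    j = cal.cost_J(model, model.params, dataset)
    m = cal.objective_M(model, model.params, dataset, cal.default_constraints())
    n = len(dataset.records)
    print(f"synthetic training data: {n} records, sigma = 0.15")
    print(f"J(truth) = {j:.1f} (~{j / n:.2f} per point); M(truth) = {m:.1f} "
          "(constraint penalties are zero at the truth)")

    # GA recovery on the reduced 4-parameter toy problem (two input levels
    # break the activation/deactivation compensation ridge)
    truth = ParameterSet(TOY_TRUTH)
    times = np.array([0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0])
    data = {}
    for u in (1.0, 0.15):
        toy = build_model(toy_definition(), truth).with_inputs(u=u)
        data[u] = simulate(toy, np.array([1.0, 0.0, 0.5]), t_grid=times).states

    def objective(params):
        total = 0.0
        for u, obs in data.items():
            system = build_model(toy_definition(), params).with_inputs(u=u)
            tc = simulate(system, np.array([1.0, 0.0, 0.5]), t_grid=times,
                          rtol=1e-7, atol=1e-9)
            total += float(np.sum((tc.states - obs) ** 2))
        return total

    free = ("k1", "Km2", "k3", "ks_b")
    bounds = {k: (TOY_TRUTH[k] / 100, TOY_TRUTH[k] * 100) for k in free}
    fit = ga_fit(objective, truth, bounds,
                 GAConfig(population=60, generations=60, seed=seed))
    errors = {k: fit.best_params[k] / TOY_TRUTH[k] for k in free}
    print("GA recovery (truth-normalised):",
          {k: round(v, 3) for k, v in errors.items()})

    # randomised neighbourhood of the reference parameters
    small = synth.synth_timecourses(
        model, config=synth.TimecourseConfig(
            seed=seed, sigma=0.0,
            conditions={"EGF_timecourse":
                        synth.default_conditions()["EGF_timecourse"]}))
    table = random_neighborhood_assessment(
        lambda p: cal.cost_J(model, p, small), model.params,
        fold_ranges=(2.0, 5.0), n=200, seed=seed)
    frac = table.groupby("fold_range")["exceeds_best"].mean()
    table.to_csv(OUT / "neighborhood.csv", index=False)
    print("fraction of random neighbours worse than the fit:",
          {f: round(v, 3) for f, v in frac.items()})
    (OUT / "summary.json").write_text(json.dumps({
        "J_truth": j, "M_truth": m,
        "ga_recovery_ratio": errors,
        "neighborhood_fraction_worse": frac.to_dict(),
    }, indent=2))


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
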