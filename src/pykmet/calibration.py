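"""Model calibration: weighted least-squares objective with qualitative
constraint penalties, genetic-algorithm fitting, and the randomised
neighbourhood fit-quality assessment.

The data model mirrors quantified immunoblot/qPCR time courses: each record
is (readout, time, condition, observed mean, observed SD), with both the
observation and the simulation expressed as fold change over the
condition's t = 0 value.  The cost is the standard chi-square

    J(p) = sum_j sum_i ((y_obs[j,i] - y_model[j,i](p)) / sd[j,i])^2

and the full objective adds three qualitative constraint penalties
(quadratic in the violation margin) encoding trained behaviours that the
quantitative data alone under-determine: the biphasic total-c-Met response
to EGF, sustained late ERK activation, and reduced STAT3/ERK activation
after PYK2 knockdown.

The genetic algorithm searches log10 parameter space with tournament
selection, blend crossover, Gaussian mutation and elitism, and is
deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ODESystem, ParameterSet
from .reference import readout_value
from .simulate import (
    DrugTreatment,
    NodePerturbation,
    SimulationError,
    Stimulus,
    SteadyStateError,
    simulate,
    steady_state,
)

__all__ = [
    "Condition",
    "ExperimentalDataset",
    "ConstraintPenalty",
    "FitResult",
    "GAConfig",
    "simulate_condition",
    "cost_J",
    "objective_M",
    "default_constraints",
    "ga_fit",
    "random_neighborhood_assessment",
    "FAILURE_SENTINEL",
]

log = logging.getLogger(__name__)

#: objective value assigned when a parameter set cannot be simulated
FAILURE_SENTINEL = 1e12


@dataclass(frozen=True)
class Condition:
    """Experimental condition: stimulus, drugs and genetic perturbations."""

    name: str
    stimulus: Stimulus = field(default_factory=lambda: Stimulus(egf=100.0))
    treatment: DrugTreatment | None = None
    perturbations: tuple[NodePerturbation, ...] = ()


@dataclass
class ExperimentalDataset:
    """Tidy observation table for calibration.

    ``records`` columns: readout, time_h, condition, mean, sd.  All SDs must
    be positive; readout names must be model readouts; normalisation is
    fold change over each (readout, condition)'s earliest time point.
    """

    records: pd.DataFrame
    conditions: dict[str, Condition]

    def __post_init__(self):
        required = {"readout", "time_h", "condition", "mean", "sd"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        if (self.records["sd"] <= 0).any():
            raise ValueError("all observation SDs must be > 0")
        unknown = set(self.records["condition"]) - set(self.conditions)
        if unknown:
            raise ValueError(f"records reference unknown conditions: {sorted(unknown)}")

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def simulate_condition(
    system: ODESystem,
    condition: Condition,
    readouts: Sequence[str],
    times: np.ndarray,
) -> dict[str, np.ndarray]:
    """Fold-change trajectories of ``readouts`` under one condition.

    The perturbed system is first relaxed to its own unstimulated steady
    state; the stimulus/treatment is then applied at t = 0 and each readout
    reported as fold change over its pre-stimulus value.
    """
    base = system
    for p in condition.perturbations:
        from .simulate import apply_node_perturbation

        base = apply_node_perturbation(base, p)
    y0 = steady_state(base)
    grid = np.unique(np.concatenate([[0.0], np.asarray(times, float)]))
    tc = simulate(
        base, y0, stimulus=condition.stimulus, treatment=condition.treatment,
        t_grid=grid if grid[0] < grid[-1] else np.array([0.0, 1e-6]),
    )
    out = {}
    for ro in readouts:
        series = tc.readout(ro)
        ref = series[0] if series[0] > 0 else 1.0
        out[ro] = np.interp(np.asarray(times, float), tc.times, series / ref)
    return out


class _SimCache:
    """Per-parameter-vector cache of condition simulations."""

    def __init__(self, system: ODESystem, dataset: ExperimentalDataset):
        self.system = system
        self.dataset = dataset
        self._cache: dict = {}

    def fold_changes(self, params: ParameterSet, cond_name: str) -> pd.DataFrame:
        key = (tuple(sorted(params.items())), cond_name)
        if key not in self._cache:
            sub = self.dataset.records[self.dataset.records["condition"] == cond_name]
            times = np.sort(sub["time_h"].unique())
            readouts = sorted(sub["readout"].unique())
            sys_p = self.system.with_params(params)
            sims = simulate_condition(
                sys_p, self.dataset.conditions[cond_name], readouts, times
            )
            frames = []
            for ro in readouts:
                frames.append(
                    pd.DataFrame(
                        {"readout": ro, "time_h": times, "sim": sims[ro]}
                    )
                )
            self._cache[key] = pd.concat(frames, ignore_index=True)
        return self._cache[key]


def cost_J(
    system: ODESystem,
    params: ParameterSet | Mapping[str, float],
    dataset: ExperimentalDataset,
    _cache: _SimCache | None = None,
) -> float:
    """Chi-square discrepancy between model and observations.

    Simulation failures yield the large finite sentinel (with a warning)
    rather than an exception, so optimisers can continue.
    """
    if not isinstance(params, ParameterSet):
        params = ParameterSet(params)
    cache = _cache or _SimCache(system, dataset)
    total = 0.0
    try:
        for cond in dataset.records["condition"].unique():
            sims = cache.fold_changes(params, cond)
            sub = dataset.records[dataset.records["condition"] == cond]
            merged = sub.merge(sims, on=["readout", "time_h"], how="left")
            if merged["sim"].isna().any():
                raise SimulationError("simulation missing requested time points")
            total += float(
                (((merged["mean"] - merged["sim"]) / merged["sd"]) ** 2).sum()
            )
    except (SimulationError, SteadyStateError) as exc:
        log.warning("simulation failure during cost evaluation: %s", exc)
        return FAILURE_SENTINEL
    return total


@dataclass(frozen=True)
class ConstraintPenalty:
    """Qualitative constraint entering the objective as weight * margin^2.

    ``evaluate`` returns the violation margin (0 when satisfied) from a
    dict of trajectory features; ``features`` names what it reads.
    """

    id: str
    description: str
    evaluate: Callable[[dict[str, float]], float]
    weight: float = 1e3

    def penalty(self, features: dict[str, float]) -> float:
        m = max(0.0, float(self.evaluate(features)))
        return self.weight * m * m


def _trajectory_features(system: ODESystem, params: ParameterSet) -> dict[str, float]:
    """Features read by the qualitative constraints (EGF and knockdown runs)."""
    sys_p = system.with_params(params)
    y0 = steady_state(sys_p)
    grid = np.linspace(0.0, 24.0, 49)
    egf = Stimulus(egf=100.0)
    tc = simulate(sys_p, y0, stimulus=egf, t_grid=grid)
    cmet = tc.readout("total_cMet")
    perk = tc.readout("pERK")
    kd = NodePerturbation("knockdown", "PYK2", 0.9)
    from .simulate import apply_node_perturbation

    sys_kd = apply_node_perturbation(sys_p, kd)
    tc_kd = simulate(sys_kd, steady_state(sys_kd), stimulus=egf, t_grid=grid)
    return {
        "cmet_basal": float(cmet[0]),
        "cmet_min": float(cmet.min()),
        "cmet_final": float(cmet[-1]),
        "perk_basal": float(perk[0]),
        "perk_final": float(perk[-1]),
        "perk_kd_final": float(tc_kd.readout("pERK")[-1]),
        "pstat3_final": float(tc.readout("pSTAT3")[-1]),
        "pstat3_kd_final": float(tc_kd.readout("pSTAT3")[-1]),
    }


def default_constraints(weight: float = 1e3) -> list[ConstraintPenalty]:
    """The three qualitative constraints used alongside the chi-square cost.

    1. total c-Met under EGF is biphasic: dips below 90% of basal and ends
       above 110% of basal by 24 h;
    2. EGF-induced ERK activation is sustained: pERK at 24 h at least
       5-fold over basal;
    3. PYK2 knockdown suppresses late pSTAT3 and pERK to below half of the
       unperturbed levels.
    """
    return [
        ConstraintPenalty(
            "R1",
            "biphasic total c-Met under EGF",
            lambda f: max(f["cmet_min"] / f["cmet_basal"] - 0.9, 0.0)
            + max(1.1 - f["cmet_final"] / f["cmet_basal"], 0.0),
            weight,
        ),
        ConstraintPenalty(
            "R2",
            "sustained EGF-induced ERK activation",
            lambda f: max(5.0 - f["perk_final"] / max(f["perk_basal"], 1e-12), 0.0)
            / 5.0,
            weight,
        ),
        ConstraintPenalty(
            "R3",
            "PYK2 knockdown lowers late pSTAT3 and pERK",
            lambda f: max(f["pstat3_kd_final"] / max(f["pstat3_final"], 1e-12) - 0.5, 0.0)
            + max(f["perk_kd_final"] / max(f["perk_final"], 1e-12) - 0.5, 0.0),
            weight,
        ),
    ]


def objective_M(
    system: ODESystem,
    params: ParameterSet | Mapping[str, float],
    dataset: ExperimentalDataset,
    constraints: Sequence[ConstraintPenalty] = (),
    _cache: _SimCache | None = None,
) -> float:
    """Aggregated objective: chi-square cost plus constraint penalties."""
    if not isinstance(params, ParameterSet):
        params = ParameterSet(params)
    j = cost_J(system, params, dataset, _cache)
    if j >= FAILURE_SENTINEL:
        return j
    if not constraints:
        return j
    try:
        feats = _trajectory_features(system, params)
    except (SimulationError, SteadyStateError) as exc:
        log.warning("simulation failure during constraint evaluation: %s", exc)
        return FAILURE_SENTINEL
    return j + sum(c.penalty(feats) for c in constraints)


# ---------------------------------------------------------------------------
# genetic algorithm


@dataclass
class GAConfig:
    population: int = 200
    generations: int = 300
    tournament: int = 3
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # default 1/n_genes
    mutation_sigma: float = 0.25  # in log10 units, annealed over generations
    mutation_sigma_final: float = 0.05
    elitism: int = 2
    seed: int = 0


@dataclass
class FitResult:
    best_params: ParameterSet
    objective: float
    trace: list[float]
    config: GAConfig
    free_names: list[str]
    residual_J: float | None = None

    def summary(self) -> dict:
        return {
            "objective": self.objective,
            "free_parameters": {n: self.best_params[n] for n in self.free_names},
            "generations": len(self.trace),
        }


def ga_fit(
    objective: Callable[[ParameterSet], float],
    base_params: ParameterSet,
    bounds: Mapping[str, tuple[float, float]],
    config: GAConfig | None = None,
    initial_guesses: Sequence[Mapping[str, float]] = (),
) -> FitResult:
    """Minimise ``objective`` over the parameters named in ``bounds``.

    Only the named parameters are searched (in log10 space); all others are
    held at ``base_params``.  Individuals seeded via ``initial_guesses``
    join the initial population.  Deterministic under ``config.seed``; the
    best individual ever seen is returned (elitism guarantees monotone
    best-so-far).
    """
    config = config or GAConfig()
    if config.population < 10:
        raise ValueError("population must be >= 10")
    rng = np.random.default_rng(config.seed)
    names = sorted(bounds)
    lo = np.log10([bounds[n][0] for n in names])
    hi = np.log10([bounds[n][1] for n in names])
    if np.any(lo >= hi):
        raise ValueError("each bound must satisfy low < high")
    n_genes = len(names)
    p_mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / max(
        n_genes, 1
    )

    def decode(x: np.ndarray) -> ParameterSet:
        return base_params.updated(**{n: 10.0 ** v for n, v in zip(names, x)})

    def evaluate(x: np.ndarray) -> float:
        try:
            return float(objective(decode(x)))
        except Exception as exc:  # noqa: BLE001 - optimiser must survive
            log.warning("objective failure treated as sentinel: %s", exc)
            return FAILURE_SENTINEL

    pop = rng.uniform(lo, hi, size=(config.population, n_genes))
    for i, guess in enumerate(initial_guesses[: config.population]):
        pop[i] = np.clip(np.log10([guess[n] for n in names]), lo, hi)
    fitness = np.array([evaluate(x) for x in pop])
    if np.all(fitness >= FAILURE_SENTINEL):
        raise RuntimeError(
            "entire initial population infeasible; widen the parameter bounds"
        )

    best_x = pop[np.argmin(fitness)].copy()
    best_f = float(fitness.min())
    trace = [best_f]

    for gen in range(config.generations):
        # geometric annealing of the mutation width sharpens late search
        frac = gen / max(config.generations - 1, 1)
        sigma = config.mutation_sigma * (
            (config.mutation_sigma_final / config.mutation_sigma) ** frac
        )
        order = np.argsort(fitness)
        elites = pop[order[: config.elitism]].copy()
        children = []
        while len(children) < config.population - config.elitism:
            idx = rng.integers(0, config.population, size=(2, config.tournament))
            pa = pop[idx[0][np.argmin(fitness[idx[0]])]]
            pb = pop[idx[1][np.argmin(fitness[idx[1]])]]
            if rng.random() < config.crossover_rate:
                # blend (BLX-alpha style) crossover in log space
                alpha = rng.uniform(-0.25, 1.25, size=n_genes)
                child = pa + alpha * (pb - pa)
            else:
                child = pa.copy()
            mask = rng.random(n_genes) < p_mut
            child = child + mask * rng.normal(0.0, sigma, n_genes)
            children.append(np.clip(child, lo, hi))
        pop = np.vstack([elites, np.array(children)])
        fitness = np.array([evaluate(x) for x in pop])
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_f:
            best_f = float(fitness[gen_best])
            best_x = pop[gen_best].copy()
        trace.append(best_f)

    return FitResult(decode(best_x), best_f, trace, config, names)


def random_neighborhood_assessment(
    objective: Callable[[ParameterSet], float],
    best_params: ParameterSet,
    free_names: Sequence[str] | None = None,
    fold_ranges: Sequence[float] = (2.0, 5.0, 10.0),
    n: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Objective values of random parameter sets around the fitted optimum.

    For each fold range f, ``n`` parameter sets are drawn log-uniformly in
    ``[p/f, p*f]`` per coordinate (over ``free_names``, default: all) and
    the objective evaluated; simulation failures count as exceeding the
    best value.  Returns a tidy table (fold_range, draw, M) plus the
    fraction exceeding M(best) accessible via groupby.
    """
    rng = np.random.default_rng(seed)
    names = list(free_names) if free_names is not None else sorted(best_params)
    base = np.log10([best_params[nm] for nm in names])
    m_best = float(objective(best_params))
    rows = []
    for f in fold_ranges:
        if f < 1.0:
            raise ValueError("fold range must be >= 1")
        span = math.log10(f)
        for k in range(n):
            x = base + rng.uniform(-span, span, size=len(names))
            params = best_params.updated(**{nm: 10.0 ** v for nm, v in zip(names, x)})
            try:
                m = float(objective(params))
            except Exception:  # noqa: BLE001
                m = FAILURE_SENTINEL
            rows.append({"fold_range": f, "draw": k, "M": m, "exceeds_best": m > m_best})
    out = pd.DataFrame(rows)
    out.attrs["M_best"] = m_best
    return out
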