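"""Time-course and steady-state simulation of the compiled network.

Protocols are described by three small value objects:

* :class:`Stimulus` — EGF/HGF ligand concentrations with an onset time;
* :class:`DrugTreatment` — doses of the four inhibitors with an application
  time (each dose multiplies its target rate law by ``1/(1 + dose/Ki)``);
* :class:`NodePerturbation` — genetic/chemical node manipulations
  (knockdown, constitutive activation, direct catalytic inhibition,
  feedback-weight scaling), applied from the start of a simulation.

Discontinuous protocols are integrated segment-by-segment with the stiff
LSODA solver, restarting exactly at each onset/application time, so event
handling is equivalent to building the treated system and integrating from
the event time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import ModelDefinition, ODESystem, ParameterSet, Reaction
from .reference import DRUG_TARGETS, FEEDBACK_LOOPS, READOUTS, readout_value

__all__ = [
    "Stimulus",
    "DrugTreatment",
    "NodePerturbation",
    "TimeCourse",
    "SteadyStateError",
    "SimulationError",
    "apply_treatment",
    "apply_node_perturbation",
    "apply_stimulus",
    "simulate",
    "steady_state",
    "default_initial_state",
]

RTOL = 1e-8
ATOL = 1e-10


class SimulationError(RuntimeError):
    """Integration failed (carries the failing time point)."""


class SteadyStateError(RuntimeError):
    """No steady state within the horizon, or sustained oscillation."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class Stimulus:
    """Growth-factor stimulus (ng/ml); zero means absent."""

    egf: float = 0.0
    hgf: float = 0.0
    onset_time: float = 0.0

    def __post_init__(self):
        if self.egf < 0 or self.hgf < 0:
            raise ValueError("ligand concentrations must be >= 0")


@dataclass(frozen=True)
class DrugTreatment:
    """Inhibitor doses in uM, applied at ``application_time`` (hours)."""

    doses: tuple[tuple[str, float], ...] = ()
    application_time: float = 0.0

    def __post_init__(self):
        for drug, dose in self.doses:
            if drug not in DRUG_TARGETS:
                raise KeyError(f"unknown drug {drug!r}")
            if dose < 0:
                raise ValueError(f"negative dose for {drug}")

    @classmethod
    def of(cls, application_time: float = 0.0, **doses: float) -> "DrugTreatment":
        return cls(tuple(doses.items()), application_time)

    def dose_map(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for drug, dose in self.doses:
            out[drug] = out.get(drug, 0.0) + dose
        return out


#: species whose abundance can be knocked down / directly inhibited and the
#: parameters realising it: (synthesis-rate params, activating catalytic params)
_KD_SYNTHESIS = {
    "PYK2": ["ktl7"],
    "cMet": ["ktl15"],
}
_KD_TOTALS = {
    "EGFR": "EGFR_tot",
    "STAT3": "STAT3_tot",
    "ERK": "ERK_tot",
    "Cbl": "Cbl_tot",
    "PTP": "PTP_tot",
}
_ACTIVATION_PARAMS = {
    "cMet": ["kb17", "kc17", "kx17"],
    "EGFR": ["kb1", "kc1", "kx1"],
    "PYK2": ["kb9", "kc9a", "kc9b"],
    "STAT3": ["kb11", "kc11"],
}


@dataclass(frozen=True)
class NodePerturbation:
    """A node-level manipulation applied for the whole simulation.

    kinds
    -----
    ``knockdown``
        fraction in [0,1]; scales synthesis (mRNA-bearing species) or the
        conserved-pool total by ``1 - magnitude``.
    ``constitutive_activation``
        replaces the target's activating rate law by a large constant-rate
        law independent of upstream kinases (only STAT3 supported).
    ``direct_inhibition``
        fraction in [0,1]; scales the target's activating catalytic rates by
        ``1 - magnitude`` (e.g. the PHA c-Met-inhibition scenario).
    ``feedback_scaling``
        target is a loop id (F1..F4); the loop's coupling weight is scaled
        by ``1 - magnitude``.
    """

    kind: str
    target: str
    magnitude: float = 0.0

    def __post_init__(self):
        if self.kind not in (
            "knockdown",
            "constitutive_activation",
            "direct_inhibition",
            "feedback_scaling",
        ):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind != "constitutive_activation" and not 0.0 <= self.magnitude <= 1.0:
            raise ValueError("magnitude must lie in [0, 1]")


def apply_stimulus(system: ODESystem, stimulus: Stimulus | None) -> ODESystem:
    if stimulus is None:
        return system
    return system.with_inputs(EGF=stimulus.egf, HGF=stimulus.hgf)


def apply_treatment(system: ODESystem, treatment: DrugTreatment | None) -> ODESystem:
    """Bind drug doses; zero dose is the identity transform."""
    if treatment is None:
        return system
    return system.with_inputs(**treatment.dose_map())


def apply_node_perturbation(system: ODESystem, p: NodePerturbation) -> ODESystem:
    if p.magnitude == 0.0 and p.kind != "constitutive_activation":
        return system
    keep = 1.0 - p.magnitude
    if p.kind == "knockdown":
        if p.target in _KD_SYNTHESIS:
            factors = {name: keep for name in _KD_SYNTHESIS[p.target]}
        elif p.target in _KD_TOTALS:
            factors = {_KD_TOTALS[p.target]: keep}
        else:
            raise KeyError(f"cannot knock down {p.target!r}")
        return system.with_params(system.params.scaled(factors))
    if p.kind == "direct_inhibition":
        names = _ACTIVATION_PARAMS.get(p.target)
        if names is None:
            raise KeyError(f"cannot directly inhibit {p.target!r}")
        return system.with_params(system.params.scaled({n: keep for n in names}))
    if p.kind == "feedback_scaling":
        names = FEEDBACK_LOOPS.get(p.target)
        if names is None:
            raise KeyError(f"unknown feedback loop {p.target!r}")
        return system.with_params(system.params.scaled({n: keep for n in names}))
    # constitutive activation: rewrite the activating rate law to a large
    # upstream-independent constant rate (100x the basal maximal rate)
    if p.target != "STAT3":
        raise KeyError("constitutive activation implemented for STAT3 only")
    defn = system.definition
    new_rxns = dict(defn.reactions)
    new_rxns["v11"] = Reaction(
        "v11",
        "(kb11 + 100.0 * kc11) * STAT3 / (Km11 + STAT3)"
        " / (1 + Stattic / KiStattic)",
        kind="michaelis-menten",
    )
    new_defn = replace(defn, reactions=new_rxns)
    from .model import build_model  # local import avoids cycle at module load

    sys2 = build_model(new_defn, system.params)
    return sys2.with_inputs(**system.input_values)


def apply_all(
    system: ODESystem,
    stimulus: Stimulus | None = None,
    treatment: DrugTreatment | None = None,
    perturbations: Sequence[NodePerturbation] = (),
) -> ODESystem:
    sys2 = system
    for p in perturbations:
        sys2 = apply_node_perturbation(sys2, p)
    sys2 = apply_stimulus(sys2, stimulus)
    sys2 = apply_treatment(sys2, treatment)
    return sys2


# ---------------------------------------------------------------------------
# time courses


@dataclass
class TimeCourse:
    """A trajectory on a time grid plus derived readouts."""

    times: np.ndarray
    states: np.ndarray  # time x species
    species: list[str]
    readouts: dict[str, np.ndarray]

    def state(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    def readout(self, name: str) -> np.ndarray:
        if name in self.readouts:
            return self.readouts[name]
        if name in self.species:
            return self.state(name)
        raise KeyError(f"unknown readout {name!r}")

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, variable, value) table with states and readouts."""
        rows = []
        for j, sp in enumerate(self.species):
            rows.append(
                pd.DataFrame(
                    {"time_h": self.times, "variable": sp, "value": self.states[:, j]}
                )
            )
        for name, series in self.readouts.items():
            rows.append(
                pd.DataFrame({"time_h": self.times, "variable": name, "value": series})
            )
        return pd.concat(rows, ignore_index=True)


def default_initial_state(system: ODESystem) -> np.ndarray:
    """Rough positive starting point used to locate the basal steady state.

    Conserved pools start unmodified at their total-abundance parameters;
    open pools (PYK2, c-Met, mRNAs) start at their leak-balance estimates.
    """
    p = system.params
    y = np.full(system.n_species, 1e-6)
    sp = system.definition.species
    idx = {s: i for i, s in enumerate(sp)}
    if "EGFR" in idx:
        y[idx["EGFR"]] = p["EGFR_tot"]
        y[idx["STAT3"]] = p["STAT3_tot"]
        y[idx["ERK"]] = p["ERK_tot"]
        m5 = p["Vs5"] * p["a5"] / p["kdeg6"]
        m13 = p["Vs13"] * p["a13"] / p["kdeg14"]
        y[idx["mRNA_PYK2"]] = m5
        y[idx["mRNA_cMet"]] = m13
        y[idx["PYK2"]] = p["ktl7"] * m5 / p["kdeg8"]
        y[idx["cMet"]] = p["ktl15"] * m13 / p["kdeg19"]
    else:  # generic fallback for toy models
        y[:] = 1.0
    return y


def _integrate(system, y0, t0, t1, t_eval, rtol, atol):
    sol = solve_ivp(
        system.rhs,
        (t0, t1),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"integration failed at t = {sol.t[-1] if len(sol.t) else t0:.4g} h: "
            f"{sol.message}"
        )
    return sol


def simulate(
    system: ODESystem,
    init: np.ndarray,
    stimulus: Stimulus | None = None,
    treatment: DrugTreatment | None = None,
    perturbations: Sequence[NodePerturbation] = (),
    t_grid: Sequence[float] | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> TimeCourse:
    """Integrate the protocol on ``t_grid`` (hours, monotone increasing).

    The stimulus switches on at its onset time and drugs at their
    application time; integration is restarted at each discontinuity.
    """
    t_grid = np.asarray(t_grid if t_grid is not None else np.linspace(0, 24, 97), float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    init = np.asarray(init, float)
    if np.any(init < 0):
        raise ValueError("initial state must be non-negative")

    base = system
    for p in perturbations:
        base = apply_node_perturbation(base, p)

    events = sorted(
        {
            t
            for t in (
                (stimulus.onset_time if stimulus else None),
                (treatment.application_time if treatment else None),
            )
            if t is not None and t_grid[0] < t < t_grid[-1]
        }
    )
    bounds = [t_grid[0], *events, t_grid[-1]]

    states = np.empty((len(t_grid), base.n_species))
    y = init.copy()
    filled = np.zeros(len(t_grid), bool)
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        seg = base
        if stimulus and t0 >= stimulus.onset_time:
            seg = apply_stimulus(seg, stimulus)
        if treatment and t0 >= treatment.application_time:
            seg = apply_treatment(seg, treatment)
        mask = (t_grid >= t0) & (t_grid <= t1) & ~filled
        t_eval = t_grid[mask]
        # always integrate to the segment end to hand off the state
        pts = np.unique(np.concatenate([t_eval, [t0, t1]]))
        sol = _integrate(seg, y, t0, t1, pts, rtol, atol)
        lookup = {t: sol.y[:, k] for k, t in enumerate(sol.t)}
        for i in np.where(mask)[0]:
            states[i] = lookup[t_grid[i]]
            filled[i] = True
        y = sol.y[:, -1]

    # numerical non-negativity: clip tiny negative excursions
    tiny = states < 0
    if np.any(states < -1e3 * atol):
        raise SimulationError("trajectory left the non-negative orthant")
    states[tiny] = 0.0

    readouts = {}
    if "pERK" in base.definition.species:
        for name in READOUTS:
            readouts[name] = np.array(
                [readout_value(base, states[i], name) for i in range(len(t_grid))]
            )
    return TimeCourse(t_grid, states, list(base.definition.species), readouts)


# ---------------------------------------------------------------------------
# steady states


def _is_stable(system: ODESystem, y: np.ndarray, eps: float = 1e-7) -> bool:
    """Linear stability via a finite-difference Jacobian at ``y``."""
    n = len(y)
    f0 = system.rhs(0.0, y)
    J = np.empty((n, n))
    for j in range(n):
        step = eps * (1.0 + abs(y[j]))
        yp = y.copy()
        yp[j] += step
        J[:, j] = (system.rhs(0.0, yp) - f0) / step
    return bool(np.max(np.linalg.eigvals(J).real) < 1e-6)


def steady_state(
    system: ODESystem,
    stimulus: Stimulus | None = None,
    treatment: DrugTreatment | None = None,
    perturbations: Sequence[NodePerturbation] = (),
    init: np.ndarray | None = None,
    tol_ss: float = 1e-8,
    max_horizon: float = 500.0,
    rtol: float = RTOL,
    atol: float = ATOL,
    continuation: bool = False,
) -> np.ndarray:
    """Equilibrium of the (constant-input) system.

    Long-horizon integration in 50 h chunks followed by a Newton polish;
    accepted only when the sup-norm of the right-hand side drops below
    ``tol_ss``.  A trajectory still moving at the horizon with an oscillation
    amplitude above 1e-6 raises :class:`SteadyStateError` rather than being
    averaged away.
    """
    sys2 = apply_all(system, stimulus, treatment, perturbations)
    y = np.asarray(init, float) if init is not None else default_initial_state(sys2)

    def residual(state):
        return float(np.max(np.abs(sys2.rhs(0.0, state))))

    def polish(state):
        sol = root(lambda s: sys2.rhs(0.0, s), state, method="hybr")
        cand = sol.x
        if np.all(cand >= -1e3 * atol) and residual(cand) < tol_ss:
            return np.clip(cand, 0.0, None)
        return None

    # In continuation mode (warm start expected to lie in the same basin),
    # try the Newton polish first and accept the root only if it is linearly
    # stable and close to the warm start; a fold/jump makes the root move far
    # away or vanish, which falls through to plain integration.  The default
    # always approaches the steady state dynamically: polishing a warm start
    # directly may otherwise converge onto an unstable or dynamically
    # unreachable fixed point of a bistable system.
    if continuation and init is not None:
        cand = polish(y)
        if cand is not None:
            close = np.max(np.abs(cand - y) / (1.0 + np.abs(y))) < 0.35
            if close and _is_stable(sys2, cand):
                return cand

    t, chunk = 0.0, 50.0
    last = None
    while t < max_horizon:
        sol = _integrate(sys2, y, t, t + chunk, np.array([t, t + chunk]), rtol, atol)
        y = np.clip(sol.y[:, -1], 0.0, None)
        t += chunk
        last = sol
        if residual(y) < 1e3 * tol_ss:
            cand = polish(y)
            if cand is not None:
                return cand
    cand = polish(y)
    if cand is not None:
        return cand
    # oscillation diagnosis over the last 10% of the horizon
    probe = _integrate(
        sys2, y, 0.0, 0.1 * max_horizon,
        np.linspace(0, 0.1 * max_horizon, 51), rtol, atol,
    )
    amp = float(np.max(probe.y.max(axis=1) - probe.y.min(axis=1)))
    r = residual(np.clip(probe.y[:, -1], 0.0, None))
    if amp > 1e-6:
        raise SteadyStateError(
            f"sustained oscillation (amplitude {amp:.3g}) — no steady state", r
        )
    raise SteadyStateError(
        f"no steady state within {max_horizon} h (residual {r:.3g})", r
    )
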