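"""Reaction-network model container and ODE right-hand-side assembly.

A :class:`ModelDefinition` is a declarative description of a biochemical
reaction network: named state variables (species), rate laws written as plain
infix expressions over species, kinetic parameters and external inputs
(ligands and drug doses), a stoichiometry map, and named conserved totals.
:func:`build_model` validates the definition against a :class:`ParameterSet`
and compiles the network into an :class:`ODESystem` whose right-hand side is
``stoichiometry x rate vector``, generated once as a single Python function
for speed.

Rate-law expressions use Python syntax (``**`` for powers) and may reference
any declared species, parameter or input name.  Inputs are held constant
during a single integration segment; time-dependent protocols (ligand onset,
drug application) are realised by segmented integration in
:mod:`pykmet.simulate`.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Reaction",
    "ModelDefinition",
    "ParameterSet",
    "ODESystem",
    "ModelValidationError",
    "build_model",
]

KINETIC_FORMS = ("michaelis-menten", "hill", "mass-action")


class ModelValidationError(ValueError):
    """Raised when a model definition and parameter set are inconsistent."""


def _names_in(expr: str) -> set[str]:
    """All identifiers appearing in an infix expression."""
    tree = ast.parse(expr, mode="eval")
    return {n.id for n in ast.walk(tree) if isinstance(n, ast.Name)}


@dataclass(frozen=True)
class Reaction:
    """A single reaction: an id, a rate-law expression and its kinetic class."""

    id: str
    expr: str
    kind: str = "michaelis-menten"

    def __post_init__(self) -> None:
        if self.kind not in KINETIC_FORMS:
            raise ModelValidationError(
                f"reaction {self.id!r}: unknown kinetic form {self.kind!r}"
            )
        # fail early on syntax errors
        ast.parse(self.expr, mode="eval")

    @property
    def names(self) -> set[str]:
        return _names_in(self.expr)


@dataclass
class ModelDefinition:
    """Declarative network description.

    Parameters
    ----------
    species:
        Ordered state-variable names.
    reactions:
        Rate laws keyed by reaction id.
    stoichiometry:
        ``reaction id -> {species: net coefficient}``.
    inputs:
        External input names (ligand concentrations, drug doses) that rate
        laws may reference; all default to 0.
    conserved:
        Named linear combinations of species that the stoichiometry must
        annihilate, e.g. ``{"EGFR_total": {"EGFR": 1, "pEGFR": 1, ...}}``.
    total_params:
        Optional map conserved-total name -> parameter carrying its value
        (used to build default initial conditions and for abundance scaling).
    algebraic:
        Quasi-steady-state helper quantities, evaluated before the rate laws
        each step (name -> expression over species/parameters/inputs).
    hill_exponents:
        Parameter names acting as Hill exponents (validated to be >= 1).
    """

    species: list[str]
    reactions: dict[str, Reaction]
    stoichiometry: dict[str, dict[str, float]]
    inputs: list[str] = field(default_factory=list)
    conserved: dict[str, dict[str, float]] = field(default_factory=dict)
    total_params: dict[str, str] = field(default_factory=dict)
    algebraic: dict[str, str] = field(default_factory=dict)
    hill_exponents: list[str] = field(default_factory=list)

    # -- introspection -------------------------------------------------
    def parameter_names(self) -> set[str]:
        """Every non-species, non-input identifier referenced by the model."""
        referenced: set[str] = set()
        for rxn in self.reactions.values():
            referenced |= rxn.names
        for expr in self.algebraic.values():
            referenced |= _names_in(expr)
        referenced |= set(self.total_params.values())
        known = set(self.species) | set(self.inputs) | set(self.algebraic)
        return referenced - known

    def validate(self, params: "ParameterSet") -> None:
        if len(set(self.species)) != len(self.species):
            raise ModelValidationError("duplicate species names")
        for rid in self.reactions:
            if rid not in self.stoichiometry:
                raise ModelValidationError(f"reaction {rid!r} missing stoichiometry")
        for rid, coeffs in self.stoichiometry.items():
            if rid not in self.reactions:
                raise ModelValidationError(f"stoichiometry for unknown reaction {rid!r}")
            for sp in coeffs:
                if sp not in self.species:
                    raise ModelValidationError(
                        f"stoichiometry of {rid!r} references unknown species {sp!r}"
                    )
        needed = self.parameter_names()
        missing = needed - set(params)
        if missing:
            raise ModelValidationError(f"unknown parameter name(s): {sorted(missing)}")
        orphans = set(params) - needed
        if orphans:
            raise ModelValidationError(
                f"orphan parameter(s) never referenced: {sorted(orphans)}"
            )
        for h in self.hill_exponents:
            if params[h] < 1.0:
                raise ModelValidationError(f"Hill exponent {h} = {params[h]} < 1")
        # conserved totals must be annihilated by the stoichiometry
        for name, combo in self.conserved.items():
            for rid, coeffs in self.stoichiometry.items():
                s = sum(combo.get(sp, 0.0) * c for sp, c in coeffs.items())
                if abs(s) > 1e-12:
                    raise ModelValidationError(
                        f"conserved total {name!r} not annihilated by reaction {rid!r}"
                    )


class ParameterSet(dict):
    """Named positive kinetic parameters (``name -> value``).

    Rate and binding constants must be strictly positive; dimensionless
    feedback coupling weights (``w_f*``) may reach zero, representing a
    fully ablated loop.
    """

    def __init__(self, values: Mapping[str, float]):
        super().__init__()
        for k, v in values.items():
            v = float(v)
            if not math.isfinite(v) or v < 0.0 or (v == 0.0 and not k.startswith("w_f")):
                raise ModelValidationError(f"parameter {k} must be strictly positive")
            self[k] = v

    def updated(self, **changes: float) -> "ParameterSet":
        new = dict(self)
        new.update(changes)
        return ParameterSet(new)

    def scaled(self, factors: Mapping[str, float]) -> "ParameterSet":
        new = dict(self)
        for k, f in factors.items():
            new[k] = new[k] * f
        return ParameterSet(new)


def _compile_rhs(defn: ModelDefinition) -> tuple[Callable, Callable]:
    """Generate `(rhs, rates)` functions from the definition.

    ``rhs(t, y, p, u)`` returns the derivative vector; ``rates(t, y, p, u)``
    returns the reaction-rate vector in the definition's reaction order.
    Both take the parameter vector ``p`` (ordered by sorted name) and input
    vector ``u`` (ordered by ``defn.inputs``).
    """
    pnames = sorted(defn.parameter_names())
    lines = ["def _rhs(t, y, p, u):"]
    for i, sp in enumerate(defn.species):
        lines.append(f"    {sp} = y[{i}]")
    for i, pn in enumerate(pnames):
        lines.append(f"    {pn} = p[{i}]")
    for i, un in enumerate(defn.inputs):
        lines.append(f"    {un} = u[{i}]")
    for name, expr in defn.algebraic.items():
        lines.append(f"    {name} = {expr}")
    rate_syms = []
    for rid, rxn in defn.reactions.items():
        sym = f"_v_{rid}"
        rate_syms.append(sym)
        lines.append(f"    {sym} = {rxn.expr}")
    derivs = []
    for sp in defn.species:
        terms = []
        for rid, coeffs in defn.stoichiometry.items():
            c = coeffs.get(sp, 0.0)
            if c == 0.0:
                continue
            if c == 1.0:
                terms.append(f"+ _v_{rid}")
            elif c == -1.0:
                terms.append(f"- _v_{rid}")
            else:
                terms.append(f"+ ({c!r}) * _v_{rid}")
        derivs.append(" ".join(terms) if terms else "0.0")
    body = ", ".join(derivs)
    lines.append(f"    return np.array(({body},))")
    rbody = ", ".join(rate_syms)
    rlines = [ln.replace("def _rhs", "def _rates") for ln in lines[:-1]]
    rlines.append(f"    return np.array(({rbody},))")
    ns: dict = {"np": np}
    exec("\n".join(lines), ns)
    exec("\n".join(rlines), ns)
    return ns["_rhs"], ns["_rates"]


class ODESystem:
    """A compiled reaction network with bound parameters and inputs.

    The right-hand side is ``stoichiometry x rate vector``.  Instances are
    cheap to re-bind (``with_params`` / ``with_inputs`` share the compiled
    code), so drug treatments and perturbations produce new systems without
    recompilation.
    """

    def __init__(
        self,
        definition: ModelDefinition,
        params: ParameterSet,
        inputs: Mapping[str, float] | None = None,
        _compiled: tuple[Callable, Callable] | None = None,
    ):
        definition.validate(params)
        self.definition = definition
        self.params = params
        self.param_names = sorted(definition.parameter_names())
        self._pvec = np.array([params[n] for n in self.param_names])
        self.input_values = {n: 0.0 for n in definition.inputs}
        if inputs:
            for k, v in inputs.items():
                if k not in self.input_values:
                    raise ModelValidationError(f"unknown input {k!r}")
                self.input_values[k] = float(v)
        self._uvec = np.array([self.input_values[n] for n in definition.inputs])
        if _compiled is None:
            _compiled = _compile_rhs(definition)
        self._compiled = _compiled
        self._rhs_fn, self._rates_fn = _compiled

    # -- derived views -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.definition.species)

    def index(self, species: str) -> int:
        return self.definition.species.index(species)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return self._rhs_fn(t, y, self._pvec, self._uvec)

    def rates(self, y: np.ndarray, t: float = 0.0) -> dict[str, float]:
        vals = self._rates_fn(t, y, self._pvec, self._uvec)
        return dict(zip(self.definition.reactions, vals))

    def with_params(self, params: ParameterSet) -> "ODESystem":
        return ODESystem(self.definition, params, self.input_values, self._compiled)

    def with_inputs(self, **inputs: float) -> "ODESystem":
        merged = dict(self.input_values)
        for k, v in inputs.items():
            if k not in merged:
                raise ModelValidationError(f"unknown input {k!r}")
            merged[k] = float(v)
        return ODESystem(self.definition, self.params, merged, self._compiled)

    def conserved_values(self, y: np.ndarray) -> dict[str, float]:
        out = {}
        for name, combo in self.definition.conserved.items():
            out[name] = float(
                sum(c * y[self.index(sp)] for sp, c in combo.items())
            )
        return out


def build_model(
    definition: ModelDefinition, params: ParameterSet | Mapping[str, float]
) -> ODESystem:
    """Validate a definition against a parameter set and compile it.

    Raises :class:`ModelValidationError` on unknown parameter names,
    stoichiometry/species mismatches, or conserved totals that the
    stoichiometry does not annihilate.
    """
    if not isinstance(params, ParameterSet):
        params = ParameterSet(params)
    return ODESystem(definition, params)
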