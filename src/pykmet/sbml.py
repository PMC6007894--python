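"""SBML Level 3 export/import of the network definition and parameters.

Writes a self-contained SBML L3V2 document: species, parameters,
reactions with content-MathML kinetic laws, assignment rules for the
quasi-steady-state enzyme activities, and external inputs as constant
parameters.  Structural metadata that SBML core does not represent
(kinetic-form tags, conserved-total definitions, input names, Hill
exponent list) travels in a JSON annotation so the round trip is exact.

Rate-law math is converted infix -> sympy -> content MathML on export and
parsed back on import; round-tripped expressions are symbolically
identical to the originals.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from typing import Mapping

import sympy

from .model import ModelDefinition, ODESystem, ParameterSet, Reaction, build_model

__all__ = ["write_sbml", "read_sbml", "to_sbml_string", "from_sbml_string"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://pykmet.invalid/sbml-annotations"

_SYMPY_LOCALS_CACHE: dict = {}


def _to_sympy(expr: str, names) -> sympy.Expr:
    local = {n: sympy.Symbol(n) for n in names}
    return sympy.sympify(expr, locals=local, evaluate=False)


def _expr_names(defn: ModelDefinition):
    return (
        set(defn.species)
        | set(defn.inputs)
        | set(defn.algebraic)
        | defn.parameter_names()
    )


def _emit(expr: sympy.Expr, parent: ET.Element) -> None:
    """Minimal content-MathML printer (sympy's mangles subscripted names)."""
    M = f"{{{MATHML_NS}}}"
    if isinstance(expr, sympy.Symbol):
        ET.SubElement(parent, f"{M}ci").text = expr.name
        return
    if isinstance(expr, sympy.Integer):
        el = ET.SubElement(parent, f"{M}cn", {"type": "integer"})
        el.text = str(int(expr))
        return
    if isinstance(expr, sympy.Rational) and not isinstance(expr, sympy.Integer):
        el = ET.SubElement(parent, f"{M}cn", {"type": "rational"})
        el.text = str(expr.p)
        ET.SubElement(el, f"{M}sep").tail = str(expr.q)
        return
    if expr.is_Number:
        ET.SubElement(parent, f"{M}cn").text = repr(float(expr))
        return
    apply = ET.SubElement(parent, f"{M}apply")
    if isinstance(expr, sympy.Add):
        ET.SubElement(apply, f"{M}plus")
        for a in expr.args:
            _emit(a, apply)
    elif isinstance(expr, sympy.Mul):
        ET.SubElement(apply, f"{M}times")
        for a in expr.args:
            _emit(a, apply)
    elif isinstance(expr, sympy.Pow):
        ET.SubElement(apply, f"{M}power")
        _emit(expr.base, apply)
        _emit(expr.exp, apply)
    else:
        raise ValueError(f"cannot serialise expression node {type(expr).__name__}")


def _math_element(expr: str, names) -> ET.Element:
    s = _to_sympy(expr, names)
    math = ET.Element(f"{{{MATHML_NS}}}math")
    _emit(s, math)
    return math


# -- content MathML -> sympy -------------------------------------------------

def _parse_mathml(node: ET.Element) -> sympy.Expr:
    tag = node.tag.split("}")[-1]
    if tag == "math":
        children = list(node)
        if len(children) != 1:
            raise ValueError("math element must have exactly one child")
        return _parse_mathml(children[0])
    if tag == "ci":
        return sympy.Symbol(node.text.strip())
    if tag == "cn":
        t = node.get("type", "real")
        if t == "rational":
            num = node.text.strip()
            sep = node.find(f"{{{MATHML_NS}}}sep")
            den = sep.tail.strip()
            return sympy.Rational(int(num), int(den))
        if t == "integer":
            return sympy.Integer(int(node.text.strip()))
        return sympy.Float(node.text.strip())
    if tag == "apply":
        children = list(node)
        op = children[0].tag.split("}")[-1]
        args = [_parse_mathml(c) for c in children[1:]]
        if op == "plus":
            return sympy.Add(*args, evaluate=False) if len(args) > 1 else args[0]
        if op == "times":
            return sympy.Mul(*args, evaluate=False) if len(args) > 1 else args[0]
        if op == "minus":
            if len(args) == 1:
                return -args[0]
            return args[0] - args[1]
        if op == "divide":
            return args[0] / args[1]
        if op == "power":
            return sympy.Pow(args[0], args[1], evaluate=False)
        if op == "root":
            return sympy.sqrt(args[0])
        if op == "exp":
            return sympy.exp(args[0])
        if op == "ln":
            return sympy.log(args[0])
        raise ValueError(f"unsupported MathML operator {op!r}")
    raise ValueError(f"unsupported MathML element {tag!r}")


def _sympy_to_infix(expr: sympy.Expr) -> str:
    return sympy.sstr(expr)


# -- export ------------------------------------------------------------------

def to_sbml_string(system: ODESystem, model_id: str = "egfr_pyk2_cmet") -> str:
    """Serialise a compiled system (definition + parameters) to SBML."""
    defn = system.definition
    names = _expr_names(defn)
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)

    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {"id": model_id})

    annot = ET.SubElement(model, f"{{{SBML_NS}}}annotation")
    meta = ET.SubElement(annot, f"{{{ANNOT_NS}}}metadata")
    meta.text = json.dumps(
        {
            "inputs": defn.inputs,
            "conserved": defn.conserved,
            "total_params": defn.total_params,
            "hill_exponents": defn.hill_exponents,
            "kinds": {rid: r.kind for rid, r in defn.reactions.items()},
            "input_values": system.input_values,
        }
    )

    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(
        comps,
        f"{{{SBML_NS}}}compartment",
        {"id": "cell", "constant": "true", "size": "1", "spatialDimensions": "3"},
    )

    sp_list = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for sp in defn.species:
        ET.SubElement(
            sp_list,
            f"{{{SBML_NS}}}species",
            {
                "id": sp,
                "compartment": "cell",
                "hasOnlySubstanceUnits": "true",
                "boundaryCondition": "false",
                "constant": "false",
                "initialAmount": "0",
            },
        )

    par_list = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for name in sorted(system.params):
        ET.SubElement(
            par_list,
            f"{{{SBML_NS}}}parameter",
            {"id": name, "value": repr(system.params[name]), "constant": "true"},
        )
    for name in defn.inputs:
        ET.SubElement(
            par_list,
            f"{{{SBML_NS}}}parameter",
            {
                "id": name,
                "value": repr(system.input_values[name]),
                "constant": "true",
            },
        )
    for name in defn.algebraic:
        ET.SubElement(
            par_list,
            f"{{{SBML_NS}}}parameter",
            {"id": name, "value": "0", "constant": "false"},
        )

    if defn.algebraic:
        rules = ET.SubElement(model, f"{{{SBML_NS}}}listOfRules")
        for name, expr in defn.algebraic.items():
            rule = ET.SubElement(
                rules, f"{{{SBML_NS}}}assignmentRule", {"variable": name}
            )
            rule.append(_math_element(expr, names))

    rxn_list = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for rid, rxn in defn.reactions.items():
        coeffs = defn.stoichiometry[rid]
        r_el = ET.SubElement(
            rxn_list, f"{{{SBML_NS}}}reaction", {"id": rid, "reversible": "false"}
        )
        reactants = {sp: -c for sp, c in coeffs.items() if c < 0}
        products = {sp: c for sp, c in coeffs.items() if c > 0}
        if reactants:
            lo = ET.SubElement(r_el, f"{{{SBML_NS}}}listOfReactants")
            for sp, c in reactants.items():
                ET.SubElement(
                    lo,
                    f"{{{SBML_NS}}}speciesReference",
                    {"species": sp, "stoichiometry": repr(float(c)), "constant": "true"},
                )
        if products:
            lo = ET.SubElement(r_el, f"{{{SBML_NS}}}listOfProducts")
            for sp, c in products.items():
                ET.SubElement(
                    lo,
                    f"{{{SBML_NS}}}speciesReference",
                    {"species": sp, "stoichiometry": repr(float(c)), "constant": "true"},
                )
        kl = ET.SubElement(r_el, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_math_element(rxn.expr, names))

    ET.indent(sbml)
    return ET.tostring(sbml, encoding="unicode", xml_declaration=True)


def write_sbml(system: ODESystem, path, model_id: str = "egfr_pyk2_cmet") -> None:
    with open(path, "w") as fh:
        fh.write(to_sbml_string(system, model_id))


# -- import ------------------------------------------------------------------

def from_sbml_string(text: str) -> ODESystem:
    """Reconstruct the compiled system from an SBML document."""
    root = ET.fromstring(text)
    model = root.find(f"{{{SBML_NS}}}model")
    meta_el = model.find(f"{{{SBML_NS}}}annotation/{{{ANNOT_NS}}}metadata")
    if meta_el is None:
        raise ValueError("missing pykmet metadata annotation")
    meta = json.loads(meta_el.text)

    species = [
        el.get("id")
        for el in model.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species")
    ]
    raw_params: dict[str, float] = {}
    for el in model.findall(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter"):
        raw_params[el.get("id")] = float(el.get("value"))

    algebraic = {}
    for rule in model.findall(f"{{{SBML_NS}}}listOfRules/{{{SBML_NS}}}assignmentRule"):
        var = rule.get("variable")
        math_el = rule.find(f"{{{MATHML_NS}}}math")
        algebraic[var] = _sympy_to_infix(_parse_mathml(math_el))

    reactions: dict[str, Reaction] = {}
    stoich: dict[str, dict[str, float]] = {}
    kinds = meta["kinds"]
    for r_el in model.findall(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        rid = r_el.get("id")
        coeffs: dict[str, float] = {}
        for ref in r_el.findall(
            f"{{{SBML_NS}}}listOfReactants/{{{SBML_NS}}}speciesReference"
        ):
            coeffs[ref.get("species")] = coeffs.get(ref.get("species"), 0.0) - float(
                ref.get("stoichiometry")
            )
        for ref in r_el.findall(
            f"{{{SBML_NS}}}listOfProducts/{{{SBML_NS}}}speciesReference"
        ):
            coeffs[ref.get("species")] = coeffs.get(ref.get("species"), 0.0) + float(
                ref.get("stoichiometry")
            )
        math_el = r_el.find(f"{{{SBML_NS}}}kineticLaw/{{{MATHML_NS}}}math")
        expr = _sympy_to_infix(_parse_mathml(math_el))
        reactions[rid] = Reaction(rid, expr, kinds.get(rid, "michaelis-menten"))
        stoich[rid] = coeffs

    inputs = meta["inputs"]
    defn = ModelDefinition(
        species=species,
        reactions=reactions,
        stoichiometry=stoich,
        inputs=inputs,
        conserved=meta["conserved"],
        total_params=meta["total_params"],
        algebraic=algebraic,
        hill_exponents=meta["hill_exponents"],
    )
    kinetic = {
        k: v for k, v in raw_params.items() if k not in inputs and k not in algebraic
    }
    system = build_model(defn, ParameterSet(kinetic))
    return system.with_inputs(**meta["input_values"])


def read_sbml(path) -> ODESystem:
    with open(path) as fh:
        return from_sbml_string(fh.read())
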