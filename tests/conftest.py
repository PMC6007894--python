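"""Shared fixtures: the reference network, its stimulated context, and a
three-species toy phosphorylation model used as an independent oracle."""

import numpy as np
import pytest

from pykmet.model import ModelDefinition, ParameterSet, Reaction, build_model
from pykmet.reference import reference_model
from pykmet.simulate import Stimulus, steady_state
from pykmet.dose import Context


# ---------------------------------------------------------------------------
# reference model (session-wide, read-only)


@pytest.fixture(scope="session")
def ref_model():
    return reference_model()


@pytest.fixture(scope="session")
def basal_state(ref_model):
    return steady_state(ref_model)


@pytest.fixture(scope="session")
def egf():
    return Stimulus(egf=100.0)


@pytest.fixture(scope="session")
def egf_state(ref_model, basal_state, egf):
    """EGF-stimulated steady state (the 'on' operating point)."""
    return steady_state(ref_model, stimulus=egf, init=basal_state)


@pytest.fixture(scope="session")
def egf_ctx(ref_model, egf):
    """Shared dose-response context; caches steady states across tests."""
    return Context(ref_model, stimulus=egf)


@pytest.fixture(scope="session")
def reverse_tables(ref_model):
    """Implicit reverse-function tables for both mRNA species (built once)."""
    from pykmet.cohort import build_reverse_function

    return {
        "PYK2": build_reverse_function(ref_model, "PYK2"),
        "cMet": build_reverse_function(ref_model, "cMet", scale_range=(0.05, 20.0)),
    }


# ---------------------------------------------------------------------------
# toy 3-species model: A <-> pA (MM cycle driven by input u), pA makes B


def toy_definition() -> ModelDefinition:
    rxns = {
        "act": Reaction("act", "(k0 + k1 * u) * A / (Km1 + A)"),
        "deact": Reaction("deact", "k2 * pA / (Km2 + pA)"),
        "prod": Reaction("prod", "ks_b + 0 * B", kind="mass-action"),
        "deg": Reaction("deg", "k3 * pA * B", kind="mass-action"),
    }
    stoich = {
        "act": {"A": -1, "pA": 1},
        "deact": {"pA": -1, "A": 1},
        "prod": {"B": 1},
        "deg": {"B": -1},
    }
    return ModelDefinition(
        species=["A", "pA", "B"],
        reactions=rxns,
        stoichiometry=stoich,
        inputs=["u"],
        conserved={"A_total": {"A": 1, "pA": 1}},
    )


TOY_TRUTH = {
    "k0": 0.05,
    "k1": 2.0,
    "Km1": 0.5,
    "k2": 1.5,
    "Km2": 0.4,
    "k3": 0.8,
    "ks_b": 0.6,
}


@pytest.fixture(scope="session")
def toy_model():
    return build_model(toy_definition(), ParameterSet(TOY_TRUTH)).with_inputs(u=1.0)


def toy_rhs_by_hand(y, p, u):
    """Independent hand-expanded derivative of the toy network."""
    A, pA, B = y
    v_act = (p["k0"] + p["k1"] * u) * A / (p["Km1"] + A)
    v_deact = p["k2"] * pA / (p["Km2"] + pA)
    v_prod = p["ks_b"]
    v_deg = p["k3"] * pA * B
    return np.array([-v_act + v_deact, v_act - v_deact, v_prod - v_deg])
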