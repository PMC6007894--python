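"""Dose-response characterisation and drug-synergy scoring.

Steady-state readouts under graded drug doses are normalised to the
untreated (zero-dose) steady state in the same context (stimulus +
background treatment), giving response curves on [0, 1].  The module
provides:

* ``compute_ICx`` — the dose inhibiting a readout by x% of its untreated
  level, found by bisection on the steady-state response (monotonicity of
  the sampled response is verified first);
* ``dose_response`` / ``dose_matrix`` — 1D curves and 2D surfaces;
* ``fit_hill`` — least-squares fit of the four-parameter Hill equation
  ``Y = (ymax - ymin) / (1 + (I/IC50)^H) + ymin``; the Hill coefficient H
  measures how switch-like the response is;
* synergy indices: Bliss independence (BI), coefficient of drug
  interaction (CDI) and the Chou-Talalay combination index (CI) from
  median-effect fits.  For all three, values < 1 indicate synergy, 1
  additivity and > 1 antagonism;
* ``rank_combinations`` — the six-pair synergy table ordered by mean log2
  score across readouts.

Steady states are obtained by integrating from the untreated stimulated
steady state, i.e. drugs are applied to stimulated cells, matching the
experimental protocol.  Because the network's positive feedback makes some
treated conditions bistable, this dynamical convention (rather than blind
root-finding) selects the branch cells actually reach.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import ODESystem
from .reference import DRUGS, readout_value
from .simulate import DrugTreatment, Stimulus, SteadyStateError, steady_state

__all__ = [
    "Context",
    "DoseResponseCurve",
    "HillFit",
    "SynergyScores",
    "NotAchievable",
    "NoTransition",
    "steady_readout",
    "compute_ICx",
    "dose_response",
    "dose_matrix",
    "fit_hill",
    "bi_score",
    "cdi_score",
    "ci_score",
    "median_effect_fit",
    "combo_scores",
    "rank_combinations",
    "DEFAULT_PAIRS",
]

DEFAULT_PAIRS = (
    ("Gefitinib", "PF396"),
    ("Gefitinib", "EMD"),
    ("Gefitinib", "Stattic"),
    ("PF396", "EMD"),
    ("PF396", "Stattic"),
    ("EMD", "Stattic"),
)


class NotAchievable(RuntimeError):
    """The requested inhibition level is not reachable within the bracket."""


class NoTransition(RuntimeError):
    """Dose-response curve is flat; a Hill fit would be degenerate."""


@dataclass
class Context:
    """Shared experimental context for dose-response work.

    Holds the stimulated, untreated reference steady state and a cache of
    treated steady states so sweeps and bisections reuse work.  The
    background treatment (fixed co-drug) is part of the context for
    sensitisation analyses.
    """

    system: ODESystem
    stimulus: Stimulus = field(default_factory=lambda: Stimulus(egf=100.0))
    background: dict[str, float] = field(default_factory=dict)
    _cache: dict = field(default_factory=dict, repr=False)
    _ref_state: np.ndarray | None = field(default=None, repr=False)

    def reference_state(self) -> np.ndarray:
        if self._ref_state is None:
            base = steady_state(self.system, stimulus=self.stimulus)
            if self.background:
                base = steady_state(
                    self.system,
                    stimulus=self.stimulus,
                    treatment=DrugTreatment.of(**self.background),
                    init=base,
                )
            self._ref_state = base
        return self._ref_state

    def treated_state(self, doses: dict[str, float]) -> np.ndarray:
        merged = dict(self.background)
        for d, c in doses.items():
            merged[d] = merged.get(d, 0.0) + c
        key = tuple(sorted((d, round(c, 12)) for d, c in merged.items() if c > 0))
        if key not in self._cache:
            self._cache[key] = steady_state(
                self.system,
                stimulus=self.stimulus,
                treatment=DrugTreatment.of(**merged) if merged else None,
                init=self.reference_state(),
                continuation=True,
            )
        return self._cache[key]

    def response(self, doses: dict[str, float], readout: str) -> float:
        """Steady-state readout normalised to the untreated context (=1)."""
        ref = readout_value(self.system, self.reference_state(), readout)
        val = readout_value(self.system, self.treated_state(doses), readout)
        return val / ref if ref > 0 else 0.0


@dataclass
class DoseResponseCurve:
    drug: str
    readout: str
    doses: np.ndarray
    responses: np.ndarray
    background: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug": self.drug,
                "readout": self.readout,
                "dose_uM": self.doses,
                "response": self.responses,
            }
        )


@dataclass
class HillFit:
    y_max: float
    y_min: float
    ic50: float
    hill: float
    residual: float


@dataclass
class SynergyScores:
    pair: tuple[str, str]
    readout: str
    level: float  # ICx level used, percent
    doses: tuple[float, float]
    ci: float | None
    bi: float
    cdi: float

    def classification(self, band: float = 0.05) -> str:
        """Synergy call from the BI score with an additivity band around 1."""
        if abs(self.bi - 1.0) <= band:
            return "additive"
        return "synergistic" if self.bi < 1.0 else "antagonistic"


# ---------------------------------------------------------------------------
# primitives


def steady_readout(ctx: Context, doses: dict[str, float], readout: str) -> float:
    return ctx.response(doses, readout)


def compute_ICx(
    ctx: Context,
    drug: str,
    readout: str,
    x: float,
    bracket: tuple[float, float] = (1e-6, 1e3),
    rel_tol: float = 1e-3,
    max_expand: int = 2,
) -> float:
    """Concentration at which ``drug`` inhibits ``readout`` by ``x`` percent.

    Bisection on the normalised steady-state response towards the target
    level ``1 - x/100``.  The response is first sampled across the bracket
    and verified to be non-increasing in dose (within a small tolerance);
    an unreachable target raises :class:`NotAchievable` — this is what the
    cohort responder filter catches.
    """
    if not 0.0 < x < 100.0:
        raise ValueError("x must be in (0, 100)")
    target = 1.0 - x / 100.0
    lo, hi = bracket
    for attempt in range(max_expand + 1):
        probe = np.geomspace(lo, hi, 9)
        resp = np.array([ctx.response({drug: d}, readout) for d in probe])
        # small (<10%) hormetic bumps from feedback compensation are
        # tolerated; larger rises invalidate the bisection premise
        if np.any(np.diff(resp) > 0.10):
            raise NotAchievable(
                f"{drug}->{readout}: response not monotone decreasing over bracket"
            )
        if resp[-1] <= target:
            break
        hi *= 10.0
    else:
        raise NotAchievable(
            f"{drug}->{readout}: {x:.0f}% inhibition not achievable below "
            f"{hi:.3g} uM (floor response {resp[-1]:.3f})"
        )
    if resp[0] <= target:  # already below target at the lower edge
        return lo
    # bisect in log dose
    f_lo, f_hi = resp[0], resp[-1]
    for _ in range(60):
        mid = math.sqrt(lo * hi)
        f_mid = ctx.response({drug: mid}, readout)
        if abs(f_mid - target) < rel_tol * target:
            return mid
        if f_mid > target:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-9:
            break
    return math.sqrt(lo * hi)


def dose_response(
    ctx: Context, drug: str, readout: str, doses: Sequence[float]
) -> DoseResponseCurve:
    """Normalised steady-state response at each dose (sorted, >= 0)."""
    doses = np.asarray(list(doses), float)
    if doses.size and (np.any(doses < 0) or np.any(np.diff(doses) < 0)):
        raise ValueError("doses must be sorted and non-negative")
    resp = np.array([ctx.response({drug: d}, readout) for d in doses])
    return DoseResponseCurve(drug, readout, doses, resp, dict(ctx.background))


def dose_matrix(
    ctx: Context,
    drugA: str,
    drugB: str,
    readout: str,
    dosesA: Sequence[float],
    dosesB: Sequence[float],
) -> np.ndarray:
    """|dosesA| x |dosesB| surface of normalised responses."""
    out = np.empty((len(dosesA), len(dosesB)))
    for i, da in enumerate(dosesA):
        for j, db in enumerate(dosesB):
            out[i, j] = ctx.response({drugA: da, drugB: db}, readout)
    return out


# ---------------------------------------------------------------------------
# Hill characterisation


def _hill(I, ymax, ymin, ic50, h):
    return (ymax - ymin) / (1.0 + (I / ic50) ** h) + ymin


def fit_hill(curve: DoseResponseCurve) -> HillFit:
    """Bounded least-squares fit of the Hill equation to a response curve.

    Initialisation: y_max/y_min from the curve extremes, IC50 from the dose
    nearest half-range, H = 1 — deterministic for monotone curves.  A curve
    whose range is below 1% of its maximum raises :class:`NoTransition`.
    """
    mask = curve.doses > 0
    I = curve.doses[mask]
    Y = curve.responses[mask]
    if I.size < 5:
        raise ValueError("need at least 5 positive-dose points to fit")
    ymax0, ymin0 = float(Y.max()), float(Y.min())
    if ymax0 - ymin0 < 0.01 * max(ymax0, 1e-12):
        raise NoTransition("flat dose-response curve; no transition to fit")
    half = 0.5 * (ymax0 + ymin0)
    ic0 = float(I[np.argmin(np.abs(Y - half))])

    def resid(p):
        return _hill(I, *p) - Y

    lo = [0.0, 0.0, I.min() / 100.0, 0.05]
    hi = [2.0 * ymax0 + 1e-6, ymax0, I.max() * 100.0, 20.0]
    p0 = np.clip([ymax0, ymin0, ic0, 1.0], lo, hi)
    sol = least_squares(resid, p0, bounds=(lo, hi), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    ymax, ymin, ic50, h = sol.x
    return HillFit(ymax, ymin, ic50, h, float(np.sqrt(np.mean(sol.fun**2))))


# ---------------------------------------------------------------------------
# synergy indices


def bi_score(eA: float, eB: float, eAB: float) -> float:
    """Bliss independence: observed vs expected remaining activity.

    ``e`` are fractional inhibitions in [0, 1).  BI < 1 means the combination
    leaves less activity than independent action predicts (synergy).
    """
    for name, e in (("eA", eA), ("eB", eB), ("eAB", eAB)):
        if not 0.0 <= e < 1.0:
            raise ValueError(f"{name} must lie in [0, 1)")
    expected_remaining = 1.0 - (eA + eB - eA * eB)
    if expected_remaining <= 0.0:
        raise ZeroDivisionError("expected remaining activity is zero")
    return (1.0 - eAB) / expected_remaining

def cdi_score(fA: float, fB: float, fAB: float) -> float:
    """Coefficient of drug interaction on remaining relative activities.

    ``f`` in (0, 1] are treated/untreated activity ratios; CDI = fAB/(fA*fB).
    Algebraically identical to :func:`bi_score` under ``f = 1 - e``.
    """
    for name, f in (("fA", fA), ("fB", fB), ("fAB", fAB)):
        if not 0.0 < f <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1]")
    return fAB / (fA * fB)


def median_effect_fit(curve: DoseResponseCurve) -> tuple[float, float]:
    """Median-effect parameters (Dm, m) from a single-drug curve.

    Fits ``fa/(1-fa) = (D/Dm)^m`` by linear regression of
    ``log(fa/fu)`` on ``log D`` over points with affected fraction
    fa in (0.005, 0.995).
    """
    mask = curve.doses > 0
    D = curve.doses[mask]
    fa = 1.0 - curve.responses[mask]  # affected fraction
    ok = (fa > 0.005) & (fa < 0.995)
    if ok.sum() < 3:
        raise ValueError("median-effect fit needs >= 3 informative points")
    x = np.log(D[ok])
    y = np.log(fa[ok] / (1.0 - fa[ok]))
    m, b = np.polyfit(x, y, 1)
    dm = math.exp(-b / m)
    return dm, m


def ci_score(
    curveA: DoseResponseCurve,
    curveB: DoseResponseCurve,
    dose_pair: tuple[float, float],
    combo_response: float,
) -> float:
    """Chou-Talalay combination index at a combination dose.

    ``Dx_i`` is the dose of drug i alone producing the combination's
    effect (from each drug's median-effect fit); CI = dA/DxA + dB/DxB.
    """
    fa = 1.0 - combo_response
    if not 0.0 < fa < 1.0:
        raise ValueError("combination effect outside (0, 1)")
    dA, dB = dose_pair
    ci = 0.0
    for d, curve in ((dA, curveA), (dB, curveB)):
        if d == 0:
            continue
        dm, mm = median_effect_fit(curve)
        fa_max = 1.0 - float(curve.responses.min())
        if fa >= fa_max and fa > 0.99:
            raise NotAchievable(
                f"combination effect {fa:.3f} outside {curve.drug}'s achievable range"
            )
        dx = dm * (fa / (1.0 - fa)) ** (1.0 / mm)
        ci += d / dx
    return ci


# ---------------------------------------------------------------------------
# pair evaluation and ranking


def combo_scores(
    ctx: Context,
    pair: tuple[str, str],
    readout: str,
    level: float = 25.0,
    curve_doses: np.ndarray | None = None,
) -> SynergyScores:
    """CI/BI/CDI for one drug pair at each drug's own ICx dose."""
    a, b = pair
    da = compute_ICx(ctx, a, readout, level)
    db = compute_ICx(ctx, b, readout, level)
    fA = ctx.response({a: da}, readout)
    fB = ctx.response({b: db}, readout)
    fAB = ctx.response({a: da, b: db}, readout)
    fA, fB = min(fA, 1.0), min(fB, 1.0)
    fAB = min(fAB, 1.0)
    bi = bi_score(1.0 - fA, 1.0 - fB, max(1.0 - fAB, 0.0))
    cdi = cdi_score(max(fA, 1e-12), max(fB, 1e-12), max(fAB, 1e-12))
    ci: float | None
    try:
        if curve_doses is None:
            curve_doses = np.geomspace(1e-4, 1e3, 25)
        ca = dose_response(ctx, a, readout, curve_doses)
        cb = dose_response(ctx, b, readout, curve_doses)
        ci = ci_score(ca, cb, (da, db), fAB)
    except (NotAchievable, ValueError, SteadyStateError):
        ci = None
    return SynergyScores(pair, readout, level, (da, db), ci, bi, cdi)


def rank_combinations(
    ctx: Context,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    readouts: Sequence[str] = ("pERK", "pSTAT3"),
    level: float = 25.0,
) -> pd.DataFrame:
    """Synergy table for all pairs, ranked most- to least-synergistic.

    Ranking is by the mean log2 of the available scores across readouts
    (lower = more synergistic); ties are broken lexicographically on the
    pair name and flagged in the ``tied`` column.
    """
    rows = []
    for pair in pairs:
        entry: dict = {"pair": "+".join(pair)}
        logs = []
        for ro in readouts:
            try:
                s = combo_scores(ctx, pair, ro, level)
            except (NotAchievable, SteadyStateError) as exc:
                entry[f"BI_{ro}"] = np.nan
                entry[f"CDI_{ro}"] = np.nan
                entry[f"CI_{ro}"] = np.nan
                entry[f"note_{ro}"] = str(exc)
                continue
            entry[f"BI_{ro}"] = s.bi
            entry[f"CDI_{ro}"] = s.cdi
            entry[f"CI_{ro}"] = s.ci if s.ci is not None else np.nan
            entry[f"doses_{ro}"] = s.doses
            for v in (s.bi, s.cdi, *([s.ci] if s.ci is not None else [])):
                if v is not None and v > 0:
                    logs.append(math.log2(v))
        entry["mean_log2_score"] = float(np.mean(logs)) if logs else np.nan
        rows.append(entry)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["mean_log2_score", "pair"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    scores = df["mean_log2_score"].round(9)
    df["tied"] = scores.duplicated(keep=False) & scores.notna()
    return df
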