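"""Synthetic data generation: noisy calibration time courses and virtual
patient cohorts with known ground truth.

The time-course generator mirrors the wet-lab training design on
MDA-MB-468 cells: EGF stimulation time courses of phospho- and total
protein readouts (0-24 h), PYK2/c-Met mRNA time courses (0-8 h), PYK2
knockdown and c-Met inhibition series.  Observations are the true model's
fold-change trajectories corrupted with multiplicative log-normal noise
(default sigma = 0.15, reflecting immunoblot quantification variability —
positivity-preserving).

The cohort generator mirrors a discovery-cohort-shaped expression table:
per-sample subtype labels and six node-expression values (EGFR, ERK,
STAT3 at protein level; PYK2, c-Met, CBL at transcript level) drawn from a
log-normal model centred on 1 (fold scale vs the modelled cell line), with
an optional planted PYK2 spread whose ground truth is stored alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import Condition, ExperimentalDataset, simulate_condition
from .model import ODESystem, ParameterSet
from .simulate import DrugTreatment, NodePerturbation, Stimulus

__all__ = [
    "TimecourseConfig",
    "CohortConfig",
    "default_conditions",
    "synth_timecourses",
    "synth_cohort",
    "COHORT_NODES",
]

COHORT_NODES = ("EGFR", "ERK", "STAT3", "PYK2", "cMet", "CBL")

#: discovery-cohort-shaped default subtype sizes
DEFAULT_SUBTYPES = {"BL1": 34, "M": 34, "LAR": 26, "UNC": 1}


def default_conditions() -> dict[str, tuple[Condition, np.ndarray, tuple[str, ...]]]:
    """The emulated training design: condition, time grid, readouts."""
    egf = Stimulus(egf=100.0)
    return {
        "EGF_timecourse": (
            Condition("EGF_timecourse", stimulus=egf),
            np.array([0.5, 1, 2, 4, 8, 16, 24], float),
            ("pEGFR", "pERK", "pSTAT3", "total_cMet", "total_PYK2"),
        ),
        "EGF_mRNA": (
            Condition("EGF_mRNA", stimulus=egf),
            np.array([0.5, 1, 2, 4, 8], float),
            ("mRNA_PYK2", "mRNA_cMet"),
        ),
        "PYK2_knockdown": (
            Condition(
                "PYK2_knockdown",
                stimulus=egf,
                perturbations=(NodePerturbation("knockdown", "PYK2", 0.9),),
            ),
            np.array([0.05, 0.17, 0.5, 1, 2, 8, 24], float),
            ("pERK", "pSTAT3", "total_cMet", "total_PYK2"),
        ),
        "cMet_inhibition": (
            Condition(
                "cMet_inhibition",
                stimulus=egf,
                perturbations=(NodePerturbation("direct_inhibition", "cMet", 0.9),),
            ),
            np.array([0.5, 1, 2, 8, 24], float),
            ("pPYK2", "pSTAT3", "pcMet", "total_cMet"),
        ),
    }


@dataclass
class TimecourseConfig:
    seed: int = 0
    noise_model: str = "lognormal"  # or "gaussian"
    sigma: float = 0.15
    conditions: Mapping | None = None  # defaults to default_conditions()

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.noise_model not in ("lognormal", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def synth_timecourses(
    system: ODESystem,
    true_params: ParameterSet | None = None,
    config: TimecourseConfig | None = None,
) -> ExperimentalDataset:
    """Simulate the training design with the true model and add noise.

    Deterministic under ``config.seed``.  The recorded SD per point is the
    noise model's standard deviation at that point (sigma-fraction of the
    mean for both models), never below a small positive floor.
    """
    config = config or TimecourseConfig()
    sys_t = system.with_params(true_params) if true_params is not None else system
    rng = np.random.default_rng(config.seed)
    spec = dict(config.conditions) if config.conditions else default_conditions()
    rows = []
    conditions = {}
    for name, (cond, times, readouts) in spec.items():
        conditions[name] = cond
        sims = simulate_condition(sys_t, cond, readouts, times)
        for ro in readouts:
            truth = sims[ro]
            if config.sigma == 0:
                obs = truth.copy()
            elif config.noise_model == "lognormal":
                obs = truth * rng.lognormal(0.0, config.sigma, size=truth.shape)
            else:
                obs = truth + rng.normal(0.0, config.sigma, size=truth.shape) * truth
                obs = np.clip(obs, 1e-9, None)
            sd = np.maximum(np.abs(truth) * max(config.sigma, 1e-3), 1e-6)
            for t, m, s in zip(times, obs, sd):
                rows.append(
                    {
                        "readout": ro,
                        "time_h": float(t),
                        "condition": name,
                        "mean": float(m),
                        "sd": float(s),
                    }
                )
    return ExperimentalDataset(pd.DataFrame(rows), conditions)


@dataclass
class CohortConfig:
    """Virtual-cohort specification.

    ``scale`` is the log-normal sigma (natural log) of every node's
    expression around median 1; ``pyk2_scale`` widens the PYK2 axis so the
    mechanistic link from PYK2 abundance to predicted combination synergy
    is detectable; ``pyk2_shift`` plants a deterministic fold increase in a
    labelled "high-PYK2" half of the cohort (ground truth stored in the
    ``truth_high_pyk2`` column).
    """

    seed: int = 0
    subtype_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPES)
    )
    scale: float = 0.2
    pyk2_scale: float = 0.2
    pyk2_shift: float = 1.0  # multiplicative shift for the planted half
    cmet_coshift_exp: float = 0.5  # c-Met co-shift = pyk2_shift ** this
    medians: Mapping[str, float] = field(
        default_factory=lambda: {n: 1.0 for n in COHORT_NODES}
    )

    def __post_init__(self):
        if any(n < 1 for n in self.subtype_sizes.values()):
            raise ValueError("subtype sizes must be >= 1")
        if self.scale < 0 or self.pyk2_scale < 0:
            raise ValueError("scales must be >= 0")


def synth_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Draw a cohort expression table.

    Columns: sample_id, subtype, the six node columns, truth_high_pyk2.
    Deterministic under ``config.seed``; subtype counts equal the request.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    rows = []
    i = 0
    for subtype, count in config.subtype_sizes.items():
        for _ in range(count):
            row = {"sample_id": f"VP{i:04d}", "subtype": subtype}
            for node in COHORT_NODES:
                scale = config.pyk2_scale if node == "PYK2" else config.scale
                row[node] = config.medians[node] * (
                    rng.lognormal(0.0, scale) if scale > 0 else 1.0
                )
            rows.append(row)
            i += 1
    df = pd.DataFrame(rows)
    # plant a high-PYK2 subgroup in a randomly chosen half
    flags = np.zeros(len(df), bool)
    half = rng.permutation(len(df))[: len(df) // 2]
    flags[half] = True
    df["truth_high_pyk2"] = flags
    if config.pyk2_shift != 1.0:
        # the planted condition is a PYK2-program upregulation: c-Met, whose
        # transcription shares the STAT3 program in the modelled network,
        # co-shifts with a configurable (default square-root) exponent
        df.loc[flags, "PYK2"] *= config.pyk2_shift
        df.loc[flags, "cMet"] *= config.pyk2_shift ** config.cmet_coshift_exp
    return df
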