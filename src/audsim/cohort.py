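"""Synthetic admissions register and patient-level outcome tables.

No patient-level data from the original admissions register are available, so
this module generates a synthetic stand-in carrying the attributes the cohort
description reports: cohort size, treatment-arm split, ICD-10 F10.x
main-diagnosis mix, sex split and admission years. Patient-level outcomes are
realised from the same per-arm negative-binomial / Bernoulli model the
simulation engine uses in aggregate, which enables end-to-end checks: column
sums of a patient table agree in distribution with the engine's group totals,
and moment re-estimation from a large table recovers the generating
parameters.

Registers and outcome tables are plain :class:`pandas.DataFrame` objects and
round-trip through CSV bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import (
    BinaryOutcomeParams,
    ConfigError,
    CountOutcomeParams,
    ScenarioAllocation,
    StudyParameterSet,
    allocate_scenario,
    derive_dispersion,
    OverdispersionError,
)

__all__ = [
    "DEFAULT_DIAGNOSIS_MIX",
    "DEFAULT_FEMALE_SHARE",
    "generate_admissions_register",
    "register_to_allocation",
    "generate_patient_outcomes",
    "ArmMomentEstimate",
    "ArmProportionEstimate",
    "ParameterEstimates",
    "estimate_outcome_params",
    "write_csv",
    "read_register",
    "read_outcomes",
]

#: Reported main-diagnosis mix of the 2051-patient admissions cohort.
#: The printed percentages sum to 99.9% (rounding); renormalised at draw time.
DEFAULT_DIAGNOSIS_MIX: dict[str, float] = {
    "F10.3": 0.535,  # withdrawal state
    "F10.2": 0.386,  # dependence syndrome
    "F10.0": 0.055,  # acute intoxication
    "F10.1": 0.023,  # harmful use
}

#: Reported share of female patients in the cohort.
DEFAULT_FEMALE_SHARE = 0.262

_REGISTER_COLUMNS = ["patient_id", "main_diagnosis", "sex", "arm", "admission_year"]
_OUTCOME_COLUMNS = [
    "patient_id",
    "arm",
    "n_hospitalisations",
    "hospital_days",
    "abstinent",
    "dead",
]


def generate_admissions_register(
    total_n: int,
    qwt_share: float,
    diagnosis_mix: Mapping[str, float] | None = None,
    female_share: float = DEFAULT_FEMALE_SHARE,
    seed: int = 0,
    admission_years: tuple[int, int] = (2016, 2017),
) -> pd.DataFrame:
    """Synthetic inpatient register with arm, diagnosis, sex and year.

    The arm split matches :func:`allocate_scenario` exactly (the QWT head
    count is deterministic; which patients are QWT is randomised), while
    diagnosis, sex and admission year are drawn i.i.d. from the given mixes.
    """
    mix = dict(DEFAULT_DIAGNOSIS_MIX if diagnosis_mix is None else diagnosis_mix)
    codes = list(mix)
    probs = np.array([mix[c] for c in codes], dtype=float)
    # Published mixes carry percentage rounding (e.g. shares summing to
    # 99.9%); tolerate that slack and renormalise, reject anything larger.
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 0.01:
        raise ConfigError("diagnosis_mix must be non-negative and sum to 1")
    probs = probs / probs.sum()
    if not 0.0 <= female_share <= 1.0:
        raise ConfigError(f"female_share must lie in [0, 1], got {female_share}")
    alloc = allocate_scenario(total_n, qwt_share, "register")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E61]))
    arm = np.array(["QWT"] * alloc.n_qwt + ["SWT"] * alloc.n_swt, dtype=object)
    rng.shuffle(arm)
    register = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(1, total_n + 1)],
            "main_diagnosis": rng.choice(codes, size=total_n, p=probs),
            "sex": np.where(rng.random(total_n) < female_share, "female", "male"),
            "arm": arm,
            "admission_year": rng.integers(
                admission_years[0], admission_years[1] + 1, size=total_n
            ),
        }
    )
    return register


def register_to_allocation(register: pd.DataFrame, label: str = "baseline") -> ScenarioAllocation:
    """Baseline scenario allocation derived from a register's arm counts."""
    if len(register) == 0:
        raise ConfigError("register is empty")
    n_qwt = int((register["arm"] == "QWT").sum())
    total_n = int(len(register))
    return ScenarioAllocation(label, total_n, n_qwt, total_n - n_qwt, baseline=True)


def generate_patient_outcomes(
    allocation: ScenarioAllocation,
    params: StudyParameterSet,
    seed: int = 0,
) -> pd.DataFrame:
    """Patient-level outcome realisations under the per-arm model.

    Each patient's hospitalisation count and hospital days are drawn from
    their arm's negative binomial (independently of each other), and the
    abstinence and death flags from independent Bernoulli draws — mirroring
    the aggregate outcome-by-outcome model, which carries no within-patient
    coupling.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x0C0]))
    frames = []
    offset = 0
    for arm_name, n in (("QWT", allocation.n_qwt), ("SWT", allocation.n_swt)):
        if n == 0:
            continue
        cols: dict[str, np.ndarray | list[str]] = {
            "patient_id": [f"P{i:06d}" for i in range(offset + 1, offset + n + 1)],
            "arm": [arm_name] * n,
        }
        for spec, col in (
            (params["hospitalisation_count"], "n_hospitalisations"),
            (params["hospital_days"], "hospital_days"),
        ):
            p_arm: CountOutcomeParams = spec.arm(arm_name)  # type: ignore[assignment]
            p = p_arm.dispersion / (p_arm.dispersion + p_arm.mean_per_patient)
            cols[col] = rng.negative_binomial(p_arm.dispersion, p, size=n).astype(np.int64)
        for spec, col in ((params["abstinence"], "abstinent"), (params["death"], "dead")):
            b_arm: BinaryOutcomeParams = spec.arm(arm_name)  # type: ignore[assignment]
            cols[col] = rng.binomial(1, b_arm.probability, size=n).astype(np.int64)
        frames.append(pd.DataFrame(cols))
        offset += n
    return pd.concat(frames, ignore_index=True)[_OUTCOME_COLUMNS]


@dataclass(frozen=True)
class ArmMomentEstimate:
    """Moment estimates for one arm of a count outcome."""

    n: int
    mean: float
    sd: float
    dispersion: float | None  # None when sd^2 <= mean (non-estimable)


@dataclass(frozen=True)
class ArmProportionEstimate:
    """Event proportion for one arm of a binary outcome."""

    n: int
    events: int
    proportion: float


@dataclass(frozen=True)
class ParameterEstimates:
    """Per-outcome, per-arm parameter estimates recovered from a patient table."""

    counts: dict[str, dict[str, ArmMomentEstimate]]
    binaries: dict[str, dict[str, ArmProportionEstimate]]


def estimate_outcome_params(table: pd.DataFrame) -> ParameterEstimates:
    """Re-estimate the generating parameters from a patient outcome table.

    Count outcomes: sample mean, sample SD (n-1 denominator) and the
    method-of-moments dispersion per arm; an arm with ``sd^2 <= mean`` gets
    ``dispersion=None`` (non-estimable) rather than an error. Binary
    outcomes: event counts and proportions per arm.
    """
    counts: dict[str, dict[str, ArmMomentEstimate]] = {}
    binaries: dict[str, dict[str, ArmProportionEstimate]] = {}
    count_cols = {"hospitalisation_count": "n_hospitalisations", "hospital_days": "hospital_days"}
    binary_cols = {"abstinence": "abstinent", "death": "dead"}
    for arm_name, sub in table.groupby("arm"):
        if len(sub) == 0:
            continue
        for outcome, col in count_cols.items():
            x = sub[col].to_numpy(dtype=float)
            mean = float(x.mean())
            sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
            try:
                k = derive_dispersion(mean, sd)
            except OverdispersionError:
                k = None
            counts.setdefault(outcome, {})[str(arm_name)] = ArmMomentEstimate(
                len(x), mean, sd, k
            )
        for outcome, col in binary_cols.items():
            e = int(sub[col].sum())
            binaries.setdefault(outcome, {})[str(arm_name)] = ArmProportionEstimate(
                len(sub), e, e / len(sub)
            )
    return ParameterEstimates(counts, binaries)


def write_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a register or outcome table as UTF-8 CSV with a header row."""
    frame.to_csv(path, index=False, encoding="utf-8")


def read_register(path: str | Path) -> pd.DataFrame:
    """Read an admissions register CSV, preserving column types."""
    return pd.read_csv(
        path,
        dtype={
            "patient_id": str,
            "main_diagnosis": str,
            "sex": str,
            "arm": str,
            "admission_year": np.int64,
        },
    )[_REGISTER_COLUMNS]


def read_outcomes(path: str | Path) -> pd.DataFrame:
    """Read a patient outcome table CSV, preserving column types."""
    return pd.read_csv(
        path,
        dtype={
            "patient_id": str,
            "arm": str,
            "n_hospitalisations": np.int64,
            "hospital_days": np.int64,
            "abstinent": np.int64,
            "dead": np.int64,
        },
    )[_OUTCOME_COLUMNS]
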