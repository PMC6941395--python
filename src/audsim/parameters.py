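"""Study parameters: outcome distributions and treatment-allocation scenarios.

Two kinds of outcome are modelled. Count outcomes (number of hospitalisations,
days spent in hospital) are overdispersed and follow a negative binomial
distribution parameterised by a per-patient mean ``mu`` and a size (dispersion)
parameter ``k`` such that ``variance = mu + mu**2 / k``. Published studies
report mean and SD, so ``k`` is recovered by the method of moments:

    k = mu**2 / (sd**2 - mu)

which requires overdispersion (``sd**2 > mu``); a negative binomial with
``sd**2 <= mu`` does not exist and is rejected rather than silently degraded
to a Poisson. Binary outcomes (abstinence, death) are Bernoulli per patient,
with the probability taken as the published events/denominator fraction.

A scenario is a split of a fixed cohort between the two treatment arms:
qualified withdrawal treatment (QWT, extended programme) and somatic
withdrawal treatment (SWT, short detoxification).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "OverdispersionError",
    "ConfigError",
    "CountOutcomeParams",
    "BinaryOutcomeParams",
    "OutcomeSpec",
    "StudyParameterSet",
    "ScenarioAllocation",
    "derive_dispersion",
    "probability_from_counts",
    "allocate_scenario",
    "round_half_up",
    "build_parameter_set",
    "scenarios_from_config",
    "load_config",
    "default_config_path",
    "CANONICAL_OUTCOMES",
]

#: Outcomes every full parameter set must define, in reporting order.
CANONICAL_OUTCOMES = ("hospitalisation_count", "hospital_days", "abstinence", "death")


class OverdispersionError(ValueError):
    """Raised when sd**2 <= mean, where no negative binomial exists."""


class ConfigError(ValueError):
    """Raised for structurally invalid configuration input."""


def round_half_up(x: float) -> int:
    """Round a non-negative value to the nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5))


def derive_dispersion(mean: float, sd: float) -> float:
    """Method-of-moments negative-binomial size parameter.

    ``k = mean**2 / (sd**2 - mean)``, so that ``mean + mean**2/k == sd**2``.

    Raises
    ------
    OverdispersionError
        If ``sd**2 <= mean`` (no overdispersion: the negative binomial is
        undefined and a Poisson fallback would misstate the variance).
    """
    if mean <= 0:
        raise OverdispersionError(f"mean must be positive, got {mean}")
    variance = sd * sd
    if variance <= mean:
        raise OverdispersionError(
            f"sd^2 ({variance:g}) must exceed mean ({mean:g}) for a "
            "negative binomial; refusing to fall back to Poisson"
        )
    return mean * mean / (variance - mean)


def probability_from_counts(events: int, denominator: int) -> float:
    """Event probability from published numerator/denominator counts."""
    if denominator <= 0:
        raise ConfigError(f"denominator must be positive, got {denominator}")
    if events < 0 or events > denominator:
        raise ConfigError(f"events ({events}) must lie in [0, {denominator}]")
    return events / denominator


@dataclass(frozen=True)
class CountOutcomeParams:
    """Per-arm negative-binomial parameters for a count outcome."""

    mean_per_patient: float
    sd_per_patient: float
    dispersion: float
    horizon: str = ""

    def __post_init__(self) -> None:
        if self.mean_per_patient < 0:
            raise ConfigError(f"mean must be non-negative, got {self.mean_per_patient}")
        if self.sd_per_patient**2 <= self.mean_per_patient:
            raise OverdispersionError(
                f"sd^2 ({self.sd_per_patient**2:g}) must exceed mean "
                f"({self.mean_per_patient:g})"
            )
        if self.dispersion <= 0:
            raise ConfigError(f"dispersion must be positive, got {self.dispersion}")

    @classmethod
    def from_moments(cls, mean: float, sd: float, horizon: str = "") -> "CountOutcomeParams":
        """Build with the dispersion derived from the moments (round-trip exact)."""
        return cls(mean, sd, derive_dispersion(mean, sd), horizon)

    @property
    def variance(self) -> float:
        """Per-patient variance implied by (mean, dispersion)."""
        mu = self.mean_per_patient
        return mu + mu * mu / self.dispersion


@dataclass(frozen=True)
class BinaryOutcomeParams:
    """Per-arm Bernoulli parameters for a binary outcome."""

    events: int
    denominator: int
    horizon: str = ""

    def __post_init__(self) -> None:
        probability_from_counts(self.events, self.denominator)  # validates

    @property
    def probability(self) -> float:
        return probability_from_counts(self.events, self.denominator)


@dataclass(frozen=True)
class OutcomeSpec:
    """One outcome with its QWT and SWT arm parameters."""

    name: str
    kind: str  # "count" | "binary"
    qwt: CountOutcomeParams | BinaryOutcomeParams
    swt: CountOutcomeParams | BinaryOutcomeParams

    def __post_init__(self) -> None:
        if self.kind not in ("count", "binary"):
            raise ConfigError(f"outcome {self.name!r}: unknown type {self.kind!r}")
        want = CountOutcomeParams if self.kind == "count" else BinaryOutcomeParams
        for arm_name, arm in (("qwt", self.qwt), ("swt", self.swt)):
            if not isinstance(arm, want):
                raise ConfigError(
                    f"outcome {self.name!r}, arm {arm_name!r}: expected "
                    f"{want.__name__}, got {type(arm).__name__}"
                )

    def arm(self, which: str) -> CountOutcomeParams | BinaryOutcomeParams:
        which = which.lower()
        if which not in ("qwt", "swt"):
            raise ConfigError(f"unknown arm {which!r}")
        return self.qwt if which == "qwt" else self.swt


@dataclass(frozen=True)
class StudyParameterSet:
    """The full per-arm parameter bundle for all four modelled outcomes."""

    outcomes: tuple[OutcomeSpec, ...]

    def __post_init__(self) -> None:
        names = [o.name for o in self.outcomes]
        missing = [n for n in CANONICAL_OUTCOMES if n not in names]
        if missing:
            raise ConfigError(f"missing outcome(s): {', '.join(missing)}")
        if len(set(names)) != len(names):
            raise ConfigError("duplicate outcome names")

    def __getitem__(self, name: str) -> OutcomeSpec:
        for o in self.outcomes:
            if o.name == name:
                return o
        raise KeyError(name)

    @property
    def outcome_names(self) -> tuple[str, ...]:
        return tuple(o.name for o in self.outcomes)


@dataclass(frozen=True)
class ScenarioAllocation:
    """A named split of the cohort into QWT and SWT group sizes."""

    label: str
    total_n: int
    n_qwt: int
    n_swt: int
    baseline: bool = False

    def __post_init__(self) -> None:
        if self.total_n < 1:
            raise ConfigError(f"total_n must be >= 1, got {self.total_n}")
        if not 0 <= self.n_qwt <= self.total_n:
            raise ConfigError(f"n_qwt ({self.n_qwt}) outside [0, {self.total_n}]")
        if self.n_qwt + self.n_swt != self.total_n:
            raise ConfigError(
                f"n_qwt + n_swt ({self.n_qwt + self.n_swt}) != total_n ({self.total_n})"
            )


def allocate_scenario(
    total_n: int, qwt_share: float, label: str = "", baseline: bool = False
) -> ScenarioAllocation:
    """Split ``total_n`` patients by QWT share, rounding the QWT count half-up.

    Half-up rounding on the QWT count (SWT takes the remainder) reproduces the
    published splits 2051 x 0.25 -> 513/1538 and 2051 x 0.50 -> 1026/1025.
    """
    if total_n < 1:
        raise ConfigError(f"total_n must be >= 1, got {total_n}")
    if not 0.0 <= qwt_share <= 1.0:
        raise ConfigError(f"qwt_share must lie in [0, 1], got {qwt_share}")
    n_qwt = round_half_up(total_n * qwt_share)
    return ScenarioAllocation(label, total_n, n_qwt, total_n - n_qwt, baseline)


# ---------------------------------------------------------------------------
# Configuration loading


def default_config_path() -> Path:
    """Path to the bundled default configuration (published parameter table)."""
    return Path(__file__).parent / "data" / "default_config.yaml"


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML configuration; ``None`` loads the bundled default."""
    p = Path(path) if path is not None else default_config_path()
    with open(p, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{p}: top level must be a mapping")
    return dict(raw)


def _require_number(entry: Mapping[str, Any], key: str, where: str) -> float:
    if key not in entry:
        raise ConfigError(f"{where}: missing field {key!r}")
    v = entry[key]
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise ConfigError(f"{where}.{key}: expected a number, got {v!r}")
    return float(v)


def _build_arm(
    kind: str, entry: Any, horizon: str, where: str
) -> CountOutcomeParams | BinaryOutcomeParams:
    if not isinstance(entry, Mapping):
        raise ConfigError(f"{where}: expected a mapping, got {entry!r}")
    if kind == "count":
        mean = _require_number(entry, "mean", where)
        sd = _require_number(entry, "sd", where)
        if entry.get("dispersion") is not None:
            k = _require_number(entry, "dispersion", where)
        else:
            try:
                k = derive_dispersion(mean, sd)
            except OverdispersionError as exc:
                raise OverdispersionError(f"{where}: {exc}") from exc
        try:
            return CountOutcomeParams(mean, sd, k, horizon)
        except (ConfigError, OverdispersionError) as exc:
            raise type(exc)(f"{where}: {exc}") from exc
    events = int(_require_number(entry, "events", where))
    denominator = int(_require_number(entry, "denominator", where))
    try:
        return BinaryOutcomeParams(events, denominator, horizon)
    except ConfigError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def build_parameter_set(raw_config: Mapping[str, Any]) -> StudyParameterSet:
    """Materialise a validated :class:`StudyParameterSet` from a config mapping.

    For count outcomes the dispersion is taken from an explicit per-arm
    ``dispersion`` key when present, otherwise derived from the (mean, sd)
    moments. Validation errors name the offending ``outcomes.<name>.<arm>``
    entry.
    """
    outcomes_cfg = raw_config.get("outcomes")
    if not isinstance(outcomes_cfg, Mapping) or not outcomes_cfg:
        raise ConfigError("config: missing or empty 'outcomes' section")
    specs = []
    for name, entry in outcomes_cfg.items():
        where = f"outcomes.{name}"
        if not isinstance(entry, Mapping):
            raise ConfigError(f"{where}: expected a mapping")
        kind = entry.get("type")
        if kind not in ("count", "binary"):
            raise ConfigError(f"{where}.type: expected 'count' or 'binary', got {kind!r}")
        horizon = str(entry.get("horizon", ""))
        arms = {}
        for arm in ("qwt", "swt"):
            if arm not in entry:
                raise ConfigError(f"{where}: missing arm {arm!r}")
            arms[arm] = _build_arm(kind, entry[arm], horizon, f"{where}.{arm}")
        specs.append(OutcomeSpec(str(name), kind, arms["qwt"], arms["swt"]))
    return StudyParameterSet(tuple(specs))


def scenarios_from_config(raw_config: Mapping[str, Any]) -> list[ScenarioAllocation]:
    """Build scenario allocations from the ``scenarios`` + ``cohort`` sections.

    Each scenario entry gives either an explicit ``qwt_n`` (used verbatim, as
    for an observed baseline head count) or a ``qwt_share`` in [0, 1]. Exactly
    one scenario must carry ``baseline: true``; if none does, the first is
    taken as baseline.
    """
    cohort = raw_config.get("cohort")
    if not isinstance(cohort, Mapping) or "total_n" not in cohort:
        raise ConfigError("config: missing 'cohort.total_n'")
    total_n = int(cohort["total_n"])
    entries = raw_config.get("scenarios")
    if not isinstance(entries, list) or not entries:
        raise ConfigError("config: missing or empty 'scenarios' list")
    allocations: list[ScenarioAllocation] = []
    for i, entry in enumerate(entries):
        where = f"scenarios[{i}]"
        if not isinstance(entry, Mapping) or "label" not in entry:
            raise ConfigError(f"{where}: expected a mapping with a 'label'")
        label = str(entry["label"])
        is_base = bool(entry.get("baseline", False))
        if "qwt_n" in entry:
            n_qwt = int(entry["qwt_n"])
            allocations.append(
                ScenarioAllocation(label, total_n, n_qwt, total_n - n_qwt, is_base)
            )
        elif "qwt_share" in entry:
            allocations.append(
                allocate_scenario(total_n, float(entry["qwt_share"]), label, is_base)
            )
        else:
            raise ConfigError(f"{where}: needs 'qwt_n' or 'qwt_share'")
    n_base = sum(a.baseline for a in allocations)
    if n_base > 1:
        raise ConfigError("config: more than one scenario flagged as baseline")
    if n_base == 0:
        allocations[0] = ScenarioAllocation(
            allocations[0].label,
            allocations[0].total_n,
            allocations[0].n_qwt,
            allocations[0].n_swt,
            True,
        )
    labels = [a.label for a in allocations]
    if len(set(labels)) != len(labels):
        raise ConfigError("config: duplicate scenario labels")
    return allocations
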