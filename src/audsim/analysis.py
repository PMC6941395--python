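"""Summaries and paired scenario comparisons of replicate vectors.

Each replicate vector is summarised by its arithmetic mean and an empirical
percentile interval (2.5th/97.5th percentiles at the default 95% level,
linear interpolation between order statistics). Scenario-versus-baseline
effects are computed on paired replicates: replicate *i* of a scenario is
matched with replicate *i* of baseline, differences (absolute, and relative
as a percentage of the baseline replicate) are formed per pair, and those
difference vectors are summarised the same way. Replicates with a zero
baseline value are excluded from the relative summary and counted.

Binary outcomes are reported as proportions of the full cohort; count
outcomes as cohort totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import SimulationResult, TotalSamples
from .parameters import (
    ConfigError,
    ScenarioAllocation,
    StudyParameterSet,
    round_half_up,
)

__all__ = [
    "SummaryStat",
    "ComparisonStat",
    "ResultsTable",
    "summarize",
    "to_proportion",
    "compare_paired",
    "build_results_table",
]


@dataclass(frozen=True)
class SummaryStat:
    """Mean with an empirical percentile confidence interval."""

    mean: float
    ci_low: float
    ci_high: float
    ci_level: float

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError(f"ci_low ({self.ci_low}) > ci_high ({self.ci_high})")


@dataclass(frozen=True)
class ComparisonStat:
    """Paired scenario-minus-baseline effect, absolute and relative.

    ``relative`` is in percent of the baseline replicate value;
    ``n_zero_baseline`` counts replicates excluded from the relative summary
    because the baseline value was zero.
    """

    absolute: SummaryStat
    relative: SummaryStat
    n_zero_baseline: int = 0


def summarize(values: np.ndarray | TotalSamples, ci_level: float = 0.95) -> SummaryStat:
    """Mean and percentile CI of a replicate vector.

    The interval endpoints are the empirical ``(1-ci_level)/2`` and
    ``1-(1-ci_level)/2`` quantiles with linear interpolation.
    """
    if isinstance(values, TotalSamples):
        values = values.values
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarise an empty replicate vector")
    if not 0.0 < ci_level < 1.0:
        raise ValueError(f"ci_level must lie in (0, 1), got {ci_level}")
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return SummaryStat(float(values.mean()), float(lo), float(hi), ci_level)


def to_proportion(samples: TotalSamples, total_n: int) -> TotalSamples:
    """Rescale event-count replicates to fractions of the cohort size."""
    if total_n < 1:
        raise ValueError(f"total_n must be >= 1, got {total_n}")
    return TotalSamples(
        samples.scenario_label, samples.outcome_name, samples.values / total_n
    )


def compare_paired(
    baseline: TotalSamples, scenario: TotalSamples, ci_level: float = 0.95
) -> ComparisonStat:
    """Paired per-replicate scenario-vs-baseline differences.

    ``d_i = scenario_i - baseline_i`` and ``r_i = 100 * d_i / baseline_i``;
    both vectors are summarised by mean and percentile CI. Pairs with
    ``baseline_i == 0`` are dropped from the relative summary and counted in
    ``n_zero_baseline``.
    """
    b = np.asarray(baseline.values, dtype=float)
    s = np.asarray(scenario.values, dtype=float)
    if b.shape != s.shape:
        raise ValueError(
            f"replicate vectors are not aligned: {b.shape} vs {s.shape}"
        )
    diff = s - b
    nonzero = b != 0
    n_zero = int((~nonzero).sum())
    if not nonzero.any():
        raise ValueError("all baseline replicates are zero; relative change undefined")
    rel = 100.0 * diff[nonzero] / b[nonzero]
    return ComparisonStat(summarize(diff, ci_level), summarize(rel, ci_level), n_zero)


@dataclass(frozen=True)
class ResultsTable:
    """Tidy per-(outcome, scenario) summary with scenario-vs-baseline effects.

    ``frame`` has one row per outcome x scenario with columns: outcome, kind,
    scenario, n_qwt, n_swt, mean, ci_low, ci_high (proportions of the cohort
    for binary outcomes, totals for counts), and for non-baseline scenarios
    abs_diff / abs_ci_low / abs_ci_high (outcome units) and rel_diff_pct /
    rel_ci_low_pct / rel_ci_high_pct (percent of baseline).
    """

    frame: pd.DataFrame
    baseline_label: str
    ci_level: float

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def to_text(self) -> str:
        """Human-readable table with published-style rounding.

        Count means print as whole totals, binary means as integer percent of
        the cohort, relative effects as integer percent; half-up rounding.
        """
        lines = []
        scen_labels = list(dict.fromkeys(self.frame["scenario"]))
        for outcome, sub in self.frame.groupby("outcome", sort=False):
            kind = sub["kind"].iloc[0]
            lines.append(f"{outcome} [{kind}]")
            for label in scen_labels:
                row = sub[sub["scenario"] == label].iloc[0]
                if kind == "binary":
                    cell = (
                        f"{_pct(row['mean'])}% "
                        f"({_pct(row['ci_low'])} to {_pct(row['ci_high'])}%)"
                    )
                else:
                    cell = (
                        f"{round_half_up(row['mean']):,} "
                        f"({round_half_up(row['ci_low']):,} to "
                        f"{round_half_up(row['ci_high']):,})"
                    )
                tag = " (baseline)" if label == self.baseline_label else ""
                line = f"  {label:<10} {cell}{tag}"
                if label != self.baseline_label and pd.notna(row["rel_diff_pct"]):
                    line += (
                        f"  diff vs baseline: {_signed_pct(row['rel_diff_pct'])}% "
                        f"({_signed_pct(row['rel_ci_low_pct'])} to "
                        f"{_signed_pct(row['rel_ci_high_pct'])}%)"
                    )
                lines.append(line)
        return "\n".join(lines) + "\n"


def _pct(fraction: float) -> int:
    return round_half_up(100.0 * fraction)


def _signed_pct(pct: float) -> str:
    r = round_half_up(abs(pct))
    sign = "-" if pct < 0 and r != 0 else ("+" if r != 0 else "")
    return f"{sign}{r}"


def build_results_table(
    result: SimulationResult,
    params: StudyParameterSet,
    ci_level: float = 0.95,
) -> ResultsTable:
    """Assemble the per-outcome, per-scenario summary table.

    Count outcomes are summarised as cohort totals, binary outcomes as
    proportions of the cohort; every non-baseline scenario is compared with
    the baseline on paired replicates (absolute differences in outcome units,
    relative in percent).
    """
    baseline = result.baseline  # raises ConfigError if absent
    rows = []
    for spec in params.outcomes:
        base_samples = result[(baseline.label, spec.name)]
        for alloc in result.scenarios:
            samples = result[(alloc.label, spec.name)]
            if spec.kind == "binary":
                stat = summarize(to_proportion(samples, alloc.total_n), ci_level)
            else:
                stat = summarize(samples, ci_level)
            row = {
                "outcome": spec.name,
                "kind": spec.kind,
                "scenario": alloc.label,
                "n_qwt": alloc.n_qwt,
                "n_swt": alloc.n_swt,
                "mean": stat.mean,
                "ci_low": stat.ci_low,
                "ci_high": stat.ci_high,
                "abs_diff": np.nan,
                "abs_ci_low": np.nan,
                "abs_ci_high": np.nan,
                "rel_diff_pct": np.nan,
                "rel_ci_low_pct": np.nan,
                "rel_ci_high_pct": np.nan,
            }
            if alloc.label != baseline.label:
                cmp = compare_paired(base_samples, samples, ci_level)
                row.update(
                    abs_diff=cmp.absolute.mean,
                    abs_ci_low=cmp.absolute.ci_low,
                    abs_ci_high=cmp.absolute.ci_high,
                    rel_diff_pct=cmp.relative.mean,
                    rel_ci_low_pct=cmp.relative.ci_low,
                    rel_ci_high_pct=cmp.relative.ci_high,
                )
            rows.append(row)
    frame = pd.DataFrame(rows)
    return ResultsTable(frame, baseline.label, ci_level)
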