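"""Cilium-length statistics: two-sample tests for gain-of-ciliation genes.

The default test is the classic equal-variance (pooled) unpaired two-tailed
Student's t-test; Welch's unequal-variance variant is available behind a
flag.  The t statistic and p-value are computed from first principles here
(degrees of freedom ``n1 + n2 - 2`` for the pooled test), with only the t
distribution's survival function taken from scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .screen_model import LengthMeasurement, Screen

__all__ = ["LengthComparison", "LengthAnalysisError", "compare_lengths", "lengths_report"]


class LengthAnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class LengthComparison:
    """Condition-vs-control cilium length comparison (micrometres)."""

    reagent_id: str
    n_condition: int
    n_control: int
    mean_condition: float
    mean_control: float
    sem_condition: float
    sem_control: float
    t_statistic: float
    p_value: float
    significant: bool


def _mean_var_sem(values: tuple[float, ...]) -> tuple[float, float, float]:
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, var, math.sqrt(var / n)


def compare_lengths(
    condition: LengthMeasurement,
    control: LengthMeasurement,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> LengthComparison:
    """Two-tailed unpaired t-test of condition vs control cilium lengths.

    Each measured cilium counts as one observation.  Both samples need at
    least two observations.  A zero pooled variance is tolerated only when
    the means are identical (t = 0, p = 1); otherwise the comparison is
    degenerate and raises.
    """
    n1, n2 = condition.n, control.n
    if n1 < 2 or n2 < 2:
        raise LengthAnalysisError(
            f"compare_lengths({condition.reagent_id!r}): both samples need >= 2 "
            f"observations (got {n1} and {n2})"
        )
    m1, v1, sem1 = _mean_var_sem(condition.lengths_um)
    m2, v2, sem2 = _mean_var_sem(control.lengths_um)

    if equal_var:
        df = n1 + n2 - 2
        pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    else:  # Welch
        se = math.sqrt(v1 / n1 + v2 / n2)
        if se > 0:
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        else:
            df = n1 + n2 - 2

    if se == 0.0:
        if m1 == m2:
            t_stat, p_value = 0.0, 1.0
        else:
            raise LengthAnalysisError(
                f"compare_lengths({condition.reagent_id!r}): zero variance with "
                f"unequal means is degenerate"
            )
    else:
        t_stat = (m1 - m2) / se
        p_value = 2.0 * stats.t.sf(abs(t_stat), df)

    return LengthComparison(
        reagent_id=condition.reagent_id,
        n_condition=n1,
        n_control=n2,
        mean_condition=m1,
        mean_control=m2,
        sem_condition=sem1,
        sem_control=sem2,
        t_statistic=t_stat,
        p_value=p_value,
        significant=p_value < alpha,
    )


def lengths_report(
    screen: Screen,
    control_reagent_id: str,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """One LengthComparison row per measured condition vs the control sample."""
    if control_reagent_id not in screen.lengths:
        raise LengthAnalysisError(
            f"no length measurements for control reagent {control_reagent_id!r}"
        )
    control = screen.lengths[control_reagent_id]
    rows = []
    for rid, measurement in sorted(screen.lengths.items()):
        if rid == control_reagent_id:
            continue
        cmp = compare_lengths(measurement, control, alpha=alpha, equal_var=equal_var)
        rows.append(
            {
                "reagent_id": cmp.reagent_id,
                "n_condition": cmp.n_condition,
                "n_control": cmp.n_control,
                "mean_condition_um": cmp.mean_condition,
                "mean_control_um": cmp.mean_control,
                "sem_condition_um": cmp.sem_condition,
                "sem_control_um": cmp.sem_control,
                "t_statistic": cmp.t_statistic,
                "p_value": cmp.p_value,
                "significant": cmp.significant,
            }
        )
    return pd.DataFrame(rows)
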