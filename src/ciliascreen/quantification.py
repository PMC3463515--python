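"""Percent-ciliation quantification, control normalization and knockdown.

Percentages are carried internally as fractions in ``[0, 1]``; reports
multiply by 100 for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .screen_model import (
    ConditionObservation,
    QPCRMeasurement,
    QPCRMode,
    Screen,
    ScreenValidationError,
)

__all__ = [
    "NormalizedEffect",
    "KnockdownResult",
    "NormalizationError",
    "percent_ciliation",
    "control_percent_by_experiment",
    "normalize_to_control",
    "quantify_knockdown",
    "quantify_all_knockdowns",
    "DEFAULT_KNOCKDOWN_CUTOFF",
]

#: Maximum fraction of transcript remaining for a duplex to count as a
#: verified knockdown.  A tunable; no published criterion exists.
DEFAULT_KNOCKDOWN_CUTOFF = 0.60


class NormalizationError(ValueError):
    """Raised when a reagent cannot be normalized against any control."""


@dataclass(frozen=True)
class NormalizedEffect:
    """Cross-experiment normalized percent ciliation for one reagent.

    ``mean_normalized`` is unitless: 1.0 means control-level ciliation;
    ``reduction`` is ``1 - mean_normalized``.
    """

    reagent_id: str
    per_experiment_normalized: tuple[float, ...]
    mean_normalized: float
    sd_across_experiments: float
    sem: float
    n_experiments: int

    @property
    def reduction(self) -> float:
        return 1.0 - self.mean_normalized


@dataclass(frozen=True)
class KnockdownResult:
    """qRT-PCR knockdown summary; ``percent_remaining_mean`` is a fraction."""

    reagent_id: str
    percent_remaining_mean: float
    percent_remaining_sd: float
    knockdown_positive: bool


def percent_ciliation(obs: ConditionObservation) -> float:
    """Fraction of DAPI-positive cells bearing a visible primary cilium."""
    if obs.total_count <= 0:
        raise ScreenValidationError(
            f"observation ({obs.experiment_id}, {obs.reagent_id}): "
            f"total_count must be positive"
        )
    return obs.ciliated_count / obs.total_count


def control_percent_by_experiment(
    screen: Screen, qc_log: Optional[list[str]] = None
) -> dict[str, float]:
    """Per-experiment scrambled-control percent ciliation.

    When an experiment contains several scrambled-control observations the
    reference is their unweighted mean, so that each individual scrambled
    duplex retains non-degenerate dispersion around 1.0 after normalization.
    Experiments whose control percent ciliation is zero are excluded with a
    warning; experiments with no scrambled observation are simply absent.
    """
    if qc_log is None:
        qc_log = screen.qc_log
    scrambled_ids = {r.reagent_id for r in screen.scrambled_reagents()}
    per_exp: dict[str, list[float]] = {}
    for obs in screen.observations:
        if obs.reagent_id in scrambled_ids:
            per_exp.setdefault(obs.experiment_id, []).append(percent_ciliation(obs))
    out: dict[str, float] = {}
    for exp, values in per_exp.items():
        mean = sum(values) / len(values)
        if mean == 0.0:
            qc_log.append(
                f"QC: experiment {exp!r} excluded from normalization "
                f"(control percent ciliation is zero)"
            )
            continue
        out[exp] = mean
    return out


def _summarize(reagent_id: str, ratios: list[float]) -> NormalizedEffect:
    n = len(ratios)
    mean = sum(ratios) / n
    if n >= 2:
        var = sum((r - mean) ** 2 for r in ratios) / (n - 1)
        sd = math.sqrt(var)
    else:
        sd = 0.0
    return NormalizedEffect(
        reagent_id=reagent_id,
        per_experiment_normalized=tuple(ratios),
        mean_normalized=mean,
        sd_across_experiments=sd,
        sem=sd / math.sqrt(n),
        n_experiments=n,
    )


def normalize_to_control(screen: Screen) -> dict[str, NormalizedEffect]:
    """Normalized percent ciliation per reagent, averaged over experiments.

    For every reagent, each experiment contributes the ratio of the reagent's
    percent ciliation to the same-experiment scrambled-control percent
    ciliation; these per-experiment ratios are then averaged unweighted.
    Experiments lacking either observation are excluded and logged.  A reagent
    with no experiment overlapping a usable control raises
    :class:`NormalizationError`.
    """
    controls = control_percent_by_experiment(screen)
    ratios: dict[str, dict[str, float]] = {}
    for obs in screen.observations:
        if obs.experiment_id not in controls:
            screen.qc_log.append(
                f"QC: ({obs.experiment_id}, {obs.reagent_id}) excluded "
                f"(no usable scrambled control in this experiment)"
            )
            continue
        per_reagent = ratios.setdefault(obs.reagent_id, {})
        if obs.experiment_id in per_reagent:
            raise ScreenValidationError(
                f"duplicate observation for ({obs.experiment_id}, {obs.reagent_id})"
            )
        per_reagent[obs.experiment_id] = (
            percent_ciliation(obs) / controls[obs.experiment_id]
        )
    effects: dict[str, NormalizedEffect] = {}
    for reagent_id in screen.reagents:
        per_reagent = ratios.get(reagent_id)
        if not per_reagent:
            if screen.observations_for(reagent_id):
                raise NormalizationError(
                    f"reagent {reagent_id!r}: no experiment overlaps a usable "
                    f"scrambled control"
                )
            continue  # reagent with no count data at all (e.g. qPCR-only)
        effects[reagent_id] = _summarize(reagent_id, list(per_reagent.values()))
    return effects


def quantify_knockdown(
    q: QPCRMeasurement,
    cutoff: float = DEFAULT_KNOCKDOWN_CUTOFF,
    control: Optional[QPCRMeasurement] = None,
) -> KnockdownResult:
    """Summarize a qRT-PCR measurement into fraction of transcript remaining.

    ``CT`` mode computes a relative quantity ``2**(-ddCt)`` per replicate,
    where ``dCt = target Ct - reference Ct`` and ``ddCt`` subtracts the
    scrambled-control dCt (replicate-paired when replicate counts match,
    otherwise the control's mean dCt).  ``PERCENT_REMAINING`` mode averages
    the precomputed values (input on the 0-100 scale) directly.
    """
    if q.mode is QPCRMode.PERCENT_REMAINING:
        values = [v / 100.0 for v in q.replicate_values]
    else:
        if q.reference_values is None:
            raise ScreenValidationError(
                f"qPCR for {q.reagent_id!r}: CT mode requires reference values"
            )
        if control is None or control.reference_values is None:
            raise ScreenValidationError(
                f"qPCR for {q.reagent_id!r}: CT mode requires the linked "
                f"scrambled-control measurement"
            )
        d_ct = [t - r for t, r in zip(q.replicate_values, q.reference_values)]
        d_ct_ctrl = [
            t - r for t, r in zip(control.replicate_values, control.reference_values)
        ]
        if len(d_ct) == len(d_ct_ctrl):
            dd_ct = [a - b for a, b in zip(d_ct, d_ct_ctrl)]
        else:
            ctrl_mean = sum(d_ct_ctrl) / len(d_ct_ctrl)
            dd_ct = [a - ctrl_mean for a in d_ct]
        values = [2.0 ** (-x) for x in dd_ct]
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1)) if n >= 2 else 0.0
    return KnockdownResult(
        reagent_id=q.reagent_id,
        percent_remaining_mean=mean,
        percent_remaining_sd=sd,
        knockdown_positive=mean <= cutoff,
    )


def quantify_all_knockdowns(
    screen: Screen, cutoff: float = DEFAULT_KNOCKDOWN_CUTOFF
) -> dict[str, KnockdownResult]:
    """Run :func:`quantify_knockdown` for every measured reagent in a screen."""
    out: dict[str, KnockdownResult] = {}
    for rid, q in screen.qpcr.items():
        control = screen.qpcr.get(q.control_link) if q.control_link else None
        reagent = screen.reagents.get(rid)
        if (
            control is None
            and q.mode is QPCRMode.CT
            and reagent is not None
            and reagent.reagent_class.name == "SCRAMBLED_CONTROL"
        ):
            control = q  # a scrambled control is its own reference (ddCt = 0)
        out[rid] = quantify_knockdown(q, cutoff=cutoff, control=control)
    return out
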