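"""Loss/gain threshold calibration from negative-control dispersion.

The loss cutoff is anchored to the normalized ciliation of a designated
positive-control reagent of known moderate effect, validated against a
``k``-standard-deviation bound on the pooled per-experiment normalized
values of all scrambled negative-control duplexes.  The gain cutoff mirrors
the bound on the high side (no anchor exists for gains).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .quantification import NormalizedEffect
from .screen_model import Screen

__all__ = [
    "ThresholdSet",
    "CalibrationError",
    "calibrate_thresholds",
    "negative_control_values",
    "DEFAULT_K_SD",
]

logger = logging.getLogger(__name__)

DEFAULT_K_SD = 4.0


class CalibrationError(ValueError):
    """Degenerate or missing control data; thresholds cannot be derived."""


@dataclass(frozen=True)
class ThresholdSet:
    """Calibrated cutoffs on mean normalized ciliation.

    ``loss_threshold`` is the maximum normalized ciliation scored as LOSS,
    ``gain_threshold`` the minimum scored as GAIN.  ``validated`` records
    whether the anchor reagent's depletion exceeded the ``k_sd`` bound below
    the negative-control mean; when it does not, ``loss_threshold`` falls
    back to that bound.
    """

    loss_threshold: float
    gain_threshold: float
    k_sd: float
    neg_mean: float
    neg_sd: float
    anchor_value: float
    validated: bool

    def __post_init__(self) -> None:
        if not self.loss_threshold < self.neg_mean < self.gain_threshold:
            raise CalibrationError(
                f"thresholds must bracket the negative-control mean: "
                f"loss {self.loss_threshold} < mean {self.neg_mean} < "
                f"gain {self.gain_threshold} violated"
            )


def negative_control_values(
    screen: Screen, effects: dict[str, NormalizedEffect]
) -> list[float]:
    """Pooled per-experiment normalized values of all scrambled duplexes."""
    values: list[float] = []
    for reagent in screen.scrambled_reagents():
        eff = effects.get(reagent.reagent_id)
        if eff is not None:
            values.extend(eff.per_experiment_normalized)
    return values


def calibrate_thresholds(
    negative_values: Sequence[float],
    anchor: "NormalizedEffect | float",
    k_sd: float = DEFAULT_K_SD,
    qc_log: Optional[list[str]] = None,
) -> ThresholdSet:
    """Derive the loss/gain cutoffs from controls.

    Parameters
    ----------
    negative_values
        Per-experiment normalized ciliation values of scrambled negative
        controls, pooled over duplexes and experiments (>= 2 required).
    anchor
        Normalized effect of the moderate positive-control reagent (or its
        mean normalized value directly).
    k_sd
        Multiplier on the negative-control standard deviation (default 4).

    The loss cutoff equals the anchor mean provided it lies at least
    ``k_sd`` standard deviations below the negative-control mean
    (``validated=True``); otherwise it falls back to
    ``neg_mean - k_sd * neg_sd`` with a warning.  The gain cutoff is the
    symmetric ``neg_mean + k_sd * neg_sd``.
    """
    if len(negative_values) < 2:
        raise CalibrationError(
            f"need >= 2 negative-control normalized values, got {len(negative_values)}"
        )
    if anchor is None:
        raise CalibrationError("anchor effect is required")
    anchor_value = anchor.mean_normalized if isinstance(anchor, NormalizedEffect) else float(anchor)

    n = len(negative_values)
    neg_mean = sum(negative_values) / n
    neg_var = sum((v - neg_mean) ** 2 for v in negative_values) / (n - 1)
    neg_sd = math.sqrt(neg_var)
    if neg_sd == 0.0:
        raise CalibrationError("negative controls are degenerate (zero dispersion)")

    lower_bound = neg_mean - k_sd * neg_sd
    validated = anchor_value <= lower_bound
    if validated:
        loss_threshold = anchor_value
    else:
        loss_threshold = lower_bound
        msg = (
            f"calibration: anchor {anchor_value:.4f} does not exceed the "
            f"{k_sd:g}-SD bound {lower_bound:.4f}; falling back to the bound"
        )
        if qc_log is not None:
            qc_log.append(msg)
            logger.debug(msg)
        else:
            logger.warning(msg)
    gain_threshold = neg_mean + k_sd * neg_sd

    return ThresholdSet(
        loss_threshold=loss_threshold,
        gain_threshold=gain_threshold,
        k_sd=k_sd,
        neg_mean=neg_mean,
        neg_sd=neg_sd,
        anchor_value=anchor_value,
        validated=validated,
    )
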