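"""Two-round duplex classification and gene-level hit calling.

Round 1 screens every candidate gene with (at least) two independent
reagents.  A gene is a hit when two or more reagents produce the same
phenotype direction and each such reagent has verified activity
(knockdown for siRNA duplexes, mimic activity for miRNA mimics).  When
exactly one reagent is effective and every other reagent is silent both in
phenotype and in knockdown, the gene is a "split" carried into round 2 with
fresh reagents; the split is confirmed only if both round-2 reagents are
effective in the pending direction.  Every other pattern is a negative.

Each decision carries a machine-readable rationale of the rule that fired.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .calibration import ThresholdSet, calibrate_thresholds, negative_control_values
from .quantification import (
    DEFAULT_KNOCKDOWN_CUTOFF,
    KnockdownResult,
    NormalizedEffect,
    normalize_to_control,
    quantify_all_knockdowns,
)
from .screen_model import Screen

__all__ = [
    "Phenotype",
    "HitStatus",
    "DuplexCall",
    "GeneDecision",
    "ScreenCallResult",
    "HitCallingError",
    "classify_duplex",
    "decide_gene_round1",
    "decide_gene_round2",
    "call_screen",
    "tally_decisions",
]


class HitCallingError(ValueError):
    pass


class Phenotype(str, enum.Enum):
    LOSS = "LOSS"
    GAIN = "GAIN"
    NONE = "NONE"


class HitStatus(str, enum.Enum):
    HIT_LOSS = "HIT_LOSS"
    HIT_GAIN = "HIT_GAIN"
    ROUND2_PENDING = "ROUND2_PENDING"
    NEGATIVE = "NEGATIVE"


@dataclass(frozen=True)
class DuplexCall:
    """Per-reagent classification against a calibrated threshold set.

    ``knockdown_positive`` is ``None`` when no qRT-PCR measurement exists for
    the reagent; a phenotype-positive call with unknown knockdown can never
    support a hit ("unverified knockdown").
    """

    reagent_id: str
    phenotype: Phenotype
    knockdown_positive: Optional[bool]

    @property
    def effective(self) -> bool:
        return self.phenotype is not Phenotype.NONE and self.knockdown_positive is True


@dataclass(frozen=True)
class GeneDecision:
    gene: str
    status: HitStatus
    decided_in_round: int
    rationale: str
    direction: Optional[Phenotype] = None


def classify_duplex(
    effect: NormalizedEffect,
    kd: Optional[KnockdownResult],
    thresholds: ThresholdSet,
) -> DuplexCall:
    """Map a reagent's normalized effect and knockdown onto a DuplexCall.

    A mean normalized ciliation exactly equal to a threshold counts as
    crossing it, so the anchor reagent always scores positive against the
    threshold it defines.
    """
    if kd is not None and kd.reagent_id != effect.reagent_id:
        raise HitCallingError(
            f"effect and knockdown refer to different reagents: "
            f"{effect.reagent_id!r} vs {kd.reagent_id!r}"
        )
    if effect.mean_normalized <= thresholds.loss_threshold:
        phenotype = Phenotype.LOSS
    elif effect.mean_normalized >= thresholds.gain_threshold:
        phenotype = Phenotype.GAIN
    else:
        phenotype = Phenotype.NONE
    return DuplexCall(
        reagent_id=effect.reagent_id,
        phenotype=phenotype,
        knockdown_positive=None if kd is None else kd.knockdown_positive,
    )


def _hit_status(direction: Phenotype) -> HitStatus:
    return HitStatus.HIT_LOSS if direction is Phenotype.LOSS else HitStatus.HIT_GAIN


def decide_gene_round1(
    gene: str, calls: Sequence[DuplexCall], allow_multi: bool = False
) -> GeneDecision:
    """Apply the round-1 decision rules to a gene's reagent calls.

    With the standard two-duplex design (``allow_multi=False``, exactly two
    calls required):

    * both effective in the same direction -> hit, decided in round 1;
    * exactly one effective, and the other silent in phenotype *and*
      knockdown-negative -> split, carried to round 2;
    * anything else -> negative.

    With ``allow_multi=True`` (>= 2 calls) a hit requires >= 2 effective
    reagents in one direction, none effective in the opposite direction and
    no knockdown-positive phenotype-silent reagent; a split requires exactly
    one effective reagent with every other reagent phenotype-silent and
    knockdown-negative.
    """
    if not allow_multi and len(calls) != 2:
        raise HitCallingError(
            f"gene {gene!r}: round 1 requires exactly 2 duplex calls, got {len(calls)}"
        )
    if allow_multi and len(calls) < 2:
        raise HitCallingError(
            f"gene {gene!r}: round 1 requires >= 2 duplex calls, got {len(calls)}"
        )

    unverified = [
        c for c in calls if c.phenotype is not Phenotype.NONE and c.knockdown_positive is None
    ]
    if unverified:
        ids = ",".join(c.reagent_id for c in unverified)
        return GeneDecision(
            gene, HitStatus.NEGATIVE, 1, f"round1:negative:unverified_knockdown[{ids}]"
        )

    effective = [c for c in calls if c.effective]
    directions = {c.phenotype for c in effective}

    if len(effective) >= 2 and len(directions) == 1:
        direction = effective[0].phenotype
        discordant = [
            c
            for c in calls
            if c.phenotype is Phenotype.NONE and c.knockdown_positive is True
        ]
        if discordant:
            ids = ",".join(c.reagent_id for c in discordant)
            return GeneDecision(
                gene,
                HitStatus.NEGATIVE,
                1,
                f"round1:negative:knockdown_without_phenotype[{ids}]",
                direction=None,
            )
        return GeneDecision(
            gene,
            _hit_status(direction),
            1,
            f"round1:hit:{len(effective)}_effective_{direction.value.lower()}",
            direction=direction,
        )

    if len(directions) > 1:
        return GeneDecision(
            gene, HitStatus.NEGATIVE, 1, "round1:negative:opposite_directions"
        )

    if len(effective) == 1:
        others = [c for c in calls if not c.effective]
        if all(
            c.phenotype is Phenotype.NONE and c.knockdown_positive is False
            for c in others
        ):
            direction = effective[0].phenotype
            return GeneDecision(
                gene,
                HitStatus.ROUND2_PENDING,
                1,
                f"round1:split:{effective[0].reagent_id}_{direction.value.lower()}",
                direction=direction,
            )
        return GeneDecision(
            gene, HitStatus.NEGATIVE, 1, "round1:negative:discordant_split"
        )

    return GeneDecision(gene, HitStatus.NEGATIVE, 1, "round1:negative:no_effective_duplex")


def decide_gene_round2(
    pending: GeneDecision, calls: Sequence[DuplexCall]
) -> GeneDecision:
    """Resolve a round-1 split with two fresh reagents.

    The split is confirmed as a hit only if *both* round-2 reagents are
    effective in the pending direction; every other round-2 outcome is a
    negative.
    """
    if pending.status is not HitStatus.ROUND2_PENDING:
        raise HitCallingError(
            f"gene {pending.gene!r}: round-2 calls supplied but gene is not "
            f"pending (status {pending.status.value})"
        )
    if len(calls) < 2:
        raise HitCallingError(
            f"gene {pending.gene!r}: round 2 requires >= 2 duplex calls, got {len(calls)}"
        )
    direction = pending.direction
    confirmed = [c for c in calls if c.effective and c.phenotype is direction]
    if len(confirmed) == len(calls):
        return GeneDecision(
            pending.gene,
            _hit_status(direction),
            2,
            f"round2:hit:confirmed_{direction.value.lower()}",
            direction=direction,
        )
    failed = ",".join(c.reagent_id for c in calls if c not in confirmed)
    return GeneDecision(
        pending.gene,
        HitStatus.NEGATIVE,
        2,
        f"round2:negative:unconfirmed[{failed}]",
        direction=None,
    )


# ---------------------------------------------------------------------------
# whole-screen orchestration
# ---------------------------------------------------------------------------


@dataclass
class ScreenCallResult:
    decisions: dict[str, GeneDecision]
    tallies: pd.DataFrame
    thresholds: ThresholdSet
    effects: dict[str, NormalizedEffect]
    knockdown: dict[str, KnockdownResult]
    calls: dict[str, DuplexCall]
    gene_categories: dict[str, str]

    def count(self, status: HitStatus) -> int:
        return sum(1 for d in self.decisions.values() if d.status is status)


def _pick_anchor(screen: Screen, effects: Mapping[str, NormalizedEffect]) -> str:
    """Default anchor: the weakest-effect positive control (conservative)."""
    candidates = [
        r.reagent_id
        for r in screen.positive_control_reagents()
        if r.reagent_id in effects
    ]
    if not candidates:
        raise HitCallingError(
            "no positive-control reagent with count data; specify the anchor "
            "reagent explicitly"
        )
    return max(candidates, key=lambda rid: effects[rid].mean_normalized)


def call_screen(
    screen: Screen,
    thresholds: Optional[ThresholdSet] = None,
    effects: Optional[dict[str, NormalizedEffect]] = None,
    knockdown: Optional[dict[str, KnockdownResult]] = None,
    k_sd: float = 4.0,
    anchor_reagent_id: Optional[str] = None,
    knockdown_cutoff: float = DEFAULT_KNOCKDOWN_CUTOFF,
) -> ScreenCallResult:
    """Run quantification, calibration and the two-round automaton end to end.

    Precomputed ``effects``/``knockdown``/``thresholds`` are honoured when
    given; anything missing is computed from the screen.  Returns one
    decision per candidate gene plus status-by-category tallies.

    For ``MIRNA_MIMIC`` reagents the qPCR slot is interpreted as a reagent
    *activity* assay (a mimic raises rather than lowers its target), so the
    ``knockdown_positive`` flag doubles as "activity confirmed".
    """
    if effects is None:
        effects = normalize_to_control(screen)
    if knockdown is None:
        knockdown = quantify_all_knockdowns(screen, cutoff=knockdown_cutoff)
    if thresholds is None:
        if anchor_reagent_id is None:
            anchor_reagent_id = _pick_anchor(screen, effects)
        if anchor_reagent_id not in effects:
            raise HitCallingError(
                f"anchor reagent {anchor_reagent_id!r} has no normalized effect"
            )
        thresholds = calibrate_thresholds(
            negative_control_values(screen, effects),
            effects[anchor_reagent_id],
            k_sd=k_sd,
            qc_log=screen.qc_log,
        )

    calls: dict[str, DuplexCall] = {}

    def _call_for(reagent_id: str) -> Optional[DuplexCall]:
        eff = effects.get(reagent_id)
        if eff is None:
            return None
        call = classify_duplex(eff, knockdown.get(reagent_id), thresholds)
        calls[reagent_id] = call
        return call

    decisions: dict[str, GeneDecision] = {}
    for record in screen.candidate_genes():
        round1 = [
            c
            for r in screen.reagents_for_gene(record.gene, round=1)
            if (c := _call_for(r.reagent_id)) is not None
        ]
        if len(round1) < 2:
            raise HitCallingError(
                f"gene {record.gene!r}: fewer than 2 round-1 reagents with count data"
            )
        decision = decide_gene_round1(record.gene, round1, allow_multi=True)

        round2_reagents = screen.reagents_for_gene(record.gene, round=2)
        round2 = [
            c
            for r in round2_reagents
            if (c := _call_for(r.reagent_id)) is not None
        ]
        if round2:
            # raises if the gene was not pending after round 1
            decision = decide_gene_round2(decision, round2)
        elif decision.status is HitStatus.ROUND2_PENDING:
            screen.qc_log.append(
                f"QC: gene {record.gene!r} is a round-1 split with no round-2 data"
            )
        decisions[record.gene] = decision

    categories = {g.gene: g.category.value for g in screen.candidate_genes()}
    return ScreenCallResult(
        decisions=decisions,
        tallies=tally_decisions(decisions, categories),
        thresholds=thresholds,
        effects=effects,
        knockdown=knockdown,
        calls=calls,
        gene_categories=categories,
    )


def tally_decisions(
    decisions: Mapping[str, GeneDecision],
    gene_categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Exact counts of decision statuses per gene category."""
    gene_categories = dict(gene_categories or {})
    statuses = [s.value for s in HitStatus]
    rows: dict[str, dict[str, int]] = {}
    for gene, dec in decisions.items():
        cat = gene_categories.get(gene, "UNKNOWN")
        row = rows.setdefault(cat, {s: 0 for s in statuses})
        row[dec.status.value] += 1
    df = pd.DataFrame.from_dict(rows, orient="index", columns=statuses).fillna(0).astype(int)
    df.index.name = "category"
    df = df.sort_index()
    df.loc["TOTAL"] = df.sum()
    return df
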