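from __future__ import annotations

import itertools

import pytest

from ciliascreen.calibration import ThresholdSet
from ciliascreen.fixtures import ANCHOR_REAGENT_ID, build_reference_screen
from ciliascreen.hit_calling import (
    DuplexCall,
    GeneDecision,
    HitCallingError,
    HitStatus,
    Phenotype,
    call_screen,
    classify_duplex,
    decide_gene_round1,
    decide_gene_round2,
    tally_decisions,
)
from ciliascreen.quantification import KnockdownResult, NormalizedEffect


THRESHOLDS = ThresholdSet(
    loss_threshold=0.65,
    gain_threshold=1.20,
    k_sd=4.0,
    neg_mean=1.0,
    neg_sd=0.05,
    anchor_value=0.65,
    validated=True,
)


def effect(rid: str, mean: float) -> NormalizedEffect:
    return NormalizedEffect(rid, (mean,), mean, 0.0, 0.0, 1)


def kd(rid: str, remaining: float) -> KnockdownResult:
    return KnockdownResult(rid, remaining, 0.0, remaining <= 0.6)


def call(phenotype: Phenotype, knockdown_positive, rid="siX-1") -> DuplexCall:
    return DuplexCall(rid, phenotype, knockdown_positive)


class TestClassifyDuplex:
    def test_strong_loss_with_knockdown_is_effective(self):
        c = classify_duplex(effect("siX-1", 0.25), kd("siX-1", 0.30), THRESHOLDS)
        assert c.phenotype is Phenotype.LOSS
        assert c.knockdown_positive is True
        assert c.effective

    def test_null_duplex(self):
        c = classify_duplex(effect("siX-1", 1.00), kd("siX-1", 1.00), THRESHOLDS)
        assert c.phenotype is Phenotype.NONE
        assert not c.effective

    def test_exactly_at_loss_threshold_scores_loss(self):
        c = classify_duplex(effect("siX-1", 0.65), kd("siX-1", 0.30), THRESHOLDS)
        assert c.phenotype is Phenotype.LOSS

    def test_exactly_at_gain_threshold_scores_gain(self):
        c = classify_duplex(effect("siX-1", 1.20), kd("siX-1", 0.30), THRESHOLDS)
        assert c.phenotype is Phenotype.GAIN

    def test_missing_knockdown_is_unknown(self):
        c = classify_duplex(effect("siX-1", 0.25), None, THRESHOLDS)
        assert c.knockdown_positive is None
        assert not c.effective

    def test_mismatched_reagents_rejected(self):
        with pytest.raises(HitCallingError, match="different reagents"):
            classify_duplex(effect("siX-1", 0.25), kd("siY-1", 0.30), THRESHOLDS)


def round1_oracle(c1: tuple[str, bool], c2: tuple[str, bool]) -> str:
    """Hand-written truth table for the published round-1 rules.

    Each call is (phenotype, knockdown_positive).  Written independently of
    the implementation: a hit needs both duplexes effective in the same
    direction; a split needs exactly one effective duplex with the other
    silent in both phenotype and knockdown; everything else is negative.
    """

    def eff(c):
        return c[0] != "NONE" and c[1]

    if eff(c1) and eff(c2):
        if c1[0] == c2[0]:
            return "HIT_LOSS" if c1[0] == "LOSS" else "HIT_GAIN"
        return "NEGATIVE"
    if eff(c1) or eff(c2):
        other = c2 if eff(c1) else c1
        if other[0] == "NONE" and other[1] is False:
            return "ROUND2_PENDING"
        return "NEGATIVE"
    return "NEGATIVE"


class TestRound1TruthTable:
    COMBOS = list(
        itertools.product(
            itertools.product(["LOSS", "GAIN", "NONE"], [True, False]), repeat=2
        )
    )

    @pytest.mark.parametrize("c1,c2", COMBOS, ids=lambda c: f"{c[0]}-{c[1]}")
    def test_agrees_with_truth_table(self, c1, c2):
        calls = [
            call(Phenotype(c1[0]), c1[1], "siX-1"),
            call(Phenotype(c2[0]), c2[1], "siX-2"),
        ]
        decision = decide_gene_round1("X", calls)
        assert decision.status.value == round1_oracle(c1, c2)
        assert decision.decided_in_round == 1

    def test_exhaustive_count(self):
        assert len(self.COMBOS) == 36


class TestRound1Specifics:
    def test_both_loss_with_knockdown_is_a_round1_hit(self):
        decision = decide_gene_round1(
            "FEZ1", [call(Phenotype.LOSS, True, "a"), call(Phenotype.LOSS, True, "b")]
        )
        assert decision.status is HitStatus.HIT_LOSS
        assert decision.direction is Phenotype.LOSS

    def test_split_goes_to_round2(self):
        decision = decide_gene_round1(
            "SYNE1", [call(Phenotype.LOSS, True, "a"), call(Phenotype.NONE, False, "b")]
        )
        assert decision.status is HitStatus.ROUND2_PENDING
        assert decision.direction is Phenotype.LOSS

    def test_silent_duplex_with_knockdown_is_negative(self):
        decision = decide_gene_round1(
            "X", [call(Phenotype.LOSS, True, "a"), call(Phenotype.NONE, True, "b")]
        )
        assert decision.status is HitStatus.NEGATIVE

    def test_opposite_effective_directions_are_negative(self):
        decision = decide_gene_round1(
            "X", [call(Phenotype.LOSS, True, "a"), call(Phenotype.GAIN, True, "b")]
        )
        assert decision.status is HitStatus.NEGATIVE
        assert "opposite" in decision.rationale

    def test_unverified_knockdown_routes_to_negative(self):
        decision = decide_gene_round1(
            "X", [call(Phenotype.LOSS, None, "a"), call(Phenotype.NONE, False, "b")]
        )
        assert decision.status is HitStatus.NEGATIVE
        assert "unverified" in decision.rationale

    def test_wrong_call_count_is_an_error(self):
        with pytest.raises(HitCallingError, match="exactly 2"):
            decide_gene_round1("X", [call(Phenotype.LOSS, True)])
        with pytest.raises(HitCallingError, match="exactly 2"):
            decide_gene_round1("X", [call(Phenotype.LOSS, True)] * 3)

    def test_determinism(self):
        calls = [call(Phenotype.LOSS, True, "a"), call(Phenotype.NONE, False, "b")]
        assert decide_gene_round1("X", calls) == decide_gene_round1("X", calls)


class TestMultiDuplexDesigns:
    def test_three_duplexes_two_effective_is_a_hit(self):
        calls = [
            call(Phenotype.LOSS, True, "a"),
            call(Phenotype.LOSS, True, "b"),
            call(Phenotype.NONE, False, "c"),
        ]
        decision = decide_gene_round1("X", calls, allow_multi=True)
        assert decision.status is HitStatus.HIT_LOSS

    def test_discordant_silent_duplex_blocks_the_hit(self):
        calls = [
            call(Phenotype.LOSS, True, "a"),
            call(Phenotype.LOSS, True, "b"),
            call(Phenotype.NONE, True, "c"),
        ]
        decision = decide_gene_round1("X", calls, allow_multi=True)
        assert decision.status is HitStatus.NEGATIVE

    def test_single_effective_with_all_silent_negatives_is_pending(self):
        calls = [
            call(Phenotype.LOSS, True, "a"),
            call(Phenotype.NONE, False, "b"),
            call(Phenotype.NONE, False, "c"),
        ]
        decision = decide_gene_round1("X", calls, allow_multi=True)
        assert decision.status is HitStatus.ROUND2_PENDING


PENDING_LOSS = GeneDecision("X", HitStatus.ROUND2_PENDING, 1, "round1:split", Phenotype.LOSS)


class TestRound2:
    def test_both_confirm_gives_round2_hit(self):
        decision = decide_gene_round2(
            PENDING_LOSS, [call(Phenotype.LOSS, True, "c"), call(Phenotype.LOSS, True, "d")]
        )
        assert decision.status is HitStatus.HIT_LOSS
        assert decision.decided_in_round == 2

    def test_neither_crosses_threshold_gives_negative(self):
        decision = decide_gene_round2(
            PENDING_LOSS, [call(Phenotype.NONE, True, "c"), call(Phenotype.NONE, True, "d")]
        )
        assert decision.status is HitStatus.NEGATIVE
        assert decision.decided_in_round == 2

    def test_one_effective_one_not_gives_negative(self):
        decision = decide_gene_round2(
            PENDING_LOSS, [call(Phenotype.LOSS, True, "c"), call(Phenotype.NONE, False, "d")]
        )
        assert decision.status is HitStatus.NEGATIVE
        assert "d" in decision.rationale

    def test_wrong_direction_confirmation_is_negative(self):
        decision = decide_gene_round2(
            PENDING_LOSS, [call(Phenotype.GAIN, True, "c"), call(Phenotype.GAIN, True, "d")]
        )
        assert decision.status is HitStatus.NEGATIVE

    def test_round2_calls_for_non_pending_gene_are_an_error(self):
        done = GeneDecision("X", HitStatus.HIT_LOSS, 1, "round1:hit", Phenotype.LOSS)
        with pytest.raises(HitCallingError, match="not.*pending"):
            decide_gene_round2(done, [call(Phenotype.LOSS, True)] * 2)


class TestCallScreen:
    def test_disc1_interactor_fixture_matches_published_outcomes(self):
        screen = build_reference_screen(categories=["DISC1_INTERACTOR"])
        result = call_screen(screen, anchor_reagent_id=ANCHOR_REAGENT_ID)
        losses = {g for g, d in result.decisions.items() if d.status is HitStatus.HIT_LOSS}
        assert losses == {"CEP63", "FEZ1", "PDE4B", "SYNE1"}
        assert result.decisions["SYNE1"].decided_in_round == 2
        assert result.decisions["CEP170"].status is HitStatus.NEGATIVE
        assert result.decisions["CEP170"].decided_in_round == 2

    def test_default_anchor_is_the_weakest_positive_control(self):
        screen = build_reference_screen(categories=["DISC1_INTERACTOR"])
        result = call_screen(screen)  # no anchor specified
        assert result.thresholds.anchor_value == pytest.approx(
            result.effects[ANCHOR_REAGENT_ID].mean_normalized
        )

    def test_tallies_are_exact_status_counts(self, reference_screen):
        result = call_screen(reference_screen, anchor_reagent_id=ANCHOR_REAGENT_ID)
        assert result.tallies.loc["TOTAL", "HIT_LOSS"] == 20
        assert result.tallies.loc["TOTAL", "HIT_GAIN"] == 3
        assert result.tallies.loc["TOTAL"].sum() == 41

    def test_determinism(self, reference_screen):
        r1 = call_screen(reference_screen, anchor_reagent_id=ANCHOR_REAGENT_ID)
        r2 = call_screen(
            build_reference_screen(), anchor_reagent_id=ANCHOR_REAGENT_ID
        )
        assert r1.decisions == r2.decisions
        assert r1.thresholds == r2.thresholds

    def test_empty_tally(self):
        tallies = tally_decisions({})
        assert tallies.loc["TOTAL"].sum() == 0


class TestStatisticalMonotonicity:
    def test_lowering_true_effect_never_reduces_hit_probability(self):
        from ciliascreen.synthetic_data import SimulationConfig, evaluate_design

        factors = {"f025": 0.25, "f050": 0.50, "f065": 0.65, "f080": 0.80, "f100": 1.0}
        config = SimulationConfig(
            n_genes={cls: 1 for cls in factors},
            effect_factors=factors,
            active_remaining=(0.2, 0.4),
            seed=5,
        )
        report = evaluate_design(config, 1000, seed=5)
        rates = [report.loc[cls, "hit_loss_rate"] for cls in factors]
        for weaker, stronger in zip(rates[1:], rates[:-1]):
            assert stronger >= weaker - 0.03  # Monte-Carlo slack
        assert rates[0] > 0.95
        assert rates[-1] < 0.01
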