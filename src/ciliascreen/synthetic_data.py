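"""Synthetic-screen generation and design evaluation.

The generative model mirrors the structure the analysis assumes:

* each experiment ``e`` draws a baseline ciliation probability
  ``p0_e ~ Normal(baseline_mean, baseline_sd)`` truncated to (0, 1);
* each reagent draws a true fraction-of-transcript-remaining, which a
  monotone dose-response link converts into a realized multiplicative
  effect on ciliation probability (no effect at remaining >= 1, full
  class effect at remaining <= ``dose_full_effect_at``);
* ciliated counts are ``Binomial(cells_per_condition, clip(p0_e * effect))``;
* qRT-PCR replicates are noisy observations of the true remaining fraction;
* cilium lengths are Gamma-distributed, with gain-class conditions shifted
  upward in mean.

A single seeded generator drives every draw in a documented, fixed order
(baselines, then per-duplex knockdowns, then counts experiment-major, then
qPCR replicates, then lengths), so a seed fully determines the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .hit_calling import HitStatus, call_screen
from .screen_model import (
    ConditionObservation,
    GeneCategory,
    GeneRecord,
    LengthMeasurement,
    QPCRMeasurement,
    QPCRMode,
    Reagent,
    ReagentClass,
    Screen,
)

__all__ = [
    "SimulationConfig",
    "SimulatedScreen",
    "simulate_screen",
    "write_screen_files",
    "simulate_lengths",
    "evaluate_design",
]

SCRAMBLED_IDS = ("scr-1", "scr-2")
STRONG_CONTROL_ID = "siIFT88-1"  # strong-loss positive control
ANCHOR_CONTROL_ID = "siPCM1-1"  # moderate-loss anchor


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic ciliation screen."""

    n_genes: Mapping[str, int] = field(
        default_factory=lambda: {"null": 8, "strong_loss": 4, "gain": 3}
    )
    effect_factors: Mapping[str, float] = field(
        default_factory=lambda: {"null": 1.0, "strong_loss": 0.25, "gain": 1.3}
    )
    n_experiments: int = 5
    cells_per_condition: int = 160
    baseline_mean: float = 0.55
    baseline_sd: float = 0.05
    active_remaining: tuple[float, float] = (0.2, 0.5)
    silent_remaining: tuple[float, float] = (0.8, 1.1)
    dose_full_effect_at: float = 0.4
    qpcr_noise_sd: float = 0.03
    qpcr_replicates: int = 3
    strong_control_effect: float = 0.25
    anchor_control_effect: float = 0.65
    control_length_mean_um: float = 2.5
    control_length_sd_um: float = 0.5
    gain_length_shift_um: float = 2.0
    n_lengths_control: int = 45
    n_lengths_condition: int = 43
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_mean < 1.0:
            raise ValueError(f"baseline_mean must be in (0,1), got {self.baseline_mean}")
        if self.baseline_sd < 0 or self.qpcr_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.cells_per_condition <= 0 or self.n_experiments <= 0:
            raise ValueError("cells_per_condition and n_experiments must be positive")
        if not 0.0 <= self.dose_full_effect_at < 1.0:
            raise ValueError("dose_full_effect_at must be in [0, 1)")
        missing = set(self.n_genes) - set(self.effect_factors)
        if missing:
            raise ValueError(f"no effect factor for gene classes: {sorted(missing)}")
        if any(f < 0 for f in self.effect_factors.values()):
            raise ValueError("effect factors must be >= 0")


@dataclass
class SimulatedScreen:
    screen: Screen
    ground_truth: pd.DataFrame
    config: SimulationConfig


def dose_response(remaining: float, factor: float, full_effect_at: float) -> float:
    """Realized multiplicative effect from a true fraction remaining.

    Linear ramp: no effect at remaining >= 1, the full class ``factor`` at
    remaining <= ``full_effect_at``.
    """
    weight = (1.0 - remaining) / (1.0 - full_effect_at)
    weight = min(1.0, max(0.0, weight))
    return 1.0 + (factor - 1.0) * weight


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0.0:
        return mean
    for _ in range(1000):
        value = rng.normal(mean, sd)
        if 0.0 < value < 1.0:
            return value
    raise ValueError("could not draw baseline in (0,1); check config")


def simulate_lengths(
    rng: np.random.Generator, n: int, mean_um: float, sd_um: float
) -> tuple[float, ...]:
    """Gamma-distributed cilium lengths with the given mean and SD."""
    shape = (mean_um / sd_um) ** 2
    scale = sd_um**2 / mean_um
    return tuple(float(v) for v in rng.gamma(shape, scale, size=n))


def simulate_screen(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> SimulatedScreen:
    """Generate a complete synthetic screen plus its ground-truth table."""
    if rng is None:
        rng = np.random.default_rng(config.seed)

    screen = Screen()
    for rid in SCRAMBLED_IDS:
        screen.reagents[rid] = Reagent(rid, None, ReagentClass.SCRAMBLED_CONTROL, 1)
    screen.reagents[STRONG_CONTROL_ID] = Reagent(
        STRONG_CONTROL_ID, "IFT88", ReagentClass.POSITIVE_CONTROL, 1
    )
    screen.reagents[ANCHOR_CONTROL_ID] = Reagent(
        ANCHOR_CONTROL_ID, "PCM1", ReagentClass.POSITIVE_CONTROL, 1
    )
    screen.add_gene(GeneRecord("IFT88", GeneCategory.CONTROL))
    screen.add_gene(GeneRecord("PCM1", GeneCategory.CONTROL))

    # draw order 1: per-experiment baselines
    baselines = [
        _truncated_normal(rng, config.baseline_mean, config.baseline_sd)
        for _ in range(config.n_experiments)
    ]

    # draw order 2: per-duplex true knockdown, in gene-class then gene order
    truth_rows: list[dict] = []
    effect_by_reagent: dict[str, float] = {rid: 1.0 for rid in SCRAMBLED_IDS}
    remaining_by_reagent: dict[str, float] = {}
    # positive controls: fixed, fully effective knockdown
    control_remaining = config.dose_full_effect_at * 0.75
    for rid, eff in (
        (STRONG_CONTROL_ID, config.strong_control_effect),
        (ANCHOR_CONTROL_ID, config.anchor_control_effect),
    ):
        effect_by_reagent[rid] = eff
        remaining_by_reagent[rid] = control_remaining

    for cls in config.n_genes:
        factor = config.effect_factors[cls]
        for i in range(config.n_genes[cls]):
            gene = f"{cls.upper().replace('_', '')}{i + 1:02d}"
            screen.add_gene(GeneRecord(gene, GeneCategory.RARE_VARIANT, {"class": cls}))
            for d in (1, 2):
                rid = f"si{gene}-{d}"
                screen.reagents[rid] = Reagent(rid, gene, ReagentClass.SIRNA, 1)
                remaining = float(rng.uniform(*config.active_remaining))
                realized = dose_response(remaining, factor, config.dose_full_effect_at)
                remaining_by_reagent[rid] = remaining
                effect_by_reagent[rid] = realized
                truth_rows.append(
                    {
                        "gene": gene,
                        "gene_class": cls,
                        "effect_factor": factor,
                        "reagent_id": rid,
                        "true_remaining": remaining,
                        "realized_effect": realized,
                    }
                )

    # draw order 3: binomial counts, experiment-major, layout order
    for e, p0 in enumerate(baselines, start=1):
        exp = f"exp{e}"
        for rid in screen.reagents:
            p = min(1.0, max(0.0, p0 * effect_by_reagent[rid]))
            ciliated = int(rng.binomial(config.cells_per_condition, p))
            screen.observations.append(
                ConditionObservation(exp, rid, ciliated, config.cells_per_condition)
            )

    # draw order 4: qPCR replicates around the true remaining fraction
    for rid, remaining in remaining_by_reagent.items():
        values = np.clip(
            rng.normal(remaining, config.qpcr_noise_sd, size=config.qpcr_replicates),
            0.0,
            None,
        )
        screen.qpcr[rid] = QPCRMeasurement(
            reagent_id=rid,
            mode=QPCRMode.PERCENT_REMAINING,
            replicate_values=tuple(float(v) * 100.0 for v in values),
        )

    # draw order 5: cilium lengths for the control and gain-class conditions
    screen.lengths[SCRAMBLED_IDS[0]] = LengthMeasurement(
        SCRAMBLED_IDS[0],
        simulate_lengths(
            rng,
            config.n_lengths_control,
            config.control_length_mean_um,
            config.control_length_sd_um,
        ),
    )
    for row in truth_rows:
        if config.effect_factors[row["gene_class"]] > 1.0:
            screen.lengths[row["reagent_id"]] = LengthMeasurement(
                row["reagent_id"],
                simulate_lengths(
                    rng,
                    config.n_lengths_condition,
                    config.control_length_mean_um + config.gain_length_shift_um,
                    config.control_length_sd_um,
                ),
            )

    screen.validate()
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene",
            "gene_class",
            "effect_factor",
            "reagent_id",
            "true_remaining",
            "realized_effect",
        ],
    )
    return SimulatedScreen(screen=screen, ground_truth=truth, config=config)


def write_screen_files(sim: SimulatedScreen, out_dir: str | Path) -> Path:
    """Write a simulated screen as the standard delimited-text tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    screen = sim.screen

    pd.DataFrame(
        [
            {
                "reagent_id": r.reagent_id,
                "gene": r.gene or "",
                "reagent_class": r.reagent_class.value,
                "round": r.round,
                "category": (
                    screen.gene_record(r.gene).category.value if r.gene else ""
                ),
            }
            for r in screen.reagents.values()
        ]
    ).to_csv(out_dir / "layout.csv", index=False)

    pd.DataFrame(
        [
            {
                "experiment_id": o.experiment_id,
                "reagent_id": o.reagent_id,
                "ciliated_count": o.ciliated_count,
                "total_count": o.total_count,
            }
            for o in screen.observations
        ]
    ).to_csv(out_dir / "counts.csv", index=False)

    qpcr_rows = []
    for q in screen.qpcr.values():
        for i, v in enumerate(q.replicate_values, start=1):
            qpcr_rows.append(
                {
                    "reagent_id": q.reagent_id,
                    "mode": q.mode.value,
                    "replicate": i,
                    "value": repr(v),
                    "reference_value": "",
                    "control_link": q.control_link or "",
                }
            )
    pd.DataFrame(qpcr_rows).to_csv(out_dir / "qpcr.csv", index=False)

    length_rows = [
        {"reagent_id": m.reagent_id, "length_um": repr(v)}
        for m in screen.lengths.values()
        for v in m.lengths_um
    ]
    pd.DataFrame(length_rows, columns=["reagent_id", "length_um"]).to_csv(
        out_dir / "lengths.csv", index=False
    )

    sim.ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return out_dir


# ---------------------------------------------------------------------------
# design evaluation
# ---------------------------------------------------------------------------


def evaluate_design(
    config: SimulationConfig,
    n_replicate_screens: int,
    seed: Optional[int] = None,
    k_sd: float = 4.0,
    knockdown_cutoff: float = 0.6,
) -> pd.DataFrame:
    """Monte-Carlo operating characteristics of the screen design.

    Runs ``simulate_screen`` followed by the full calling pipeline
    ``n_replicate_screens`` times and reports, per gene class: empirical
    loss/gain hit rates with binomial standard errors, and bias/RMSE of the
    per-duplex normalized-effect estimate against both the realized effect
    and the nominal class factor.
    """
    if n_replicate_screens < 1:
        raise ValueError("n_replicate_screens must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    per_class: dict[str, dict[str, list[float]]] = {
        cls: {"loss": [], "gain": [], "err_realized": [], "err_factor": []}
        for cls in config.n_genes
    }

    for _ in range(n_replicate_screens):
        sim = simulate_screen(config, rng=rng)
        result = call_screen(
            sim.screen,
            k_sd=k_sd,
            anchor_reagent_id=ANCHOR_CONTROL_ID,
            knockdown_cutoff=knockdown_cutoff,
        )
        class_of_gene = dict(zip(sim.ground_truth["gene"], sim.ground_truth["gene_class"]))
        for gene, decision in result.decisions.items():
            cls = class_of_gene[gene]
            per_class[cls]["loss"].append(decision.status is HitStatus.HIT_LOSS)
            per_class[cls]["gain"].append(decision.status is HitStatus.HIT_GAIN)
        for row in sim.ground_truth.itertuples(index=False):
            est = result.effects[row.reagent_id].mean_normalized
            acc = per_class[row.gene_class]
            acc["err_realized"].append(est - row.realized_effect)
            acc["err_factor"].append(est - row.effect_factor)

    rows = []
    for cls, acc in per_class.items():
        n_calls = len(acc["loss"])
        loss_rate = float(np.mean(acc["loss"])) if n_calls else float("nan")
        gain_rate = float(np.mean(acc["gain"])) if n_calls else float("nan")
        err_r = np.asarray(acc["err_realized"])
        err_f = np.asarray(acc["err_factor"])
        rows.append(
            {
                "gene_class": cls,
                "effect_factor": config.effect_factors[cls],
                "n_gene_calls": n_calls,
                "hit_loss_rate": loss_rate,
                "hit_loss_se": math.sqrt(max(loss_rate * (1 - loss_rate), 0.0) / n_calls)
                if n_calls
                else float("nan"),
                "hit_gain_rate": gain_rate,
                "hit_gain_se": math.sqrt(max(gain_rate * (1 - gain_rate), 0.0) / n_calls)
                if n_calls
                else float("nan"),
                "effect_bias_vs_realized": float(err_r.mean()) if err_r.size else float("nan"),
                "effect_bias_vs_factor": float(err_f.mean()) if err_f.size else float("nan"),
                "effect_rmse_vs_realized": float(np.sqrt((err_r**2).mean()))
                if err_r.size
                else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("gene_class")
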