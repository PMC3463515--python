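"""Packaged reference fixture: the qualitative outcome pattern of the screen.

``data/paper_outcomes.csv`` encodes, for 41 candidate genes plus controls,
the per-reagent outcome pattern (phenotype direction and knockdown status)
reconstructed from the published summary hit lists.  No raw counts were ever
published, so :func:`build_reference_screen` expands each pattern into a
deterministic count-level screen (five experiments, 200 cells/condition)
whose quantitative values are chosen to land each reagent unambiguously on
the intended side of the calibrated thresholds.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Optional

import pandas as pd

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

__all__ = ["load_paper_outcomes", "build_reference_screen", "ANCHOR_REAGENT_ID"]

ANCHOR_REAGENT_ID = "siPCM1-1"

N_EXPERIMENTS = 5
TOTAL_CELLS = 200

# ciliated counts per pattern (out of 200 cells); the scrambled reference
# averages 110 (= 55%), so loss -> ~0.25 normalized, anchor -> ~0.65,
# gain -> ~1.13 (beyond the +4 SD bound of ~1.04), none -> ~1.0
_CILIATED = {"loss": 28, "anchor": 72, "none": 110, "gain": 124}
_SCR1_CILIATED = (110, 110, 110, 110, 110)
_SCR2_CILIATED = (108, 112, 111, 107, 112)  # small jitter: non-degenerate controls

# triplicate percent-remaining values (0-100 scale)
_KD_YES = (28.0, 30.0, 32.0)
_KD_NO = (93.0, 95.0, 97.0)


def load_paper_outcomes() -> pd.DataFrame:
    """The packaged per-reagent outcome pattern table."""
    with resources.files("ciliascreen.data").joinpath("paper_outcomes.csv").open() as fh:
        return pd.read_csv(fh, dtype=str, keep_default_na=False)


def build_reference_screen(
    categories: Optional[Iterable[str]] = None,
    with_lengths: bool = True,
) -> Screen:
    """Expand the outcome pattern into a deterministic count-level screen.

    ``categories`` restricts the candidate genes (controls always included).
    With ``with_lengths`` the scrambled control and each gain-arm reagent get
    a fixed synthetic cilium-length sample.
    """
    outcomes = load_paper_outcomes()
    if categories is not None:
        wanted = {c.upper() for c in categories}
        keep = outcomes["category"].isin(wanted | {"", "CONTROL"})
        outcomes = outcomes[keep]

    screen = Screen()
    for row in outcomes.itertuples(index=False):
        gene = row.gene or None
        screen.reagents[row.reagent_id] = Reagent(
            row.reagent_id,
            gene,
            ReagentClass(row.reagent_class),
            int(row.round),
        )
        if gene is not None:
            screen.add_gene(GeneRecord(gene, GeneCategory(row.category)))

        if row.reagent_class == "SCRAMBLED_CONTROL":
            ciliated = _SCR1_CILIATED if row.reagent_id == "scr-1" else _SCR2_CILIATED
        else:
            ciliated = (_CILIATED[row.phenotype],) * N_EXPERIMENTS
        for e, c in enumerate(ciliated, start=1):
            screen.observations.append(
                ConditionObservation(f"exp{e}", row.reagent_id, c, TOTAL_CELLS)
            )

        if row.knockdown in ("yes", "no"):
            screen.qpcr[row.reagent_id] = QPCRMeasurement(
                reagent_id=row.reagent_id,
                mode=QPCRMode.PERCENT_REMAINING,
                replicate_values=_KD_YES if row.knockdown == "yes" else _KD_NO,
            )

    if with_lengths:
        import numpy as np

        rng = np.random.default_rng(20121003)  # fixed: fixture is deterministic
        from .synthetic_data import simulate_lengths

        screen.lengths["scr-1"] = LengthMeasurement(
            "scr-1", simulate_lengths(rng, 45, 2.5, 0.5)
        )
        gain_rows = outcomes[outcomes["phenotype"] == "gain"]
        for rid in gain_rows["reagent_id"]:
            screen.lengths[rid] = LengthMeasurement(
                rid, simulate_lengths(rng, 43, 4.5, 0.5)
            )

    screen.validate()
    return screen
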