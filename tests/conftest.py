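from __future__ import annotations

import pytest

from ciliascreen.screen_model import (
    ConditionObservation,
    GeneCategory,
    GeneRecord,
    Reagent,
    ReagentClass,
    Screen,
)


def make_screen(
    counts: dict[str, dict[str, tuple[int, int]]],
    classes: dict[str, ReagentClass] | None = None,
    genes: dict[str, str] | None = None,
) -> Screen:
    """Build an in-memory screen from nested {reagent: {experiment: (cil, tot)}}.

    ``classes`` defaults every reagent to SIRNA except ids starting with
    "scr" (scrambled).  ``genes`` maps reagent_id -> gene; defaults to the
    reagent id itself for non-scrambled reagents, each gene categorized as
    RARE_VARIANT.  Validation is deliberately skipped so tests can build
    minimal screens (e.g. single-duplex genes).
    """
    classes = classes or {}
    genes = genes or {}
    screen = Screen()
    for rid, per_exp in counts.items():
        rclass = classes.get(
            rid,
            ReagentClass.SCRAMBLED_CONTROL if rid.startswith("scr") else ReagentClass.SIRNA,
        )
        gene = None
        if rclass is not ReagentClass.SCRAMBLED_CONTROL:
            gene = genes.get(rid, rid)
            category = (
                GeneCategory.CONTROL
                if rclass is ReagentClass.POSITIVE_CONTROL
                else GeneCategory.RARE_VARIANT
            )
            screen.add_gene(GeneRecord(gene, category))
        screen.reagents[rid] = Reagent(rid, gene, rclass, 1)
        for exp, (cil, tot) in per_exp.items():
            screen.observations.append(ConditionObservation(exp, rid, cil, tot))
    return screen


@pytest.fixture
def reference_screen():
    from ciliascreen.fixtures import build_reference_screen

    return build_reference_screen()
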