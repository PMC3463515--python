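"""Domain types and delimited-text I/O for arrayed RNAi ciliation screens.

A screen is a collection of reagents (siRNA duplexes, miRNA mimics,
scrambled negative controls and positive-control duplexes) laid out over
genes, together with per-experiment ciliated/total cell counts, optional
qRT-PCR knockdown measurements and optional per-cilium length measurements.

All input tables are UTF-8 comma-delimited text with a header row:

``counts.csv``
    experiment_id, reagent_id, ciliated_count, total_count
``layout.csv``
    reagent_id, gene, reagent_class, round, category
``qpcr.csv``
    reagent_id, mode, replicate, value, reference_value, control_link
``lengths.csv``
    reagent_id, length_um

Gene names are case-preserving but matched case-insensitively throughout.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ReagentClass",
    "GeneCategory",
    "QPCRMode",
    "Reagent",
    "GeneRecord",
    "ConditionObservation",
    "QPCRMeasurement",
    "LengthMeasurement",
    "Screen",
    "ScreenValidationError",
    "read_screen",
    "write_results",
    "read_results",
    "DEFAULT_MIN_CELLS",
]

#: Protocol target for cells examined per condition per experiment.
DEFAULT_MIN_CELLS = 150


class ScreenValidationError(ValueError):
    """A malformed or inconsistent input row; message names the offending row."""


class ReagentClass(str, enum.Enum):
    SIRNA = "SIRNA"
    MIRNA_MIMIC = "MIRNA_MIMIC"
    SCRAMBLED_CONTROL = "SCRAMBLED_CONTROL"
    POSITIVE_CONTROL = "POSITIVE_CONTROL"


class GeneCategory(str, enum.Enum):
    DISC1_INTERACTOR = "DISC1_INTERACTOR"
    RARE_VARIANT = "RARE_VARIANT"
    COMMON_VARIANT = "COMMON_VARIANT"
    CONTROL = "CONTROL"


class QPCRMode(str, enum.Enum):
    CT = "CT"
    PERCENT_REMAINING = "PERCENT_REMAINING"


@dataclass(frozen=True)
class Reagent:
    """One transfected RNA reagent (duplex, mimic or control)."""

    reagent_id: str
    gene: Optional[str]
    reagent_class: ReagentClass
    round: int = 1

    def __post_init__(self) -> None:
        if self.round not in (1, 2):
            raise ScreenValidationError(
                f"reagent {self.reagent_id!r}: round must be 1 or 2, got {self.round!r}"
            )
        if self.reagent_class is ReagentClass.SCRAMBLED_CONTROL and self.gene is not None:
            raise ScreenValidationError(
                f"reagent {self.reagent_id!r}: scrambled control must not target a gene"
            )
        if self.reagent_class is not ReagentClass.SCRAMBLED_CONTROL and self.gene is None:
            raise ScreenValidationError(
                f"reagent {self.reagent_id!r}: non-scrambled reagent requires a gene"
            )


@dataclass
class GeneRecord:
    """A screened gene with its category and pass-through annotations."""

    gene: str
    category: GeneCategory
    annotations: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ConditionObservation:
    """Ciliated / total cell counts for one reagent in one experiment."""

    experiment_id: str
    reagent_id: str
    ciliated_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.total_count <= 0:
            raise ScreenValidationError(
                f"observation ({self.experiment_id}, {self.reagent_id}): "
                f"total_count must be positive, got {self.total_count}"
            )
        if not 0 <= self.ciliated_count <= self.total_count:
            raise ScreenValidationError(
                f"observation ({self.experiment_id}, {self.reagent_id}): "
                f"ciliated_count {self.ciliated_count} outside [0, {self.total_count}]"
            )


@dataclass
class QPCRMeasurement:
    """Replicated qRT-PCR readout for one reagent.

    In ``CT`` mode ``replicate_values`` are raw target Ct cycles and
    ``reference_values`` are the matching normalizer-gene Ct cycles;
    ``control_link`` names the scrambled-control measurement taken alongside.
    In ``PERCENT_REMAINING`` mode ``replicate_values`` are precomputed
    percent-RNA-remaining values on the 0-100 scale.
    """

    reagent_id: str
    mode: QPCRMode
    replicate_values: tuple[float, ...]
    reference_values: Optional[tuple[float, ...]] = None
    control_link: Optional[str] = None

    def __post_init__(self) -> None:
        self.replicate_values = tuple(float(v) for v in self.replicate_values)
        if self.reference_values is not None:
            self.reference_values = tuple(float(v) for v in self.reference_values)
        if len(self.replicate_values) < 3:
            raise ScreenValidationError(
                f"qPCR for {self.reagent_id!r}: at least 3 replicates required, "
                f"got {len(self.replicate_values)}"
            )
        if self.mode is QPCRMode.PERCENT_REMAINING:
            if any(v < 0 for v in self.replicate_values):
                raise ScreenValidationError(
                    f"qPCR for {self.reagent_id!r}: percent remaining must be >= 0"
                )
        else:
            if self.reference_values is None:
                raise ScreenValidationError(
                    f"qPCR for {self.reagent_id!r}: CT mode requires reference Ct values"
                )
            if len(self.reference_values) != len(self.replicate_values):
                raise ScreenValidationError(
                    f"qPCR for {self.reagent_id!r}: reference/target replicate "
                    f"counts differ"
                )


@dataclass
class LengthMeasurement:
    """Per-cilium length sample (micrometres) for one reagent condition."""

    reagent_id: str
    lengths_um: tuple[float, ...]

    def __post_init__(self) -> None:
        self.lengths_um = tuple(float(v) for v in self.lengths_um)
        if any(v <= 0 for v in self.lengths_um):
            raise ScreenValidationError(
                f"lengths for {self.reagent_id!r}: all lengths must be > 0"
            )

    @property
    def n(self) -> int:
        return len(self.lengths_um)


@dataclass
class Screen:
    """A cross-validated in-memory screen."""

    reagents: dict[str, Reagent] = field(default_factory=dict)
    genes: dict[str, GeneRecord] = field(default_factory=dict)  # keyed casefolded
    observations: list[ConditionObservation] = field(default_factory=list)
    qpcr: dict[str, QPCRMeasurement] = field(default_factory=dict)
    lengths: dict[str, LengthMeasurement] = field(default_factory=dict)
    qc_log: list[str] = field(default_factory=list)

    # -- gene access (case-insensitive match, case-preserving storage) -------

    def gene_record(self, gene: str) -> GeneRecord:
        return self.genes[gene.casefold()]

    def add_gene(self, record: GeneRecord) -> None:
        self.genes.setdefault(record.gene.casefold(), record)

    def candidate_genes(self) -> list[GeneRecord]:
        """Genes subject to hit calling (everything except controls)."""
        return [g for g in self.genes.values() if g.category is not GeneCategory.CONTROL]

    # -- reagent access ------------------------------------------------------

    def reagents_for_gene(self, gene: str, round: Optional[int] = None) -> list[Reagent]:
        key = gene.casefold()
        out = [
            r
            for r in self.reagents.values()
            if r.gene is not None and r.gene.casefold() == key
        ]
        if round is not None:
            out = [r for r in out if r.round == round]
        return out

    def scrambled_reagents(self) -> list[Reagent]:
        return [
            r
            for r in self.reagents.values()
            if r.reagent_class is ReagentClass.SCRAMBLED_CONTROL
        ]

    def positive_control_reagents(self) -> list[Reagent]:
        return [
            r
            for r in self.reagents.values()
            if r.reagent_class is ReagentClass.POSITIVE_CONTROL
        ]

    def experiments(self) -> list[str]:
        seen: dict[str, None] = {}
        for obs in self.observations:
            seen.setdefault(obs.experiment_id, None)
        return list(seen)

    def observations_for(self, reagent_id: str) -> list[ConditionObservation]:
        return [o for o in self.observations if o.reagent_id == reagent_id]

    def validate(self, min_cells: int = DEFAULT_MIN_CELLS) -> None:
        """Cross-check referential integrity and record QC warnings."""
        for obs in self.observations:
            if obs.reagent_id not in self.reagents:
                raise ScreenValidationError(
                    f"observation ({obs.experiment_id}, {obs.reagent_id}): "
                    f"unknown reagent"
                )
            if obs.total_count < min_cells:
                msg = (
                    f"QC: ({obs.experiment_id}, {obs.reagent_id}) examined only "
                    f"{obs.total_count} cells (< {min_cells})"
                )
                if msg not in self.qc_log:
                    self.qc_log.append(msg)
        for rid in list(self.qpcr) + list(self.lengths):
            if rid not in self.reagents:
                raise ScreenValidationError(f"qPCR/lengths refer to unknown reagent {rid!r}")
        for q in self.qpcr.values():
            if q.mode is QPCRMode.CT and q.control_link is not None:
                if q.control_link not in self.qpcr:
                    raise ScreenValidationError(
                        f"qPCR for {q.reagent_id!r}: control_link "
                        f"{q.control_link!r} has no measurement"
                    )
        for record in self.genes.values():
            if record.category is GeneCategory.CONTROL:
                continue
            n_round1 = len(self.reagents_for_gene(record.gene, round=1))
            if n_round1 < 2:
                raise ScreenValidationError(
                    f"gene {record.gene!r}: needs >= 2 round-1 reagents, has {n_round1}"
                )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, required: Sequence[str], label: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{label} table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScreenValidationError(
            f"{label} table {path}: missing columns {missing}; found {list(df.columns)}"
        )
    return df


def _int_field(raw: str, label: str) -> int:
    try:
        return int(raw)
    except (TypeError, ValueError):
        raise ScreenValidationError(f"{label}: not an integer: {raw!r}") from None


def _float_field(raw: str, label: str) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ScreenValidationError(f"{label}: not a number: {raw!r}") from None


def read_layout(path: str | Path) -> tuple[dict[str, Reagent], dict[str, GeneRecord]]:
    df = _read_table(path, ["reagent_id", "gene", "reagent_class", "round", "category"], "layout")
    reagents: dict[str, Reagent] = {}
    genes: dict[str, GeneRecord] = {}
    known_cols = {"reagent_id", "gene", "reagent_class", "round", "category"}
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        where = f"layout row {idx}"
        rid = row.reagent_id.strip()
        if not rid:
            raise ScreenValidationError(f"{where}: empty reagent_id")
        if rid in reagents:
            raise ScreenValidationError(f"{where}: duplicate reagent_id {rid!r}")
        gene = row.gene.strip() or None
        try:
            rclass = ReagentClass(row.reagent_class.strip())
        except ValueError:
            raise ScreenValidationError(
                f"{where}: unknown reagent_class {row.reagent_class!r}"
            ) from None
        try:
            category = GeneCategory(row.category.strip()) if row.category.strip() else None
        except ValueError:
            raise ScreenValidationError(f"{where}: unknown category {row.category!r}") from None
        rnd = _int_field(row.round, where + " (round)")
        reagents[rid] = Reagent(rid, gene, rclass, rnd)
        if gene is not None:
            key = gene.casefold()
            if key not in genes:
                if category is None:
                    raise ScreenValidationError(f"{where}: gene {gene!r} missing category")
                extra = {
                    c: getattr(row, c)
                    for c in df.columns
                    if c not in known_cols and getattr(row, c)
                }
                genes[key] = GeneRecord(gene, category, extra)
            elif category is not None and genes[key].category is not category:
                raise ScreenValidationError(
                    f"{where}: gene {gene!r} assigned conflicting categories"
                )
    return reagents, genes


def read_counts(path: str | Path) -> list[ConditionObservation]:
    df = _read_table(
        path, ["experiment_id", "reagent_id", "ciliated_count", "total_count"], "counts"
    )
    out: list[ConditionObservation] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        where = f"counts row {idx} ({row.experiment_id}, {row.reagent_id})"
        try:
            out.append(
                ConditionObservation(
                    experiment_id=row.experiment_id.strip(),
                    reagent_id=row.reagent_id.strip(),
                    ciliated_count=_int_field(row.ciliated_count, where),
                    total_count=_int_field(row.total_count, where),
                )
            )
        except ScreenValidationError as err:
            raise ScreenValidationError(f"{where}: {err}") from None
    return out


def read_qpcr(path: str | Path) -> dict[str, QPCRMeasurement]:
    df = _read_table(path, ["reagent_id", "mode", "replicate", "value"], "qpcr")
    grouped: dict[str, dict] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        where = f"qpcr row {idx} ({row.reagent_id})"
        rid = row.reagent_id.strip()
        try:
            mode = QPCRMode(row.mode.strip())
        except ValueError:
            raise ScreenValidationError(f"{where}: unknown mode {row.mode!r}") from None
        rec = grouped.setdefault(
            rid, {"mode": mode, "values": [], "refs": [], "link": None}
        )
        if rec["mode"] is not mode:
            raise ScreenValidationError(f"{where}: mixed qPCR modes for one reagent")
        rec["values"].append(_float_field(row.value, where))
        ref = getattr(row, "reference_value", "").strip() if hasattr(row, "reference_value") else ""
        if ref:
            rec["refs"].append(_float_field(ref, where + " (reference)"))
        link = getattr(row, "control_link", "").strip() if hasattr(row, "control_link") else ""
        if link:
            if rec["link"] not in (None, link):
                raise ScreenValidationError(f"{where}: conflicting control_link values")
            rec["link"] = link
    out: dict[str, QPCRMeasurement] = {}
    for rid, rec in grouped.items():
        out[rid] = QPCRMeasurement(
            reagent_id=rid,
            mode=rec["mode"],
            replicate_values=tuple(rec["values"]),
            reference_values=tuple(rec["refs"]) if rec["refs"] else None,
            control_link=rec["link"],
        )
    return out


def read_lengths(path: str | Path) -> dict[str, LengthMeasurement]:
    df = _read_table(path, ["reagent_id", "length_um"], "lengths")
    grouped: dict[str, list[float]] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        where = f"lengths row {idx} ({row.reagent_id})"
        grouped.setdefault(row.reagent_id.strip(), []).append(
            _float_field(row.length_um, where)
        )
    return {
        rid: LengthMeasurement(reagent_id=rid, lengths_um=tuple(vals))
        for rid, vals in grouped.items()
    }


def read_screen(
    counts: str | Path,
    layout: str | Path,
    qpcr: str | Path | None = None,
    lengths: str | Path | None = None,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> Screen:
    """Load and cross-validate a screen from delimited-text tables.

    Referential errors (counts/qPCR/lengths naming a reagent absent from the
    layout, ciliated > total, malformed numbers) raise
    :class:`ScreenValidationError` naming the offending row.  Conditions with
    fewer than ``min_cells`` total cells are recorded in ``Screen.qc_log`` as
    warnings, not errors.
    """
    reagents, genes = read_layout(layout)
    screen = Screen(reagents=reagents, genes=genes)
    screen.observations = read_counts(counts)
    if qpcr is not None:
        screen.qpcr = read_qpcr(qpcr)
    if lengths is not None:
        screen.lengths = read_lengths(lengths)
    screen.validate(min_cells=min_cells)
    return screen


# ---------------------------------------------------------------------------
# results I/O
# ---------------------------------------------------------------------------


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_results(
    out_dir: str | Path,
    decisions: Mapping[str, "GeneDecision"],
    effects: Mapping[str, "NormalizedEffect"] | None = None,
    thresholds: "ThresholdSet | None" = None,
    knockdown: Mapping[str, "KnockdownResult"] | None = None,
    qc_log: Iterable[str] = (),
    gene_categories: Mapping[str, str] | None = None,
) -> Path:
    """Write the machine-readable results tree and a human summary table.

    Produces ``results.json`` (full tree), ``summary.tsv`` (one row per gene)
    and ``tallies.tsv`` (category x status counts).  Reading the tree back
    with :func:`read_results` reproduces every call bit-exactly.
    """
    from .hit_calling import tally_decisions  # deferred: avoids import cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gene_categories = dict(gene_categories or {})

    tree = {
        "thresholds": _to_jsonable(thresholds) if thresholds is not None else None,
        "effects": {rid: _to_jsonable(e) for rid, e in (effects or {}).items()},
        "knockdown": {rid: _to_jsonable(k) for rid, k in (knockdown or {}).items()},
        "decisions": {g: _to_jsonable(d) for g, d in decisions.items()},
        "gene_categories": gene_categories,
        "qc_log": list(qc_log),
    }
    (out_dir / "results.json").write_text(json.dumps(tree, indent=2, sort_keys=True))

    rows = []
    for gene, dec in sorted(decisions.items()):
        rows.append(
            {
                "gene": dec.gene,
                "category": gene_categories.get(gene, ""),
                "status": dec.status.value,
                "decided_in_round": dec.decided_in_round,
                "direction": dec.direction.value if dec.direction is not None else "",
                "rationale": dec.rationale,
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=["gene", "category", "status", "decided_in_round", "direction", "rationale"],
    )
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)

    tallies = tally_decisions(decisions, gene_categories)
    tallies.to_csv(out_dir / "tallies.tsv", sep="\t")
    return out_dir


def read_results(out_dir: str | Path) -> dict:
    """Read a results tree written by :func:`write_results` back into types."""
    from .calibration import ThresholdSet
    from .hit_calling import GeneDecision, HitStatus, Phenotype
    from .quantification import KnockdownResult, NormalizedEffect

    tree = json.loads((Path(out_dir) / "results.json").read_text())
    decisions = {
        g: GeneDecision(
            gene=d["gene"],
            status=HitStatus(d["status"]),
            decided_in_round=d["decided_in_round"],
            rationale=d["rationale"],
            direction=Phenotype(d["direction"]) if d["direction"] is not None else None,
        )
        for g, d in tree["decisions"].items()
    }
    effects = {
        rid: NormalizedEffect(
            reagent_id=e["reagent_id"],
            per_experiment_normalized=tuple(e["per_experiment_normalized"]),
            mean_normalized=e["mean_normalized"],
            sd_across_experiments=e["sd_across_experiments"],
            sem=e["sem"],
            n_experiments=e["n_experiments"],
        )
        for rid, e in tree["effects"].items()
    }
    knockdown = {
        rid: KnockdownResult(
            reagent_id=k["reagent_id"],
            percent_remaining_mean=k["percent_remaining_mean"],
            percent_remaining_sd=k["percent_remaining_sd"],
            knockdown_positive=k["knockdown_positive"],
        )
        for rid, k in tree["knockdown"].items()
    }
    thresholds = None
    if tree["thresholds"] is not None:
        t = tree["thresholds"]
        thresholds = ThresholdSet(
            loss_threshold=t["loss_threshold"],
            gain_threshold=t["gain_threshold"],
            k_sd=t["k_sd"],
            neg_mean=t["neg_mean"],
            neg_sd=t["neg_sd"],
            anchor_value=t["anchor_value"],
            validated=t["validated"],
        )
    return {
        "decisions": decisions,
        "effects": effects,
        "knockdown": knockdown,
        "thresholds": thresholds,
        "gene_categories": tree["gene_categories"],
        "qc_log": tree["qc_log"],
    }
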