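"""Evidence data model and delimited-text IO.

One :class:`ExpressionObservation` is a single piece of expression
evidence: a gene (or a staining target), a cell, a sex, the modality
that produced the call, and a tri-level call (``absent`` /
``variable_dim`` / ``present``).  scRNA rows additionally carry the
number of detection thresholds passed (0-4); their level is *derived*
from that number and the two must agree.

Evidence files are UTF-8 TSV with the header::

    gene  cell  sex  modality  level  scrna_threshold_pass  stage  provenance  [intensity]

The optional ``intensity`` column carries an ordinal annotation
(low/medium/high) used only by the sexual-dimorphism scaling detector.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .knowledge import STAIN_TARGETS, KnowledgeBase

__all__ = [
    "ExpressionObservation",
    "EvidenceTable",
    "EvidenceError",
    "read_evidence",
    "write_evidence",
    "LEVELS",
    "MODALITIES",
    "STAIN_MODALITIES",
]

LEVELS = ("absent", "variable_dim", "present")
MODALITIES = (
    "reporter_allele",
    "fosmid_reporter",
    "promoter_transgene",
    "antibody_stain",
    "direct_stain",
    "scrna",
)
STAIN_MODALITIES = frozenset({"antibody_stain", "direct_stain"})
STAGES = ("young_adult", "larval")
INTENSITIES = ("low", "medium", "high")

SCHEMA_VERSION = "1.0"
COLUMNS = (
    "gene", "cell", "sex", "modality", "level",
    "scrna_threshold_pass", "stage", "provenance",
)
OPTIONAL_COLUMNS = ("intensity",)


class EvidenceError(ValueError):
    """Raised for schema violations in evidence tables."""


def scrna_level(threshold_pass: int) -> str:
    """Derive the tri-level call from the number of thresholds passed."""
    if threshold_pass == 0:
        return "absent"
    if threshold_pass in (1, 2):
        return "variable_dim"
    if threshold_pass in (3, 4):
        return "present"
    raise EvidenceError(f"scrna_threshold_pass must be 0-4, got {threshold_pass}")


@dataclass(frozen=True)
class ExpressionObservation:
    gene: str
    cell: str
    sex: str
    modality: str
    level: str
    scrna_threshold_pass: int | None = None
    stage: str = "young_adult"
    provenance: str = ""
    intensity: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("hermaphrodite", "male"):
            raise EvidenceError(f"unknown sex {self.sex!r}")
        if self.modality not in MODALITIES:
            raise EvidenceError(f"unknown modality {self.modality!r}")
        if self.level not in LEVELS:
            raise EvidenceError(f"unknown level {self.level!r}")
        if self.stage not in STAGES:
            raise EvidenceError(f"unknown stage {self.stage!r}")
        if self.intensity is not None and self.intensity not in INTENSITIES:
            raise EvidenceError(f"unknown intensity {self.intensity!r}")
        if self.modality == "scrna":
            if self.scrna_threshold_pass is None:
                raise EvidenceError(f"scrna row {self.gene}/{self.cell} lacks threshold count")
            if scrna_level(self.scrna_threshold_pass) != self.level:
                raise EvidenceError(
                    f"scrna row {self.gene}/{self.cell}: level {self.level!r} does not "
                    f"match {self.scrna_threshold_pass} thresholds passed"
                )
        elif self.scrna_threshold_pass is not None:
            raise EvidenceError(
                f"{self.modality} row {self.gene}/{self.cell} must not carry a "
                "scrna threshold count"
            )

    @property
    def key(self) -> tuple[str, str, str, str, str]:
        return (self.gene, self.cell, self.sex, self.modality, self.stage)

    @property
    def is_stain(self) -> bool:
        return self.modality in STAIN_MODALITIES


@dataclass
class EvidenceTable:
    """A validated collection of observations resolvable against a KB.

    ``strict=False`` (permissive mode) skips cell-name resolution so
    synthetic atlases with namespaced class names ("SYN-001") can flow
    through the same pipeline.
    """

    observations: list[ExpressionObservation]
    kb: KnowledgeBase | None = None
    strict: bool = True
    schema_version: str = SCHEMA_VERSION
    sex_coverage: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.validate()
        self.sex_coverage = frozenset(o.sex for o in self.observations)

    def validate(self) -> None:
        seen: set[tuple] = set()
        unknown_cells: list[str] = []
        for obs in self.observations:
            if obs.key in seen:
                raise EvidenceError(f"duplicate observation for {obs.key}")
            seen.add(obs.key)
            if obs.is_stain:
                if obs.gene not in STAIN_TARGETS:
                    raise EvidenceError(
                        f"staining row must target one of {sorted(STAIN_TARGETS)}, "
                        f"got {obs.gene!r}"
                    )
            elif self.kb is not None and obs.gene not in self.kb.genes:
                raise EvidenceError(f"unknown gene {obs.gene!r}")
            if self.kb is not None and self.strict:
                try:
                    self.kb.resolve_cell(obs.cell)
                except KeyError:
                    unknown_cells.append(obs.cell)
        if unknown_cells:
            names = ", ".join(sorted(set(unknown_cells)))
            raise EvidenceError(f"unknown cell {names}")

    def __iter__(self) -> Iterator[ExpressionObservation]:
        return iter(self.observations)

    def __len__(self) -> int:
        return len(self.observations)

    def filtered(self, **fields) -> "EvidenceTable":
        """Sub-table of observations matching all given field values."""
        obs = [
            o
            for o in self.observations
            if all(getattr(o, k) == v for k, v in fields.items())
        ]
        return EvidenceTable(obs, kb=self.kb, strict=self.strict)

    def extended(self, extra: Iterable[ExpressionObservation]) -> "EvidenceTable":
        return EvidenceTable(self.observations + list(extra), kb=self.kb, strict=self.strict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for o in self.observations:
            rows.append(
                {
                    "gene": o.gene,
                    "cell": o.cell,
                    "sex": o.sex,
                    "modality": o.modality,
                    "level": o.level,
                    "scrna_threshold_pass": (
                        "" if o.scrna_threshold_pass is None else o.scrna_threshold_pass
                    ),
                    "stage": o.stage,
                    "provenance": o.provenance,
                    "intensity": o.intensity or "",
                }
            )
        return pd.DataFrame(rows, columns=COLUMNS + OPTIONAL_COLUMNS)


def _obs_from_row(row: dict) -> ExpressionObservation:
    raw = row.get("scrna_threshold_pass", "")
    threshold = None
    if raw not in ("", None) and not (isinstance(raw, float) and pd.isna(raw)):
        threshold = int(raw)
    intensity = row.get("intensity") or None
    if isinstance(intensity, float) and pd.isna(intensity):
        intensity = None
    return ExpressionObservation(
        gene=str(row["gene"]),
        cell=str(row["cell"]),
        sex=str(row["sex"]),
        modality=str(row["modality"]),
        level=str(row["level"]),
        scrna_threshold_pass=threshold,
        stage=str(row.get("stage") or "young_adult"),
        provenance=str(row.get("provenance") or ""),
        intensity=intensity,
    )


def read_evidence(
    path: str | Path | io.TextIOBase,
    kb: KnowledgeBase | None = None,
    strict: bool = True,
) -> EvidenceTable:
    """Read a TSV evidence file and validate it against *kb*."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise EvidenceError(f"evidence header missing columns: {missing}")
    observations = [_obs_from_row(row) for row in df.to_dict("records")]
    return EvidenceTable(observations, kb=kb, strict=strict)


def write_evidence(table: EvidenceTable, path: str | Path, header_comment: str | None = None) -> None:
    """Write a TSV evidence file (optionally with a ``#`` provenance header)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        table.to_frame().to_csv(fh, sep="\t", index=False)


def dim(obs: ExpressionObservation) -> ExpressionObservation:
    """Copy of an observation with its level downgraded to variable_dim."""
    return replace(obs, level="variable_dim")
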