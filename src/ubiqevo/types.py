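"""Core domain types shared across the pipeline.

Coordinates are 1-based, inclusive, in protein space everywhere in the public
API.  Alignment columns are 0-based and internal only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: Sentinel for "no ortholog in this organism" in residue vectors.
MISSING: Optional[str] = None


class ValidationError(ValueError):
    """An input record violated a type invariant."""


@dataclass(frozen=True)
class SiteRecord:
    """One modified residue on a human protein (1-based position)."""

    protein_id: str
    position: int
    residue: str = "K"
    modification: str = "ubiquitination"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"{self.protein_id}: position must be >= 1, got {self.position}"
            )
        if len(self.residue) != 1 or self.residue not in AMINO_ACIDS:
            raise ValidationError(
                f"{self.protein_id}@{self.position}: bad residue {self.residue!r}"
            )


@dataclass(frozen=True)
class OrganismOrder:
    """Reference organisms ordered by divergence from human, nearest first.

    ``epochs`` maps a named divergence boundary to its cut-point: boundary
    ``b`` lies between organisms ``names[b-1]`` and ``names[b]``; ``b ==
    len(names)`` denotes the boundary beyond the most distant organism.
    """

    names: tuple
    epochs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if len(set(self.names)) != len(self.names):
            raise ValidationError("organism names must be unique")
        for epoch, b in self.epochs.items():
            if not 0 <= b <= len(self.names):
                raise ValidationError(
                    f"epoch {epoch!r}: boundary {b} outside [0, {len(self.names)}]"
                )

    def __len__(self) -> int:
        return len(self.names)

    def index(self, organism: str) -> int:
        return self.names.index(organism)

    def boundary_of(self, epoch: str) -> int:
        if epoch not in self.epochs:
            raise KeyError(
                f"unknown epoch {epoch!r}; known: {sorted(self.epochs)}"
            )
        return self.epochs[epoch]

    def label(self, boundary: int) -> str:
        """Human-readable label for a boundary index (named epoch if any)."""
        for epoch, b in self.epochs.items():
            if b == boundary:
                return epoch
        if boundary == 0:
            return "human-lineage"
        if boundary >= len(self.names):
            return "ancestral"
        return f"after:{self.names[boundary - 1]}"


@dataclass
class AlignedOrthologPair:
    """Pairwise global alignment of a human protein and one ortholog."""

    human_id: str
    organism: str
    aligned_human: str
    aligned_ortholog: str
    ortholog_id: str = ""
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.aligned_human) != len(self.aligned_ortholog):
            raise ValidationError(
                f"{self.human_id}/{self.organism}: aligned lengths differ "
                f"({len(self.aligned_human)} vs {len(self.aligned_ortholog)})"
            )

    @property
    def human_sequence(self) -> str:
        return self.aligned_human.replace(GAP, "")

    @property
    def ortholog_sequence(self) -> str:
        return self.aligned_ortholog.replace(GAP, "")

    @property
    def column_of_human_position(self) -> dict:
        """Map 1-based human position -> 0-based alignment column."""
        cols = {}
        pos = 0
        for col, ch in enumerate(self.aligned_human):
            if ch != GAP:
                pos += 1
                cols[pos] = col
        return cols


@dataclass(frozen=True)
class SiteObservation:
    """A human position paired with its orthologous residue in one organism.

    ``ortholog_residue`` is an amino acid, '-' for a gap, or None when the
    organism has no ortholog of the protein at all (MISSING).
    ``region`` distinguishes the modified site from its flanking background.
    """

    protein_id: str
    position: int
    human_residue: str
    organism: str
    ortholog_residue: Optional[str]
    region: str = "sites"  # "sites" | "flanks"

    def __post_init__(self) -> None:
        r = self.ortholog_residue
        if r is not None and r != GAP and r not in AMINO_ACIDS:
            raise ValidationError(
                f"{self.protein_id}@{self.position}/{self.organism}: "
                f"bad ortholog residue {r!r}"
            )


@dataclass(frozen=True)
class GainEvent:
    """The inferred first appearance of a site along the divergence order."""

    site: SiteRecord
    boundary: int          # cut-point index in the OrganismOrder
    epoch: str             # label of that boundary (named epoch if configured)
    residues: tuple        # per-organism residue vector supporting the call
    low_coverage: bool = False


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of one category at one epoch."""

    epoch: str
    category: str
    observed: int
    expected: float
    p_value: float
    corrected_p: float
    direction: str  # "enriched" | "depleted"
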