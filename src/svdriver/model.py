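"""Shared data model and coordinate conventions.

All genomic coordinates are held 0-based, half-open. Readers for 1-based
inclusive formats (VCF, GTF-derived tables) convert exactly once at parse
time; BED/BEDPE inputs are taken as already 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

SV_TYPES = ("DEL", "DUP", "INV", "TRA", "INS", "BND")
ORIENTATIONS = ("head", "tail")
STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def distance_to_position(self, chrom: str, pos: int) -> Optional[int]:
        """Base-pair distance from a position to this interval (0 if inside);
        None when on another chromosome."""
        if chrom != self.chrom:
            return None
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - (self.end - 1)
        return 0


@dataclass(frozen=True)
class BreakpointEnd:
    chrom: str
    position: int
    orientation: str = "tail"  # tail: retained segment extends to lower coords

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("breakpoint position must be >= 0")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"invalid orientation {self.orientation!r}")


@dataclass(frozen=True)
class BreakpointJunction:
    """One novel adjacency between two oriented genomic positions."""

    id: str
    pos_a: BreakpointEnd
    pos_b: BreakpointEnd
    sv_type: str = "BND"
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"invalid sv_type {self.sv_type!r}")
        if (
            self.sv_type in ("DEL", "DUP", "INV")
            and self.pos_a.chrom == self.pos_b.chrom
            and not self.pos_a.position < self.pos_b.position
        ):
            raise ValueError(
                f"junction {self.id}: {self.sv_type} requires pos_a < pos_b"
            )

    @property
    def is_intra(self) -> bool:
        return self.pos_a.chrom == self.pos_b.chrom

    def positions(self) -> list[tuple[str, int]]:
        return [
            (self.pos_a.chrom, self.pos_a.position),
            (self.pos_b.chrom, self.pos_b.position),
        ]

    def span(self) -> Optional[GenomicInterval]:
        """Derived DEL/DUP/INV interval; None for other types."""
        if self.sv_type in ("DEL", "DUP", "INV") and self.is_intra:
            return GenomicInterval(
                self.pos_a.chrom, self.pos_a.position, self.pos_b.position
            )
        return None


@dataclass
class SVSet:
    """All de novo breakpoint junctions of one patient.

    A multi-junction complex rearrangement is simply a set of junctions
    sharing the patient id; DEL/DUP/INV spans are materialized only from
    junctions explicitly typed as such — BND pairs are never re-interpreted
    as copy-number events.
    """

    patient_id: str
    junctions: list[BreakpointJunction] = field(default_factory=list)

    def __post_init__(self) -> None:
        for j in self.junctions:
            if j.patient_id and j.patient_id != self.patient_id:
                raise ValueError(
                    f"junction {j.id} belongs to {j.patient_id}, not {self.patient_id}"
                )

    def spans(self, sv_types: tuple[str, ...] = ("DEL", "DUP", "INV")) -> list[tuple[BreakpointJunction, GenomicInterval]]:
        out = []
        for j in self.junctions:
            if j.sv_type in sv_types:
                iv = j.span()
                if iv is not None:
                    out.append((j, iv))
        return out

    def junction_positions(self, chrom: Optional[str] = None) -> list[int]:
        """All breakpoint positions, optionally restricted to one chromosome."""
        pos = []
        for j in self.junctions:
            for c, p in j.positions():
                if chrom is None or c == chrom:
                    pos.append(p)
        return sorted(pos)

    @property
    def chromosomes(self) -> set[str]:
        return {c for j in self.junctions for c, _ in j.positions()}


@dataclass
class GeneRecord:
    """A protein-coding gene with dosage/disease and phenotype annotation.

    Only records carrying both a RefSeq mRNA id and an HGNC symbol qualify
    as protein-coding; where several transcripts exist the longest
    transcript's coordinates are used upstream of this container.
    """

    symbol: str
    refseq_id: str
    interval: GenomicInterval
    pLI: Optional[float] = None
    rvis_percentile: Optional[float] = None
    hi_percentile: Optional[float] = None
    clingen_hi_triplo: Optional[int] = None
    in_ddg2p: bool = False
    in_omim: bool = False
    modes_of_inheritance: frozenset[str] = frozenset()
    hpo_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.symbol or not self.refseq_id:
            raise ValueError("protein-coding gene requires symbol and refseq_id")
        bad = set(self.modes_of_inheritance) - {"AD", "AR", "XD", "XR"}
        if bad:
            raise ValueError(f"unknown modes of inheritance: {sorted(bad)}")

    @property
    def tss(self) -> int:
        """Transcription start site: interval start on '+', end-1 on '-'."""
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class PhenotypeProfile:
    patient_id: str
    hpo_terms: frozenset[str]
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"invalid sex {self.sex!r}")
        self.hpo_terms = frozenset(self.hpo_terms)


@dataclass
class AnalysisConfig:
    """Every tunable cutoff of the prioritization workflow.

    Defaults follow the published tiering table; component thresholds of the
    position-effect support score are package choices (see docs/methods.md).
    """

    flank_bp: int = 2_000_000
    # phenomatch thresholds: scores "higher than 1" / "higher than 5"
    low_threshold: float = 1.0
    high_threshold: float = 5.0
    explained_threshold: float = 5.0  # per-term cutoff for explained-phenotype %
    explained_largely_pct: float = 75.0
    # position-effect component cutoffs
    v4c_window_bp: int = 2_000_000
    promoter_slop_bp: int = 5_000
    v4c_min: float = 0.2
    ix_min: float = 0.2
    min_celltype_fraction: float = 0.5
    min_enhancers: int = 1
    min_enhancer_celltypes: int = 2
    top_k_expression: int = 3
    rpkm_expressed: float = 0.5
    # differential expression component
    de_p_max: float = 0.05
    de_lfc_min: float = 0.5
    # SV-effect support cutoffs ("> 1" weak, "> 3" strong)
    support_weak: int = 1
    support_strong: int = 3
    # deleted = any overlap with a DEL span; set True to require containment
    deletion_requires_containment: bool = False
    # rescale support denominator when optional resources are absent
    rescale_missing_resources: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return replace(cls(), **d)
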