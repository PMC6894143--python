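"""Direct effect of SVs on genes: deleted / duplicated / truncated /
inverted / adjacent classification and gene scoping.

Categories are mutually exclusive per gene with precedence
deleted > truncated > duplicated > inverted > adjacent:

* deleted — gene overlaps a deletion span (any overlap by default; a config
  switch requires full containment),
* truncated — a breakpoint falls strictly inside the gene body,
* duplicated — gene fully contained in a duplication span,
* inverted — gene fully contained in an inversion span and left intact,
* adjacent — within the scoping flank of a breakpoint but untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import AnalysisConfig, GeneRecord, SVSet

DIRECT_CATEGORIES = ("deleted", "duplicated", "truncated", "inverted", "adjacent", "none")


@dataclass(frozen=True)
class DirectEffectClass:
    category: str
    distance_to_nearest_junction: int

    def __post_init__(self) -> None:
        if self.category not in DIRECT_CATEGORIES:
            raise ValueError(f"invalid category {self.category!r}")

    @property
    def is_direct(self) -> bool:
        return self.category in ("deleted", "duplicated", "truncated")


def _nearest_junction_distance(gene: GeneRecord, svs: SVSet) -> int | None:
    best = None
    for j in svs.junctions:
        for chrom, pos in j.positions():
            d = gene.interval.distance_to_position(chrom, pos)
            if d is not None and (best is None or d < best):
                best = d
    return best


def classify_direct_effect(
    gene: GeneRecord, svs: SVSet, config: AnalysisConfig | None = None
) -> DirectEffectClass:
    """Classify one in-scope gene against a patient's SV set."""
    config = config or AnalysisConfig()
    iv = gene.interval
    dist = _nearest_junction_distance(gene, svs)

    deleted = False
    duplicated = False
    inverted = False
    for j, span in svs.spans():
        if j.sv_type == "DEL":
            if (config.deletion_requires_containment and span.contains(iv)) or (
                not config.deletion_requires_containment and span.overlaps(iv)
            ):
                deleted = True
        elif j.sv_type == "DUP" and span.contains(iv):
            duplicated = True
        elif j.sv_type == "INV" and span.contains(iv):
            inverted = True
    truncated = any(
        chrom == iv.chrom and iv.start < pos < iv.end
        for j in svs.junctions
        for chrom, pos in j.positions()
    )

    if deleted:
        category = "deleted"
    elif truncated:
        category = "truncated"
    elif duplicated:
        category = "duplicated"
    elif inverted:
        category = "inverted"
    elif dist is not None and dist <= config.flank_bp:
        # dist == 0 happens only when a break falls exactly on a gene edge
        # (between the last upstream base and the first gene base): the gene
        # body stays intact, so the gene is adjacent, not truncated
        category = "adjacent"
    else:
        category = "none"

    if category in ("deleted", "truncated"):
        dist = 0  # a breakpoint touches the gene body
    return DirectEffectClass(category=category, distance_to_nearest_junction=int(dist or 0))


def select_genes_in_scope(
    genes: list[GeneRecord], svs: SVSet, config: AnalysisConfig | None = None
) -> list[tuple[GeneRecord, DirectEffectClass]]:
    """Protein-coding genes at or adjacent to the SVs, with their direct class.

    A gene is in scope when it overlaps a derived SV span or lies within
    ``config.flank_bp`` of any breakpoint junction position.
    """
    config = config or AnalysisConfig()
    out = []
    for gene in genes:
        overlaps_span = any(span.overlaps(gene.interval) for _, span in svs.spans())
        dist = _nearest_junction_distance(gene, svs)
        if overlaps_span or (dist is not None and dist <= config.flank_bp):
            out.append((gene, classify_direct_effect(gene, svs, config)))
    return out
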