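"""Breakpoint-junction callset intersection and trio de novo filtering.

Two junctions match when their ends can be paired (in either order) on the
same chromosomes, with both positional offsets within a tolerance (default
+/- 100 bp, inclusive) and, by default, identical orientations under that
pairing. Matching is per-junction: individual junctions of a complex event
are filtered independently.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import BreakpointEnd, BreakpointJunction


@dataclass(frozen=True)
class JunctionMatchRule:
    tolerance_bp: int = 100
    require_same_orientation: bool = True

    def __post_init__(self) -> None:
        if self.tolerance_bp < 0:
            raise ValueError("tolerance_bp must be >= 0")


def _ends_match(a: BreakpointEnd, b: BreakpointEnd, rule: JunctionMatchRule) -> bool:
    if a.chrom != b.chrom:
        return False
    if rule.require_same_orientation and a.orientation != b.orientation:
        return False
    return abs(a.position - b.position) <= rule.tolerance_bp


def junctions_match(
    a: BreakpointJunction, b: BreakpointJunction, rule: JunctionMatchRule | None = None
) -> bool:
    """True when the two junctions describe the same adjacency within tolerance."""
    rule = rule or JunctionMatchRule()
    return (_ends_match(a.pos_a, b.pos_a, rule) and _ends_match(a.pos_b, b.pos_b, rule)) or (
        _ends_match(a.pos_a, b.pos_b, rule) and _ends_match(a.pos_b, b.pos_a, rule)
    )


def intersect_callsets(
    primary: list[BreakpointJunction],
    confirm: list[BreakpointJunction],
    rule: JunctionMatchRule | None = None,
) -> list[BreakpointJunction]:
    """Keep junctions of ``primary`` confirmed by at least one ``confirm`` call.

    Order is preserved and nothing is deduplicated; used to retain e.g.
    Manta calls confirmed by Delly within +/- 100 bp.
    """
    rule = rule or JunctionMatchRule()
    return [p for p in primary if any(junctions_match(p, c, rule) for c in confirm)]


def filter_de_novo(
    child: list[BreakpointJunction],
    father: list[BreakpointJunction],
    mother: list[BreakpointJunction],
    rule: JunctionMatchRule | None = None,
) -> list[BreakpointJunction]:
    """Keep child junctions absent (within tolerance) from both parental callsets."""
    rule = rule or JunctionMatchRule()
    parental = father + mother
    return [
        j for j in child if not any(junctions_match(j, p, rule) for p in parental)
    ]
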