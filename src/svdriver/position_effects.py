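"""Position-effect prediction: disruption of a gene's regulatory landscape.

For each gene near an SV the following evidence components are evaluated:

1. TAD disruption — a breakpoint falls strictly inside the TAD containing
   the gene's TSS, in more than half of the assessed cell types;
2. enhancer loss — at least one active enhancer lies on the disrupted
   portion of the TAD in at least two of the three cell types in which the
   gene is most highly expressed (RPKM > 0.5);
3. virtual-4C disruption — more than a minimum fraction (default 20%) of
   the gene's Hi-C interaction signal within a +/- 2 Mb window around its
   TSS viewpoint is separated from the TSS by a breakpoint, in more than
   half of the Hi-C cell types;
4. promoter-capture Hi-C disruption — >= 20% of the gene's promoter-anchored
   interactions cross a breakpoint;
5. DHS-connection disruption — same rule on DNase-hypersensitivity pairs;
6. differential expression of the gene in the patient (p < 0.05 and
   |log2FC| > 0.5).

The support score (0-6) counts the satisfied components; together with the
direct-effect class it yields the none/weak/strong SV-effect strength.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .direct_effects import DirectEffectClass
from .model import AnalysisConfig, GeneRecord, GenomicInterval, SVSet

logger = logging.getLogger(__name__)

COMPONENT_NAMES = (
    "tad_disrupted",
    "enhancers_lost",
    "v4c_disrupted",
    "pchic_disrupted",
    "dhs_disrupted",
    "expression_changed",
)

EFFECT_LEVELS = ("none", "weak", "strong")


@dataclass
class V4CProfile:
    """One viewpoint row of a binned Hi-C matrix around a gene's TSS."""

    cell_type: str
    chrom: str
    resolution: int
    viewpoint_bin: int
    window_start_bin: int
    signal: np.ndarray  # values for bins window_start_bin .. +len-1

    def bin_mid(self, bin_index: int) -> float:
        return (bin_index + 0.5) * self.resolution


@dataclass
class CellTypeEvidence:
    tad_disrupted: bool = False
    disrupted_tad_portion: Optional[GenomicInterval] = None
    enhancers_lost: int = 0
    v4c_fraction: Optional[float] = None  # None when no Hi-C for this cell type


@dataclass
class PositionEffectEvidence:
    gene: str
    per_cell_type: dict[str, CellTypeEvidence] = field(default_factory=dict)
    top_cell_types: list[str] = field(default_factory=list)
    pchic_fraction: float = 0.0
    pchic_n: int = 0
    dhs_fraction: float = 0.0
    dhs_n: int = 0
    expression_changed: bool = False
    components: dict[str, bool] = field(default_factory=dict)
    support_score: int = 0


@dataclass(frozen=True)
class SVEffect:
    strength: str
    basis: str  # direct_dup | direct_del_trunc | position

    def __post_init__(self) -> None:
        if self.strength not in EFFECT_LEVELS:
            raise ValueError(f"invalid strength {self.strength!r}")


def tad_disruption(
    gene: GeneRecord,
    tads: Sequence[tuple[int, int]],
    svs: SVSet,
) -> tuple[bool, Optional[GenomicInterval]]:
    """Is the TAD containing the gene's TSS broken by a breakpoint, and which
    part of it lies beyond the breakpoint nearest the TSS?

    ``tads`` are (start, end) pairs for the gene's chromosome in one cell
    type. Overlapping domains: the smallest TAD containing the TSS is used.
    Breakpoints exactly on a boundary do not disrupt (strict interiority).
    """
    tss = gene.tss
    containing = [(s, e) for s, e in tads if s <= tss < e]
    if not containing:
        return False, None
    if len(containing) > 1:
        logger.warning(
            "gene %s TSS inside %d overlapping TADs; using the smallest",
            gene.symbol,
            len(containing),
        )
    start, end = min(containing, key=lambda t: (t[1] - t[0], t[0]))
    inside = [p for p in svs.junction_positions(gene.chrom) if start < p < end]
    if not inside:
        return False, None
    nearest = min(inside, key=lambda p: (abs(p - tss), p))
    if nearest >= tss:
        portion = GenomicInterval(gene.chrom, nearest, end)
    else:
        portion = GenomicInterval(gene.chrom, start, nearest)
    return True, portion


def top_expressing_cell_types(
    gene: GeneRecord,
    expression: pd.DataFrame,
    k: int = 3,
    rpkm_expressed: float = 0.5,
) -> list[str]:
    """The k cell types with highest RPKM among those where the gene is
    expressed (RPKM > 0.5); ties broken lexicographically by cell type."""
    if gene.symbol not in expression.index:
        return []
    row = expression.loc[gene.symbol]
    expressed = [(ct, float(v)) for ct, v in row.items() if float(v) > rpkm_expressed]
    expressed.sort(key=lambda x: (-x[1], x[0]))
    return [ct for ct, _ in expressed[:k]]


def count_lost_enhancers(
    portion: Optional[GenomicInterval],
    enhancers: Sequence[tuple[int, int]],
) -> int:
    """Enhancers (same chromosome) overlapping the disrupted TAD portion."""
    if portion is None:
        return 0
    return sum(1 for s, e in enhancers if s < portion.end and portion.start < e)


def extract_v4c_profile(
    matrix: np.ndarray,
    resolution: int,
    chrom: str,
    tss: int,
    cell_type: str,
    window_bp: int = 2_000_000,
) -> V4CProfile:
    """Take the Hi-C matrix row whose bin contains the TSS, windowed to
    +/- window_bp and truncated at chromosome ends."""
    n_bins = matrix.shape[0]
    vp = tss // resolution
    if not 0 <= vp < n_bins:
        raise ValueError(f"TSS {chrom}:{tss} outside matrix of {n_bins} bins")
    radius = window_bp // resolution
    lo = max(0, vp - radius)
    hi = min(n_bins, vp + radius + 1)
    return V4CProfile(
        cell_type=cell_type,
        chrom=chrom,
        resolution=resolution,
        viewpoint_bin=vp,
        window_start_bin=lo,
        signal=np.asarray(matrix[vp, lo:hi], dtype=float),
    )


def v4c_disruption_fraction(
    profile: V4CProfile, svs: SVSet, tss_position: int
) -> float:
    """Fraction of windowed v4C signal separated from the TSS by a breakpoint.

    A bin is separated when at least one junction position lies strictly
    between the bin midpoint and the TSS. The viewpoint's own bin is
    excluded from both numerator and denominator.
    """
    junctions = np.asarray(svs.junction_positions(profile.chrom), dtype=float)
    bins = np.arange(profile.window_start_bin, profile.window_start_bin + len(profile.signal))
    mids = (bins + 0.5) * profile.resolution
    keep = bins != profile.viewpoint_bin
    signal = profile.signal[keep]
    mids = mids[keep]
    total = float(signal.sum())
    if total == 0.0:
        logger.debug("all-zero v4C profile for %s viewpoint bin %d", profile.chrom, profile.viewpoint_bin)
        return 0.0
    if junctions.size == 0:
        return 0.0
    lo = np.minimum(mids, tss_position)
    hi = np.maximum(mids, tss_position)
    separated = ((junctions[None, :] > lo[:, None]) & (junctions[None, :] < hi[:, None])).any(axis=1)
    return float(signal[separated].sum() / total)


def interaction_disruption(
    interactions: Sequence[tuple[GenomicInterval, GenomicInterval]],
    gene: GeneRecord,
    svs: SVSet,
    promoter_slop_bp: int = 5_000,
) -> tuple[float, int]:
    """Fraction of a gene's promoter-anchored interactions broken by an SV.

    Interactions are first restricted to pairs with one anchor overlapping
    the TSS +/- slop; an intra-chromosomal interaction is broken when a
    junction position lies strictly between its two anchor midpoints.
    Returns (fraction, number of promoter-anchored interactions).
    """
    tss = gene.tss
    lo, hi = tss - promoter_slop_bp, tss + promoter_slop_bp + 1
    promoter = [
        (a, b)
        for a, b in interactions
        if (a.chrom == gene.chrom and a.start < hi and lo < a.end)
        or (b.chrom == gene.chrom and b.start < hi and lo < b.end)
    ]
    if not promoter:
        return 0.0, 0
    n_broken = 0
    for a, b in promoter:
        if a.chrom != b.chrom:
            continue
        ma = (a.start + a.end) / 2
        mb = (b.start + b.end) / 2
        p_lo, p_hi = min(ma, mb), max(ma, mb)
        if any(p_lo < p < p_hi for p in svs.junction_positions(a.chrom)):
            n_broken += 1
    return n_broken / len(promoter), len(promoter)


def expression_component(
    de_table: Optional[pd.DataFrame],
    gene: GeneRecord,
    p_max: float = 0.05,
    lfc_min: float = 0.5,
) -> bool:
    """Patient differential expression: p < 0.05 and |log2FC| > 0.5."""
    if de_table is None or gene.symbol not in de_table.index:
        return False
    row = de_table.loc[gene.symbol]
    return float(row["p"]) < p_max and abs(float(row["log2fc"])) > lfc_min


def support_score(components: dict[str, bool]) -> int:
    """Number of satisfied evidence components (0-6)."""
    unknown = set(components) - set(COMPONENT_NAMES)
    if unknown:
        raise ValueError(f"unknown components: {sorted(unknown)}")
    return sum(bool(components.get(name, False)) for name in COMPONENT_NAMES)


def evaluate_position_effect(
    gene: GeneRecord,
    svs: SVSet,
    bundle,
    de_table: Optional[pd.DataFrame] = None,
    config: AnalysisConfig | None = None,
) -> PositionEffectEvidence:
    """Compute all evidence components and the support score for one gene.

    ``bundle`` is a :class:`svdriver.io.ResourceBundle`; absent resources
    leave their components false (conservative default), or shrink the
    evaluated component set when ``config.rescale_missing_resources`` is set.
    """
    config = config or AnalysisConfig()
    ev = PositionEffectEvidence(gene=gene.symbol)
    chrom = gene.chrom

    tad_cts = [ct for ct in bundle.cell_types if ct in bundle.tads]
    hic_cts = [ct for ct in bundle.cell_types if ct in bundle.hic]

    for ct in bundle.cell_types:
        cte = CellTypeEvidence()
        if ct in bundle.tads:
            tads = bundle.tads[ct].get(chrom, [])
            cte.tad_disrupted, cte.disrupted_tad_portion = tad_disruption(gene, tads, svs)
        if ct in bundle.enhancers and cte.disrupted_tad_portion is not None:
            enh = bundle.enhancers[ct].get(chrom, [])
            cte.enhancers_lost = count_lost_enhancers(cte.disrupted_tad_portion, enh)
        if ct in bundle.hic:
            matrix = bundle.hic[ct].get(chrom)
            if matrix is not None:
                profile = extract_v4c_profile(
                    matrix, bundle.hic_resolution, chrom, gene.tss, ct, config.v4c_window_bp
                )
                cte.v4c_fraction = v4c_disruption_fraction(profile, svs, gene.tss)
        ev.per_cell_type[ct] = cte

    if bundle.expression is not None:
        ev.top_cell_types = top_expressing_cell_types(
            gene, bundle.expression, config.top_k_expression, config.rpkm_expressed
        )

    # component 1: TAD disrupted in a majority of cell types
    n_tad_disrupted = sum(ev.per_cell_type[ct].tad_disrupted for ct in tad_cts)
    comp_tad = bool(tad_cts) and n_tad_disrupted / len(tad_cts) > config.min_celltype_fraction

    # component 2: enhancers lost in >= 2 of the top-3 expressing cell types
    n_enh_cts = sum(
        1
        for ct in ev.top_cell_types
        if ev.per_cell_type.get(ct, CellTypeEvidence()).enhancers_lost >= config.min_enhancers
    )
    comp_enh = n_enh_cts >= config.min_enhancer_celltypes

    # component 3: v4C disrupted in a majority of Hi-C cell types
    v4c_fracs = [
        ev.per_cell_type[ct].v4c_fraction
        for ct in hic_cts
        if ev.per_cell_type[ct].v4c_fraction is not None
    ]
    comp_v4c = (
        bool(v4c_fracs)
        and sum(f >= config.v4c_min for f in v4c_fracs) / len(v4c_fracs)
        > config.min_celltype_fraction
    )

    ev.pchic_fraction, ev.pchic_n = interaction_disruption(
        bundle.pchic or [], gene, svs, config.promoter_slop_bp
    )
    comp_pchic = ev.pchic_n > 0 and ev.pchic_fraction >= config.ix_min
    ev.dhs_fraction, ev.dhs_n = interaction_disruption(
        bundle.dhs or [], gene, svs, config.promoter_slop_bp
    )
    comp_dhs = ev.dhs_n > 0 and ev.dhs_fraction >= config.ix_min

    ev.expression_changed = expression_component(
        de_table, gene, config.de_p_max, config.de_lfc_min
    )

    ev.components = {
        "tad_disrupted": comp_tad,
        "enhancers_lost": comp_enh,
        "v4c_disrupted": comp_v4c,
        "pchic_disrupted": comp_pchic,
        "dhs_disrupted": comp_dhs,
        "expression_changed": ev.expression_changed,
    }
    score = support_score(ev.components)
    if config.rescale_missing_resources:
        present = _present_components(bundle, de_table)
        if 0 < len(present) < len(COMPONENT_NAMES):
            score = round(score * len(COMPONENT_NAMES) / len(present))
    ev.support_score = score
    return ev


def _present_components(bundle, de_table) -> list[str]:
    present = []
    if bundle.tads:
        present.append("tad_disrupted")
    if bundle.enhancers and bundle.expression is not None:
        present.append("enhancers_lost")
    if bundle.hic:
        present.append("v4c_disrupted")
    if bundle.pchic:
        present.append("pchic_disrupted")
    if bundle.dhs:
        present.append("dhs_disrupted")
    if de_table is not None:
        present.append("expression_changed")
    return present


def sv_effect(
    direct: DirectEffectClass, support: int, config: AnalysisConfig | None = None
) -> SVEffect:
    """Combine direct class and support score into the SV-effect strength.

    Deleted/truncated genes are strongly affected regardless of support;
    duplicated genes are at least weakly affected; adjacent and inverted
    genes depend on the support score alone (> 3 strong, > 1 weak).
    """
    config = config or AnalysisConfig()
    if direct.category in ("deleted", "truncated"):
        return SVEffect("strong", "direct_del_trunc")
    if support > config.support_strong:
        positional = "strong"
    elif support > config.support_weak:
        positional = "weak"
    else:
        positional = "none"
    if direct.category == "duplicated":
        strength = positional if positional == "strong" else "weak"
        return SVEffect(strength, "direct_dup")
    return SVEffect(positional, "position")
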