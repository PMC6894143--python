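"""Per-gene disease-association score and phenotype-association strength.

The disease association score awards one point per satisfied criterion:
pLI > 0.9; RVIS percentile < 10; haploinsufficiency percentile < 10 or a
ClinGen haploinsufficiency/triplosensitivity score between 1 and 3
(inclusive); presence in DDG2P; presence in OMIM. Missing annotation never
scores. The phenotype association strength combines this score with the
phenomatch totals and the mode of inheritance (strongest satisfied column
wins; all criteria within a column must hold).
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import AnalysisConfig, GeneRecord, PhenotypeProfile
from .ontology import Ontology
from .phenomatch import PhenomatchResult, phenomatch_gene

ASSOCIATION_LEVELS = ("none", "weak", "medium", "strong")


@dataclass(frozen=True)
class DiseaseAssociationScore:
    points_pli: int
    points_rvis: int
    points_hi: int
    points_ddg2p: int
    points_omim: int

    @property
    def total(self) -> int:
        return (
            self.points_pli
            + self.points_rvis
            + self.points_hi
            + self.points_ddg2p
            + self.points_omim
        )


@dataclass
class PhenotypeAssociation:
    strength: str
    disease_score: DiseaseAssociationScore
    phenomatch: PhenomatchResult
    moi_compatible: bool


def disease_association_score(gene: GeneRecord) -> DiseaseAssociationScore:
    """0-5 count of dosage/disease-annotation criteria met by the gene."""
    pli = int(gene.pLI is not None and gene.pLI > 0.9)
    rvis = int(gene.rvis_percentile is not None and gene.rvis_percentile < 10)
    hi = int(
        (gene.hi_percentile is not None and gene.hi_percentile < 10)
        or (gene.clingen_hi_triplo is not None and 1 <= gene.clingen_hi_triplo <= 3)
    )
    return DiseaseAssociationScore(
        points_pli=pli,
        points_rvis=rvis,
        points_hi=hi,
        points_ddg2p=int(gene.in_ddg2p),
        points_omim=int(gene.in_omim),
    )


def moi_compatible(gene: GeneRecord, patient: PhenotypeProfile) -> bool:
    """Dominant or X-linked compatibility: AD, XD, or XR in an XY patient."""
    moi = gene.modes_of_inheritance
    return "AD" in moi or "XD" in moi or ("XR" in moi and patient.sex == "male")


def association_strength(
    disease_total: int,
    total_phenomatch: float,
    pct_high: float,
    moi_ok: bool,
) -> str:
    """Highest association column whose cutoffs are all satisfied."""
    if disease_total > 2 and total_phenomatch > 10 and pct_high > 25 and moi_ok:
        return "strong"
    if disease_total > 0 and total_phenomatch > 4 and pct_high > 10 and moi_ok:
        return "medium"
    if disease_total > 0 and total_phenomatch > 0 and pct_high > 0:
        return "weak"
    return "none"


def phenotype_association(
    gene: GeneRecord,
    patient: PhenotypeProfile,
    ontology: Ontology,
    config: AnalysisConfig | None = None,
    phenomatch: PhenomatchResult | None = None,
) -> PhenotypeAssociation:
    config = config or AnalysisConfig()
    if phenomatch is None:
        phenomatch = phenomatch_gene(patient, gene, ontology, config)
    score = disease_association_score(gene)
    moi_ok = moi_compatible(gene, patient)
    strength = association_strength(
        score.total, phenomatch.total_score, phenomatch.pct_high, moi_ok
    )
    return PhenotypeAssociation(
        strength=strength,
        disease_score=score,
        phenomatch=phenomatch,
        moi_compatible=moi_ok,
    )
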