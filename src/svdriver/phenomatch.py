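"""Phenomatch scoring: semantic match between a patient's HPO profile and a
gene's HPO annotations.

Each patient term is scored against a gene as the best Resnik similarity to
any of the gene's terms; the total phenomatch score is the sum over patient
terms. Matches scoring higher than 1 are "low" phenomatches and higher than
5 "high" phenomatches, and the percentage of patient terms with a high
phenomatch feeds the tiering table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import AnalysisConfig, GeneRecord, PhenotypeProfile
from .ontology import Ontology


@dataclass
class PhenomatchResult:
    gene: str
    per_term_scores: dict[str, float] = field(default_factory=dict)
    total_score: float = 0.0
    n_low: int = 0
    n_high: int = 0
    pct_high: float = 0.0


def phenomatch_gene(
    patient: PhenotypeProfile,
    gene: GeneRecord,
    ontology: Ontology,
    config: AnalysisConfig | None = None,
) -> PhenomatchResult:
    """Score one gene against one patient phenotype profile.

    A gene without HPO annotations scores 0 on every term.
    """
    config = config or AnalysisConfig()
    if not patient.hpo_terms:
        raise ValueError(f"patient {patient.patient_id} has no HPO terms")
    ontology.validate_terms(patient.hpo_terms)

    scores: dict[str, float] = {}
    for term in sorted(patient.hpo_terms):
        best = 0.0
        for gterm in gene.hpo_terms:
            s = ontology.term_similarity(term, gterm)
            if s > best:
                best = s
        scores[term] = best

    total = sum(scores.values())
    n_low = sum(1 for s in scores.values() if s > config.low_threshold)
    n_high = sum(1 for s in scores.values() if s > config.high_threshold)
    return PhenomatchResult(
        gene=gene.symbol,
        per_term_scores=scores,
        total_score=total,
        n_low=n_low,
        n_high=n_high,
        pct_high=100.0 * n_high / len(scores),
    )
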