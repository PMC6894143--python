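"""End-to-end driver prioritization for patients with de novo SVs."""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .classify import (
    DriverCall,
    PatientSummary,
    classify_tier,
    cohort_summary,
    effect_basis,
    summarize_patient,
)
from .direct_effects import select_genes_in_scope
from .gene_scoring import phenotype_association
from .io import ResourceBundle
from .model import AnalysisConfig, GeneRecord, PhenotypeProfile, SVSet
from .ontology import Ontology
from .phenomatch import PhenomatchResult
from .position_effects import evaluate_position_effect, sv_effect


def run_patient(
    svs: SVSet,
    patient: PhenotypeProfile,
    genes: list[GeneRecord],
    ontology: Ontology,
    bundle: ResourceBundle,
    de_table: Optional[pd.DataFrame] = None,
    config: AnalysisConfig | None = None,
) -> tuple[list[DriverCall], dict[str, PhenomatchResult]]:
    """Classify every gene at or adjacent to one patient's SVs.

    Returns the per-gene driver calls (including tier "none", for audit)
    and the phenomatch results keyed by gene symbol.
    """
    config = config or AnalysisConfig()
    ontology.validate_terms(patient.hpo_terms)
    calls: list[DriverCall] = []
    phenomatches: dict[str, PhenomatchResult] = {}
    for gene, direct in select_genes_in_scope(genes, svs, config):
        assoc = phenotype_association(gene, patient, ontology, config)
        phenomatches[gene.symbol] = assoc.phenomatch
        evidence = evaluate_position_effect(gene, svs, bundle, de_table, config)
        effect = sv_effect(direct, evidence.support_score, config)
        tier = classify_tier(assoc.strength, effect.strength)
        calls.append(
            DriverCall(
                patient_id=patient.patient_id,
                symbol=gene.symbol,
                tier=tier,
                association=assoc,
                effect=effect,
                direct_category=direct.category,
                distance_bp=direct.distance_to_nearest_junction,
                effect_basis=effect_basis(direct.category, evidence.support_score, config),
                position_evidence=evidence,
            )
        )
    return calls, phenomatches


def run_cohort(
    patients: list[tuple[SVSet, PhenotypeProfile, Optional[pd.DataFrame]]],
    genes: list[GeneRecord],
    ontology: Ontology,
    bundle: ResourceBundle,
    config: AnalysisConfig | None = None,
    previous_classification: Optional[dict[str, str]] = None,
) -> tuple[list[DriverCall], list[PatientSummary], dict]:
    """Run the full workflow over a cohort and summarize it."""
    config = config or AnalysisConfig()
    all_calls: list[DriverCall] = []
    summaries: list[PatientSummary] = []
    for svs, profile, de_table in patients:
        calls, phenomatches = run_patient(
            svs, profile, genes, ontology, bundle, de_table, config
        )
        all_calls.extend(calls)
        summaries.append(summarize_patient(profile, calls, phenomatches, config))
    summary = cohort_summary(summaries, previous_classification)
    return all_calls, summaries, summary
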