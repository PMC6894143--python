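"""Driver tier classification and patient/cohort summaries.

Tier mapping (phenotype association x SV effect):

* T1 — strong association, strongly affected;
* T2 — weak/medium association with a strong effect, or medium/strong
  association with a weak effect;
* T3 — weak association, weak effect;
* none — either side absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .gene_scoring import PhenotypeAssociation
from .model import AnalysisConfig, PhenotypeProfile
from .phenomatch import PhenomatchResult
from .position_effects import PositionEffectEvidence, SVEffect

TIERS = ("T1", "T2", "T3", "none")
_TIER_ORDER = {t: i for i, t in enumerate(TIERS)}


@dataclass
class DriverCall:
    patient_id: str
    symbol: str
    tier: str
    association: PhenotypeAssociation
    effect: SVEffect
    direct_category: str
    distance_bp: int
    effect_basis: str  # direct | position | both
    position_evidence: Optional[PositionEffectEvidence] = None

    @property
    def association_strength(self) -> str:
        return self.association.strength

    @property
    def effect_strength(self) -> str:
        return self.effect.strength


@dataclass
class PatientSummary:
    patient_id: str
    n_T1: int
    n_T2: int
    n_T3: int
    pct_hpo_explained: float
    explained: str  # largely | partially | none
    driver_category: str  # direct | position | both | none


def classify_tier(association: str, effect: str) -> str:
    """Map (association strength, effect strength) to a driver tier."""
    if association not in ("none", "weak", "medium", "strong"):
        raise ValueError(f"invalid association strength {association!r}")
    if effect not in ("none", "weak", "strong"):
        raise ValueError(f"invalid effect strength {effect!r}")
    if association == "none" or effect == "none":
        return "none"
    if association == "strong" and effect == "strong":
        return "T1"
    if effect == "strong":  # weak or medium association
        return "T2"
    if association in ("medium", "strong"):  # weak effect
        return "T2"
    return "T3"  # weak + weak


def effect_basis(direct_category: str, support: int, config: AnalysisConfig | None = None) -> str:
    """direct / position / both provenance of the SV effect on a gene."""
    config = config or AnalysisConfig()
    direct = direct_category in ("deleted", "duplicated", "truncated")
    positional = support > config.support_weak
    if direct and positional:
        return "both"
    if direct:
        return "direct"
    return "position"


def pct_hpo_explained(
    patient: PhenotypeProfile,
    calls: list[DriverCall],
    phenomatch_results: dict[str, PhenomatchResult],
    threshold: float = 5.0,
) -> tuple[float, str]:
    """Percentage of the patient's HPO terms with a phenomatch score above
    ``threshold`` against at least one T1/T2 driver gene, and the resulting
    largely (> 75%) / partially (> 0) / none label."""
    if not patient.hpo_terms:
        raise ValueError(f"patient {patient.patient_id} has no HPO terms")
    t12_genes = [c.symbol for c in calls if c.tier in ("T1", "T2")]
    explained_terms = set()
    for sym in t12_genes:
        result = phenomatch_results.get(sym)
        if result is None:
            continue
        for term, score in result.per_term_scores.items():
            if score > threshold:
                explained_terms.add(term)
    pct = 100.0 * len(explained_terms & patient.hpo_terms) / len(patient.hpo_terms)
    if pct > 75.0:
        label = "largely"
    elif pct > 0.0:
        label = "partially"
    else:
        label = "none"
    return pct, label


def summarize_patient(
    patient: PhenotypeProfile,
    calls: list[DriverCall],
    phenomatch_results: dict[str, PhenomatchResult],
    config: AnalysisConfig | None = None,
) -> PatientSummary:
    config = config or AnalysisConfig()
    pct, label = pct_hpo_explained(
        patient, calls, phenomatch_results, config.explained_threshold
    )
    t12 = [c for c in calls if c.tier in ("T1", "T2")]
    bases = {c.effect_basis for c in t12}
    if not t12:
        category = "none"
    elif "both" in bases or len(bases - {"both"}) > 1:
        category = "both"
    elif bases == {"direct"}:
        category = "direct"
    else:
        category = "position"
    return PatientSummary(
        patient_id=patient.patient_id,
        n_T1=sum(c.tier == "T1" for c in calls),
        n_T2=sum(c.tier == "T2" for c in calls),
        n_T3=sum(c.tier == "T3" for c in calls),
        pct_hpo_explained=pct,
        explained=label,
        driver_category=category,
    )


def cohort_summary(
    summaries: list[PatientSummary],
    previous_classification: Optional[dict[str, str]] = None,
) -> dict:
    """Cohort-level fractions of patients with T1/T2 drivers, broken down by
    direct / position / both driver provenance."""
    if not summaries:
        raise ValueError("cohort summary requires at least one patient")
    n = len(summaries)
    with_t12 = [s for s in summaries if s.n_T1 + s.n_T2 > 0]
    by_cat = {"direct": 0, "position": 0, "both": 0}
    for s in with_t12:
        by_cat[s.driver_category] += 1
    out = {
        "n_patients": n,
        "n_with_T1_T2": len(with_t12),
        "fraction_with_T1_T2": len(with_t12) / n,
        "n_direct_only": by_cat["direct"],
        "n_position_only": by_cat["position"],
        "n_both": by_cat["both"],
        "n_T1_total": sum(s.n_T1 for s in summaries),
        "n_T2_total": sum(s.n_T2 for s in summaries),
        "n_T3_total": sum(s.n_T3 for s in summaries),
        "n_largely_explained": sum(s.explained == "largely" for s in summaries),
        "n_partially_explained": sum(s.explained == "partially" for s in summaries),
    }
    if previous_classification:
        strata: dict[str, dict[str, int]] = {}
        for s in summaries:
            stratum = previous_classification.get(s.patient_id, "unclassified")
            d = strata.setdefault(stratum, {"n": 0, "n_with_T1_T2": 0})
            d["n"] += 1
            d["n_with_T1_T2"] += int(s.n_T1 + s.n_T2 > 0)
        out["by_previous_classification"] = {k: strata[k] for k in sorted(strata)}
    return out


def sort_calls(calls: list[DriverCall]) -> list[DriverCall]:
    """Deterministic report order: patient, tier, descending phenomatch, symbol."""
    return sorted(
        calls,
        key=lambda c: (
            c.patient_id,
            _TIER_ORDER[c.tier],
            -c.association.phenomatch.total_score,
            c.symbol,
        ),
    )
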