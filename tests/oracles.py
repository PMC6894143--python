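"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and coded from the published rules, not from the package
implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


# --- ontology / phenomatch --------------------------------------------------

def brute_ancestors(term: str, parents: dict[str, list[str]]) -> set[str]:
    out = {term}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for p in parents.get(t, []):
            if p not in out:
                out.add(p)
                frontier.append(p)
    return out


def brute_ic(term: str, parents: dict[str, list[str]], gene_ann: dict[str, set[str]], root: str):
    """IC from explicit descendant/annotation enumeration."""
    genes_at = {g for g, terms in gene_ann.items()
                if any(term in brute_ancestors(t, parents) for t in terms)}
    genes_root = {g for g, terms in gene_ann.items() if terms}
    if not genes_at:
        return None
    return -math.log(len(genes_at) / len(genes_root))


def brute_similarity(t1, t2, parents, gene_ann, root) -> float:
    common = brute_ancestors(t1, parents) & brute_ancestors(t2, parents)
    best = 0.0
    for a in common:
        ic = brute_ic(a, parents, gene_ann, root)
        if ic is not None and ic > best:
            best = ic
    return best


def brute_phenomatch_total(patient_terms, gene_terms, parents, gene_ann, root):
    """Direct double-loop recomputation of per-term and total scores."""
    per_term = {}
    for pt in patient_terms:
        best = 0.0
        for gt in gene_terms:
            s = brute_similarity(pt, gt, parents, gene_ann, root)
            best = max(best, s)
        per_term[pt] = best
    return per_term, sum(per_term.values())


# --- junction matching ------------------------------------------------------

def brute_match(a, b, tol, same_orientation=True) -> bool:
    def end_ok(x, y):
        if x.chrom != y.chrom:
            return False
        if same_orientation and x.orientation != y.orientation:
            return False
        return abs(x.position - y.position) <= tol

    return (end_ok(a.pos_a, b.pos_a) and end_ok(a.pos_b, b.pos_b)) or (
        end_ok(a.pos_a, b.pos_b) and end_ok(a.pos_b, b.pos_a)
    )


def brute_intersect(primary, confirm, tol):
    out = []
    for p in primary:
        for c in confirm:
            if brute_match(p, c, tol):
                out.append(p)
                break
    return out


def brute_denovo(child, father, mother, tol):
    out = []
    for j in child:
        if not any(brute_match(j, p, tol) for p in father + mother):
            out.append(j)
    return out


# --- disease association score ---------------------------------------------

def disease_score_oracle(pli, rvis, hi, clingen, ddg2p, omim) -> int:
    score = 0
    if pli is not None and pli > 0.9:
        score += 1
    if rvis is not None and rvis < 10:
        score += 1
    if (hi is not None and hi < 10) or (clingen is not None and 1 <= clingen <= 3):
        score += 1
    if ddg2p:
        score += 1
    if omim:
        score += 1
    return score


def association_oracle(disease, total, pct_high, moi) -> str:
    """Strength columns coded independently, strongest first."""
    if moi and disease > 2 and total > 10 and pct_high > 25:
        return "strong"
    if moi and disease > 0 and total > 4 and pct_high > 10:
        return "medium"
    if disease > 0 and total > 0 and pct_high > 0:
        return "weak"
    return "none"


# --- tier mapping -----------------------------------------------------------

def tier_oracle(association: str, effect: str) -> str:
    """Verbatim transcription of the published tier definitions: T1 = strong
    association + strongly affected; T2 = weak/medium association + strong
    effect, or medium/strong association + weak effect; T3 = weak + weak."""
    if association == "strong" and effect == "strong":
        return "T1"
    if association in ("weak", "medium") and effect == "strong":
        return "T2"
    if association in ("medium", "strong") and effect == "weak":
        return "T2"
    if association == "weak" and effect == "weak":
        return "T3"
    return "none"


# --- v4C / interaction disruption -------------------------------------------

def brute_v4c_fraction(signal, bins, resolution, viewpoint_bin, tss, junction_positions):
    """Per-bin betweenness summation."""
    total = 0.0
    cut = 0.0
    for value, b in zip(signal, bins):
        if b == viewpoint_bin:
            continue
        total += value
        mid = (b + 0.5) * resolution
        lo, hi = min(mid, tss), max(mid, tss)
        if any(lo < p < hi for p in junction_positions):
            cut += value
    return 0.0 if total == 0 else cut / total


def brute_interaction_fraction(pairs, junction_positions):
    """pairs: ((chrom, mid_a), (chrom, mid_b)) promoter-anchored; count
    intra-chromosomal pairs with a junction strictly between anchors."""
    if not pairs:
        return 0.0
    broken = 0
    for (ca, ma), (cb, mb) in pairs:
        if ca != cb:
            continue
        lo, hi = min(ma, mb), max(ma, mb)
        if any(lo < p < hi for p, c in junction_positions if c == ca):
            broken += 1
    return broken / len(pairs)


# --- random fixtures ---------------------------------------------------------

def random_dag(rng: np.random.Generator, n_terms: int):
    """Random rooted DAG as (parents map, term list); term 0 is the root and
    each later term gets 1-2 parents among earlier terms."""
    terms = [f"T{i}" for i in range(n_terms)]
    parents: dict[str, list[str]] = {terms[0]: []}
    for i in range(1, n_terms):
        k = 1 + int(rng.random() < 0.3 and i > 1)
        picks = rng.choice(i, size=min(k, i), replace=False)
        parents[terms[i]] = [terms[int(p)] for p in picks]
    return parents, terms


def random_annotations(rng: np.random.Generator, terms, n_genes: int):
    ann: dict[str, set[str]] = {}
    non_root = terms[1:] if len(terms) > 1 else terms
    for g in range(n_genes):
        size = int(rng.integers(1, min(4, len(non_root) + 1)))
        picks = rng.choice(len(non_root), size=size, replace=False)
        ann[f"G{g}"] = {non_root[int(p)] for p in picks}
    return ann
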