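# Methods

## Problem and overall model

`svdriver` prioritizes candidate driver genes in patients carrying de novo
structural variants (SVs). An SV can disrupt a gene directly — deleting,
duplicating, or truncating it — or indirectly, by breaking the chromatin
context (topologically associating domains, enhancer–promoter contacts)
that regulates an intact gene: a *position effect*. The tool combines two
orthogonal axes of evidence per gene and patient:

1. **Phenotype association** — how well the gene's known phenotype spectrum
   (HPO annotations) matches the patient's HPO profile, together with
   dosage-sensitivity and disease-database annotation and the mode of
   inheritance;
2. **SV effect** — how severely the SV is predicted to affect the gene,
   either directly or through regulatory disruption.

The two axes are discretized (none/weak/medium/strong and none/weak/strong)
and combined into driver tiers: T1 = strong association + strong effect;
T2 = weak/medium association + strong effect, or medium/strong association
+ weak effect; T3 = weak + weak; anything with an absent axis is not
reported as a driver.

## Breakpoint-junction representation and filtering

Every SV is reduced to its breakpoint junctions: pairs of oriented genomic
positions forming a novel adjacency. Copy-number spans (DEL/DUP/INV) are
materialized only from junctions explicitly typed as such by the caller;
breakend (BND) pairs are never re-interpreted as copy-number events, since
apparent gains are frequently insertions elsewhere in the genome.

Callset intersection (e.g., keeping Manta calls confirmed by Delly) and
trio de novo filtering match junctions end-to-end with a ±100 bp tolerance
(inclusive) on both ends, pairing ends in either order. Orientation must
also match by default; this prevents reciprocal events from merging and can
be switched off. Matching is per-junction, so individual junctions of a
complex rearrangement are filtered independently. Whether parental matching
should be restricted to same-type calls is unknown; matching here is
type-blind (configurable through the rule object).

## Phenomatch scoring

The semantic match between a patient term *t* and a gene is
`max_g sim(t, g)` over the gene's HPO terms, using Resnik similarity:
`sim(t1, t2) = max{ IC(a) : a ∈ common ancestors of t1, t2 }` with
information content estimated from gene-annotation frequencies,
`IC(a) = −ln(n_a / n_root)`, where `n_a` counts genes annotated to *a* or
any descendant. Natural log is used; the downstream thresholds are plain
config keys so any monotone IC variant can be recalibrated. Terms with no
annotated gene have undefined IC and are skipped as match anchors; the root
(IC 0) guarantees a non-negative score. The exact scoring function behind
published phenomatching tools is not fully specified; Resnik-by-MICA with
max-per-patient-term, sum-into-total aggregation is the conventional choice
and drives all downstream thresholds here.

Per gene we report: the **total phenomatch score** (sum over patient
terms), **low phenomatches** (terms scoring > 1), **high phenomatches**
(terms scoring > 5), and the percentage of patient terms with a high
phenomatch. Both thresholds are strict inequalities and configurable
(`low_threshold`, `high_threshold`). The count of low phenomatches is
surfaced in reports but does not enter the strength decision, which is
driven by the total score and the high-phenomatch percentage. One related
published figure legend mentions a per-term threshold of 4 where the
accompanying text uses 5; the default here is 5 (`explained_threshold`).

Patient terms absent from the loaded ontology are a hard error rather than
a silent skip — a typo in an HPO ID should never quietly weaken a profile.

## Phenotype association strength

The disease association score (0–5) awards one point each for: pLI > 0.9;
RVIS percentile < 10; haploinsufficiency percentile < 10 *or* ClinGen
haploinsufficiency/triplosensitivity score in [1, 3]; presence in DDG2P;
presence in OMIM. All inequalities are strict except the ClinGen interval
(inclusive); missing annotation never scores. RVIS and HI are on percentile
scales, so "< 10" selects the most intolerant decile.

Strength columns (evaluated strongest-first, all criteria within a column
AND-ed):

| | weak | medium | strong |
|---|---|---|---|
| disease association score | > 0 | > 0 | > 2 |
| total phenomatch score | > 0 | > 4 | > 10 |
| % terms with high phenomatch | > 0 | > 10 | > 25 |
| mode of inheritance | — | AD/XD/XR+XY | AD/XD/XR+XY |

The mode-of-inheritance condition is dominant-or-X-linked compatibility:
the gene lists AD or XD, or lists XR and the patient is male. The weak
column deliberately has no MOI requirement, matching the published cutoff
table where MOI entries align with medium and strong only.

## Direct effects

Genes at or adjacent to the SVs (within `flank_bp`, default 2 Mb; large
cohort analyses conventionally use 1 Mb) are classified with precedence
deleted > truncated > duplicated > inverted > adjacent:

- **deleted** — overlaps a deletion span. Any overlap counts by default: a
  gene losing any sequence to a deletion is dosage-affected
  (`deletion_requires_containment` switches to strict containment);
- **truncated** — a breakpoint falls strictly inside the gene body (a break
  at position *p* separates bases *p−1* and *p*, so an edge-exact break
  leaves the gene intact);
- **duplicated** — fully contained in a duplication span; a gene straddling
  a duplication boundary is truncated instead (one allele's structure is
  disrupted by a partial tandem duplication);
- **inverted** — fully contained in an inversion, intact; such genes carry
  no intrinsic effect strength and are evaluated for position effects like
  adjacent genes.

Deleted and truncated genes are strongly affected regardless of regulatory
evidence; duplicated genes at least weakly.

## Position effects

Six evidence components are evaluated per gene; the support score (0–6) is
their count. The published score lists five labelled data sources for a 0–6
range; enhancer loss — a counting step described separately from TAD
disruption — is taken as the sixth component.

1. **TAD disruption**: a breakpoint lies strictly inside the TAD containing
   the gene's TSS (smallest containing TAD when calls overlap; boundary
   hits do not disrupt), in more than `min_celltype_fraction` (default 0.5)
   of cell types with TAD calls. The *disrupted portion* is the part of the
   TAD on the far side of the breakpoint nearest the TSS.
2. **Enhancer loss**: ≥ `min_enhancers` (default 1) active enhancers
   overlap the disrupted portion in at least 2 of the 3 cell types where
   the gene is most expressed (RPKM > 0.5, ties broken lexicographically).
   Genes expressed nowhere fail this component.
3. **Virtual 4C disruption**: the v4C profile is the Hi-C matrix row of the
   TSS bin, windowed to ±2 Mb (matching the scoping flank) with the
   self-interaction bin excluded to avoid the dominant diagonal. A bin is
   *separated* when any breakpoint lies strictly between the bin midpoint
   and the TSS; the disrupted fraction is the separated share of windowed
   signal. Component true when the fraction ≥ `v4c_min` (default 0.2) in
   more than half of the Hi-C cell types.
4. **PCHiC disruption**: among interactions with one anchor overlapping the
   TSS ± 5 kb, the fraction whose anchors (midpoints) are separated by a
   breakpoint, ≥ `ix_min` (default 0.2). Tissue-specific interaction sets
   are pooled into one promoter-anchored set per resource.
5. **DHS-connection disruption**: identical rule on DNase-hypersensitivity
   connection pairs.
6. **Differential expression**: the gene is differentially expressed in the
   patient (p < 0.05 and |log2FC| > 0.5, mirroring the fold-change band
   used for display in the source analyses).

The component cutoffs (0.2 interaction loss, majority of cell types, one
enhancer in two of three top cell types) are package choices: the published
workflow figure does not print exact values. Rationale: losing a fifth of a
promoter's contacts is a plausibly meaningful regulatory change, and
majority-of-cell-types voting guards against single-dataset noise. Every
cutoff is a config key. Missing resources leave their components false
(conservative: absent evidence is not evidence), with an optional
denominator rescaling switch (`rescale_missing_resources`).

Effect strength for adjacent/inverted genes: strong when support > 3, weak
when support > 1 (both strict, configurable). Duplicated genes take the
stronger of "weak" and the support-derived strength.

## Synthetic cohorts

The generator writes complete toy datasets in exactly the formats the
readers consume, with a ground-truth table of planted drivers. Defaults: 2
chromosomes × 10 Mb, 40 kb Hi-C bins, 60 genes, 3 cell types, 8 patients —
a full simulate-plus-analyze cycle runs in about a second, and the
50-patient runs used by the recovery checks stay well under a minute.

- **TADs** tile each chromosome (600 kb–1.2 Mb), sharing boundaries across
  cell types up to ±1 bin of jitter. **Hi-C** is Poisson noise on a block
  mean (base 1.0, +5.0 within a TAD), seeded per (cell type, chromosome).
- **Ontology**: rare leaf terms annotated to a single background gene reach
  IC ≈ ln(2000) ≈ 7.6 (> 5, the high-phenomatch regime); common leaves
  (tens of genes) land in the low-match band (1 < IC ≤ 5); intermediate
  nodes receive direct background-gene annotations so that only planted
  leaves score high. Patient profiles (8 terms) and decoy-gene annotations
  are drawn from disjoint branches, so decoy genes cannot phenomatch.
  The annotation universe holds ~2000 background genes because a 60-gene
  locus alone cannot exceed IC ≈ 4.1.
- **Planted drivers** per patient: deletion/truncation/duplication of a
  target gene, or an enhancer-loss translocation separating the target TSS
  from its TAD's enhancer cluster (placed with margins that survive
  boundary jitter); association strength is planted through shared rare
  terms plus disease annotations (strong: score 5 + AD; medium: score 2 +
  AD; weak: OMIM only, no MOI). Decoy SVs land on a driver-free chromosome.
  Duplication plantings only accept medium association: a duplication's
  effect strength depends on its realized support score, and medium
  association yields T2 either way, keeping the expected tier exact.
- **Expected tiers** come from an independently coded mode-plus-association
  table; enhancer-loss plantings are additionally verified to reach a
  strong support score through the real evaluation path before the ground
  truth is written.
- The patient **DE tables** mark dosage-affected genes (log2FC ≈ −1 for
  deletion/truncation/enhancer loss, ≈ +0.58 for duplication, p ≪ 0.05),
  qualitatively emulating the reduced expression observed for such genes
  in real cohorts.

What the generator does *not* emulate: distance-decaying Hi-C signal,
sequence context, incomplete penetrance, noisy or imprecise breakpoints,
ontology mis-annotation, and inter-chromosomal contacts. Passing recovery
tests therefore demonstrates the correctness of the decision logic under
its stated assumptions, not calibrated performance on real patient data.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; VCF (1-based) is converted
  exactly once at parse time, BED/BEDPE is taken as is.
- TSS: interval start on '+', end − 1 on '−' strands.
- Junction-at-gene-edge (distance 0, body intact) classifies as adjacent.
- All-zero v4C profiles, genes without promoter-anchored interactions, and
  genes absent from the expression table score 0 / false on the affected
  components (logged).
- Report rows are deterministically ordered (patient, tier, descending
  total phenomatch, symbol); identical inputs give byte-identical outputs.
- Junction matching treats the ±tolerance as inclusive.

## Known limitations

- Disruption only: gain-of-interaction effects (neo-TADs, enhancer
  adoption) are out of scope by design.
- The phenomatch formula is a faithful conventional reconstruction, not a
  byte-compatible reimplementation of any specific tool.
- Frequency-database filtering of common SVs is expressed through the same
  generic junction-matching rule; no equivalence with any in-house database
  pipeline is claimed.
- No liftover: all inputs must share one genome build.
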