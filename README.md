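# svdriver

Candidate driver gene prioritization for patients with de novo structural
variants (SVs).

Most SV interpretation tools only consider genes an SV hits directly. Yet a
balanced translocation can be pathogenic without touching any exon, by
separating an intact gene from its enhancers — a *position effect* mediated
by the disruption of topologically associating domains (TADs) and
long-range chromatin contacts. `svdriver` integrates, per gene and patient:

- **Phenotype association** — Resnik-style phenomatching of the patient's
  HPO terms against gene HPO annotations (per-term score
  `max_g IC(MICA(t, g))`, thresholds > 1 for low and > 5 for high matches),
  a 0–5 disease-association score (pLI > 0.9, RVIS < 10, HI < 10 or
  ClinGen 1–3, DDG2P, OMIM), and dominant/X-linked inheritance
  compatibility, discretized to none/weak/medium/strong;
- **SV effect** — direct classification
  (deleted/duplicated/truncated/inverted/adjacent) plus a 0–6 position-
  effect support score counting TAD disruption, enhancer loss, virtual-4C
  disruption, PCHiC and DHS-connection disruption, and patient differential
  expression, discretized to none/weak/strong (> 1 / > 3 support for
  adjacent genes; deletion/truncation is always strong);
- **Tiering** — T1 = strong + strong; T2 = weak/medium association with a
  strong effect or medium/strong association with a weak effect;
  T3 = weak + weak.

It also implements the upstream junction-level filters (dual-caller ±100 bp
intersection, trio de novo filtering) and a synthetic-data generator that
writes complete toy cohorts — ontology, gene tables, TADs, binned Hi-C,
enhancers, expression, PCHiC/DHS, patient SVs — with planted drivers and a
ground-truth tier per patient.

See `docs/methods.md` for the full model description and every tunable
cutoff.

## Worked example

Simulate an 8-patient cohort and analyze one patient:

```bash
svdriver simulate --seed 5 --patients 8 --out fixtures/
svdriver run \
    --sv fixtures/patients/P01.svs.bedpe \
    --hpo fixtures/patients/P01.hpo.tsv \
    --de fixtures/patients/P01.de.tsv \
    --genes fixtures/genes.tsv \
    --gene2hpo fixtures/gene2hpo.tsv \
    --ontology fixtures/ontology.obo \
    --resources fixtures/resources.yaml \
    --out report/
```

which prints

```
wrote 8 patients, 60 genes, 3 cell types -> fixtures
ground truth: fixtures/ground_truth.tsv
25 genes in scope; 1 T1/T2 candidate drivers -> report/
```

`report/drivers.tsv` holds one audit row per in-scope gene. For P01 the
planted driver is a deletion of GENE0001 in a patient sharing three rare
HPO terms with that gene; the top row reads (abridged):

```
patient_id gene      tier association effect  effect_basis direct_category total_phenomatch pct_high support_score
P01        GENE0001  T1   strong      strong  both         deleted         28.1729          37.50    5
```

i.e. the deleted gene matches > 25% of the patient's HPO terms with high
phenomatches (3 of 8 terms above score 5), carries a disease-association
score of 5 with an AD inheritance mode, and is strongly affected — a T1
candidate driver. `report/patients.tsv` and `report/cohort.json` summarize
per patient (T1/T2/T3 counts, percentage of HPO terms explained) and per
cohort (fraction of patients with a T1/T2 driver, direct / position / both
breakdown).

The junction-level filters are available standalone:

```bash
svdriver intersect-callsets --primary manta.bedpe --confirm delly.bedpe --tolerance 100 --out confirmed.bedpe
svdriver denovo-filter --child child.bedpe --father father.bedpe --mother mother.bedpe --out denovo.bedpe
```

Everything is also a library (`svdriver.run_cohort`,
`svdriver.phenomatch_gene`, `svdriver.evaluate_position_effect`, ...).

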