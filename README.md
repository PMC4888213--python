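# oncointerp

Integrative genomic interpretation for personalized cancer therapy (PCT).
Given a patient's somatic and germline variant calls (VCF), copy-number
segments and gene-expression tables, `oncointerp` produces the kind of
structured "genomic findings" document a molecular tumor board works from:
a tiered list of cancer-relevant somatic mutations, evidence-ranked drug
response predictions, toxicity and prognosis calls, pathway projections,
clinical-trial matches, actionability counts and in-silico comparisons
against targeted gene panels — all driven by a curated, data-driven
knowledge base (a compact, fully executable mini-KB ships with the
package).

It is aimed at bioinformaticians building or studying clinical cancer
genomics interpretation pipelines, and at methodologists who need a fully
deterministic, simulation-backed testbed for tiering, decision-tree and
panel-comparison logic.

## The core model

**Somatic mutation tiers.** Every somatic mutation is assigned exactly one
of five tiers, first match wins:

1. the gene is curated for the patient's cancer type;
2. the gene is a pan-cancer gene (not tier 1);
3. the gene is curated for some other cancer type;
4. the exact (gene, p. change) pair is catalogued in tumors but the gene is
   not a known cancer gene;
5. everything else.

Tiers 1–4 are *cancer-relevant*.

**Drug response decision tree.** Therapies split into tier 1 (FDA-approved
for the tumor type) and tier 2 (everything else, including experimental
agents). For each tier-1 drug, biomarker rules are walked strictly in
evidence order *Definitive > Strong > Moderate > Weak*; the first level with
a matching rule fixes the call (benefit / lack-of-benefit / resistance) and
lower levels are never consulted. Tier-2 recommendations come from a
drug–target table: activation of a druggable oncogenic node (mutation, copy
gain or overexpression), or loss of a suppressor gating a druggable axis,
yields a sensitivity call; curated feedback-loop pairs and two-pathway
lesions trigger combination recommendations. Any alteration supporting a
tier-1 or tier-2 recommendation is an *actionable alteration*, counted in
gene × source units (somatic / CNA / germline / expression).

**Statistics.** Mutations/Mb (non-synonymous + splice SNVs on canonical
isoforms over the coding target area), the six-class substitution spectrum
in the pyrimidine convention (C>A, C>G, C>T, T>A, T>C, T>G), tumor purity
from the somatic allelic-fraction distribution (purity = 2 × the clonal AF
cluster center under a diploid-heterozygous model), cross-platform CNA
concordance via a break-union genome partition and length-weighted Pearson
correlation, two-sample Kolmogorov–Smirnov comparison, and nearest-centroid
(Spearman) intrinsic-subtype calls.

## Worked example

Write one of the packaged colorectal cases to disk and interpret it:

```python
from oncointerp.knowledgebase import packaged_kb
from oncointerp.synthetic import table_fixtures
from oncointerp.cohort_io import write_profile_dir

kb = packaged_kb()
p0025 = next(p for p in table_fixtures(kb)["colorectal"] if p.patient_id == "P0025")
write_profile_dir("demo/P0025", p0025)
```

```bash
oncointerp interpret demo/P0025 --out demo/out --seed 1
```

The rendered findings (`demo/out/P0025.findings.md`) begin:

```
# Genomic findings — P0025

Cancer type: **colorectal**
Cancer-relevant somatic mutations (tiers 1–4): 4
Actionable alterations: 7

## Drug response

| Drug | Tier | Effect | Evidence | Basis |
|---|---|---|---|---|
| cetuximab | 1 | lack of benefit | Strong | NRAS p.Q61R |
| panitumumab | 1 | lack of benefit | Strong | NRAS p.Q61R |
| bevacizumab | 1 | benefit | Moderate | KDR p.Q472H, CXCR2 p.S276T |
| oxaliplatin | 1 | lack of benefit | Moderate | ERCC1 p.N118N, ERCC2 p.K751Q, ERCC5 p.D1104H, XRCC1 p.R399Q |
| trametinib | 2 | sensitivity | Moderate | NRAS p.Q61R |
```

Read: the activating NRAS p.Q61R predicts no benefit from anti-EGFR
antibodies at Strong evidence; germline KDR/CXCR2 variants predict benefit
from bevacizumab while germline ERCC1/2/5 and XRCC1 variants predict
reduced benefit (and elevated toxicity) from oxaliplatin — germline calls
no tumor-only panel could make. The seven actionable alterations are
1 somatic + 6 germline gene×source units.

Comparing the integrative profile against three approximate commercial
panel designs on the 19-patient colorectal cohort:

```bash
oncointerp compare-panels demo/cohort --out demo/table.tsv
```

```
approach              mean_cancer_relevant (range)  ...  mean_actionable (range)  fold_change_actionable
integrative           3.4 (1-5)                          1.58 (0-7)
hotspot_cancer_panel  1.9 (0-3)                          0.89 (0-2)               1.76
oncomine_like         1.9 (1-3)                          1.00 (0-2)               1.58
foundation_like       3.3 (1-5)                          1.11 (0-3)               1.43
```

Every panel fold-change is ≥ 1 by construction: a panel sees a subset of
the integrative profile and is interpreted with the same knowledge base.

Other subcommands: `oncointerp simulate` (seeded synthetic cohorts),
`oncointerp stats` (per-tumor mutations/Mb + spectrum), and
`oncointerp concordance` (cross-platform CNA correlation).

## Layout

- `src/oncointerp/variant_model.py` — domain types, VCF/TSV IO, substitution
  classes, assay selection
- `src/oncointerp/knowledgebase.py` — KB schemas, loader, predicate grammar
- `src/oncointerp/tiering.py`, `therapy.py`, `toxicity.py` — interpretation
  engines
- `src/oncointerp/stats.py` — cohort/tumor statistics
- `src/oncointerp/panels.py` — in-silico panel restriction and comparison
- `src/oncointerp/report.py`, `cli.py` — findings documents and the CLI
- `src/oncointerp/synthetic.py` — seeded generators and encoded cohorts
- `src/oncointerp/data/kb/` — the packaged mini knowledge base (TSV)
- `docs/methods.md` — models, assumptions, parameter choices, limitations
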