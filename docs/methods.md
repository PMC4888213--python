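# Methods

This note documents the models and procedures implemented in `oncointerp`,
the assumptions behind them, the parameters that matter, and what the
packaged synthetic data do and do not establish.

## Unit of analysis and conventions

A `PatientProfile` bundles one patient's somatic variants, germline
variants, copy-number (CNA) segments and gene-level expression records.
Coordinates are 1-based inclusive everywhere internally (the VCF
convention); BED input is converted on read. Gene symbols are upper-cased
and matched exactly. Protein changes are normalized HGVS p. strings with
isoform qualifiers stripped; a coarse consequence class (missense,
nonsense, frameshift, inframe indel, splice site, synonymous, other) is
inferred from the p. string when no explicit class is supplied. Somatic
VCFs may be multi-sample (one column per tumor specimen of a patient); a
variant called in two or more specimens is flagged *recurrent*. Records
whose FILTER is neither `PASS` nor `.` are dropped on read by default —
they represent calls rejected during manual review — with a flag to keep
them.

## Mutation tiering

Five tiers partition all somatic mutations; rules are evaluated in order
and the first match wins (see README for the definitions). Two choices are
worth making explicit. Tier-4 catalog matching requires an exact
protein-change string match after normalization; a variant without a
protein change cannot match the catalog — exact matching is the
conservative reading of "previously observed in tumors", and coordinates
are deliberately not used as a fallback. Second, an unknown cancer type
(no curated gene list) makes tier 1 unreachable; evaluation falls through
to the pan-/other-cancer rules with a warning rather than failing.
Tiering is monotone in the knowledge base: adding a gene to a cancer-type
list can only lower (improve) tier numbers.

## Drug response

Tier-1 drugs are those approved for the patient's tumor type; each is
evaluated by walking its biomarker rules strictly in evidence order
Definitive > Strong > Moderate > Weak and stopping at the first level with
a match (the evidence short-circuit). When one level contains both a
positive and a negative match for the same drug, the call resolves to the
negative (lack-of-benefit / resistance) — a conservative clinical default
for a situation the evidence hierarchy itself does not order.

Tier-2 recommendations are data-driven through a drug–target table. Each
row names a drug, a target gene, and a *trigger*: `activation` (matched by
an activating somatic mutation, a copy gain, or overexpression of the
gene), `loss` (an inactivating mutation or copy loss of a suppressor whose
loss activates the drugged axis — e.g. PTEN loss recommending mTOR-axis
inhibition), or `germline` (e.g. DNA-repair genes recommending PARP
inhibition). Whether a somatic variant is "activating" is resolved from a
curated per-gene list of activating changes, with a fallback: a catalogued
missense hotspot change in an oncogene is activating, and a truncating
change (nonsense, frameshift, splice site) in a tumor suppressor is
inactivating. Combination therapy is recommended only from an explicit
curated feedback-loop pair table plus a generic rule firing when tier-2
lesions span at least two independent pathways; no broader combination
algorithm is attempted.

Actionability is counted in gene × source units over the union of
supporting alterations of all non-empty tier-1 predictions and all tier-2
recommendations; the union is idempotent, so duplicated prediction lists
cannot inflate counts, and removing knowledge-base rules can never
increase a patient's count. Germline variants that modulate efficacy or
toxicity of standard chemotherapy count as actionable germline
alterations.

One consequence of the evidence short-circuit is that rules for the same
drug at *different* levels are not independent contributors to
actionability: a Weak-level gene never surfaces when a Moderate-level gene
for the same drug also matches. The packaged mini-KB therefore keeps rule
families that describe interchangeable evidence (e.g. the four germline
oxaliplatin pharmacogenomic markers) at a single level.

## Toxicity and prognosis

Toxicity prediction for a tier-1 drug matches germline/somatic marker
rules and reports one of Severe Toxicity, Elevated Toxicity, Normal, Less
Toxicity. With multiple matches the most severe outcome wins regardless of
rule order (clinical-safety bias); with no match the prediction is Normal,
which is therefore exactly the no-evidence state. Prognostic biomarkers are
matched per cancer type and all matches are reported without aggregation —
opposite directions may legitimately co-occur and the report preserves
both.

## Panels and cohort comparison

Panel definitions come in three modes: `hotspot` keeps somatic SNV/indels
whose genomic position falls in a hotspot interval; `full_gene` keeps
somatic variants on panel genes; `full_gene_plus_cna` additionally keeps
CNA events on panel genes. No DNA panel detects expression, and the three
shipped panels are tumor-only (no germline). The shipped panel contents
are *approximate* editable stand-ins for three commercial designs — a
small hotspot panel, a mid-size full-gene panel and a large gene+CNA panel
— since exact commercial contents are versioned products; hotspot windows
are expressed as codon ranges per gene and converted to genomic intervals
through the packaged loci, covering the classic hotspot codons (KRAS
12/13/61, BRAF 600, RET 634/918, APC 1309, TP53 DNA-binding domain) while
deliberately excluding the EGFR extracellular domain around codon 587.

The cohort comparison re-runs tiering and the full therapy engine on each
panel-restricted profile with the *same* knowledge base, so detection
breadth is the only compared variable. This yields the restriction
invariant: panel-detected cancer-relevant and actionable counts are
subsets of the integrative counts, hence every defined fold-change
(integrative mean / panel mean) is ≥ 1; a zero panel mean leaves the fold
change undefined rather than infinite.

## Statistics

- **Mutations/Mb** counts non-synonymous and splice-site SNVs on canonical
  isoforms divided by the coding-exon area of the sequencing target. The
  denominator is a configuration value (CLI default 30 Mb, a generic
  exome-coding placeholder) because real target regions are kit-specific.
- **Spectrum**: SNVs collapse onto six classes named by the pyrimidine
  member of the base pair; indels are excluded from the denominator.
- **Purity**: under a diploid-heterozygous clonal model a somatic mutation
  sits at AF = purity/2, so purity = min(1, 2 × center of the clonal AF
  cluster). The clonal cluster is the upper cluster of an exact 1-D
  two-cluster (2-means) split of the AFs and its center is the median,
  robust to a subclonal tail. Estimates from fewer than 10 AFs are flagged
  unreliable; purity < 5 % sets a low-purity flag. This estimator is a
  documented stand-in with the decision-relevant behavior (AF-distribution
  based, low-purity flagging); it assumes diploidy and ignores copy-number
  distortion of AFs.
- **CNA concordance**: the genome territory covered by both platforms is
  cut at every segment break from either side, so each partition overlaps
  exactly one segment per platform; the per-partition segment statistics
  (log2 copy ratio, log2 mirrored-BAF) are then correlated with
  length-weighted Pearson correlation. Zero variance on either side yields
  NaN with a warning rather than a fabricated value. Normal and undecided
  segments participate in partitions. Group comparisons (e.g. FFPE- vs
  frozen-derived correlation distributions) use the two-sided two-sample
  Kolmogorov–Smirnov test (`scipy.stats.ks_2samp`, exact p where sample
  sizes permit).
- **Expression**: levels are called high/low/intermediate against a
  reference distribution by quantile (defaults 0.75/0.25); fold changes are
  tumor/normal with an optional pseudocount, off by default, and a positive
  normal value is required otherwise.
- **Subtype**: nearest-centroid classification by Spearman correlation over
  shared signature genes (at least 50 % of the signature must be present),
  ties broken by declared label order with a warning. Spearman is the
  common practice for intrinsic-subtype centroids; the packaged tests use
  synthetic centroids, not a clinically validated signature.

## Synthetic data: what it emulates and what it does not

The generator draws, per patient: a cancer type from a configurable
mixture (default 40 % colorectal, 15 % breast, 10 % medullary thyroid
carcinoma, 35 % other — the shape of a small solid-tumor program cohort);
driver genes by independent Bernoulli draws at configured per-gene
frequencies with canonical protein changes; a background mutation load at
a lognormally dispersed per-Mb rate (default median 2.0/Mb, log-sd 0.2 —
modest within-type variability) with substitution classes drawn from the
spectrum weights (default C>T-dominant, as in most solid tumors); allelic
fractions from Binomial(depth, purity/2) with Poisson depths (mean 110)
and truncated-normal purity (mean 0.6, sd 0.15); and per-source
knowledge-base-actionable events at configured Poisson rates, implemented
by drawing distinct genes from per-cancer-type pools of events verified
actionable by probing the engine itself. Everything is deterministic given
the mandatory seed, and generated profiles round-trip exactly through the
package's file formats.

The encoded study cohorts (5 MTC, 19 colorectal, 7 breast profiles plus
one cancer-of-unknown-primary case with an activating EGFR
extracellular-domain mutation at 387/1998 reads) carry exactly the
alterations of their source tables; genomic coordinates are synthetic but
stable, derived from a packaged gene-locus table under a contiguous-CDS
toy gene model (codon *n* maps to locus start + 3(n−1)). Two rows of the
colorectal table render ambiguously; the encoding follows the per-gene
frequency row as the authoritative constraint and records the assignment
rationale in the fixture comments.

What passing tests on these data do **not** show: the generator has no
sequencing-artifact model (no FFPE damage, strand bias or mapping error),
no subclonal structure, no linkage between drivers and background load,
and independent genes — real cohorts violate all four. Recovery of
configured frequencies, spectra, purity and actionable means demonstrates
the pipeline's bookkeeping and estimators, not performance on real tumors.
The packaged mini-KB makes every encoded case executable but is a compact
stand-in, not a clinical knowledge base; absolute cohort means computed on
synthetic data depend on it and are not comparable to any real cohort.

## Numerical choices and degenerate inputs

Evidence levels and toxicity severities are fixed total orders; ties in
subtype correlation break to the declared label order with a warning; the
purity split is exact (all split points scanned), so no initialization is
involved anywhere. Empty inputs raise domain errors where a number would
be meaningless (purity of zero AFs, KS of an empty group, correlation of
fewer than two partitions) and return empty/zero results where that is the
honest answer (no matching rules, empty pathway projection, zero
actionable alterations). Findings documents are rendered as canonical
sorted-key JSON (the document of record, byte-identical across runs);
markdown regenerates from the JSON alone, and a shipped JSON schema
validates the structure.

## Known limitations

Gene fusions, liftover, variant calling and annotation-source management
are out of scope; expression-level calls rely on levels provided upstream
or on a user-supplied reference distribution; the assay-selection rules
model DNA-mass thresholds with a closed upper middle bracket (1.5–2.5 µg
inclusive runs panel+WES; strictly above 2.5 µg adds the array); and the
toxicity model forbids mixed outcomes per drug by construction
(most-severe-wins), which loses information when a knowledge base encodes
genuinely independent increased- and decreased-risk markers for one drug.
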