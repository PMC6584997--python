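# Methods

## The procedure

The pipeline implements a disease-based repurposing cascade for cutaneous
malignant melanoma. Its premise: genes and proteins implicated in the
disease by several independent lines of evidence are credible drug targets,
and an already-approved drug acting on such a target in the *right
direction* — suppressing a gain-of-function (GOF) contributor, boosting a
loss-of-function (LOF) one — is a repurposing candidate, provided it is not
already indicated for the disease and its transcriptional signature behaves
like known anti-melanoma drugs.

Stages, in order:

1. **Evidence ingestion.** Five table dialects are harmonized into one
   record type: GWAS rows (trait, mapped gene, SNP, p-value), PheWAS rows
   (phenotype, SNP, p-value, gene), metabolite→protein associations with an
   enzyme/transporter role, and two plain gene lists (differential
   expression; OMIM-style disease–gene). Gene symbols are uppercased and
   stripped; an optional alias map handles synonyms — no live nomenclature
   service is consulted, so runs are reproducible offline. Trait/phenotype
   filters are case-insensitive; p-value thresholds are **inclusive** (a
   PheWAS row at exactly p = 0.05 is retained, matching the boundary of the
   reported retained range). The GWAS reader does not enforce a
   significance cut by default: catalog exports are thresholded upstream,
   so the observed p-range is a property of the input. Multi-gene cells are
   exploded; intergenic labels ("TERT - CLPTM1L") split on the *spaced*
   hyphen only, so hyphenated symbols (HLA-B) survive.
2. **Integration.** One provenance profile per gene: the set of supporting
   sources, per-source record counts, and the minimum p-value where
   p-values exist (GWAS/PheWAS). Venn accounting counts genes per exact
   source combination; the counts partition the unified set by
   construction. Metabolomics proteins and the other sources' genes share
   one namespace after harmonization.
3. **Metabolite–protein network.** A bipartite graph, metabolites on one
   side, proteins on the other, edges labelled with the protein's role.
   The two classes are separate namespaces; exports prefix node names with
   `m:` / `p:` so a label collision cannot merge nodes. Multi-role
   duplicate edges are kept as parallel edges in GraphML and one line per
   role in SIF; both exports round-trip losslessly.
4. **Drug mapping.** Approved drugs (group filter configurable) with at
   least one target in the unified set; the target list of each candidate
   is restricted to in-set targets.
5. **Known-indication exclusion.** Trial lists carry no database
   accessions, so matching is by name, case-folded with punctuation and
   whitespace stripped.
6. **Concordance filter.** The verdict table is total over direction ×
   action: lowering actions (inhibitor, antagonist, blocker) are concordant
   with GOF, raising actions (agonist, inducer, activator) with LOF;
   substrate, binder and unknown are neutral (a substrate relationship
   carries no direction of effect — the published candidate table retains
   substrate drugs under both GOF and LOF); the remaining pairs are
   discordant. A drug is retained iff at least one *annotated* target is
   concordant or neutral; unannotated targets are ignored, and a drug with
   no annotated target is rejected with reason `NO_ANNOTATION`. The
   default policy is STRICT. A LENIENT policy downgrades a discordant
   verdict to neutral when the same target also carries a neutral action,
   accommodating mixed-mode entries (the published table itself contains
   one strict violation, a CYP1A2 inhibitor on a LOF annotation).
7. **Connectivity scoring.** The signed KS enrichment (README formula) per
   tag set per instance; the per-instance score is `ES_up − ES_down`,
   zeroed when the two share a sign (a same-signed pair carries no
   directional information), or the single-sided ES when one tag set is
   empty. Raw scores are rescaled across the whole instance collection —
   positives by the maximum positive raw, negatives by the magnitude of
   the minimum negative raw — so both extremes map to exactly ±1 and zero
   stays zero. Per drug: arithmetic mean over instances, plus a
   second-level KS enrichment of the drug's instance positions in the
   descending-score ordering of all instances (deterministic tie-break on
   instance id), signed so that concentration among the top-scoring
   instances is positive, consistent with the mean. Selection keeps drugs
   whose mean agrees in sign with the positive-anchor mean, disagrees with
   the negative-anchor mean, and exceeds a configurable magnitude
   threshold (default 0: the anchors define a direction, not a magnitude).
   Anchors with agreeing signs are a refused, erroneous configuration.
   Candidate drugs without panel entries are reported `NOT_IN_CMAP` and
   dropped.

## Numerical and degenerate-input choices

- The KS statistic is exact rational arithmetic over the rank grid up to
  float evaluation; it is checked against a brute-force oracle (explicit
  evaluation of both maxima over all j) exactly, not to a tolerance.
- Reversing a ranking does **not** negate ES exactly: the two running
  maxima use `j/t` vs `(j−1)/t`, so a top-concentrated score ES > 0
  reverses to exactly `−ES − 1/n`, and a tag set piled at *both* ends
  scores negative in either orientation. The tests assert this exact
  identity rather than a blanket sign flip.
- Ranking ties are forbidden (each signature is a strict permutation);
  rank-transforming upstream data is the caller's responsibility.
- Tag genes missing from a signature's universe raise an error naming the
  gene, surfacing harmonization bugs; `skip_missing` downgrades this to
  skipping for exploratory use.
- A batch whose raw scores are all one sign rescales only that side; zeros
  are preserved exactly. A drug's enrichment in a single-instance panel is
  defined as 0.
- Empty evidence produces an empty report with a warning, not an error;
  an empty gene set maps to zero candidates.
- Conflicting GOF/LOF annotations for one target, and positive/negative
  anchor sets that agree in sign, are input errors, never silently
  resolved.

## The synthetic generator

The generator fabricates every input with planted, recoverable structure;
its defaults are the study conditions of the published melanoma cascade:
per-source unique gene counts 55 (GWAS), 260 (PheWAS), 616 (metabolomics
proteins), 27 (transcriptomics), 11 (biomedical); 50 multi-source genes;
GWAS p-values log-uniform on [4e−37, 8e−06] and PheWAS on
[1.106e−16, 0.05] with the endpoints planted exactly; 23 metabolites with
800 unique associations covering every protein; 731 mapped drugs on 193
targets; 75 trial-overlapping drugs; 277 survivors on 74 annotated
targets; and a signature panel in which 35 survivors are planted active,
27 are absent (`NOT_IN_CMAP`), and the rest are planted reversed, plus
active positive anchors and a reversed negative anchor.

Five of the multi-source genes are the literature-named ones (TYR in
PheWAS+GWAS+biomedical, TERT in GWAS+biomedical, CYP1B1 in
metabolomics+GWAS, CYP19A1 and CYP1A1 in metabolomics+PheWAS); the rest
are synthetic two-source genes placed into the sources with most remaining
capacity. Note the arithmetic consequence: with these per-source sizes
(summing to 969) and 50 genes shared between sources, the unified set has
918 members — the per-source counts bound the union, and the pipeline
reports the computed value.

Signatures are strict permutations of a 1000-gene universe, 4 instances
per drug. Active instances place up-tags near the top and down-tags near
the bottom with truncated-geometric rank offsets, P(offset) ∝ e^(−c·offset)
with concentration c = 0.02 (mean offset ≈ 50 ranks — strong but not
degenerate concentration); reversed instances swap the two tag sets;
inactive instances are uniform permutations. As c → ∞ an active drug's
scaled score approaches 1. Geometric bias was chosen for its single
interpretable parameter and closed-form extreme.

One integer seed drives one named pseudo-random stream per file type
(seed-sequence splitting on a label hash), so adding a new generator never
perturbs existing fixtures and regeneration is byte-identical. All planted
cascade counts are structural — exact for every seed; only gene/drug
identities and p-value draws vary.

**What passing the planted-recovery tests shows, and what it does not.**
The generator's drugs separate cleanly into active and reversed signature
classes, its evidence tables contain decoys only of the kinds the parsers
filter (wrong traits, non-significant p-values, wrong approval groups,
out-of-set targets), and its trial list matches candidates up to
case/punctuation variants. Recovery therefore demonstrates that the
cascade's logic is correct and leak-free, not that the method would
achieve any particular sensitivity on real catalog exports, where symbol
synonymy, borderline connectivity scores, and incomplete pathogenesis
annotation dominate the error budget.

## The packaged candidate table

`data/table1.tsv` transcribes the published 35-drug candidate table, one
row per (drug, target) with the drug-level action set, pathogenic
direction and literature-evidence flag repeated across a drug's targets.
Counting unique target symbols as printed yields 21; the publication
states 20 without identifying the merged symbol, so the package reports
the computed count and does not force agreement. The stage counts of the
published cascade also contain one arithmetic inconsistency (731 mapped
drugs minus 75 excluded is 656, stated as 658); the pipeline always
reports its computed counts.

## Problem sizes

The shipped tests and the acceptance script run the generator at its
default scale (≈1,000 instances of a 1,000-gene universe, 916 drug–target
rows) in a few seconds on one CPU; unit tests use a smaller configuration
(200-gene universe) for speed. Both scales exercise identical code paths.

## Known limitations

- No live querying of GWAS/PheWAS/HMDB/DrugBank/OMIM/CMap services; all
  inputs are flat files, and database-version-dependent headline counts
  are reproducible only against fixed exports.
- Gene harmonization is lexical (uppercase + strip + optional alias map);
  true synonym resolution needs an external nomenclature table.
- Permutation p-values and specificity scores for connectivity results are
  not computed.
- The indication-exclusion join is name-level; a drug listed under a brand
  name in the trial list would escape exclusion.
- Network export targets SIF/GraphML for downstream viewers; no layout or
  styling is produced.
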