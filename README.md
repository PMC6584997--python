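# melanoseek

Disease-based drug repurposing for cutaneous malignant melanoma, built as a
tested, fully offline pipeline. Given tabular evidence linking genes and
proteins to melanoma from five kinds of study — GWAS catalog exports, PheWAS
catalog exports, HMDB-style metabolite→protein associations, a
differentially-expressed gene list, and OMIM-style disease–gene tables —
the package:

1. **integrates** the evidence into per-gene provenance profiles (which
   sources support each gene, at what best p-value) and a unified
   melanoma gene/protein set;
2. **reconstructs** the bipartite metabolite–protein network behind the
   metabolomics evidence and exports it as SIF/GraphML;
3. **maps** the gene set onto a DrugBank-style drug–target table, keeping
   approved drugs with at least one in-set target;
4. **excludes** drugs already in melanoma-related clinical trials
   (name-level matching, case/punctuation-insensitive);
5. **filters** on pathogenesis/action concordance: a drug survives only if
   it inhibits/antagonizes a gain-of-function (GOF) target or
   activates/induces a loss-of-function (LOF) target (substrate/binder
   actions are direction-neutral);
6. **scores** the survivors against Connectivity-Map-style ranked expression
   signatures and keeps drugs whose connectivity agrees in sign with
   positive anchor drugs (paclitaxel, vinblastine) and disagrees with the
   negative anchor (selegiline).

It is aimed at computational drug-repurposing researchers who want the whole
cascade reproducible from flat files, with an audit trail for every drug at
every stage.

## The statistic at the core

Each drug *instance* is a strict ranking of the gene universe (position 1 =
most up-regulated). For a tag set of *t* query genes with ascending rank
positions V(1) ≤ … ≤ V(t) in a list of length *n*, the signed
Kolmogorov–Smirnov enrichment is

```
a  = max_j [ j/t − V(j)/n ]
b  = max_j [ V(j)/n − (j−1)/t ]
ES = a  if a > b,  else  −b
```

so tags concentrated at the top give ES → +1 and at the bottom ES → −1.
A per-instance connectivity score combines up- and down-tag enrichment
(zeroed when the two agree in sign, hence carry no direction) and is
rescaled across the instance collection so the extreme raw scores map to
exactly ±1. Per-drug results carry the mean over instances plus a
second-level KS enrichment of the drug's instances within the score-ordered
instance list.

## Worked example

All inputs can be fabricated by the packaged generator, which plants a known
ground truth at the scale of the published melanoma study (55/260/616/27/11
genes per source, 50 multi-source genes, 731 mapped drugs on 193 targets,
75 trial-overlapping drugs, 277 concordant survivors on 74 annotated
targets, 35 connectivity-concordant finalists):

```bash
melanoseek synth --seed 1 --out fixtures/
melanoseek run --fixtures fixtures/ --out out/
```

which prints the per-stage accounting:

```
ingest	drugs=None	targets=918
integrate	drugs=None	targets=918
metnet	drugs=None	targets=616
map	drugs=731	targets=193
exclude	drugs=656	targets=193
pathofilter	drugs=277	targets=74
connectivity	drugs=250	targets=None
select	drugs=35	targets=34
```

Reading: 918 unique genes/proteins were ingested across the five sources
(the per-source counts overlap in 50 genes); the metabolite–protein network
carries 616 proteins; 731 approved drugs map onto 193 in-set targets; 75
known-indication drugs are excluded leaving 656; 277 drugs on 74 annotated
targets pass the GOF/LOF concordance filter; 250 of them have signature
panel entries (27 are reported `NOT_IN_CMAP`), and 35 drugs agree with the
anchors and are retained. `out/report.json` holds the full report,
`out/filter_trace.tsv` the per-drug audit trail, and
`out/connectivity.tsv` the per-drug mean/enrichment scores.

The packaged transcription of the published 35-candidate table can be
summarized with:

```bash
melanoseek check-table1
```

which reports 35 drugs (30 with literature evidence, 5 without), 21 unique
target symbols, and a concordance tally over the 52 drug–target pairs.

## Layout

```
src/melanoseek/
  types.py         shared domain types (evidence, drugs, annotations)
  evidence_io.py   TSV/CSV readers/writers for all table dialects
  integration.py   per-gene provenance profiles, Venn accounting
  metnet.py        bipartite metabolite-protein network + SIF/GraphML
  pharm.py         map / exclude / concordance cascade with audit trail
  connectivity.py  KS enrichment, connectivity scores, selection, RNK/GMT
  synthetic.py     fixture generator with planted ground truth
  pipeline.py      end-to-end orchestration + candidate-table checks
  cli.py           melanoseek run | synth | check-table1 | score
  data/table1.tsv  transcribed published candidate table
```

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
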