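# metaregnet

Multi-cohort discovery of transcriptional regulators of a target gene:
consensus mutual-information network inference, random-effects correlation
meta-analysis, promoter binding-site prediction with conservation filtering,
regulon enrichment, and qPCR quantification — exercised end to end on
synthetic data with planted ground truth.

## The problem

Which transcription factors drive the expression of a gene of interest —
for example a prognostic marker such as *THY1* in gastric adenocarcinoma —
when the available evidence is a handful of heterogeneous tumor expression
cohorts (RNA-seq counts and microarray intensities), each split into
histological subtypes?  Single-cohort network inference is fragile; this
package implements the multi-cohort refinement chain used to make such
calls robust:

1. **Per-cohort networks.**  For each cohort x subtype, an ARACne-style
   network is inferred: edge weight is the plug-in mutual information (MI,
   in bits) on rank-binned profiles; significance comes from a pooled
   permutation null with Benjamini–Hochberg adjustment; edges must then
   survive a bootstrap robustness screen and data-processing-inequality
   (DPI) triangle pruning, and receive a sign from the Pearson correlation.
2. **Consensus.**  Only edges present (with the same sign) in *every*
   network survive; the consensus weight is the mean MI.
3. **Effect-size filter.**  For each consensus regulator of the focal gene,
   cohort-level Pearson correlations are pooled per subtype with a
   Fisher-z random-effects model (z = atanh r, v = 1/(n−3),
   DerSimonian–Laird τ²); regulators need |pooled r| > 0.4 with p < 0.05 in
   **both** subtypes.
4. **Binding sites.**  Surviving regulators must have a canonical binding
   site (PWM hit at ≥ 85% relative score whose matched string equals the
   literature consensus) in the focal gene's 3-kb promoter or first intron.
5. **Supporting evidence.**  Cross-species conservation of each site,
   hypergeometric over-representation of each regulon in gene-set
   collections, and RT-qPCR (2^−ΔΔCt) / ChIP-qPCR (% input) quantification.

Because the real cohorts are controlled-access, the package ships a
first-class synthetic-data module (`metaregnet.syndata`) that generates the
whole study — three cohorts on two platform models driven by one planted
signed network with a co-activated six-regulator module on a focal hub
gene, planted promoter sites, ortholog alignments, and qPCR plates — so
every stage is testable against known truth.

## Worked example

```bash
python examples/06_full_pipeline.py
```

runs the complete chain on the default synthetic design (300 genes, 30 TFs,
3 cohorts × 2 subtypes × 100 samples, 1000 permutations and 1000 bootstraps
per network, seed 1) and prints:

```
planted regulators:   TF001, TF003, TF014, TF016, TF025, TF027
recovered regulators: TF001, TF014, TF016, TF025, TF027
recall 0.833  precision 1.000

final regulator evidence (consensus MI, pooled r per subtype, sites):
  TF001: MI=1.02 sign=+1 sites=2  diffuse=+0.87  intestinal=+0.87
  TF014: MI=0.94 sign=+1 sites=2  diffuse=+0.86  intestinal=+0.83
  TF016: MI=0.83 sign=+1 sites=2  diffuse=+0.83  intestinal=+0.80
  TF025: MI=0.88 sign=-1 sites=2  diffuse=-0.84  intestinal=-0.84
  TF027: MI=0.93 sign=-1 sites=2  diffuse=-0.86  intestinal=-0.85
```

Five of the six planted regulators are recovered with no false positives at
this seed (the sixth sits just below the significance cutoff in one of the
six networks, so the strict all-networks consensus excludes it).
Recall/precision score the final list against the planted regulator module;
the per-regulator rows show the consensus MI (bits), the sign of action,
the pooled per-subtype correlations that passed the |r| > 0.4 filter, and
the number of canonical binding sites found in the planted promoter/intron.
The other examples (`examples/01`–`05`) demonstrate each capability in
isolation: cohort simulation, single-network inference, meta-analysis,
motif scanning + conservation, and qPCR quantification.

A thin CLI wraps the two shell-level tasks:

```bash
metaregnet simulate --seed 2 --out scratch/sim      # synthetic dataset on disk
metaregnet run-all --seed 1 --out scratch/run       # full pipeline + report bundle
```

## Layout

```
src/metaregnet/
  syndata.py    synthetic cohorts, promoters, alignments, qPCR plates
  dataio.py     expression-matrix TSV IO, gene-space intersection, quartiles
  normalize.py  median-of-ratios + VST, quantile normalization, EB batch
  trn.py        MI, permutation/bootstrap significance, DPI, signed networks
  consensus.py  network intersection, regulon classes, power-law topology
  metacorr.py   Fisher-z random-effects meta-analysis, regulator filter
  motif.py      JASPAR PWMs, double-strand scanning, canonical-site filter
  conserve.py   aligned blocks, coordinate projection, conservation grids
  enrich.py     GMT gene sets, hypergeometric ORA, BH adjustment
  qpcr.py       2^-ddCt folds, % input, IgG subtraction, rank tests
  pipeline.py   end-to-end orchestration with manifests and reports
  cli.py        thin `metaregnet` command
```

`docs/methods.md` documents the models, estimators, synthetic study
conditions and numerical conventions in detail.
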