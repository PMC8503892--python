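# epnsig

Molecular-group classification of paediatric ependymomas from targeted
expression signatures.

## The problem

Paediatric ependymomas are molecularly heterogeneous. Most supratentorial
tumours carry an oncogenic fusion — *ZFTA–RELA* or *YAP1–MAMLD1* — while
posterior-fossa (PF) tumours lack recurrent mutations and split into the
expression/methylation groups PFA (younger patients, worse prognosis) and
PFB. Group membership matters clinically, but methylation arrays and RNA
sequencing are expensive for routine FFPE material. A practical alternative
is digital counting of a *small* panel of group-specific marker genes
(NanoString nCounter): 4–5 signature genes per group plus housekeeping
controls, classified by hierarchical clustering against reference samples
of known fusion status.

`epnsig` implements that workflow end to end as a tested Python library:

1. **Marker discovery** (`epnsig.markers`) — from a labelled multi-entity
   expression matrix: quantile normalization, log2 transform, variance
   filter (var < 0.25 dropped), then a resampled Student t-test: the target
   group (size *t*) is compared 100× against equal-sized draws from the
   pooled other entities. Per probe, the mean p-value and mean linear
   fold-change `2^(Δ mean log2)` are the marker score; candidates need a
   fold ≥ 5 within the top 20 significance positions.
2. **nCounter normalization** (`epnsig.nanostring`) — per-lane scaling by
   the batch mean of positive-control geometric means (technical), then the
   same using the housekeeping genes ACTB/GAPDH/TBP (biological), then
   log2(x+1) of the endogenous counts.
3. **Group assignment** (`epnsig.classify`) — average-linkage hierarchical
   clustering on Euclidean distances over the signature genes:
   reference-anchored RELA+/YAP1+/NC calls for supratentorial tumours,
   PFA/PFB with outlier detection, PFA1/PFA2 sub-clustering (SKAP2/WIF1 vs
   EN2/CNPY1), and a two-gene NELL2/LAMA2 trichotomy.
4. **Clinical statistics** (`epnsig.stats`) — Fisher's exact test for
   signature-vs-fusion concordance, Kaplan–Meier OS/PFS with log-rank
   comparisons, Student t-tests, and survivor counting rules. A 15-patient
   supratentorial clinical table ships with the package
   (`epnsig.load_table2()`).
5. **Synthetic cohorts** (`epnsig.simulate`) — generators for labelled
   expression cohorts with planted markers, nCounter lane batches
   (negative-binomial counts, lognormal lane factors, positive-control
   ladder) and survival tables with designed hazards, so every stage is
   testable without any external download.

## Worked example

```sh
python examples/clinical_statistics.py
```

prints, from the packaged patient table:

```
signature class vs ZFTA-RELA fusion (YAP1+ excluded):
  RELA+ : 9 detected, 1 not detected
  NC    : 0 detected, 4 not detected
  two-sided Fisher exact p = 0.005
The RELA+ expression signature is strongly associated with the fusion.

RELA+ patients with verified survival >= 5 years: 8 of 10
```

The 2×2 table counts ZFTA-RELA fusion detections among samples with and
without the RELA+ expression signature; p = 0.005 is the exact two-sided
(minimum-likelihood) hypergeometric tail, meaning such a concordance is
very unlikely if signature and fusion were unrelated. Eight of the ten
RELA+ patients have verified follow-up of at least five years without
death.

The other examples each exercise one capability and state what they print:

```sh
python examples/marker_discovery.py              # resampled t-test marker selection
python examples/supratentorial_classification.py # RELA+/YAP1+/NC assignment
python examples/posterior_fossa_classification.py# PFA/PFB, PFA1/2, NELL2/LAMA2
```

A thin CLI wraps the same stages (`epnsig simulate|select-markers|
normalize|classify|stats|run`); `epnsig run --demo --out out/ --seed 7`
runs a full simulate → normalize → classify → stats pipeline and writes a
`report.json` with provenance (config hash, seed, version).

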