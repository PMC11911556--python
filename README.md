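# m5censemble

Ensemble identification of 5-methylcytosine (m5C) sites in RNA from
fixed-length sequence windows.

m5C is a post-transcriptional cytosine modification involved in mRNA
export, stability and translation; locating modified cytosines
experimentally is expensive, so sequence-based classifiers are used to
prioritize candidate sites. `m5censemble` implements a full prediction
pipeline for this problem: each candidate site is represented as a
41-nt RNA window over {A, C, G, U} with the candidate C at position 21,
mapped to a positional/compositional feature vector, and classified by
bagging or boosting tree ensembles.

## Feature stack

Each window `P = R1 R2 … R41` is described by 434 features:

- **Statistical moments (30).** The numerically encoded window
  (A=1, C=2, G=3, U=4) is embedded row-major in a 7×7 matrix `β` and
  summarized by raw moments `R_uv = Σ_a Σ_b a^u b^v β_ab`, central
  moments `n_ij = Σ (a−x̄)^i (b−ȳ)^j β_ab`, and orthonormalized discrete
  Hahn moments `H_ij = Σ_x Σ_y h̃_i(x) h̃_j(y) β_xy`, for all orders
  u+v ≤ 3 (10 per family).
- **PRIM / RPRIM.** Position relative incidence matrices at mono-, di-
  and tri-nucleotide granularity (4×4, 16×16, 64×64): entry (i, j)
  accumulates the offsets of every occurrence of k-mer *j* after the
  first occurrence of k-mer *i*. The mono matrices enter the feature
  vector raw (16 values each); the di/tri matrices are reduced to their
  30 moment coefficients. RPRIM is the PRIM of the reversed window.
- **FV / AAPIV / RAAPIV (84 each).** Overlapping k-mer counts; the
  accumulative absolute position incidence vector ρ_i = sum of the
  1-based positions of k-mer *i*'s occurrences; and its reverse-order
  counterpart.

Features are z-score standardized with statistics fit on training rows
only. Classifiers: random forest (RF), extra trees (ETC), decision
tree (DT) and bagged trees (BC); gradient boosting (GB),
histogram-based gradient boosting (HGB), AdaBoost (AB) and XGBoost
(XGB). Evaluation uses a stratified 80:20 independent split and
stratified 10-fold cross-validation, reporting Acc, Sp, Sn,
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) and ROC/AUC.

## Worked example

```sh
m5censemble simulate --output sim.fa --n-pos 100 --n-neg 100 --effect 0.4 --seed 7
m5censemble extract  --input sim.fa --output feats.csv
m5censemble train    --features feats.csv --family RF --seed 7 \
                     --model-out rf.model --report-out train.json
m5censemble cv       --features feats.csv --family DT --k 10 --seed 7 \
                     --report-out cv.json
m5censemble predict  --model rf.model --input sim.fa --output scores.tsv
```

prints (timings vary):

```
INFO m5censemble: simulate: 200 windows -> sim.fa (0.01s)
INFO m5censemble: extract: 200 windows x 434 features -> feats.csv (0.58s)
INFO m5censemble: train RF: held-out acc=0.550 mcc=0.102 (0.21s)
INFO m5censemble: cv DT: mean acc=0.540 +- 0.124 (0.26s)
INFO m5censemble: predict: 200 windows -> scores.tsv (0.56s)
```

`simulate` draws balanced labeled windows whose positive class is
G-enriched at eight positions flanking the central C (`--effect`
controls the strength; 0 means the classes are indistinguishable).
`train` reports metrics on the held-out 20%: with only 200 windows the
signal at effect 0.4 is weak, hence the near-chance accuracy here —
accuracy rises with the sample size and effect (see
`results/acceptance.json` after running the script below). Each
command writes a `*.config.yaml` sidecar capturing its full resolved
configuration. Real windows can be supplied as FASTA with `|label=0/1`
header tags or a two-column TSV of labels; DNA-alphabet input (T) is
converted to U.

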