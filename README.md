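# laipt

Identification of lysine acetylation sites from protein sequence, using
polynomial positional-influence feature encoding and a flexible neural tree
(FNT) classifier.

## The problem

Acetylation of the lysine ε-amino group is a reversible post-translational
modification central to chromatin regulation and signaling.  Experimental
site mapping (mass spectrometry, ChIP) is slow and expensive, so sequence-
based predictors are used to triage candidate lysines.  Each candidate is
represented by a peptide window of length 2n+1 centered on the lysine
(offsets k = −n..+n, the site at k = 0); experimentally proven sites are the
positive class, all other lysines the negative class.

## The method

**Positional influence encoding.**  The contribution of a flanking residue
is modeled as an even polynomial function of its offset k, one of three
families:

    constant      y = c₁
    square root   y = a₁·|k|^½ + b₁
    quadratic     y = a₂·k² + b₂

Realized at the 2n+1 offsets this gives an *influence vector*.  A window is
encoded by multiplying, position by position, the influence weight with the
residue's physico-chemical property value (13 bundled AAIndex properties,
z-scored across the 20 residues), one block per property: P×(2n+1) features,
or P features under the summed-per-property reduction that the parameter
scans use.  With a constant influence of 1 this reduces to the raw property
profile.

**Flexible neural tree.**  Leaves read features; each function node computes
a weighted sum of its children, net = Σⱼ wⱼ·yⱼ, and applies a Gaussian
activation exp(−((net − m)/n_act)²), so scores lie in (0, 1].  Tree
structure is searched by genetic programming and node parameters
(wⱼ, m, n_act) by particle swarm optimization, alternating per generation;
everything is reproducible from one seed.

**Evaluation.**  Sensitivity, specificity, accuracy, F1 and Matthews
correlation are computed both from the confusion matrix and in the
per-class (Chou) parameterization — N⁺, N⁻ class totals with N⁻⁺, N⁺⁻
misclassification counts — which are algebraically identical and
property-tested against each other.  ROC/AUC (Mann–Whitney tie handling),
precision–recall and stratified k-fold cross-validation are included.

A synthetic-data module generates labeled windows in which the positive
class carries a position-dependent property shift with a chosen family
profile and effect size, so the whole pipeline — including recovery of the
generating family and of a planted informative bandwidth — is testable
without external data.

## Worked example

```
laipt simulate --out-fasta demo.fasta --out-sites demo.tsv \
    --n 12 --n-pos 250 --n-neg 250 --family quadratic --effect-size 3 --seed 1
laipt encode --fasta demo.fasta --sites demo.tsv --n 12 \
    --family quadratic --coefficient 1 --coefficient 0 --out demo_features.tsv
laipt cv --features demo_features.tsv --k 4 --seed 1 --out demo_cv.json
```

The `encode` step writes 500 windows × 325 features (13 properties ×
25 positions).  On this run `cv` reports

```
INFO laipt: 4-fold mean AUC 0.937 -> demo_cv.json
```

i.e. the cross-validated probability that a random true site outscores a
random non-site is ≈ 0.95 on strongly signaled synthetic data.  The same
workflow is available as library calls (`laipt.synthetic.generate`,
`laipt.encoders.encode_dataset`, `laipt.fnt.train_fnt`,
`laipt.metrics.kfold_cv`).

Two scans mirror the published protocol: `laipt scan-bandwidth` compares
window lengths 21–31 (step 2) by cross-validated AUC, and
`laipt search-params` grid-searches the family coefficients with slopes in
[−10, 10] and intercepts in [−100, 100].  Inputs are assumed
redundancy-reduced (e.g. CD-HIT at 40% identity) beforehand.

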