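# Methods

## Windows and labels

Every candidate sample is a peptide window of length 2n+1 centered on a
lysine, with signed offsets −n..+n and the site at offset 0.  Annotation
coordinates are 1-based (biological convention).  Windows overhanging a
terminus are padded with 'X'; padding keeps the feature dimensionality fixed
and 'X' contributes exactly 0 to every property-based encoder, so a padded
position is informationless rather than biased.  Non-standard residue codes
(B, Z, U, O, J) are mapped to 'X' on ingest with a warning.

All unannotated lysines are negative candidates — the data give no way to
distinguish "tested and unmodified" from "never tested", so no distinction
is attempted.  Because real site data are heavily imbalanced (roughly 15
negatives per positive), `build_dataset` subsamples negatives without
replacement to a configurable ratio (default 1:1, seeded); `"all"` keeps
every candidate.  Sequence-redundancy reduction is an upstream concern
(conventionally CD-HIT at 40% identity) and is not reimplemented.

## Positional influence encoding

The influence of a flanking residue at offset k is an even function of k,
one of three families: constant c₁; square-root a₁·|k|^½ + b₁; quadratic
a₂·k² + b₂.  Evenness encodes the assumption that upstream and downstream
flanks matter symmetrically; the square-root family is evaluated on |k|,
the only reading under which it is a well-defined even function on signed
offsets.  Reference coefficients c₁ = 57.6, a₁ = 4.1, b₁ = 27.1, a₂ = −2.7,
b₂ = 67.1 ship as defaults; search ranges are a ∈ [−10, 10] and
b, c ∈ [−100, 100].

A window's features are the elementwise product of the influence vector
with the per-position property profile, concatenated property-major:
P×(2n+1) values.  This combination rule is the minimal one that reduces to
the plain property profile under constant influence 1.  Property values are
the 13 bundled AAIndex entries (CHOP780207 … QIAN880101), z-scored per
property across the 20 residues by default so no property dominates by raw
scale; standardization can be disabled.

A summed-per-property reduction (Σₖ influence[k]·property[residue_k], P
features) is available and is what the family/coefficient/bandwidth
comparisons use.  The reason is structural: on per-position features an
influence weight is a pure per-column rescaling, which carries no class
information (and none at all once columns are standardized), so family
comparison is only meaningful on the projected features, where the
influence vector acts as a matched filter along positions.  Default
encoding for feature export remains per-position.

Baselines included for completeness: one-hot (20×(2n+1)), amino-acid and
grouped composition over non-'X' positions, and per-property means.

## Flexible neural tree

Leaves return raw feature values.  A function node with children y₁..y_r
computes net = Σⱼ wⱼ·yⱼ and returns exp(−((net − m)/n_act)²); child weights
live on the parent edge, and each node carries its own activation center m
and width n_act.  |n_act| is clamped at 1e−6 and the exponent capped at 700
so outputs are always in (0, 1] even under floating-point underflow.  The
root's output is the classification score; hard labels use threshold 0.5
(score exactly at threshold → positive), while ROC/AUC uses raw scores and
is unaffected by the threshold.

Training alternates two searches, the canonical pairing for this model
class:

* **Structure** — genetic programming: tournament selection (size 3),
  subtree crossover with rejection sampling against the depth cap,
  three-way mutation (parameter jitter / leaf retargeting / subtree
  replacement), and elitism, so the best training fitness is monotone.
  Defaults: arities {2, 3}, max depth 3, population 24, 8 generations.
* **Parameters** — particle swarm optimization over the flattened
  (w, m, n_act) vector of the current best structure: 16 particles, 20
  iterations, inertia 0.72, cognitive/social pulls 1.49, velocity clamped
  to ±1.  The incumbent vector seeds the swarm, so tuning never worsens
  training fitness.

Fitness is RMSE of the score against the 0/1 labels by default; 1−AUC is
available for imbalanced data.  The master seed is split into named
substreams (init / evolve / swarm), so identical (data, config, seed) give
byte-identical serialized models.  These population sizes are matched to
the few-hundred-sample datasets used throughout; scale them up for larger
problems.  Cross-validation pipelines z-score feature columns on training
statistics before fitting — without this, comparisons between encodings
reflect feature scale (conditioning of the search) rather than information.

## Metrics

Confusion-based metrics are implemented twice: from TP/TN/FP/FN, and
directly in the per-class parameterization (N⁺, N⁻ totals; N⁻⁺ missed
positives; N⁺⁻ false calls), including its MCC form

    MCC = (1 − (N⁻⁺/N⁺ + N⁺⁻/N⁻)) / √((1 + (N⁺⁻ − N⁻⁺)/N⁺)(1 + (N⁻⁺ − N⁺⁻)/N⁻)).

The two routes are algebraically identical under TP = N⁺ − N⁻⁺,
TN = N⁻ − N⁺⁻, FP = N⁺⁻, FN = N⁻⁺; a property test enforces agreement to
1e−12 rather than assuming it.  Degenerate MCC denominators (single-class
predictions) return 0 by convention.  AUC uses Mann–Whitney average ranks
(ties credited 0.5), identical to the trapezoidal area under the swept ROC
curve and stable under permutation.  k-fold cross-validation is stratified
(per-fold class counts within one of an even split) because the application
is class-imbalanced; folds are a seeded shuffle.

## Synthetic data

`synthetic.generate` draws windows whose flanking residues are i.i.d.
uniform over the 19 non-lysine residues (negatives) or tilted (positives):
at offset k the sampling weight of residue r is proportional to
exp(effect·g(k)·z_p(r)), where z_p is the z-scored signal property
(default JANJ780101, accessible surface area) and g(k) is the chosen
family's even profile normalized to max 1 over its support, optionally
restricted to |k| ≤ signal_halfwidth.  Tilted *sampling* (rather than
additive feature noise) keeps every window a valid sequence, so the same
data feed all encoders and round-trip through FASTA + annotation TSV.  Each
positive window's effect is additionally scaled by a N(1, 0.25) draw
(clipped at 0), so signal strength is heterogeneous across windows.
Excluding lysine from flanks means each record has exactly one candidate
site, making the FASTA round trip exact.

Defaults (n = 12, 250 + 250 windows, quadratic family, effect 3) constitute
a strongly signaled dataset on which a trained tree reaches held-out
AUC ≥ 0.9, while effect 0 is exchangeable between classes (AUC ≈ 0.5).
The *recovery* experiments — ranking families by CV AUC and locating a
planted informative bandwidth — are run at effect 1.5: at effect 3 every
candidate saturates near AUC 0.99 and the ranking degenerates to noise, a
ceiling effect; the moderate regime is where model comparison is
identifiable.  What these data do not emulate: realistic proteome residue
composition, motif grammars, homology structure between windows, or
between-protein effects; passing tests demonstrate the machinery recovers
planted structure, not field performance on biological data.

## Numerical and design notes

* Best-bandwidth ties prefer the smaller window (cheaper features); grid
  ties prefer the earlier grid point, so reruns are identical.
* Coefficient grids whose influence vector is identically zero are scored
  at 0.5, flagged invalid, and never selected.
* Window extraction, labeling, subsampling, training, CV and both scans are
  pure functions of (inputs, config, seed); CLI commands write a provenance
  JSON beside each output.
* Problem sizes in the test-suite experiments (hundreds of windows, small
  GP/PSO budgets, 4-fold CV, 10 replicates for recovery rates) were chosen
  as the smallest at which the assessed effects are stable.
* Known limitations: the FNT is a small-capacity model — a single Gaussian
  root is unimodal in net, so monotone score/label relationships rely on
  the optimizer placing m outside the data's net range; trees select few
  features, which suits the projected (per-property) encoding better than
  the full per-position one; PSO is a local heuristic and model quality on
  hard data varies with seed.
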