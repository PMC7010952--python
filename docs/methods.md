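# Methods

This note records the model, the numerical choices, and the places where the
design was genuinely open, in the order the pipeline runs.

## Sequence cleaning

Inputs are uppercased and characters outside the 20 standard one-letter
residue codes (ambiguity codes X/B/Z/J/U/O, `*`, gaps) are stripped with a
warning rather than rejected, because real FASTA files routinely contain
them. A sequence with nothing left after cleaning is an error. All
downstream encoders assume cleaned sequences.

## Unit-circle F-vector (40-d)

The six physicochemical classes (aliphatic AVLIMC, aromatic FWYH, polar
STNQ, positive KR, negative DE, special GP) are regrouped into four
super-groups B/J/O/U in ten fixed ways; every regrouping keeps the aliphatic
class inside B. The ten regroupings are hard-coded — they are the standard
table for this encoding, and no ranking rule exists to derive them from the
twenty possible regroupings, so the table is normative.

Within a regrouping, the q-th occurrence (out of n_L) of letter L is placed
on the unit circle at angle base(L) + (π/2)·q/(n_L + 1), with base angles
0, π/2, π, 3π/2 for B, J, O, U. Occurrences of a letter are therefore spread
evenly over the open arc of its quadrant; letters absent from a sequence
simply contribute no points. Per regrouping the descriptor stores the means
and sample variances (denominator n − 1) of the x and y coordinates, in the
fixed order (Mx, My, Vx, Vy), concatenated pattern-major for the ten
regroupings.

Degenerate input: for a length-1 sequence the n − 1 variance denominator is
undefined; variance is defined as 0 (the conventional variance of a single
observation), keeping the encoder total.

## Composition/transition descriptor (400-d)

The binary profile is a 20 × n indicator matrix over the fixed residue order
`ARNDCEQGHILKMFPSTWYV`. Each row is cut into L = 4 contiguous segments with
boundaries ⌊i·n/L⌋, giving lengths that differ by at most one; the split
rule is not dictated by the encoding itself, and the floor-based near-equal
split was chosen for reproducibility. Per segment, five statistics in
percent: frequency of 0 and of 1 (denominator m, the segment length),
frequency of overlapping `11` pairs and of adjacent unequal bits
(denominator m − 1), and frequency of overlapping `111` triples
(denominator m − 2). Substring counts are overlapping (`111` contains two
`11`). Any statistic whose denominator is non-positive is 0. These
denominators and the overlap convention are fixed by the worked example the
encoding is defined by (a 20-residue track with counts 10/10/4/1 yields
50%, 50%, 21.05%, 5.56% and transitions 57.89%). Output stays on the 0–100
percent scale, so downstream scaling is explicit.

## PCA reconstruction and pair vectors

The 40-d and 400-d descriptors concatenate to a 440-d raw feature. PCA
reduces it to k = 30 components. Choices:

* **Fit scope.** By default the basis is fitted on the proteins referenced
  by training-fold pairs only, and held-out proteins are merely projected —
  the honest, leakage-free protocol. A `paper_mode` flag fits on all
  proteins instead, since published pipelines of this family often fit the
  projection once on the whole protein set.
* **Scaling.** Default is mean-centering only (plain PCA). The CT block
  lives on a 0–100 scale and dominates the circle-scale F block; a `scale`
  flag divides each feature by its training standard deviation first for
  users who want the blocks balanced.
* **Determinism.** Component signs are fixed by making the
  largest-magnitude coefficient of each axis positive, so repeated fits are
  bit-identical.
* k is capped at (number of fitted proteins − 1); in small training folds
  the effective dimension shrinks accordingly.

A pair (A, B) is the concatenation of the two projected proteins, in the
order given by the pair file; no symmetrization is applied by default
(pairs are unordered for identity purposes, but the vector keeps the listed
orientation).

## Weighted sparse representation classification

Training pair-vectors are stacked as dictionary columns and ℓ2-normalized;
the query is normalized too (config-disable), because the reconstruction
tolerance ε = 0.005 is only meaningful on the unit-norm scale. Weights are
Gaussian similarities d(y, xᵢ) = exp(−‖y − xᵢ‖²/2σ²) with σ = 1.5.

**Weight direction.** Two modes are exposed. `literal` (default) uses the
similarity itself as the ℓ1 penalty weight, exactly as the weighting matrix
is conventionally written. Note that this penalizes *near* columns more: on
unit-norm 60-d vectors with σ = 1.5 the weights span only [0.41, 1], so
literal WSRC behaves close to plain (unweighted) SRC, with a mild
anti-local tilt. `inverse` uses 1/d(y, xᵢ), which implements the locality
rationale usually given for the weighting (nearer samples should be cheaper
to use). Both modes satisfy the solver contract; all defaults and shipped
evaluations use `literal`.

**Solver.** With βᵢ = wᵢαᵢ the program min Σwᵢ|αᵢ| s.t. ‖y − Xα‖ ≤ ε is
basis-pursuit denoising in the column-rescaled dictionary. It is solved on
the lasso homotopy path (`lars_path`): coefficients are affine in the
regularization weight between knots, so the point where the residual norm
crosses ε is found exactly from a scalar quadratic. A coordinate-descent
bisection on the lasso penalty is kept as a fallback for numerically
difficult paths. On random instances the solution matches a high-accuracy
general-purpose convex optimizer to ~1e−9 relative in objective.

**Degenerate queries.** If ‖y‖ ≤ ε the zero vector is returned. If the
query is not within ε of the dictionary's span (possible when a training
fold has fewer columns than dimensions), `solve_weighted_l1` raises;
the classifier instead relaxes ε to the least-squares residual — the
tightest reconstruction any coefficient vector can reach — so
classification stays total. The relaxation only activates in small-sample
regimes.

**Decision rule.** Per-class residual rᵢ(y) = ‖y − Xδᵢ(α̂)‖ with δᵢ keeping
class-i coefficients; label = argmin. Exact ties go to the non-interacting
class (the conservative call in an interaction screen). The continuous
score is r₀ − r₁ (Euclidean residuals; higher = more likely interacting),
used for ROC/AUC; the method itself defines no canonical score, and the
residual difference is the natural margin of the argmin rule.

## Evaluation harness

Stratified k-fold cross-validation (default k = 5) over pairs, stratified
by label so every fold carries both classes; a `repeats` parameter averages
several independent fold assignments (10 reproduces the common
ten-times-five-fold protocol). Per fold, PCA and dictionary are rebuilt
from training pairs only (see above). Metrics: Sn = TP/(TP+FN),
Sp = TN/(TN+FP), Acc, Mcc, each defined as 0 when its denominator vanishes
(only possible in degenerate folds); AUC equals the Mann–Whitney
probability, ties counted ½. Headline numbers are per-fold means. Runs are
fully reproducible from a single integer seed.

## Synthetic data generator

The generator emulates a balanced two-class pair set over random protein
sequences with a learnable sequence-level rule. Defaults, chosen once as
the standard study conditions:

* 200 proteins, i.i.d. uniform residues, lengths uniform in 120–220.
* Half the proteins carry an aromatic-rich 80-residue module
  (`WYFC`×20), half a charged module (`KRDE`×20), inserted whole at a
  random position — a caricature of complementary binding chemistry
  (aromatic surface vs charged disordered region) at realistic
  interaction-domain size (cf. SH3/PDZ domains, 60–90 aa).
* 100 positive pairs join carriers of complementary modules; 100 negative
  pairs join two carriers of the same module. Pairs are distinct, never
  self-pairs, orientation randomized.

The domain inserts shift residue composition strongly enough that the rule
is detectable by the CT encoder, which is the design requirement: during
design, 10-residue motifs produced a dataset *no* similarity-based
classifier could learn (the composition shift drowns in the multinomial
background noise, which scales as motif_length/√length), defeating the
generator's purpose. Under the defaults the default-config pipeline reaches
~0.94–0.99 accuracy across seeds, and label-shuffled controls sit at
chance.

What the generator does *not* emulate: homology structure between related
sequences, hub proteins appearing in many pairs, compositional bias of real
proteomes, and label noise from false-positive screens. Passing the
synthetic study therefore demonstrates that the pipeline recovers a
composition-level interaction signal end-to-end — not that it attains any
particular accuracy on curated interactome benchmarks, which additionally
require external data and homology filtering (negative-pair sampling for
real data is provided; apply cd-hit-style filtering upstream).

## Problem sizes in shipped checks

The shipped tests and the reproduction script use the default study
(200 proteins, 200 pairs, 5 folds) for end-to-end checks, 60-protein sets
for harness mechanics, and d = 10, n = 20 random instances for solver
benchmarking — sizes at which the independent convex oracle is exact and
fast while every code path (including the small-fold relaxation) is
exercised.

## Known limitations

* The literal weighting direction (default) is anti-local; users wanting
  the locality behaviour the weighting is usually motivated by should set
  `weight_mode="inverse"`.
* WSRC is a lazy classifier: prediction cost grows with the training-set
  size (one homotopy solve per query).
* ε and σ are fixed defaults (0.005, 1.5); they are not auto-tuned.
* The e-constraint is interpreted on the normalized scale; disabling query
  normalization makes ε effectively scale-dependent.
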