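# Methods

## Problem setting

I-CreI is a homodimeric LAGLIDADG meganuclease recognizing a 22 bp
pseudopalindromic DNA site, indexed −11…−1, +1…+11 from the center.  The
protein–DNA interface factorizes: residues 44, 68, 70, 75, 77 (the *p5N3*
half) contact bases ±3…±5 (the *5N3* region) and residues 30, 32, 33, 38,
40 (the *p11N4* half) contact bases ±8…±11 (the *11N4* region); the central
*2N4* bases (±1, ±2) are cleaved but not contacted, and the *7N2* bases
(±6, ±7) are read by scaffold residues that the engineering process never
varies.  Redesign proceeds combinatorially: module libraries of
half-variants are screened once against all 64 possible 5N3 and all 256
possible 11N4 region targets; for a new site, modules active on its two
regions are assembled at random into a pool of full variants (about 35 × 35
modules, sampled with replacement at 3× the theoretical diversity, hence an
expected coverage of 1 − (1 − 1/N)^(3N) ≈ 95%), the pool is screened in
bulk, and only positive clones are sequenced.  Combinations absent from the
positives are *assumed* negative; the package keeps that assumption
explicit through a per-record `measured` flag.

The package learns, from such screens, a scorer A(t, p) that ranks
candidate variants p for a target t, and ranks designs by the trade-off
score R_α = α·A + (1 − α)·S, where S is specificity — a mutant's activity
on the target of interest divided by its total activity over an enumerated
target space (the 64 5N3 targets by default).

## Scoring model

The scorer is an ensemble of two learners on two views of the same records:

* **LASSO** — L1-penalized logistic regression on a binary encoding.
  *Bin1* one-hot-encodes each protein position (10 columns of residues)
  and each target position in the modeled regions (7 columns of
  nucleotides), and carries two real-valued columns: the measured library
  activity of the record's p5N3 half on the target's 5N3 region and of its
  p11N4 half on the 11N4 region.  *Bin2* appends element-wise products of
  Bin1 column pairs — protein×protein (M2M) and protein×target (M2T)
  interactions, each tagged intra- or cross-module.  Products are kept when
  both parents have more than 200 nonzero entries; reading the support
  filter on the parents rather than the products bounds the enumeration,
  and a product-level variant is available as a configuration switch
  (target×target products are off by default for the same reason: the
  interaction analysis concerns protein effects).  The penalty is
  parameterized per observation (mean log-loss + λ‖β‖₁, glmnet-style), so
  fits are invariant to duplicating rows; λ is selected from
  {2·10⁻³, 2·10⁻⁴, 2·10⁻⁵} by inner cross-validation.
* **GBM** — a histogram gradient-boosted tree classifier (binomial loss,
  learning rate 0.1, 120 trees) on the categorical view of the same
  columns.  Tree depth is selected by inner CV from {2, 3}; for feature
  groups whose hypothesis class excludes interactions the grid is {1}
  (stumps), so depth cannot smuggle interactions into a main-effects-only
  ablation.

Inner cross-validation always splits at the target level (grouped 2-fold),
so a candidate pool never straddles an inner train/validation boundary, and
hyperparameters never see outer test targets (training-set fingerprints are
checked when members are combined).  The ensemble averages the members'
within-pool fractional ranks, making it invariant to monotone transforms of
any member's raw scores; score-averaging and single-member operation are
configuration options.  Rankings break ties lexicographically on the
variant residue string so results are reproducible.

Because assumed negatives outnumber positives ~75:1, training subsamples
them to at most 300 per target (all positives kept) — the standard
class-rebalancing treatment for positive-only screening data; prediction
and evaluation always rank full pools.

### Feature groups

Named column subsets drive the ablation analysis: `Mact` (the two
module-activity columns only), `SM-5`/`SM-11` (plus the sequence columns of
one interface side), `SM-5_11` (both sides), `SM-M2M`/`SM-M2T` (plus one
interaction class), `SM-Intra`/`SM-Cross` (interactions within one module
side vs across sides), `SeqMact` (everything), and `SeqMactFxStr-ext`
(schema hook for external real-valued columns such as physics-based scores;
no physics is computed here).  Every group contains the module-activity
columns, so each is an extension of the `Mact` baseline.

## Evaluation

Metrics are per target: AUC in its Mann–Whitney form (ties ½; single-class
pools are excluded from AUC averages with a logged reason but still count
for TopN), TopN (actives among the N top-ranked, N = 10 by default), and
hitN/%TopN (at least one active in the top N; percentage over test
targets).  Outer cross-validation holds out whole targets (10% per
replicate, ≥1 target), refits on the rest, and aggregates over replicates
with standard errors; replicate seeds are derived from the master seed by
fixed offsets so any replicate reproduces in isolation.  Learning curves
reuse the per-replicate split and subsample training targets; distance
subsampling removes training targets within a Hamming radius of any test
target (computed over the modeled r11N4+r5N3 regions — the regions the
screen varies; full-site distance is a switch) with a size-matched uniform
control.

## Ground-truth simulator

The real screening corpus is proprietary, so the package ships a generative
twin with planted, recoverable structure.  Each simulated module half has a
cognate region target and a quality q ~ U(0.55, 1); its latent activity on
region target s is q·δ^d(cognate, s) with decay δ = 0.35 (5N3) or 0.30
(11N4); libraries report latent activity plus N(0, 0.04) measurement noise,
clipped to [0, 1].  Cognates cycle through a shuffled enumeration so every
region target has an active module.  Residues are drawn from per-position
repertoires with non-uniform weights — wild-type residues and the workhorse
base-contacting substitutions (notably arginine at 44 and 77) recur across
many modules, as they do in engineered libraries.  This matters
statistically as well as biologically: a pairwise effect is identifiable
only if the pair occurs across several distinct module backgrounds.

A combined variant's activity is an additive score, clipped to [0, 1]:

    z = bias + 0.55·a5 + 0.55·a11 + nonspecific + M2M + M2T + N(0, 0.08)

where a5/a11 are the *latent* module compatibilities and the sequence
effects model what changes when two mutated halves are combined (folding,
expression, interface cross-talk) — hence invisible to the module-activity
measurements, which is exactly why sequence-aware models beat the
module-activity baseline on these data.  Planted named effects are always
present: 44F −0.45 and 32K −0.35 (single-mutation penalties) and the
simultaneous 44R+77R pair −0.50 (electrostatic repulsion analogue); around
them, random per-mutation effects (probability 0.4, sd 0.12), eight intra-
and two cross-module random pairs (sd 0.20/0.10), and residue–nucleotide
preferences at the structurally contacting position pairs (70↔+3/+4,
44↔+4, 68↔+5, 30/38↔+9, 33↔+10; probability 0.35, sd 0.18) are drawn once
per world.  A variant is active when its score reaches τ_active = 0.25
(strongly active at 0.8); both thresholds are configurable.

Screening simulation mirrors the lab protocol: per target (distinct
GTAC-centered pseudopalindromes with the invariant 7N2 region), the ~35
modules most active on each region by *measured* library activity are
pooled, assembled at 3× oversampling, scored against the ground truth, and
only positives are "sequenced".  Because the randomly drawn world-level
effects shift the activity scale between worlds, the generator calibrates
its bias on a small probe simulation so the marginal active rate matches
the emulated screen's descriptive statistics (≈15 positives in an
1,160-candidate pool); targets with no positive are rejection-resampled, as
in the reference corpus where every target had at least one positive.  The
specificity generator (p5N3 mutants × all 64 5N3 targets, wild-type p11N4
half) calibrates the same way to a 6.6% positive fraction *after* its
per-mutant rejection (every mutant active somewhere), and encodes the
classic activity/specificity trade-off: a mutant's off-cognate decay rises
with its quality (from 0.15 to 0.55), so the most active mutants are the
most promiscuous.

What the simulator does *not* model: 2N4 sequence effects (held at GTAC),
PCR/sequencing error, assay noise structure beyond additive Gaussian, or
any physical energetics.  Passing tests therefore demonstrate that the
pipeline recovers the kinds of structure the generative model plants —
module-compatibility signal, mutation-level and pairwise effects — not that
it would achieve any particular accuracy on real screens.

## What the checks show, and their problem sizes

* **Ordering recovery** — on a default 40-target world, outer CV (30
  replicates) orders mean AUC SeqMact > SM-M2M > SM-5_11 > Mact with gaps
  beyond replicate standard error, and zeroing all sequence effects
  collapses the SeqMact−Mact gap (the acceptance script runs the same
  comparison at 10 replicates to stay in the minutes range).
* **Sign recovery** — LASSO on Bin2 recovers the planted 44F, 32K and
  44R×77R signs in ≥90% of 20 independent 40-target worlds.
* **Trade-off shape** — the α-sweep check uses a directly constructed
  candidate ensemble with anticorrelated true activity and specificity and
  a noisy predictor.  Inside the full simulator every mutant is active on
  at least one target (a property of the reference corpus itself), which
  couples true specificity on t to true activity on t: a pure-specificity
  ranking of that matrix cannot fail badly, so no interior maximum can
  emerge there.  The constructed ensemble isolates the phenomenon the
  trade-off score exists for; the boundary reductions (α = 1 ⇒ activity
  ranking, α = 0 ⇒ specificity ranking) and profile normalization are
  checked exactly.
* **Calibration** — the default 251-target screening simulation and the
  2,576-mutant specificity matrix reproduce the descriptive statistics they
  are calibrated to (mean pool ≈1,160 within 10%; positives per target
  within ±50% of 15; positive fraction 6.6% ± 2 points).

## Numerical and degenerate-input choices

Degenerate (IUPAC) bases are rejected, never expanded.  Module-activity
lookups that cannot be resolved become NaN (the tree learner treats NaN as
missing; the linear learner imputes the training-column mean) — never a
silent zero.  Single-class training labels raise an error.  Identically
zero interaction products (including same-block products) are dropped.
AUC of a single-class pool is undefined and excluded from averages rather
than defaulted.  All randomness flows through explicit seeds; CLI runs
write a JSON manifest (parameters, seeds, version, input fingerprints).

## Known limitations

The ensemble combination rule (per-pool rank averaging) is one reasonable
choice among several; score-averaging is available but untuned.  rankSVM
and AUC-optimized boosting are not implemented.  The wild-type 22-mer site
ships as a configurable constant.  Absolute cross-validation numbers on
simulated worlds are not comparable to any real screen — only the
qualitative orderings and calibration targets above are meaningful.
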