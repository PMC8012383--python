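# Methods

This note documents the models and numerical choices behind `howlid`: what
each pipeline stage assumes, how the synthetic howl generator is built and
what it does and does not emulate, and where the design was genuinely open.

## Contours and features

A howl enters the pipeline as a digitised f0 trace: (time, frequency)
points along the lowest spectrogram band, irregularly spaced because they
are clicked by hand. Contour files are two-column delimited text; rows are
sorted and duplicate time stamps (a digitiser artefact) are collapsed by
averaging their frequencies. Resampling onto the uniform 0.1 s grid uses
linear interpolation — digitised points are dense along a smooth contour,
so linear is adequate and exactly checkable by hand. Resampling is
idempotent and can never extrapolate outside the input frequency range.

Duration is measured from the raw trace endpoints, not the resampled grid,
so up to 0.1 s of trailing contour is never silently lost; when a resampled
contour is exported, the raw endpoints are preserved as `# t_start=` /
`# t_end=` comment headers. The grid is anchored at the trace start, which
makes every feature invariant to time translation.

Of the thirteen per-howl variables, the conventions the definitions leave
open are resolved as follows:

- **Stdv** uses the sample (n−1) denominator — the default of the
  spreadsheet/R ecosystem the analysis chain comes from. A population-SD
  switch (`sd_mode="population"`) is provided.
- **Abrupt counts** use strict comparisons (> 25/50/100 Hz), reading
  "more than" literally.
- **Pos Min / Pos Max** take the first occurrence in time on ties and are
  measured from the raw start, divided by the raw duration.
- **Mean f** is the arithmetic mean of the grid samples, not a
  duration-weighted integral; **Co fm**'s n is the number of grid samples,
  so the sum runs over the n−1 steps.

The default duration filter keeps howls strictly longer than 5 s: shorter
squeak-like calls mimic howls but carry little identity. The filter is
aimed at real survey recordings; synthetic corpora contain only genuine
howls, so the end-to-end validation runs disable it (`min_duration=0`).

## PCA

The thirteen variables mix Hz, seconds, counts and dimensionless ratios,
so the default is correlation-matrix PCA (z-scored variables); covariance
mode exists for re-running analyses done on raw scales. The
decomposition is a symmetric eigensolve of the 13×13 correlation matrix;
component signs are fixed by forcing each component's largest-magnitude
loading positive, so results are platform-reproducible. Components whose
variance fraction strictly exceeds 5% are retained.

Because Range f = Max f − Min f exactly, the correlation matrix has rank at
most 12 and the trailing eigenvalue is zero; eigenvalues are clipped at
zero before normalising.

The PCA may be fitted on more howls than the labelled training set:
`run_train(..., unlabeled_contours=...)` includes unidentified howls (for
example the survey batch about to be identified) in the PCA only, never in
the discriminant stage. This matters: with few training individuals and
strong vocal individuality, a training-only correlation matrix is dominated
by the training wolves' particular differences, and the >5% rule can then
retain a subspace that projects away exactly the directions in which
*novel* wolves differ. Widening the PCA corpus keeps those directions
representable. Identities are never used in this step, so including
unlabelled howls is transductive but leak-free.

## Discriminant functions

Standard multi-class LDA on the retained PC scores: pooled within-class
covariance `Sw` (a relative ridge of 1e-8 guards near-singular cases, with
a warning when rows are scarce), between-class covariance `Sb` from the
class means, and the generalised eigenproblem `Sb v = λ Sw v`. Discriminant
vectors are normalised to unit pooled within-class variance (`vᵀ Sw v = 1`,
the classical DFA convention) with the largest coefficient forced positive;
at most K−1 discriminants exist for K individuals. Classification is the
Gaussian linear rule — nearest class centre in full LD space minus log
prior — with priors defaulting to training class proportions (uniform
available) and exact ties going to the lexicographically first label.

Two discriminants are carried to clustering by default (the 2-D LD plane is
also what field workers plot); this is configurable up to K−1. Training
howls project identically whether scored during fitting or through the
saved model, and the same fitted equations are applied to novel howls.

## AGNES clustering and the clustering scale

Agglomerative nesting over LD scores: Manhattan (L1) distances, average
linkage by default (single and complete available), Lance–Williams updates,
and fully declared tie-breaking (lowest merge height, then the
lexicographically smallest leaf id in each candidate cluster), so
dendrograms are bit-reproducible and invariant to input row order. Cutting
the tree at a height yields flat clusters; the cluster count is the
estimated number of wolves. Dendrograms export to Newick with height
differences as branch lengths.

**The clustering scale is not a universal constant.** LDA's normalisation
fixes the pooled *training* within-class variance at one per axis, so for a
fresh single-recording batch the within-individual Manhattan distances in
the 2-D LD plane sit near 2.3 units (and out-of-sample noise inflates them
further) — a fixed cut such as 2.2 raw units lands *inside* the
within-individual scale and over-splits, regardless of how the data were
generated. Rescaling by batch spread (the AGNES `stand` convention, mean
absolute deviation) or by the batch's median nearest-neighbour distance
makes heights comparable across batches (both are available via
`height_scale`), but the correct cut still depends on where the unknown
individuals happen to sit. The pipeline therefore calibrates the scale on
the labelled training dendrogram: the cut maximising one-to-one
cluster-to-individual accuracy (which penalises over-splitting, unlike the
plurality score), preferring fewer clusters on ties, anchored just above
the within-individual edge of the winning height interval (factor 1.75,
capped at the interval midpoint) because the within edge transfers to new
batches up to modest out-of-sample inflation while the between edge is
specific to the training individuals. When session dates are available the
calibration runs on single-session-per-individual subsets (median across
session ranks), since identification batches in the field are single
sessions and multi-session training clusters are wider than the batches the
cut will be applied to. A fixed numeric `cut_height` — such as a published
per-dataset value like 2.2 — and a direct `n_clusters` criterion remain
available.

Evaluation maps each cluster to the individual holding the plurality of its
members (ties: the individual with more howls overall, then lexicographic;
ties are logged); `one_to_one=True` instead computes the optimal one-to-one
assignment via the Hungarian algorithm, leaving surplus clusters unmapped.
Accuracy is the fraction of howls whose cluster maps to their true owner.

## The synthetic howl generator

Each simulated wolf is a parameter vector (`IndividualProfile`): baseline
f0, mean duration, modulation depth, arc count (1–3 half-sine arcs), a
time-warp exponent controlling where the contour peaks, break rate and
size, and the size of a terminal pitch fall. A howl is synthesised directly
on the 0.1 s grid as

    f0(t) = baseline + mean-centred, amplitude-decaying warped arcs
            + Poisson-count onset breaks + terminal fall + white tremor,

clipped positive. Population means follow the Indian-wolf figures (422 Hz,
5.21 s). Structural choices worth spelling out:

- **Arcs** decay ~20% in amplitude over the howl and the contour drifts
  slightly downward. Without this, multi-arc contours have twin
  equal-height peaks (and odd-count contours have equal-valued endpoints),
  so sample tremor flips the global extremum between distant positions and
  Pos Min / Pos Max become bimodal within an individual — an artefact of
  perfectly symmetric synthetic arcs that real howls do not show.
- **Breaks** are brief (1–2 sample) upward excursions confined to the first
  15% of the howl — onset instability while phonation settles. There the
  contour is low, so breaks rise toward the mean level: they register in
  the abrupt-change counters and Co fm without displacing the extrema.
  Magnitudes are lognormal around 30 Hz, populating the 25 Hz class
  heavily, the 50 Hz class occasionally and the 100 Hz class rarely.
- **The terminal fall** (≈0.9 × depth + an individual excess) is a steep
  drop on the final sample, as howls trail off. It anchors the contour
  minimum at the howl's end, makes Min f individual-specific, and is what
  populates Abrupt_0.1: whether the final step crosses 100 Hz depends on
  the individual.
- **Sessions.** Wolves drift from day to day, so within-individual
  variation is split into session-level components (pitch and duration
  offsets, depth and break-rate multipliers, terminal-fall offsets) and
  smaller per-howl residuals. Training corpora span three sessions per
  wolf; test batches are one session per wolf — the structure of real
  training libraries versus survey batches, and the reason single-session
  batches cluster more tightly than the pooled training scatter suggests.
- **Separation.** All identity-bearing parameters have between-individual
  spread proportional to one `separation` factor; the baseline-f0 spread is
  `separation × within_sd` exactly. At separation 0 every wolf shares the
  population profile and only noise remains, so identification collapses
  to chance; at separation 3 individuals are well-separated on every axis.

What the generator does **not** emulate: chorus howls and overlapping
callers, atmospheric/propagation distortion of the contour, digitiser
operator error beyond duplicate time stamps, squeak calls (hence no
duration filtering in synthetic runs), and non-stationary individuality
(profiles are fixed per wolf). Passing the synthetic recovery checks
therefore demonstrates that the *chain* recovers identity under controlled,
favourable conditions; it does not bound accuracy on field recordings.

## Observed behaviour and limitations

With the default study design (5 training wolves × 10 howls across 3
sessions; 4 novel wolves × 5 howls, one session; separation 3), training
DFA accuracy is typically 95–100% and held-out identification accuracy
averages ≈0.90 over seeds, rising with separation from chance at
separation 0. Counting is harder than assignment: the estimated number of
wolves is exactly right only in a minority of runs, with over-splitting the
common error (which leaves assignment accuracy intact under plurality
mapping). Three structural reasons, all visible in the code-level
diagnostics rather than fixable by tuning:

1. The correct cut must separate the batch's within-individual merge
   heights from its between-individual merges, and the gap's location
   depends on the random configuration of the unknown wolves — information
   no training-derived threshold carries.
2. LD axes overfit the training individuals: novel wolves' between-distances
   shrink out-of-sample while within-distances inflate, narrowing the
   usable plateau.
3. With ~9 individuals total, the feature correlation structure is partly
   chance; at high separation the >5% retention rule can drop directions
   that separate particular novel wolves, which is why accuracy does not
   keep improving from separation 3 to 5.

Small survey batches (the guideline is 50–100 calls, at least 3–5 per
individual in training, warnings otherwise) and reporting cluster tables
alongside the count — so an operator can inspect the dendrogram — remain
the recommended practice.

## Reproducibility

All randomness flows through explicitly passed `numpy` generators seeded
from configuration; reports record the package version, full configuration
and a SHA-256 digest of the input contours. Model files (PCA and LDA) are
versioned JSON and round-trip exactly. Problem sizes used by the test suite
and the acceptance script — 70-howl corpora, 20-seed replicates, 120-contour
feature-oracle sweeps, 200-draw agglomeration oracles — were chosen to make
the statistical checks stable while keeping a full run in tens of seconds.
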