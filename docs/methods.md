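# Methods

## Band decomposition

Each voxel series is split with a real FFT, an ideal (brick-wall) bin
mask, and the inverse transform at the original length.  Bins are
assigned half-open, `[f_low, f_high)`, except that the topmost band of
a partition owns its closed upper edge; the DC bin is always removed
and no other detrending is applied.  Consequences we rely on and test:
touching bands partition the spectrum exactly, so the band components
sum to the band-passed signal to machine precision; components of
disjoint bands are orthogonal (Parseval); decomposition is linear and
idempotent.  A brick-wall mask rings in the time domain when signal
power sits exactly at a band edge; we accept this because the
decomposition is defined spectrally and every downstream statistic is
computed from the restored signals as such.  An FIR/IIR filter would
trade ringing for passband distortion and break the exact-additivity
property the multi-graph construction depends on.

Bands default to low 0.01–0.06 Hz, intermediate 0.06–0.15 Hz, high
0.15–0.2 Hz; any disjoint set within Nyquist = 1/(2·TR) is accepted,
and a band containing no representable frequency bin at the given
(n_timepoints, TR) is rejected rather than silently returning zeros.

## Network construction

Edges come from the Euclidean distance between band signals under a
strict threshold, d < λ (ties at λ are excluded, so construction is
deterministic under vertex reordering).  Two choices the similarity
rule leaves open:

- **Scaling.** Raw band amplitudes differ by orders of magnitude, so a
  single λ across bands is only meaningful after per-voxel z-scoring
  within each band.  Normalisation is on by default and can be
  disabled.  Zero-variance voxels cannot be z-scored; they are flagged,
  logged, and left edgeless instead of raising.
- **Threshold selection.** λ can be given absolutely, or chosen to hit
  a target edge density (default 0.15) — per band for single-subject
  cross-band comparisons (`build_multigraph`), or pooled across a
  cohort (`build_cohort_multigraphs`) so every subject's band network
  is built under the *same* λ.  The pooled mode matters for
  classification: per-subject density targeting forces every subject to
  the same edge count and thereby erases between-subject connectivity
  differences, which are precisely the group signal.  Pooling uses
  unlabelled distances only, so no label information leaks into
  construction.

Distances are computed in row blocks (O(block × n) memory) through the
same C kernel as the scalar distance function, so block streaming,
all-pairs brute force, and single-pair evaluation agree bit-for-bit —
including at threshold ties.

Edge-set algebra (`edge_algebra_count`) evaluates expressions such as
`|E(H_L ∩ H_I ∪ H_Full)|` left-to-right with equal operator precedence;
parentheses group explicitly.  This matches the row labels of
comparative edge-count tables; the decorative `|E( )|` wrapper is
accepted and ignored.

## Graph metrics

- **Clustering** is the mean over vertices of closed-triplet fraction,
  vertices of degree < 2 contributing 0.
- **Path length** averages shortest paths over *connected* pairs only
  and reports the connected-pair fraction alongside, so the exclusion
  is never invisible.  Band networks at moderate density are often
  disconnected (two communities with no between-edges connect ~49% of
  pairs); a penalty convention for disconnected pairs would make L
  depend on an arbitrary constant.
- **Random references** are degree-preserving double-edge-swap
  randomisations (default 10×|E| accepted swaps).  γ = C/C̄ᴿ,
  λ = L/L̄ᴿ, σ = γ/λ over n_random references (default 20);
  per-reference values are kept so dispersion can be inspected.  For
  *null* calibration (a rewired graph against its own ensemble) a mean
  degree around 20 at n = 200 is needed for single-draw clustering to
  concentrate within a ±0.1 band around σ = 1; at mean degree 10 the
  stationary clustering level (~0.04) fluctuates ~10% between draws
  and σ inherits that spread.
- **Power-law fits** use the discrete maximum-likelihood estimator with
  Hurwitz-zeta normalisation; x_min minimises the Kolmogorov–Smirnov
  distance between fitted and empirical tail (computed on unique
  support values — the textbook sorted-sample ECDF formula is wrong
  for tied discrete data).  Fits are refused below 10 distinct degrees
  or for tails shorter than 50.  Recovery is within ±0.2 of the truth
  at 5000 samples (tested over 10 replicates; empirically within
  ±0.05).
- **Hubs** are top-k by degree (default top 1%), ties broken by
  ascending vertex index.  Atlas coverage counts each region at most
  once regardless of how many hubs fall within δ of its center;
  A = M/R.  δ defaults to half the mean nearest-neighbour distance
  between atlas centers.
- **Difference tests** are permutation tests on distance statistics
  (edge-set Jaccard distance, degree-distribution KS, region-matrix
  Frobenius), p = (1 + #{replicates ≥ observed})/(1 + n_perm).  The
  null relabels vertices of one graph (Jaccard, Frobenius) or pools and
  re-splits degrees (KS).  Identical inputs give p = 1 under every
  statistic, and p ≥ 1/(1 + n_perm) by construction.  These tests are a
  principled stand-in: the analyses they support report bare p-values
  without naming a test, so no specific published procedure is being
  reproduced.

## Classification

Per band, the Weisfeiler–Lehman subtree kernel: initial vertex labels
are degree buckets (`degree // width`, width default 2 — raw degrees
make histograms needlessly fine on small graphs), refined for `depth`
rounds (default 2) by hashing each vertex's label with its sorted
neighbour labels through one dictionary shared across the cohort; the
kernel is the inner product of label-count histograms over all rounds,
cosine-normalised to unit diagonal.  A subject with an edgeless band
graph gets an empty histogram — zero similarity to every non-empty
graph — with a warning; its self-similarity is set to 1 by convention
so the matrix stays a valid unit-diagonal PSD kernel.

Fusion is the convex combination K = Σ μₘ Kₘ.  Weights are uniform,
fixed, or selected by grid search over the simplex (default step 0.25)
maximising inner-CV accuracy; accuracy ties broadly on a coarse grid
(adding a weak kernel at small weight rarely flips a prediction), so
ties break first by pooled out-of-fold AUC, then toward the most
uniform weights, then lexicographically — selection is deterministic.

Back ends: kernel ELM solves (I/C + K)β = y (C default 1.0; the solve
is verified by its residual) and predicts k·β; kernel SVM delegates to
a precomputed-kernel SVC.  Evaluation is stratified k-fold (default
10): band kernels are computed once over all subjects — legitimate
because the WL similarity of two graphs does not involve any third
subject or any label — while weight selection and classifier training
see training folds only.  Accuracy, sensitivity, specificity and AUC
come from pooled out-of-fold scores.

At desk scale subjects' voxel graphs (60 voxels) feed the kernels
directly; for larger inputs graphs can be reduced to region level
before kernel computation, since nothing in the kernel requires voxel
granularity.

## Synthetic data: what it emulates, what it does not

`generate_bold` builds each band's signal from one carrier per
community — a random-phase sum of up to 6 sinusoids whose frequencies
are DFT bins strictly inside the open band interval, normalised to unit
standard deviation — scaled by the band amplitude and summed across
bands, plus i.i.d. Gaussian noise.  Bin-aligned carriers make the
spectral-placement invariant exact (all carrier power inside the
nominal band) and let the FFT decomposition recover components
perfectly, which is what makes the generator a usable oracle.

Defaults (60 voxels, 128 volumes, TR 2 s; amplitudes low 1.0,
intermediate 1.0, high 0.6; noise SD 10) emulate a short resting-state
acquisition in which structured fluctuations carry roughly 2% of
per-voxel variance.  The noise level was calibrated so band networks
sit in the *partial-recovery* regime — within-community edge fractions
below saturation.  This matters: with weak noise every subject's band
network recovers the community blocks perfectly, all subjects look
identical, and a cohort whose groups differ in coupling strength
becomes undetectable by construction.  The low band remains the
spectrally densest (equal variance in the narrowest interval), echoing
the low-frequency dominance seen in real BOLD spectra.

Cohorts derive per-subject seeds deterministically from the cohort seed
(`numpy` SeedSequence spawning), so cohorts are bit-reproducible and
subjects independent.  Group B multiplies the affected band's carrier
amplitude by (1 + effect_size), i.e. strengthens (or weakens)
within-community coupling in exactly one band.

Not modelled: hemodynamic response convolution, spatial smoothness or
autocorrelated noise, motion or physiological artifacts, scanner
drift.  Passing tests therefore show that the *pipeline* recovers
band-specific structure it is pointed at — not that real fMRI contains
such structure, and not anything about fMRI physics.  Likewise the
grid atlas from `generate_atlas` is a synthetic stand-in for an
anatomical parcellation table, not an anatomical object.

## Numerical choices and degenerate inputs

- Band masks use a 1e-12 absolute tolerance at edges; the single-pair
  and blockwise distance paths share one C kernel so threshold ties
  resolve identically everywhere.
- Kernel matrices validate symmetry and PSD-ness (min eigenvalue
  ≥ −1e-8 × max) at construction; k-SVM clips negative eigenvalues at
  zero with a warning rather than failing.
- Graphs where no legal edge swap exists are returned unchanged with a
  warning; empty graphs refuse path-length computation explicitly.
- All randomness flows through seeded `numpy` generators (and seeded
  networkx swaps); identical config + seed ⇒ identical outputs, which
  the CLI logs (config hash, seed, versions) make auditable.

## Problem sizes

Default test and demonstration sizes — 60-voxel subjects, 40-subject
cohorts, 200-vertex metric graphs, 20 random references, 5000-sample
power-law fits — were chosen so every property is exercised at a scale
where brute-force oracles are feasible and the whole suite runs in well
under a minute, while remaining large enough for the stochastic claims
(σ concentration, exponent recovery, classification contrast) to hold
with comfortable margins.

## Known limitations

- The Euclidean-distance similarity is the only connectivity estimator;
  correlation or wavelet coherence alternatives are out of scope.
- The permutation difference tests do not reproduce any specific
  published test (none is specified for the analyses they mirror).
- Power-law fitting reports the KS distance as goodness but does not
  bootstrap a plausibility p-value.
- The WL kernel ignores vertex identity by design; group effects that
  preserve all graph invariants while moving edges among fixed voxel
  pairs are invisible to it (the cohort-level shared-λ construction is
  what keeps density differences visible).
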