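# Methods

This note documents the models, defaults and numerical choices behind
`eegbiotype`, and what the synthetic-data tests do and do not establish
about real EEG.

## Task model and epoch handling

The simulated paradigm is a three-condition auditory oddball: 600 stimuli
per run with probabilities 0.2 (target), 0.2 (distractor), 0.6
(standard) and inter-stimulus intervals jittered uniformly in
1.16–1.44 s. Only target tones followed by a button press ("attended"
targets) are epoched and analysed; button presses are Bernoulli per
target with probability `attend_prob` (default 0.9). The default of 150
retained attended targets per subject is an explicit guess — real
post-rejection trial counts vary by lab and subject — and is
configurable.

Epochs run from −800 ms to +1000 ms around stimulus onset at 500 Hz
(simulation tests use 250 Hz for speed; both configurable). The −800 ms
start is deliberate: the Morlet cone of influence at 4 Hz spans ≈342 ms,
so a shorter pre-stimulus segment would leave no valid theta samples in
the −300–0 ms analysis window. Time is expressed in milliseconds
relative to onset; windows map to samples half-open, `[start, end)`.
Artifact rejection drops any trial whose absolute amplitude exceeds
±100 µV on any channel (configurable; no ICA). Baseline correction
subtracts the per-trial, per-channel prestimulus mean.

## Coupling model of the generator

Each trial carries a band-limited carrier: coupled oscillators log-spaced
over `carrier_band` (default theta, 4–8 Hz), all sharing one per-channel,
per-trial phase offset. A single tone would leave most wavelet scales in
the band noise-dominated and dilute band-averaged PLV; with the
band-limited carrier every in-band scale sees the programmed coupling.

The per-channel offset is von Mises jitter around a common trial phase.
For concentration κ the mean resultant is A(κ) = I₁(κ)/I₀(κ), so the
expected PLV of a channel pair whose offsets are independent draws is
A(κ_x)·A(κ_y). Programming a pairwise PLV ρ therefore means solving
A(κ) = √ρ numerically (Brent's method on the exponentially scaled Bessel
ratio). This calibration is exact in expectation and is verified by the
test suite to ±0.05 at 200 trials across ρ ∈ {0.2, 0.5, 0.8}.

Spatial heterogeneity: each channel's resultant is scaled by a profile
multiplier 1 + σ_c·z truncated to [0.6, 1.6] (default σ_c = 0.2). The
truncation matters — an unboundedly weak channel makes inverse-weight
path lengths arbitrarily heavy-tailed. Heterogeneity is what gives the
normalised path length its variance: on a near-uniform PLV matrix the
direct edge is always the shortest path and weight-permutation surrogates
preserve the mean inverse weight exactly, so normalised PL degenerates to
1 identically.

The two built-in subgroup profiles encode the qualitative contrast the
clustering is meant to recover: `C1_LIKE` has lower prestimulus coupling
(0.30) rising to 0.45 in the response window, a homogeneous profile
(σ_c = 0.15) and a 2× response amplitude gain (strong spectral
concentration); `C2_LIKE` has higher prestimulus coupling (0.45),
near-zero modulation, a more heterogeneous profile (σ_c = 0.35 — hence
longer normalised PL and lower SW) and almost no amplitude gain. Window
transitions use a cosine ramp over 0–150 ms along the shortest phase arc,
so neither analysis window contains the transition.

What the generator does **not** emulate: volume conduction beyond shared
additive noise, 1/f background spectra, per-channel impedance
differences, eye/muscle artifact morphology, or any head geometry.
Passing tests therefore demonstrate that the estimators recover known
coupling and subgroup structure under the stated statistical model — not
that they are robust to every property of real scalp EEG.

## Phase connectivity

Phase is extracted by continuous wavelet transform with a complex Morlet
of centre-frequency parameter ω₀ = 6 (in pywt's bandwidth-centre
parameterisation, `cmor2.0-0.9549`), on a log-spaced grid with 4 voices
per octave; both configurable. The cone of influence uses the e-folding
time of the Gaussian envelope, √2·s with s = (ω₀ + √(2 + ω₀²))/(4πf);
grid points closer than this to either epoch edge are masked.

PLV is computed per (time, scale) point as the modulus of the
trial-averaged unit phasor of the phase difference, then averaged over
the COI-valid points of the band × window rectangle — averaging PLV
values, not phases, because the matrix entries are defined as PLV. No
threshold is applied; matrices are symmetric with unit diagonal in
[0, 1]. For broadband (1–70 Hz) matrices the lowest frequencies have no
COI-valid samples inside the short analysis windows and simply drop out
of the average (with the default epoch, frequencies below ≈2.7 Hz).
Volume conduction is addressed only the way the windowed contrast
addresses it — prestimulus and response share the conduction bias — and
no leakage correction (e.g. imaginary coherence) is applied.

## Graph metrics

- CS: mean off-diagonal weight (equivalently mean node strength/(n−1)).
- CLC: Onnela-style weighted clustering — weights scaled by the matrix
  maximum, node clustering = Σ (ŵ_ij ŵ_ih ŵ_jh)^(1/3) / (k_i(k_i−1)),
  averaged over nodes. Verified against explicit triangle enumeration
  and networkx.
- PL: all-pairs shortest paths (Dijkstra) with edge distance 1/weight,
  averaged over ordered pairs. Verified against exhaustive simple-path
  enumeration on small graphs.
- SW = CLC/PL, an exact identity maintained per subject and window.

Normalisation divides CLC and PL by their mean over 50 surrogates that
permute the off-diagonal weight multiset (upper triangle permuted, then
mirrored; seeded). This yields values near 1 that measure topology beyond
the weight distribution. The surrogate count, scheme and seed are part of
the pipeline config; normalisation can be disabled. The same engine
serves functional (PLV) and structural (FA-weighted) matrices; structural
input may have a zero diagonal and has no modulation.

## Spectral entropy

SE = −Σ p_f log p_f / log N_f with p_f the normalised trial-averaged
wavelet power over 1–70 Hz, averaged across the COI-valid samples of a
window; frequencies valid in only one window are excluded from both so
the two entropies share a support. Power is averaged over trials before
the entropy (event-related regularity), not entropy-per-trial averaged;
this is a deliberate, configurable choice. Modulation = response −
prestimulus; spectral concentration during the response (control-like
dynamics) makes it negative.

The factor summary takes the first principal factor of the sensor
correlation matrix; the loading vector is sign-flipped if its sum is
negative so the sensor consensus loads positively (a per-sensor sign
cannot be forced: a genuinely anti-correlated sensor must load
negatively on a single factor). Scores are standardised to mean 0, SD 1
over the fitted sample. Degenerate inputs (fewer than 2 sensors, fewer
than 3 subjects, a zero-variance sensor) are rejected; an exactly
rank-one table is legitimate and yields variance_explained = 1.

## Biotype extraction

Features: PL, CS and SW in prestimulus and modulation windows — six
variables; CLC is computed and reported but excluded from the clustering
set. Features default to the broadband matrices (configurable; the
theta band is the better-conditioned choice for small simulated cohorts
and is what the EEG-level determinism test uses).

z-scoring stores column means/SDs for projecting held-out samples;
zero-variance columns are an error naming the column.

Cluster count: 13 validity indices (silhouette, Calinski–Harabasz,
Davies–Bouldin, Dunn, C-index, McClain–Rao, PBM, Ratkowsky–Lance,
Ball–Hall, Hartigan, Krzanowski–Lai, gap statistic with 10 uniform
reference draws, Xie–Beni) each vote for a k in 2–8 following their
published optimum rule (max, min, largest successive drop, Hartigan's
H ≤ 10, or the gap criterion); the modal k wins and ties break toward
the smallest k. The ensemble is configurable; the contract is
majority-rule behaviour, not any specific index list.

Partition: k-means from 50 seeded random-centroid initialisations; the
restart with the highest mean silhouette width is kept, with all restart
seeds logged. Stability: k-medoids (greedy build + Voronoi iteration)
on 50 random subsets of size min(40 + 2k, n) with Euclidean distance;
the subset solution with the lowest total dissimilarity over the whole
sample assigns everyone to their nearest medoid, and agreement with the
k-means labels is computed after Hungarian matching (labels are
arbitrary, so all agreement statistics use optimal matching).

Discriminant: homoscedastic linear discriminant on the z-scored
features; a (near-)singular pooled covariance raises an error suggesting
the ridge `shrinkage` flag. Coefficients are reported raw and rescaled
so the modulation-PL coefficient equals 1 — the rescaled form matches
the conventional presentation for this feature set, but neither form is
asserted as canonical. Jackknife: each subject classified by a model
refitted without it; folds that would empty a class are skipped with a
warning. Projection applies the stored z-scoring and discriminant to
replication or control tables and reports agreement with an independent
clustering of those tables when available.

## Statistics

Chi-squared (Pearson, no continuity correction), one-way ANOVA with
pairwise t contrasts Bonferroni-multiplied by the number of pairs
(capped at 1), Benjamini–Hochberg step-up FDR applied independently
within each comparison family (family tags are config-driven), and
Mann–Whitney U with tie-corrected, continuity-corrected normal z.
Two-sided p by default. The normal approximation is verified against
exhaustive permutation enumeration for samples of 5–8 values each (to
within 0.02); below that the approximation to the discrete U
distribution is genuinely coarser, which no convention repairs.
Small-subgroup Mann–Whitney contrasts are intentionally emitted without
multiplicity correction.

## Problem sizes used in checks

Feature-level recovery simulations use 60 subjects per group with 3-SD
per-feature centroid separation over 20 seeds; "separation" is defined
per feature in within-group SD units (a 3-SD Euclidean offset spread
over six unit-variance dimensions would leave ~7% Bayes error and could
not support the ≥0.96 recovery rates the machinery is checked against).
The EEG-level end-to-end run uses 10 subjects per group, 10 channels,
60 attended targets at 250 Hz with theta-band features — the smallest
configuration at which the two latent subgroups are recovered with a
balanced split. Smaller EEG cohorts can yield singleton clusters; that
is a small-sample property of clustering six noisy features, not an
implementation defect, and it is why study-scale samples (hundreds of
subjects) are used in real biotyping work.

## Known limitations

- Surrogate normalisation uses weight permutation; other null models
  (strength-preserving rewiring) would give different normalised scales.
- The wavelet's temporal smoothing blurs phase transitions over roughly
  an e-folding time; coupling changes within ~200 ms of a window edge
  leak across it (the generator's 0–150 ms ramp sits between the
  analysis windows for this reason).
- The discriminant assumes homoscedastic classes; strongly unequal
  cluster covariances would favour a quadratic rule.
- BrainVision reading is a thin MNE wrapper and assumes stimulus
  markers; condition/press bookkeeping for real sessions must come from
  the acquisition's event table.
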