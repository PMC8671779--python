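# eegbiotype

Data-driven subtyping ("biotyping") of psychosis from the global network
properties of task EEG. Given epoched event-related recordings from an
auditory oddball task, the package computes inter-trial phase-locking
connectivity, summarises each subject's functional network with weighted
graph metrics, and extracts patient subgroups with a validated two-stage
clustering procedure — the analysis strategy used in EEG biotyping studies
of schizophrenia and bipolar disorder, packaged as reusable, tested
scikit-learn-style components.

Because event-related patient EEG is rarely shareable, a synthetic cohort
generator with known ground truth (programmed phase coupling, latent
subgroup membership) makes every stage testable end to end.

## The method

**Connectivity.** For channels *x*, *y*, the inter-trial phase-locking
value at time *k* and wavelet scale *s* is

```
PLV_xy(k, s) = | (1/N_t) Σ_n exp(i Δφ_xy(k, s, n)) |
```

with `Δφ_xy` the instantaneous phase difference extracted by convolution
with a complex Morlet wavelet (ω₀ = 6) and `N_t` the number of retained
trials — only target tones followed by a button press ("attended"
targets) are analysed. Cone-of-influence masking removes edge effects;
PLV is averaged over a band (theta 4–8 Hz or broadband 1–70 Hz) and an
analysis window (prestimulus −300–0 ms or response 150–450 ms) into an
unthresholded connectivity matrix with entries in [0, 1].

**Graph metrics.** Each matrix is summarised by connectivity strength
(CS, mean off-diagonal weight), the averaged weighted clustering
coefficient (CLC, geometric-mean triangle intensity), the characteristic
path length (PL, mean shortest 1/weight path), and the small-world index
SW = CLC / PL. CLC and PL are normalised by the mean over 50
weight-permutation surrogate networks. The response-minus-prestimulus
difference is each metric's task **modulation** (chronnectomics).
Spectral entropy (normalised Shannon entropy of the wavelet power
spectrum) and its modulation quantify event-related regularity change;
per-sensor entropy modulation is summarised by a single factor score.

**Biotype extraction.** The six features — PL, CS and SW in prestimulus
and modulation — are z-scored; the cluster count is chosen by majority
vote of 13 validity indices (ties go to the smallest k); k-means with 50
random-centroid restarts keeps the best-silhouette solution; a
CLARA-style k-medoids run over 50 random subsets checks stability; a
linear discriminant function characterises the subgroups, validated by
leave-one-out (jackknife) reclassification, and projects replication and
control samples through the stored z-scoring. Group comparisons use
chi-squared, ANOVA with Bonferroni pairwise contrasts, Benjamini–Hochberg
FDR per comparison family, and Mann–Whitney U.

## Worked example

```python
import pandas as pd
import eegbiotype as eb

# Two-group synthetic feature cohort: 60 subjects per group, centroids
# three within-group SDs apart on each of the six network features.
table, truth = eb.simulate_feature_cohort(60, separation=3.0, seed=7)

model = eb.BiotypeClustering(random_state=7).fit(table)
print("selected k          :", model.k_)
print("silhouette          :", round(model.silhouette_, 3))
print("k-medoids agreement :", round(model.stability_agreement_, 3))

z = pd.DataFrame(model.scaler_.transform(table), columns=table.columns)
disc = eb.fit_discriminant(z, model.labels_)
print("jackknife accuracy  :", round(eb.jackknife_accuracy(z, model.labels_), 3))
print(disc.coefficients_scaled_.round(3))
```

prints

```
selected k          : 2
silhouette          : 0.606
k-medoids agreement : 1.0
jackknife accuracy  : 1.0
pl_prestim       1.271
cs_prestim       1.836
sw_prestim       1.756
pl_modulation    1.000
cs_modulation    1.878
sw_modulation    1.166
```

Twelve of the thirteen validity indices vote for two clusters
(`model.index_votes_`); the k-medoids stability check assigns every
subject to the same cluster as k-means, and the discriminant function
reclassifies all subjects correctly under leave-one-out — the behaviour
expected of the machinery on well-separated subgroups. Coefficients are
reported rescaled so the modulation-PL coefficient equals 1.

The same pipeline runs from a shell, including EEG-level simulation:

```bash
eegbiotype simulate --n-per-group 60 --separation 3 --seed 7 --out cohort/
eegbiotype cluster cohort/features.tsv --seed 7
eegbiotype run --seed 7 --n-per-group 60 --out results/
```

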