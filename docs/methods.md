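# Methods

## Cohort model and filters

The package targets longitudinal EHR cohorts on the AD continuum. A
patient's state is Pre-MCI until the first MCI diagnosis code
(ICD-9-CM 331.83, 294.9; ICD-10-CM G31.84, F06.7, F09, R41.840, R41.841,
R41.89, R41.9), MCI until the first AD code (331.0; G30, G30.0, G30.1,
G30.8, G30.9), and AD thereafter; states are absorbing from the first
qualifying code onward, which makes window labels well defined and
monotone. Inclusion rules, applied in order: at least one MCI code; age
≥ 50 at the first MCI code; no AD code on or before it; at least 365 days
of recorded data on each side of the index date (the first MCI code); and,
for converters, a conversion time strictly greater than 180 days ("more
than six months" read at day resolution). Each rule's exclusions are
counted in a ledger.

## Enhanced encounter windows

Records are tiled into half-open 90-day windows `[start, start+90)`
anchored at the patient's first encounter (anchoring and boundary handling
are conventions of this package; a code dated exactly on a window's end
day belongs to the next window). A code bit is set iff the mapped code
occurs at least once in the window; diagnosis codes map to Phecodes and
drug codes to third-level ATC classes through packaged many-to-one tables,
with unmapped codes routed to one catch-all bucket per system so the
feature dimension is stable. Demographics are re-encoded per window (age
in 5-year bins from 50 to 90+, plus a guard bin below 50 for pre-index
windows). BMI uses the WHO cuts (≤ 18.5 / < 25 / < 30 / ≥ 30); blood
pressure the five ACC/AHA classes (elevated ≥ 120 systolic; stage 1
≥ 130/80; stage 2 ≥ 140/90; crisis > 180/120), configurable; smoking is
four categories. A window's label is the patient's state at the start of
the following window; the final window is unlabeled and used only for
sequence building.

## Directed patient graph

Nodes are windows. Each node proposes edges to its top-k Jaccard
neighbors over the whole node set (k = 25 by default; exact pairwise
search, ties broken by similarity then node order so the build is
deterministic), and consecutive windows of a patient are always linked.
All edges are oriented from the chronologically earlier node (ties by
node order) and carry elapsed days as weight. The degree guarantee is at
the proposal stage: each node initiates exactly k similarity candidates,
so at most n·k similarity edges exist after deduplication; a popular node
may additionally receive edges from many proposers.

The magnetic Laplacian L(q) = I − D_s^{-1/2} H(q) D_s^{-1/2}, with
H(q) = A_s ⊙ exp(i·2πq(A−Aᵀ)) and A_s the symmetrized 0/1 connectivity,
is Hermitian with real spectrum in [0, 2]; q = 0 recovers the symmetrized
normalized Laplacian, q = 0.25 (the default) is maximally
direction-sensitive. Convolution consumes 0/1 connectivity by default;
exp(−Δdays/τ) magnitudes are available behind a switch. The propagation
operator adds self-loops before normalization.

## Encoders and training

All four variants share the two-layer-plus-head shape and produce
embeddings of the configured width (default 32). MagNet carries the
complex signal as separate real/imaginary channels with shared real
weights and complex propagation; ReLU applies channel-wise; the head
consumes the real∥imaginary concatenation (so each channel contributes
half the embedding width). GCN and GraphSAGE (mean aggregator, separate
self/neighbor weights) run on the symmetrized graph; GAT uses single-head
additive attention with a detached per-segment max in its softmax (exact,
by shift invariance).

Training is transductive full-graph gradient descent (adaptive-moment
optimizer implemented in the package's small reverse-mode autodiff
engine; gradients are finite-difference-checked in the tests) with
patient-level 70/10/20 splits, focal loss (γ = 2) by default, seeded
initialization, and checkpointing on validation loss. Defaults: learning
rate 1e-2, 100 epochs, patience 20. The epoch budget is deliberately
moderate: held-out discrimination saturates early (AUROC is
rank-based), while continued optimization progressively rotates the
embedding basis toward the three outcome directions and erodes the
patient-level structure that the clustering stage consumes. One hundred
epochs sits where discrimination is essentially converged but the
representation is still rich. Test-set nodes remain in the graph during
message passing (a leakage-scope property of transductive training; the
supervised metrics use held-out patients' labels only).

## From embeddings to progression subphenotypes

Embedding sequences Hⁿ are compared with DTW (pointwise Euclidean, full
warping band by default, Sakoe-Chiba band available) and clustered with
DTW k-means: k-means++-style seeding, DBA centroid updates at fixed
length equal to the median sequence length, five restarts by default
(three in the end-to-end pipeline wrapper), objective J kept monotone
non-increasing by terminating a restart on a non-improving update, empty
clusters re-seeded from the farthest sequence.

Before sequence building, the pipeline post-processes node embeddings
with a two-level decorrelation: embeddings are whitened (unit-variance
PCA scores) and projected onto the leading principal directions of the
*patient-mean* embeddings (default dimension: a quarter of the embedding
width). Rationale: an outcome-trained encoder concentrates most embedding
variance in a few directions aligned with the supervised next-state task,
and within-patient temporal dynamics dominate pointwise distances;
progression subphenotypes are patient-level structure, so distances are
taken in the between-patient subspace, where planted-subtype recovery on
synthetic cohorts is robust (adjusted Rand index 1.0 at full separation
across seeds, ≈ 0 at zero separation). Raw, z-scored and whitened
representations remain available behind the `representation` switch.

Validity uses the silhouette score and a Davies–Bouldin index computed
under DTW (σᵢ = mean member-to-centroid DTW; Δᵢⱼ = centroid-to-centroid
DTW), with the conventional acceptability reading SS > 0.25 and DBI < 1;
the K scan (2–10) reports scores and flags, leaving the final choice to
the caller. Stability refits on 90% subsamples (100 iterations by
default), assigns all sequences to the subsample centroids, matches
cluster labels to the full-sample solution by Hungarian assignment on
overlap counts, and reports per-cluster Jaccard agreement with SS/DBI
summaries.

A caveat measured on the synthetic cohorts: although the planted
partition is recovered exactly at full separation, the absolute validity
indices of the recovered clustering are modest — SS ≈ 0.21–0.26
(hovering at the conventional 0.25 cutoff across seeds) and
DBI ≈ 1.6–1.75, well above the conventional 1.0. The geometry those
thresholds describe exists in the graph-smoothed *input* space (SS ≈ 0.55,
DBI ≈ 0.78 at the true labels), but outcome-oriented training mixes
within-patient dynamics into every high-variance embedding direction, and
no unsupervised reweighting we evaluated restores that compactness while
keeping exact recovery. Validity indices on outcome-trained embeddings
are therefore best read comparatively (across K, against a null) rather
than against absolute cutoffs.

## Characterization and prediction

Kaplan–Meier estimation and the K-sample log-rank test come from
lifelines (95% CIs on the log(−log) scale). Mortality time runs from the
first AD code to death, censored at last follow-up; conversion time from
first MCI to first AD, non-converters censored at the last visit.
Prevalence profiles are patient-level "ever present" indicators; cluster
pairs are compared per feature with 2×2 χ² tests (Fisher's exact when an
expected cell is below 5), annotated with tiers (p < 0.01/0.001/0.0001/
0.00001); no multiple-testing correction is applied, matching the raw-tier
reporting convention — a caveat for interpretation. Pearson correlations
compare whole cluster prevalence vectors.

The pre-index predictor aggregates all data up to and including the index
date by OR over feature bits (demographics evaluated at the index date);
a standing erasure test asserts that deleting every post-index row leaves
the features unchanged. Models: logistic/lasso/ridge/elastic-net
(one-vs-rest where multiclass) and XGBoost; hyperparameters by seeded
random search (default 20 trials) over declared grids with 5-fold CV on
the training split, random over/under-sampling applied inside training
folds only. Importance is permutation-based (mean macro-AUROC drop over
20 shuffles per feature); SHAP values are substituted when the optional
shap package is installed.

## Synthetic cohort generator

The generator emulates the study conditions of an MCI→AD EHR cohort with
a three-state semi-Markov process and log-normal sojourns. Per-subtype
defaults follow the published per-subphenotype statistics: MCI→AD sojourn
means (854, 1236, 952, 805) days with sds (577, 725, 628, 563); pre-MCI
record spans chosen so first-record→AD averages (2395, 2939, 2543, 2365)
days; subtype proportions (0.514, 0.162, 0.162, 0.162); age at first MCI
N(76, 8.88) truncated at 50; 61.66% women; race-ethnicity (NHW/NHB/
Hispanic/Other) = (0.648, 0.165, 0.109, 0.078). Post-AD survival means
(1200, 800, 900, 1100) days (sd 60%) encode the reported ordering (the
slow progressors carry worse post-AD survival). Encounters arrive as a
homogeneous Poisson process at 3 per 90 days (a realistic outpatient
visit rate for this age group; the true distribution is not published),
with forced visits at the first record, both state changes, and the end
of follow-up; censoring (default probability 0.3) truncates follow-up
before an unrecorded death, never below the one-year post-index minimum.

Code emissions are per-window Bernoulli draws from per-(subtype, state)
profiles, recorded at a random visit inside the window (a window without
a visit records nothing). Profiles are a shared base prevalence
(0.05/window) plus subtype-specific signature blocks that partition the
vocabulary; at `separation = 1` a signature code reaches 0.9/window in
MCI/AD and 0.5 pre-MCI, and `separation` also interpolates all duration
parameters toward their pooled means, so at 0 the subtypes are
exchangeable *by construction* — a single dial from null to fully
expressed. Vitals are drawn with mild subtype-dependent blood-pressure
shifts (scaled by the same dial) and always recorded at the intake visit.

What the generator does not emulate: realistic ICD code semantics and
co-occurrence structure, coding intensity that varies with disease stage
or site, measurement error in staging (the first MCI/AD codes are exact),
lab values beyond discretized vitals, non-converting MCI patients, and
informative censoring. Passing tests therefore demonstrate that the
pipeline recovers planted structure of this kind at desk scale — not that
it would resolve subphenotypes in any particular real cohort.

## Numerical choices and scale

Dates are day-resolution; elapsed time is integer days. DTW uses full
dynamic programming (numba-accelerated when available) and is verified
against exhaustive path enumeration for short sequences. The magnetic
Laplacian is validated for Hermiticity at 1e-10 and spectrum containment
in [0, 2]. Jaccard search is exact (chunked matrix products); determinism
of graph construction, training trajectories, k-means and importance
rankings under a fixed seed is asserted in the tests. Default problem
sizes in the test suite and acceptance script (cohorts of 150–300
patients, ~10⁴ graph nodes, 100 training epochs, 10-iteration stability
bootstraps) are the package's desk-scale defaults; all are configurable
upward.
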