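# progsub

Graph-based disease-progression subphenotyping from longitudinal electronic
health records (EHRs), built around the MCI→AD continuum (mild cognitive
impairment progressing to Alzheimer's dementia).

Patients with the same diagnosis can follow very different progression
pathways. `progsub` identifies data-driven progression subphenotypes from
routine-care encounter data in four stages:

1. **Featurize.** Each eligible patient's record (age ≥ 50 at the first MCI
   diagnosis, no AD code before MCI, > 6 months MCI→AD conversion time,
   ≥ 1 year of data before and after the index date) is tiled into 90-day
   windows. Each window becomes a binary *enhanced encounter* vector
   x̂ₜ over [age bins ∥ sex ∥ race-ethnicity ∥ Phecodes ∥ ATC-3 drug
   classes ∥ discretized vitals], labeled with the patient's state
   (Pre-MCI / MCI / AD) in the **following** window.
2. **Directed patient graph (DPG).** Windows become nodes; directed edges
   link each node to its top-k Jaccard-similar nodes across the cohort and
   to the patient's own next window, always oriented earlier→later and
   weighted by elapsed days. Direction enters spectral convolution through
   the magnetic Laplacian L(q) = I − D⁻¹ᐟ² (Aₛ ⊙ e^{i2πq(A−Aᵀ)}) D⁻¹ᐟ²,
   a complex Hermitian matrix with a real spectrum in [0, 2].
3. **Outcome-oriented representation learning.** A two-layer graph encoder
   (MagNet by default; GCN / GAT / GraphSAGE variants included) with a
   fully connected softmax head y = θ(W h_v + b) is trained end-to-end to
   predict the next-window state (cross-entropy or focal loss), with
   patient-level 70/10/20 splits. The learned node embeddings h_v are
   outcome-oriented: they encode where the patient is heading on the
   disease continuum.
4. **Time-series clustering.** Each patient's chronological embedding
   sequence Hⁿ = {h₁ⁿ, …, h_Tⁿ} is compared by dynamic time warping (DTW)
   and clustered with DTW k-means (DBA centroids), minimizing
   J = Σᵢ Σ_{j∈Cᵢ} DTW(Hⱼ, μᵢ). K is scanned over 2–10 with silhouette
   (SS) and Davies–Bouldin (DBI) validity scores (conventional
   acceptability: SS > 0.25, DBI < 1) and 90%-subsample bootstrap
   stability (per-cluster Jaccard after Hungarian matching).

Recovered subphenotypes are characterized with Kaplan–Meier curves
(post-AD mortality, MCI→AD conversion; log-rank tests), transition-time
statistics, and prevalence heatmaps with pairwise χ²/Fisher tests; their
predictability from pre-index information (everything up to the first MCI
diagnosis) is assessed with linear models and gradient boosting plus
permutation feature importance.

Because real claims/EHR cohorts cannot be redistributed, the package ships
a seeded synthetic cohort generator (`progsub.synth`) that plants
progression subphenotypes — subtype-specific comorbidity/medication
profiles and log-normal state sojourn times — behind a single `separation`
dial (0 = subtypes exchangeable, 1 = fully expressed). Every stage of the
pipeline is tested against this generator's ground truth.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from progsub import synth, gnn, cluster
from progsub.pipeline import run_pipeline

cfg = synth.GeneratorConfig(n_patients=300, n_subtypes=4,
                            separation=1.0, seed=1)
res = run_pipeline(cfg, n_clusters=4, cluster_seed=0)

print("held-out macro AUROC:",
      round(gnn.evaluate(res.train_result, res.graph, "test")["macro_auroc"], 3))
print("ARI vs planted subtypes:",
      round(adjusted_rand_score(res.true_subtypes(),
                                res.model.assignments), 3))
```

prints (seed 1):

```
held-out macro AUROC: 0.926
ARI vs planted subtypes: 1.0
```

i.e. the encoder predicts the next-window disease state well on held-out
patients (AUROC 0.92), and DTW k-means on the embedding sequences recovers
the four planted progression subphenotypes exactly (adjusted Rand index
1.0). At `separation=0` the same pipeline returns ARI ≈ 0, as it should.

The same pipeline is scriptable from the shell:

```bash
progsub simulate --out cohort/ --seed 7 --n-patients 100
progsub featurize --in cohort/ --out feat/
progsub train --in cohort/ --variant magnet --k 25 --seed 7 --out run/
progsub cluster --embeddings run/ --kmin 2 --kmax 6 --final-k 4 --out clus/
progsub characterize --assignments clus/assignments.csv --cohort cohort/ --out chr/
progsub predict --cohort cohort/ --labels clus/assignments.csv --model logistic --out pred/
```

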