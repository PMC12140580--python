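# dynmod

Dynamic modularity of resting-state functional brain networks, and its
relationship to sensorimotor learning.

Individual differences in how people learn a visuomotor rotation task —
fast on both days (FF), slow on both days (SS), or slow then fast (SF) —
can be predicted from the *dynamics* of their resting-state functional
connectivity before the task.  `dynmod` implements that analysis as a
reusable pipeline:

1. **Connectivity** — per-subject region×time BOLD panels are decomposed
   with the maximal-overlap discrete wavelet transform (Haar, scale 1 =
   0.125–0.25 Hz at TR = 2 s); magnitude-squared coherence is estimated
   in 64-s sliding windows (32 volumes, 50% overlap) for every region
   pair and thresholded at the 95th percentile of a shuffled-window
   null, yielding sparse multislice networks.
2. **Multilayer modularity** — networks are partitioned by maximizing

       Q = (1/2μ) Σ_ijlr [(A_ijl − γ k_il k_jl / 2m_l) δ_lr + δ_ij ω c_lr] δ(g_il, g_jr)

   (Newman–Girvan null, γ = ω = 1, ordinal inter-layer coupling) with a
   generalized Louvain heuristic, repeated for an ensemble of
   partitions per subject.
3. **Reconfiguration** — cohesion strength (mutual module changes per
   transition, summed over partners) and disjointedness (lone changes
   per transition) per region and subject.
4. **Allegiance networks** — the module allegiance matrix P = T/C
   (probability of same-module co-occurrence over slices, partitions
   and subjects), summarized into networks by Newton-like symmetric NMF
   (Y ≈ HHᵀ, H ≥ 0, best of many inits, rank selected by RMSE /
   dispersion / cophenetic criteria); recruitment I_kk and integration
   I′ = I_k1k2/√(I_k1k1 I_k2k2) per network.
5. **Behavior** — binned median endpoint errors give early/late error
   per day and savings; k-means over the five measures (validated by
   Silhouette and Caliński-Harabasz with a multivariate-normal null)
   identifies learner subgroups, and the sign-fixed first principal
   component (PC1) is the scalar learning outcome.
6. **Inference** — OLS regression of PC1 on each network measure with
   leave-one-out cross-validation, a 10,000-fold permutation null on
   the LOOCV error, Benjamini–Hochberg FDR within declared families,
   Steiger's test for dependent correlations, and subgroup t-tests.

Raw fMRI from the study is not public, so the package ships a
first-class **synthetic cohort generator** that plants every structure
the pipeline is supposed to recover: window-varying module memberships
with cohesive and disjoint switch events, profile-dependent coupling
strength, and exponential learning curves linked to the planted
coupling.  All recovery and calibration claims in the test suite are
made against this generator.

## Worked example

```python
import dynmod as dm

cfg = dm.RunConfig(
    cohort=dm.CohortConfig(
        n_subjects=8, n_regions=20, n_volumes=96, n_modules_planted=3,
        subgroup_sizes={"FF": 4, "SS": 2, "SF": 2}, seed=7),
    n_runs=5, null_iters=200, symnmf_inits=10,
    kmeans_restarts=30, k_range=(2, 5), n_perm=199, seed=7)
report = dm.run_pipeline(cfg)
for m, r in report["models"].items():
    print(f"{m}: beta={r['beta']:+.3f} R2={r['r_squared']:.3f} p={r['p']:.3f}")
```

prints

```
mean_q: beta=-8.071 R2=0.247 p=0.210
cohesion: beta=+27.594 R2=0.819 p=0.002
disjointedness: beta=-21.692 R2=0.079 p=0.500
recruitment: beta=+8.227 R2=0.632 p=0.018
integration: beta=-8.501 R2=0.677 p=0.012
node_strength: beta=+0.988 R2=0.800 p=0.003
```

Each line is a simple regression of the behavioral PC1 on one
resting-state network measure across the 8 synthetic subjects: the
slope sign shows the direction of the brain-behavior association
(positive for cohesion, recruitment and node strength; negative for
disjointedness and integration — matching the planted structure), R²
the variance explained, and p the F-test p value.  At this toy size
only the strongest associations reach significance; the test suite
demonstrates sign recovery in ≥ 95% of 32-subject cohorts.

The same stages are available from a shell:

```bash
dynmod simulate --subjects 8 --regions 40 --out cohort/
dynmod connect --in cohort/sub-000/rest1.tsv --scale 1 --null-iters 10000 --seed 1 --out net/
dynmod partition --net net/ --gamma 1 --omega 1 --runs 100 --seed 1 --out ens/
dynmod metrics --ensemble ens/ --out scores.tsv
dynmod derive --allegiance allegiance_P.tsv --ranks 2:15 --inits 250 --seed 1 --out nmf/
dynmod behavior --trials cohort/ --restarts 1000 --krange 2:9 --seed 1 --out behavior.tsv
dynmod predict --measures measures.tsv --outcome behavior.tsv --perms 10000 --seed 1 --fdr --out models.json
```

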