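# Methods

`dynmod` implements a resting-state dynamic-modularity analysis for
parcellated BOLD time series: it builds time-resolved functional
networks from wavelet coherence, partitions them into spatiotemporal
modules, summarizes how modules reconfigure and which regions ally,
reduces two-day visuomotor-rotation learning curves to a scalar
behavioral outcome, and tests whether the network measures predict that
outcome under internal (leave-one-out + permutation) validation.  A
synthetic cohort generator provides ground-truth data with the same
statistical structure, so every stage is testable end to end.

## Connectivity

Each subject's panel is an N×T matrix of z-scored region signals with
sampling interval `tr` (defaults N = 142, T = 180, tr = 2 s).  The full
series is decomposed once with the maximal-overlap discrete wavelet
transform (Haar family, periodic boundary); the scale-j detail series
occupies the band [1/(2^(j+1)·tr), 1/(2^j·tr)] Hz — 0.125–0.25 Hz for
scale 1 at tr = 2 s.  The MODWT pyramid is implemented directly
(circular filtering with the rescaled quadrature-mirror filters taken
from PyWavelets); it is energy-preserving, and a unit test checks the
energy identity to 1e-6 relative error.

The coefficient series are cut into sliding windows (default 32
volumes = 64 s, step 16 = 50% overlap; 10 windows at T = 180).  Within
each window, magnitude-squared coherence is estimated for every region
pair by Welch's method — 16-sample hann-tapered segments, 50% segment
overlap, per-segment mean removal — and averaged over the discrete
frequencies inside the band.  The all-pairs path computes segment FFTs
once per window and assembles cross-spectra by einsum; a test pins it
to `scipy.signal.coherence` at 1e-10.

**Null threshold.** A per-scan null is built by repeatedly drawing two
regions and two window start times at random, permuting the coefficient
samples independently within each window (destroying auto- and
cross-correlation, preserving marginals), and recording the band
coherence; entries below the null's 95th percentile are zeroed
(default 10,000 draws).  One global threshold is used per scan.  At full
study dimensions this yields a mean network sparsity of ≈ 86%, which the
acceptance script recomputes.  Thresholding has a coupling-strength
floor: with three Welch segments the null 95th percentile sits near
0.56, so pairs whose population coherence (the squared within-module
correlation) is below ≈ 0.75 drop out of some windows; recovery tests
account for this.

A uniform-sparsity control (`enforce_uniform_sparsity`) retains the top
`ceil(density·N(N−1)/2)` edges per layer with stable-index tie-breaking.

## Multilayer modularity

Quality of an L×N labeling:

Q = (1/2μ) Σ_{ijlr} [ (A_ijl − γ k_il k_jl / 2m_l) δ_lr + δ_ij ω c_lr ] δ(g_il, g_jr)

with Newman–Girvan intra-layer null, γ = ω = 1 by default, ordinal
coupling c_lr = 1 iff |l−r| = 1, and 2μ the total weight including
couplings.  Empty layers contribute coupling terms only; an all-empty
network with ω = 0 has undefined Q and raises.

The generalized Louvain heuristic works on the L·N supra-node problem.
The first-phase node sweep visits supra-nodes in random order and moves
each to a module chosen at random among the quality-increasing
candidates with probability proportional to the increase; aggregation
phases are deterministic (best move).  The converged partition is
re-fed as the initial condition until the output equals the input up to
label permutation, with a configurable outer-iteration cap.  Node-to-
module link weights W = B·M are maintained incrementally (two column
updates per move), which makes a 100-run ensemble on a 10-layer,
142-region problem tractable on one core.  On exhaustive-search-sized
instances (5 nodes, 2 layers; Bell(10) = 115,975 partitions) the
best-of-100 heuristic attains the global optimum on ≥ 95% of seeded
instances.

Subject-level Q is the mean over the partition ensemble (default R=100;
the reduced test profile uses R = 4–25).  `modularity_null_test`
compares observed mean Q against one of three null-network families —
temporal (layer order permuted), connectional (within-layer edge
weights permuted over region pairs), nodal (inter-layer coupling
targets permuted) — with the add-one estimate
p = (1 + #{Q_null ≥ Q_obs}) / (n_nulls + 1).  The family is a config
choice; the connectional null is the default used in calibration tests.

## Reconfiguration metrics

For each transition between consecutive windows, a region either keeps
its module, moves together with partners (identical source AND target
module, both changing), or moves alone.  Cohesion strength counts
partners summed over all other regions and transitions, divided by
L−1; disjointedness is the fraction of transitions with a lone move.
Mutual movers are counted once per partner.  Module identity across
layers comes from the multilayer labels themselves — no relabeling or
matching step.  Ensemble scores average regions over partitions; the
subject scalar is the grand mean (order-independent by linearity).
Both metrics are pinned exactly to a brute-force event-enumeration
oracle.

## Allegiance, recruitment, integration

T_ij counts co-assignments of regions i and j over every included time
slice × partition × subject; C is the number of slices counted and
P = T/C.  Group matrices pool counts before normalizing, so the pooled
computation equals the slice-count-weighted average of per-subject
matrices (tested).  Optional null-zeroing uses the within-slice label
permutation null: under it, P_ij for every off-diagonal pair has the
same distribution — a mean of Bernoulli draws with per-slice success
probability Σ_k n_k(n_k−1)/(N(N−1)) — so the 95th-percentile cutoff is
simulated directly from that distribution instead of materializing
permuted matrices.  The diagonal (P_ii = 1) is exempt.

Block means of P over a hard region→network assignment give the
interaction I_{k1,k2}; recruitment is I_{k,k} (diagonal included, per
the block-mean formula; an off-diagonal-only variant is exposed);
integration is I′ = I_{k1,k2}/√(I_{k1,k1} I_{k2,k2}), reported without
clamping (it can exceed 1).  Network similarity uses the Jaccard index
×100 and Pearson correlation over the N(N−1)/2 off-diagonal entries.

## SymNMF

Summary networks come from symmetric NMF of an allegiance matrix:
minimize ‖Y − HHᵀ‖²_F with H ≥ 0.  The optimizer is a curvature-scaled
projected-gradient scheme: Barzilai–Borwein secant steps (a diagonal
Newton surrogate) with Armijo backtracking along the projection arc,
stopping at relative loss change < 1e-6 or 500 iterations.  Armijo
acceptance enforces a monotone loss decrease, asserted per iterate in
tests.  Each fit uses 250 uniform-[0,1] initializations by default
(reduced in tests) and keeps the lowest final loss; an independent
multiplicative-update solver serves as a test-only cross-check on
attained loss.

Rank selection reports, per rank in 2..15: mean and best RMSE
(√(‖Y−HHᵀ‖²/N²)), the dispersion coefficient ρ = mean(4(c̄−½)²) and the
cophenetic correlation (average linkage) of the across-init consensus
matrix of hard assignments, and explained variance against both the
mean of Y and zero (both are reported because the reference is a
modeling choice).  Rank acceptance is not automated; a documented
default takes the smallest rank with explained variance ≥ 0.8.
Hard clusters assign each region to its strongest factor, ties to the
lowest index, computed on H exactly as fitted.  A region with an
all-zero loading row is unassignable; callers may supply Y to fall back
to the allegiance-aligned factor, and the pipeline re-derives from the
un-zeroed group matrix if null-zeroing isolated a region outright
(only observed in very small synthetic cohorts).

## Behavior

Trial tables carry day, trial, bin, target angle and endpoint error for
two days of 40 learning bins × 8 trials.  Per-bin medians give the
binned median error (absent discarded trials are simply missing rows);
early/late error are means of bins 1–3 and 38–40 (24 trials each), and
savings = early1 − early2 exactly.

Subgrouping: k-means over the five z-scored measures for k = 2..9, 1,000
random restarts by default (own Lloyd loop, random k-distinct-point
inits, emptied clusters re-seeded at the farthest point), keeping the
restart with the lowest within-cluster sum of squared distances — the
objective Lloyd minimizes and the quantity k-means software reports for
best-of-restarts.  Each k is scored by Silhouette and Caliński-Harabasz;
the selected k must agree across both indices, and disagreement raises
rather than resolving silently.  Significance comes from refitting the
whole sweep on draws from a multivariate normal matched to the data's
mean and covariance (shrinkage ridge added if singular, reported) and
comparing the observed maximum of each index to the null maxima.
Because the null's parameters are estimated from the observed sample,
this procedure is conservative: at α = 0.05 its measured type-I error
on normal data is ≈ 1%, while the identical statistic calibrated
against the true generating parameters rejects at the nominal rate.
Tests check both facts (nominal calibration under the exact null, no
inflation under the estimated-parameter null).

The behavioral outcome is the first principal component of the five
z-scored measures (SVD), sign-fixed so that higher PC1 correlates
negatively with mean early error — higher scores mean faster learning.
Standardization (correlation-matrix PCA) is the default because savings
and raw errors have different dispersions; a raw-scale flag exists.

## Brain-behavior inference

Simple OLS models predict PC1 from each network measure (statsmodels).
Internal validity: leave-one-out prediction errors via the hat-matrix
identity e_i/(1−h_ii) (points with leverage ≈ 1 fall back to an explicit
refit), with the identity itself pinned to literal refitting at 1e-10.
The permutation test shuffles the predictor-outcome mapping (default
10,000 times, vectorized through the fixed hat matrix) and reports the
add-one tail proportion of null LOOCV MSEs ≤ the observed MSE — small p
means the model predicts better than chance.  Benjamini–Hochberg FDR is
applied within explicitly declared families.  Steiger's test (Williams
form, df = n−3) compares dependent correlations sharing one variable;
pooled-variance two-sample t-tests (df = n1+n2−2) and paired t-tests
cover subgroup and scan contrasts.  All four permutation/analytic tests
are calibrated: under their own nulls the rejection rate at α = 0.05
lies inside the binomial 95% CI (200–2,000 replicates, scaled counts).

## Synthetic cohorts

The generator emulates the study's data structure: 32 subjects in three
learner profiles (FF/SS/SF, sizes 15/10/7), two 180-volume rest panels
each, and two days of trial tables.

**Time series.**  Regions in the same planted module share a Gaussian
latent signal z_k(t); region noise is scaled by √((1−ρ)/ρ) so the
within-module correlation equals the subject's planted coupling ρ
(`noise_sd` multiplies this calibrated scale; 0 gives correlation 1).
Default couplings: FF 0.8, SF 0.55, SS 0.3, jittered ±0.05 per subject.
Memberships are piecewise-constant on half-window blocks (16 volumes);
the planted partition of analysis window l is the membership of block l,
so a window overlapping a switch mixes two memberships — switch rates
are kept low enough (≤ 0.8 events/transition) that recovery stays
well-posed.  Cohesive events move groups of 2–3 regions from one module
to a common target; disjoint events move a lone region with a
(source, target) pair unused by any other move at that boundary; events
never empty a module.  Rates: cohesive FF 0.8 / SF 0.4 / SS 0.1,
disjoint FF 0.1 / SF 0.4 / SS 0.8 per transition.  These follow the
study's qualitative structure (coordinated reconfiguration in fast
learners, fragmented in slow); their magnitudes are chosen for
recoverability at desk scale, as no quantitative values exist for
resting data.

**Behavior.**  error(t) = a·exp(−t/τ_day) + b + noise, truncated at
±180°, with a = 40°, b = 5° (each given a per-day N(0, 2²)/N(0, 1²)
perturbation), trial noise 2°, and profile τ (trials): FF (15, 10),
SS (120, 110), SF (120, 15).  τ is scaled by exp(−1.5·(ρ−ρ_profile))
— the coupling→learning-speed link — plus independent per-day
log-normal variability (σ = 0.08).  The per-day perturbations and
day-wise τ variability keep within-profile spread roughly isotropic in
the five-measure space; purely shared (between-day) variation elongates
the clusters and makes the Caliński-Harabasz index over-split.

Randomness: every stream derives from (master seed, stage name, subject
index, scan) through `numpy.random.SeedSequence`, so outputs are
byte-identical under a fixed seed and independent of generation order.

**What the generator does not emulate:** spatial autocorrelation and
hemodynamics, head-motion and physiological artifacts, heavy-tailed
noise, region-specific coupling heterogeneity, or any task-scan
structure.  Passing recovery tests therefore demonstrate that the
pipeline recovers the planted statistical structure under idealized
Gaussian conditions, not that it would detect effects of this size in
real BOLD data.

## Problem sizes in the test and acceptance profile

Unit and acceptance tests run reduced problem sizes, chosen as the
package's desk-scale profile: synthetic cohorts of 32 subjects × 24
regions × 180 volumes with 4-run partition ensembles for the end-to-end
sign-recovery experiment (20 replicate cohorts; the ≥ 95% requirement
becomes ≥ 19/20); 6 replicate cohorts for behavioral recovery;
permutation calibrations at 199–1,999 permutations with 200–2,000
replicates; SymNMF with 10–15 inits on constructed block matrices.
Study-scale parameters (100 runs, 250 inits, 10,000 permutations,
142 regions) are plain arguments away and used where cheap (the
sparsity computation runs at full 142×180).

## Known limitations

- The generalized Louvain move rule is probabilistic only in the
  first-phase sweep; other published variants randomize aggregation as
  well.
- Null-zeroing of allegiance uses a scalar threshold (exact under the
  permutation null's pair-exchangeability); if regions had structurally
  different module-size exposure the per-entry distribution would
  differ.
- The Caliński-Harabasz index over-splits compact clusters whose
  within-cluster variance concentrates in dimensions without cluster
  structure; the selected-k contract surfaces such disagreement rather
  than hiding it (in ~2% of default synthetic cohorts CH prefers a
  larger k and `selected_k` raises).
- Integration's direction under the generator reflects two competing
  mechanisms (partition noise in weakly coupled subjects raises it;
  planted cohesive switching in strongly coupled subjects also raises
  it); the default rates keep the first dominant.
- LOOCV validation is internal only; no external-cohort validation is
  provided.
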