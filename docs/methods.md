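# Methods

## Model

Each of the n = 90 regions of the AAL90 parcellation is a Stuart-Landau
oscillator — the normal form of a supercritical Hopf bifurcation — written
in Cartesian coordinates and coupled diffusively through the structural
connectome M (symmetric, nonnegative, max-normalized so the strongest
connection is 1):

```
dx_i = [ (a_i - x_i^2 - y_i^2) x_i - w_i y_i + G Σ_j M_ij (x_j - x_i)
         + F_i(t) cos(w_i t) ] dt + β dW_i^x
dy_i = [ (a_i - x_i^2 - y_i^2) y_i + w_i x_i + G Σ_j M_ij (y_j - y_i)
         + F_i(t) sin(w_i t) ] dt + β dW_i^y
```

For a_i > 0 an uncoupled noise-free node has a stable limit cycle of radius
√a_i rotating at f_i = w_i/2π; for a_i < 0 the origin is a stable focus and
activity is noise-driven; a_i = 0 (the default working point) sits at the
bifurcation. x_i(t) is the BOLD-like output. Variants of these equations
circulate with the cubic term typeset as (x² − y²) and with both rotation
terms negative; neither yields the limit-cycle/fixed-point bifurcation at
radius √a and frequency f_i that defines this model (two negative rotation
terms give real eigenvalues a ± w and no oscillation at all), so the
standard form above is implemented and the alternatives are treated as
typesetting slips.

Parameters, units, defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| a_i | 0 | bifurcation parameter, dimensionless; "close to the bifurcation" |
| f_i | 0.05 Hz | intrinsic frequency of every node (slow BOLD band) |
| β | 0.1 | SD of the additive Gaussian noise |
| G | fitted | global coupling scaling all structural links |
| dt | 0.1 s | Euler-Maruyama step |
| duration | 900 s | 15 min of simulated resting state |
| transient | 60 s | discarded before analysis (initial-condition decay; not prescribed upstream, configurable) |
| F0_i | 0.5 on targets | sinusoidal forcing amplitude (stimulation only) |
| σ | 0–2 | SD of the forcing-amplitude noise, swept in the stimulation protocol |

Integration is Euler-Maruyama: `state += drift·dt + β·√dt·N(0,1)` with
independent noise streams for x and y, redrawn each step; the forcing
amplitude noise μ_i(t) is redrawn each step and shared between the cos and
sin terms of a node. Initial conditions are uniform in [−0.1, 0.1]² per
node from the seeded stream. Output x is band-passed 0.01–0.1 Hz with a
zero-phase (forward-backward) third-order Bessel filter and exactly
demeaned; note the doubled pass squares the magnitude response, so a
0.05 Hz tone is preserved at |H|² ≈ 0.87, and the analytic response is the
test oracle. There is no haemodynamic convolution; the slow oscillators
are themselves the BOLD surrogate. Halving dt changes mean FC by < 0.02 on
the default configuration.

Numerical safety: any non-finite state aborts with the step index (reached
at very large G); such sweep cells are excluded from fitting means rather
than scored zero, to avoid biasing the arg-max.

## Coupling fit

The single free parameter G is swept over a grid (full scale 0:3:0.05, 61
points; reduced experiments use 0:2:0.1) and each (G, seed) cell is scored
by the Structural Similarity Index between the simulated FC (Pearson
correlations of the band-passed signals) and the target FC. SSIM uses a
sliding uniform 7×7 window over the full matrix including the diagonal,
data range 2 (FC spans [−1, 1]), constants C1 = (0.01·2)², C2 = (0.03·2)².
The per-G mean over seeds is maximized; ties break toward the smallest G
(parsimony). Whether to include the diagonal is not prescribed; full
matrix is the default with an `exclude_diagonal` option.

Two empirical properties of this estimator matter for validation and are
reproducible with the package:

1. **Window matching.** The FC level of slow band-limited signals depends
   on the correlation window length (components near 0.01 Hz are partly
   absorbed into the window mean on short windows). A target computed from
   a longer run than the fitting simulations therefore reads as "higher
   coupling" and shifts the fitted G up by several grid steps.
2. **Realization noise.** With a single-run target, the realized global FC
   level of that one draw sets the recovered G; because level(G) is
   concave, the deviation distribution is skewed upward.

The synthetic target is therefore a seed-average of `reference_runs = 5`
runs at the standard 900 s duration — which is also the faithful stand-in
for an empirical grand-average FC (an average over many subjects). For
self-consistency experiments `sweep_g(average_fc=True)` additionally
averages the simulated FCs across seeds per G before a single SSIM
evaluation (variance-reduced scoring); the default scoring remains the
per-seed mean. Under this protocol the group-average fit recovers the
generating coupling within one 0.1 grid step for reference G ∈
{0.6, 1.0, 1.4} across dataset seeds.

## Synthetic cohort

The generator stands in for a restricted two-group cohort (expert
real-time-strategy players vs non-players, 31 per group) with
streamline-count connectomes and a weekly-playing-time covariate. Per
dataset: one base SC is sampled (density 0.25 of the 4005 undirected
edges, log-normal weights with shape σ = 1.2), per-subject matrices add
multiplicative symmetric edge noise (SD 0.05) and are max-normalized;
expert subjects additionally have the planted edges — the full
parieto-occipital clique plus the fronto-parietal pairs (SFGdor–IPG,
MFG–ANG, SMA–PCUN) in both hemispheres — multiplied by `effect_size`
(default 1.5). Non-experts play uniform 0–2 h/week; expert log-hours are
constructed from the standardized planted-edge strength to realize
`covariate_r` (default 0.6) against natural-log hours, floored at 6 h/week.

Two stabilizing choices keep the generator's conditions identifiable:

* the strongest ("trunk") edge is pinned at the normalization ceiling and
  is never planted, and weights saturate at a robust quantile-based
  ceiling. A raw heavy-tailed maximum would make the normalized matrix's
  overall coupling scale fluctuate ~3× across datasets (flattening the
  SSIM landscape) and could silently cancel the planted effect whenever
  the maximum landed on a planted edge;
* planted edges are capped at 60% of the ceiling for the same reason.

What the generator does **not** emulate: spatial autocorrelation of real
cortical connectivity, distance-dependent connection probability,
hemispheric asymmetries, realistic degree distributions, or any
behavioral/demographic covariates beyond playing time. Passing tests
therefore show that the pipeline's inference machinery is calibrated and
recovers planted effects under its stated assumptions — not that the
original empirical effect sizes are reproduced.

## Graph analysis

FC (or SC) matrices are proportionally thresholded — the top p of ranked
off-diagonal edges retained by signed value (negative correlations are
never retained at the densities used; absolute-value ranking is an
option) — and binarized. Binary global efficiency (mean inverse shortest
path, disconnected pairs contributing 0) measures integration; Newman's
transitivity (collectively normalized triangle density) measures
segregation. Both are summarized by the trapezoidal AUC over thresholds
5%–18% in 1% steps. Implementations are numpy/scipy-based and are checked
against exhaustive enumeration of all ≤ 6-node graphs and against networkx.

Network-based statistics: edges are ranked by a one-tailed pooled-variance
two-sample t statistic, thresholded at t = 3 for FC (t = 1.5 for the
sparser-signal SC variant), and the size of the largest connected
component — counted in edges, the original NBS convention — is compared
with its label-permutation null; p uses add-one smoothing so it is never
0. The pooled subject rows are canonically re-ordered before permutation
so p-values are invariant to subject order. Degenerate (zero-variance)
edges score t = 0 with a warning.

## Greedy covariate search

Within an edge mask (typically the NBS component), step 1 picks the edge
whose FC values across expert subjects maximize Pearson correlation with
log playing time; each later step adds the edge that maximizes the
correlation of the running mean FC, stopping at the first non-improving
step. Ties break by (r desc, edge lexicographic). "Global maximum" means
the maximum of the greedy trace; the search cannot certify a global
optimum over all subsets. The expert group only is correlated by default
(log hours ≥ log 6); an option includes all subjects with log(h+1).

## Connectome conversion

Eligible structural edges (expert mean weight > 0.01) are ranked by
expert-minus-nonexpert difference; the top fraction is transplanted into
the non-expert average SC, which is then rescaled to preserve its mean
strength. For each fraction, the converted model (reusing the non-expert
fitted G; refitting optional) is simulated over seeds, the FC averaged and
restricted to the NBS mask, and the Euclidean distance to the expert
reference FC computed. The plateau is the smallest fraction within 2%
(relative) of the curve minimum — a proxy for the visual "stable
reduction" criterion — and the edges transferred at the plateau form the
core subnetwork. Structural similarity changes are reported as Pearson
correlation of upper-triangle weights (the similarity metric is not
prescribed upstream; correlation is scale-invariant, which suits
normalized matrices).

## Stimulation protocol

Homotopic occipital pairs (six in AAL90) are stimulated one at a time with
F0 = 0.5 on both members at the nodes' own frequency while σ is swept 0–2
(default step 0.2; the step is not prescribed upstream). Per subject,
noise level and pair, the four metrics (overall FC, parieto-occipital FC,
efficiency AUC, transitivity AUC) are computed from the simulated FC with
the identical thresholding/AUC procedure as resting state, then averaged
across pairs and seeds; a resting baseline runs alongside. Group
difference curves are tested per (σ, metric) with pooled t tests and
BH-FDR across the whole tested family. A simultaneous-stimulation mode is
intentionally not the default (the pair-wise average is the reading
adopted); forcing frequency equals each node's intrinsic w_i.

## Statistics

Pooled-variance Student t tests by default (Welch optional); two-sided
label-permutation tests on the mean difference with exact enumeration when
the number of splits is ≤ 20 000 and add-one-smoothed Monte-Carlo p
otherwise; Pearson correlations with t-transform p-values; Benjamini-
Hochberg step-up FDR; Cohen's D with pooled SD, binned negligible/small/
moderate/large/huge at 0.2/0.5/0.8/1.2 with boundary values assigned to
the lower bin (the conventional strict inequalities leave boundaries
unassigned).

## Problem sizes used in the shipped validation

Tests and the acceptance script run reduced configurations chosen to keep
the full suite fast while preserving every qualitative property: 6–8
subjects per group (31 at full scale), 5 fitting seeds (100 at scale),
coupling grid 0:2:0.1 (0:3:0.05 at scale), NBS with 1000 permutations and
200 null replicates at 20 nodes, stimulation with 10 seeds and 2 pairs,
conversion with 5 seeds at fractions {0, 0.5}. `RunConfig.full_scale()`
restores the full-scale settings.

## Known limitations

* No transmission delays, no Balloon-Windkessel haemodynamics, no regional
  heterogeneity of a_i or f_i; G is the only fitted parameter.
* The SSIM fit inherits the target's realization noise unless targets are
  seed-averaged (see above); fitted G values from single noisy targets are
  comparable within a study but slightly upward-displaced.
* The greedy search is order-dependent and offers no optimality guarantee
  beyond its per-step maximality.
* Synthetic data cannot validate claims about real anatomy; it validates
  calibration and recovery of the inference machinery only.
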