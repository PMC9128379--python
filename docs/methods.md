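# Methods notes

This note documents the models, conventions and numerical choices behind
`dynreconf`, in the spirit of the methods documentation of statsmodels or
msprime: what is computed, under which assumptions, and where the genuinely
open design choices were resolved.

## Window geometry

Windows are specified in seconds and converted to volumes by rounding to the
nearest integer (`w = round(length/TR)`, `s = max(1, round(step/TR))`);
starts advance by `s` while the window fits, giving `floor((N − w)/s) + 1`
windows. At the default acquisition (200 volumes, TR 2.2 s, 60 s/10 s) this
yields 27-volume windows stepping by 5, i.e. 35 windows. No simple rounding
convention reproduces smaller window counts sometimes quoted for comparable
set-ups, which suggests upstream series truncation we cannot reconstruct;
window geometry is therefore fully parameterized and the window *count* is
never treated as a check of correctness. The 44 s variant gives 20-volume
windows (37 windows).

Gaussian-tapered windows weight samples by `exp(−(t − c)²/(2σ²))`, centred at
the window midpoint with σ in TR units (default 3), truncated to the window
and used through the standard weighted mean/covariance formulas; square
windows are the all-ones special case, for which the weighted Pearson
correlation reduces exactly to the ordinary one.

Correlations are clipped to |r| ≤ 1 − 1e−7 before `arctanh` so that
degenerate (perfectly correlated) synthetic inputs stay finite; connectivity
is |arctanh(r)|. The diagonal is stored as NaN and is *excluded* everywhere —
it never dilutes a mean.

## Iterative reassignment

Q-values, tie rules and the stopping rule are deterministic and documented:
argmin Q breaks ties toward the lowest region index; the best target network
is the candidate (currently non-empty, membership counted without the region
itself) with the highest mean connectivity, ties preferring the region's
current network and then the lowest network index. The loop stops when the
same region is selected in two successive iterations. That rule alone does
not provably terminate (two regions can in principle alternate as argmin), so
a hard cap of 100 × n_regions iterations guarantees termination; hitting it
is logged per window, never raised.

Edge cases the Q definition leaves open are resolved as: a region alone in
its subnetwork has C_within = 0 (hence Q = −1 when it has any connectivity,
prioritising its reassignment); a fully disconnected region has Q = 0;
emptied subnetworks remain in the label set but are not valid targets while
empty.

Each window initializes from the canonical partition and is solved
independently (results do not depend on window processing order); a
warm-start mode (initialize from the previous window's solution) exists as an
option. The inner loop maintains per-network connectivity sums incrementally
and is JIT-compiled; results are identical to recomputing Q from scratch each
iteration up to float associativity, and a pure-Python from-scratch reference
implementation in the test suite checks full trajectories on random inputs.

## Metric conventions

Promiscuity is reported as the *fraction* of subnetworks visited
(distinct/7), flexibility, cohesion and disjointedness as fractions of the
W − 1 possible transitions. Affine rescalings of these choices are absorbed
by the HC z-scoring, so group statistics are unaffected; fractions are kept
for interpretability, raw counts are exposed alongside.

A switch is *mutual* when at least one other region switches at the same
transition into the same target subnetwork; the same source is not required
(a stricter same-source-and-target variant is a flag; the decomposition
identity holds under both). Every switch is classified exactly once, and
flexibility is computed *as* cohesion + disjointedness so the decomposition
identity `flexibility = cohesion + disjointedness` is bit-exact; this differs
from `switches/(W − 1)` by at most one ulp (shared-denominator float sums are
not always exact) and is exactly equal whenever the sum is representable, in
particular for every small worked example. The per-pair mutual co-switch
count matrix is available separately for exploratory use and plays no role in
the per-node metrics.

Subnetwork aggregation always groups regions by their *canonical* label, not
the dynamic one. HC z-scoring uses the sample SD (n − 1 denominator; HC
samples are small) per network, metric and time-point; per-time-point
referencing also absorbs scanner/session effects. The global value is the
mean of the seven network z-scores.

## Surrogate null

Phase randomization adds random phases to the positive-frequency Fourier
bins (DC and Nyquist untouched), so each surrogate keeps every region's
amplitude spectrum exactly. The default shares one phase vector across all
regions, which preserves all cross-spectra and hence the full-series static
correlation matrix to numerical precision — the null destroys *dynamics*
while keeping static coupling, which is the comparison of interest. Fully
independent phases per region (a pure-noise null that also destroys static
coupling) are an option; which variant an original MATLAB implementation
used is not documentable from the outside, so both are first-class.
Ensemble runs are seeded by spawning from the configured seed; the default is
50 runs (the `test` CLI profile uses 5 to keep desk runs short), and the
ensemble mean enters downstream analysis as an additional covariate rather
than by subtraction.

## Synthetic cohorts

The generator emulates the target acquisition: 190 regions in 7 subnetworks,
200 volumes at TR 2.2 s, groups HC/CP/MCI/CI, two visits 5 years apart.
Signals are zero-mean unit-variance factor models — correlation
`within_block_corr` (default 0.6) inside a region's current subnetwork,
`between_block_corr` (default 0.1) across — with AR(1) smoothing (default
φ = 0.2), which leaves the contemporaneous correlation structure unchanged.
Latent segments are aligned to window-transition boundaries (the midpoint of
the symmetric difference of consecutive windows) so planted switches are
recoverable by the windowed pipeline. Switch events are planted per
transition at a group-dependent expected rate per region (defaults
HC/CP 0.01, MCI 0.02, CI 0.03 per region per transition); a configurable
fraction (default 0.8) are mutual pairs drawn from one source subnetwork
moving to one target, the rest independent with targets kept distinct within
a transition so the planted mutual/independent labels match the metric
definitions. Every event is recorded as ground truth.

Cognitive domain scores are group-mean-shifted unit normals (defaults
HC 0, CP −0.2, MCI −1.7, CI −2.5 — free parameters chosen to give the
classifier realistic margins, not calibrated to any empirical cohort);
28% of patients are planted as declining, losing 0.6 z/year on 3 random
domains. Age/sex/education are independent of everything by default
(confound-free null); a `confounded` mode ties age to both switch rate and
cognition so covariate-adjustment behaviour can be tested. What the
generator does *not* emulate: haemodynamics, scanner noise spectra,
physiological confounds, spatial structure, or realistic between-subject
heterogeneity of static connectivity — passing recovery tests shows the
pipeline's internal consistency on its own generative model, not performance
on real BOLD data.

## Classification

The MCI rule is read inclusively by default (≥ 2 domains z < −1.5, not
meeting the CI rule), the convention in this literature; the literal band
reading (−2 ≤ z < −1.5) is a flag. The decline rule is implemented literally
as stated operationally — additive practice correction by the mean HC change,
annualized, thresholded at 0.25 z/year on ≥ 2 domains; a classical
SD-normalized RCI denominator is available as a flag since the exact
correction formula behind published uses is not reproducible from text.

## Statistics

Cross-sectional "mixed" models with one observation per subject reduce to
OLS (a random intercept is unidentifiable there) and are fit as such;
longitudinal models are random-intercept MixedLM fits with group × time
interactions, with normal-approximation p-values for fixed-effect contrasts
(the degrees-of-freedom convention of the original SPSS analyses is not
stated anywhere reproducible; exact p-value matching is explicitly not a
goal). Partial correlations residualize both variables on the covariates and
use the t distribution with n − k − 2 degrees of freedom; pingouin serves as
an independent cross-check in the tests. The testing ladder applies
Bonferroni divisors 2/2/7 with gating: cohesion/disjointedness are tested
only when flexibility shows an effect, per-network tests only for metrics
with a global effect, and gated-off families are absent from the output.

## Problem sizes used in the checks

The planted-recovery study in the acceptance suite runs 50 replicates of a
cohort with 70 regions (10 per subnetwork), 200 volumes, 15 subjects per
group (HC/CP/CI; MCI plays no role in the CI-vs-CP contrast under test) and
5 surrogate runs per subject — the package's desk-scale choice that keeps a
full replication under a few minutes on one core while leaving the planted
effect comfortably detectable. Defaults elsewhere remain 190 regions.
Type-I calibration uses 200 null replicates of an 80-subject cohort.

## Known limitations

- The reassignment loop optimizes each region greedily; it is not a global
  modularity optimizer and is not meant to be — it is a constrained
  relabeling of 7 fixed subnetworks.
- Non-convergence (alternating argmin) is handled by the iteration cap, not
  prevented; on realistic inputs convergence is fast, but the log should be
  inspected for pathological matrices.
- Surrogate preservation of static correlation is exact only in the
  common-phase mode and only for the full-series (not windowed) correlation.
- The longitudinal mixed model assumes a compound-symmetry covariance via the
  random intercept; no serial-correlation structures are fitted.
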