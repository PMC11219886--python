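# Methods

`remcpm` implements a complete analysis chain for the question *does
individual variation in REM sleep map onto resting-state functional
connectivity, and does split-night REM deprivation alter the implicated
network?* — together with a synthetic cohort generator so every stage is
testable without access to clinical recordings.

## 1. Hypnograms and sleep parameters

A hypnogram is a sequence of 30-second epochs over the AASM alphabet
{W, N1, N2, N3, R}, anchored at a lights-off clock time.  From it we score

| parameter | definition (this package) |
|---|---|
| TST | minutes in N1/N2/N3/R |
| SL  | minutes from lights-off to the first non-wake epoch |
| WASO | wake minutes strictly between sleep onset and the final sleep epoch |
| SE  | TST / time in bed (lights-off to lights-on) |
| stage % | stage minutes / TST × 100 |
| REM duration / proportion | minutes in R; percent of TST |

Scoring manuals leave several of these operationally open; the choices
above are fixed deliberately: onset is the first epoch of *any* sleep
stage; WASO excludes terminal wake so that TIB = TST + SL + WASO +
terminal wake holds exactly (the conservation law the tests assert); the
SE denominator is the full recording span (a sleep-period-time variant
would only rescale SE, not change any ordering).  All-wake recordings
report TST = 0 with percentages as missing, never as zeros.  Splitting a
night at a clock time snaps to the nearest epoch boundary and is exact:
concatenating the halves reproduces the record and every duration metric
is additive across the split.

## 2. Connectomes

Connectivity is the Pearson correlation matrix of regional time series,
Fisher-z transformed (`z = atanh(r)`), symmetric with a zero diagonal.
Correlations are clipped to |r| ≤ 0.999999 before `atanh` so degenerate
synthetic inputs stay finite.  The canonical edge vector is the upper
triangle (i < j) in row-major order — 25 651 edges for the default
227-node parcellation.  Nodes carry one of ten large-scale network labels
(DMN, VIS, FPN, DAN, VAN, SAN, CON, AUD, SMN, SUB); the parcellation is
consumed purely as a node→network table, so any node count with these
labels works.  An edge inherits the unordered pair of its endpoint
labels: 55 possible pairs (10 within-network, 45 between).

## 3. Connectome-based predictive modeling

CPM predicts a behavior (REM duration, minutes) from edge strengths under
leave-one-out cross-validation:

1. **Selection.** On each training fold, every edge is correlated with
   behavior; edges with two-sided p < α (default α = 0.01, a common
   protocol choice — exposed in `CPMConfig.selection_alpha`) enter the
   positive (r > 0) or negative (r < 0) mask.
2. **Features.** Per subject, the Fisher-z weights are summed over each
   mask — the positive- and negative-strength features.
3. **Models.** Ordinary least squares on the training subjects: one model
   per tail plus a combined two-feature model.  The positive model is the
   headline output.  A fold whose training mask is empty predicts the
   training behavior mean (logged) so weak-signal data never aborts.
4. **Score and significance.** `r_obs` = Pearson r between the n
   cross-validated predictions and the observed behavior.  Significance
   is a one-tailed permutation test: behavior is permuted, the *entire*
   pipeline — per-fold selection included — is rerun, and
   p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1) with n_perm = 1000 by
   default (floor p ≈ 0.001).

Implementation note: per-fold correlations use exact leave-one-out
downdates of the full cross-products, algebraically identical to refitting
each fold from scratch (the tests verify bitwise-boolean mask equality and
1e-9 prediction agreement against a brute-force oracle) but ~two orders of
magnitude faster, which is what makes full-pipeline permutation testing
affordable.

**Null behavior.** Cross-validated r is *negatively* biased under the
null: the left-out training mean anti-correlates with the held-out value,
so null r concentrates below zero (measured mean ≈ −0.3 at n = 40).  This
is why significance comes from the permutation distribution rather than a
parametric test on r.  When edge selection almost never fires, permuted
replicates produce exactly tied r values and the add-one estimator becomes
conservative (valid, but not uniform); with any realistic selection rate
the permutation p is uniform under the null, as the calibration tests
check.

**Consensus connectome.** An edge enters the consensus mask when selected
with the same sign in ≥ `consensus_fraction` of folds (default 1.0, the
intersection — the strictest, most reproducible choice; 0⁺ recovers the
union).

## 4. Characterization

The consensus mask is profiled at three levels.  *Network pairs*: edge
counts and normalized shares over all 55 pairs (zeros included), and a
"contribution" per occupied pair — the absolute Pearson correlation
between behavior and the per-subject sum of the pair's consensus-edge
strengths.  *Large-scale networks*: endpoint shares (each within-network
edge contributes both endpoints, so shares sum to one over 2×edges) and
incident-edge contributions.  *Regions*: consensus degree and incident
contribution, plus the degree–contribution similarity (Pearson over all
nodes).  "Normalized" always means divide-by-total (each distribution
sums to one) and reported variances are population variances of the
normalized values; both conventions matter because the absolute size of
such variances is meaningless without them.  Pairs with zero consensus
edges are excluded from the contribution normalization but kept as zeros
in the edge-share distribution.  Contributions use |r| so positive- and
negative-tail edges are comparable.

## 5. Group comparison

Per subject, the strength of a network pair is the **mean** Fisher-z over
the pair's consensus edges (mean, not sum, so pairs with different edge
counts are comparable).  Pairs with ≥ 1 consensus edge are compared
across the three schedule groups with one-way fixed-effects ANOVA,
corrected with BH-FDR at q = 0.05 (Bonferroni available).  Pairs
surviving correction (gatekeeping) get Welch post-hoc contrasts — with
both Cohen's d conventions reported, pooled-SD and t/√N, because the
applied literature mixes them — and a per-edge ANOVA follow-up corrected
within the pair.  `welch_t_from_summary` implements the same contrast
from published mean ± SD tables; it reproduces a printed t of 6.80 for
the REM-percentage row (24.41 ± 6.56, n = 41 vs 15.18 ± 5.31, n = 36) to
within 0.3%.

**A calibration caveat.**  When the compared mask is *selected* on a
behavior that is itself group-structured (REM duration differs strongly
between schedule groups), every retained pair inherits group differences
by construction — selected edges correlate with behavior, behavior
correlates with group.  Group-difference false-positive rates are
therefore only well defined for a mask fixed independently of behavior;
the calibration experiments in the test suite use the planted mask with
the behavior coupling switched off, and real-data users should interpret
select-then-compare group tests as descriptive, not confirmatory.

## 6. Synthetic cohorts

The generator emulates the split-night study design:

* **Schedules**: FS in bed 23:00–08:00 (1080 epochs), early-night
  deprivation asleep 03:00–07:30, late-night deprivation asleep
  23:00–03:30 (540 epochs each).
* **Hypnograms**: sleep-onset latency ~ N(8, 4²) min clipped to [1, 25];
  ~90-minute cycles (N(180, 15²) epochs clipped to [150, 210]) composed
  N1→N2→N3→N2→R; brief awakenings inside cycles and a short terminal
  wake.  The REM share of a cycle follows a circadian ramp anchored to
  clock time since 23:00 — 10% early rising to 35% by the sixth cycle
  hour — and slow-wave share declines complementarily.  Anchoring to
  clock rather than to time-since-onset is what makes the early-night
  deprivation group (who sleep the REM-rich late hours) the most
  REM-preserved group, as the split-night design intends.  No claim of
  physiological fidelity beyond these constraints: no spindles, arousals
  microstructure, or EEG waveforms.
* **Behavior**: per-group REM-duration laws, defaults FS 102.2 ± 28.6,
  early-deprivation 61.3 ± 16.5, late-deprivation 38.2 ± 13.4 minutes —
  back-computed from group TST × REM% summaries and therefore
  *approximations*, since only percentages plus TST are published at
  group level.  Each drawn duration is reconciled with the subject's
  hypnogram by relabeling sleep epochs at REM-run boundaries until the
  scored REM duration matches the draw to within one epoch (TST is
  untouched, so proportion stays consistent).
* **Connectivity**: edge z = baseline + planted signal + noise.  The
  baseline is atanh(0.3) within networks and atanh(0.1) between; 40
  planted edges (14 DMN-DMN, 10 DMN-VIS, 8 VIS-SUB, 8 CON-CON, mirroring
  the composition such a REM connectome is expected to have) add
  β × standardized REM duration; independent N(0, 0.1²) noise lands on
  every edge; `dmn_group_delta` optionally depresses the planted DMN-DMN
  edges in the late-deprivation group.  The linear-Gaussian coupling is
  chosen to match CPM's linear-regression assumption, so parameter
  recovery is a fair test of the machinery, not of model robustness.
* **Calibration helper**: `planted_beta_for_r2` solves the closed form
  β = σ√(R²/(1−R²)) (per-edge) or β = σ√(R²/((1−R²)·E)) (for the summed
  feature).  Note the two differ by √E: with 40 equal-β planted edges and
  independent noise, a summed-feature R² of 0.10 corresponds to a
  per-edge r of only ≈ 0.053, *below* the p < 0.01 selection threshold at
  n ≈ 110 (r_crit ≈ 0.245) — such a signal is invisible to selection-based
  CPM even though the oracle feature predicts.  The end-to-end recovery
  experiments therefore calibrate at per-edge R² = 0.10 (r ≈ 0.316), the
  weakest per-edge signal the selection step can reliably retain.
* **Time series**: `realize_timeseries` back-transforms a z-matrix to a
  correlation matrix (eigenvalue-clipped to the nearest PSD correlation
  when needed, logged) and draws zero-mean multivariate normal series —
  enough to exercise the FC stage end to end, with no hemodynamics or
  autocorrelation.

Everything is reproducible from the config seed; identical config + seed
yields byte-identical artifacts.

What passing these tests shows — and does not.  The synthetic data match
the analysis assumptions by construction (linear coupling, Gaussian edge
noise, exchangeable subjects).  Recovery and calibration results
therefore validate the *implementation*, not the robustness of CPM to
motion artifacts, non-Gaussian noise, site effects, or hypnogram scoring
disagreement, none of which are simulated.

## 7. Problem sizes and numerical choices

Simulation-heavy checks run at sizes chosen once for a single-CPU
workflow: CPM experiments use a 46-node / 1035-edge parcellation (the
default 227-node split scaled down, preserving all ten networks) with the
110-subject group structure (33/41/36); prediction-recovery ensembles use
20 seeds; the type-I calibration uses 200 replicate cohorts × 199
permutations; the group-difference power check runs at the full 227-node
scale over 50 seeds.  Other fixed choices: correlation clip 0.999999;
matrix symmetrization tolerance 1e-6 (larger asymmetries are rejected as
data errors); edge-selection threshold implemented as the exact |r|
equivalent of the two-sided t-test p < α; degenerate ANOVA (all values
identical) reported as F = 0, p = 1; constant prediction vectors reported
as r = 0 rather than NaN; permutation p floored at 1/(n_perm+1).

## 8. Known limitations

* The hypnogram model is a constraint-satisfying caricature of sleep
  architecture; its REM ramp parameters were set to reproduce the
  early/late-night REM asymmetry, nothing more.
* Group-level REM duration defaults are back-computed approximations (see
  §6).
* One published figure caption gives the connectivity matrix as
  "227×277"; the methods text says 227 regions throughout, and this
  package treats the caption as a typo for 227×227.
* No covariate regression (age/sex/motion) — the hook in `CPMConfig`
  is a documented no-op.
* Only LOOCV is implemented; k-fold variants are out of scope.
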