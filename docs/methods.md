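# Methods

`intseg` quantifies how altered states of consciousness reorganize large-scale
brain activity along an integration–segregation axis, using three
complementary metrics computed from parcellated BOLD time series at three
nested spatial levels, and aggregates the resulting paired effect sizes into a
data-driven ordering of states.  This note documents the models, the numerical
choices, and what the synthetic cohorts do and do not establish.

## Analysis model

**Inputs.** Each recording is a frames × ROIs matrix of parcel-averaged BOLD
signal, standardized per ROI (zero mean, unit variance).  A partition assigns
every ROI to one of seven canonical networks (VIS, SMN, DAN, VAN, LIM, FPN,
DMN); six of these form the unimodal (VIS, SMN), attention (DAN, VAN) and
transmodal (FPN, DMN) hierarchy tiers, with the limbic network unassigned and
therefore excluded from hierarchy-level quantities only.

**Functional connectivity (FC).** Pearson correlation between all ROI pairs.
Summaries: whole-brain mean over unique off-diagonal pairs; 7 × 7 network
block-mean matrix; six hierarchy block means; global within-/between-network
values as unweighted means of the 7 diagonal and 21 off-diagonal block means.
Raw correlations are averaged (no Fisher transform) and negative values are
retained.  A pair-pooled global convention is available
(`fc_convention: pooled`) because the block-mean vs pair-pooled choice is a
genuine convention ambiguity; block means are the default for consistency
with how the efficiency and complexity levels aggregate.

**Topological integration.** Weighted global efficiency
Eg = (1/(N(N−1))) Σ_{i≠j} 1/d(i,j), with shortest paths d(i,j) computed by
Floyd–Warshall after the logarithmic weight-to-distance transform
len(w) = −log w.  Only positive weights form edges; w ≥ 1 is clipped to
1 − 1e−10; unreachable pairs contribute 0 to the average (1/∞ = 0) and are
never dropped from the denominator, keeping Eg comparable across graphs of
equal size.  Every reported value is normalized, Eg_norm = Eg / Eg_rand,
where Eg_rand is the mean efficiency of n_null surrogate graphs whose
off-diagonal weights are permuted as a multiset (weight distribution
preserved; degree sequence deliberately not).  Between-set efficiency builds
the joint submatrix of both node sets, lets shortest paths relay through
either set, and averages inverse path lengths over cross-set pairs only;
within-set pairs are excluded from numerator and denominator.  The null
shuffle happens on the submatrix before the distance transform.  `n_null`
defaults to 100 in the pipeline configuration (Monte-Carlo SE of Eg_rand
well under 1 % on pilot graphs); the replication-scale studies in the test
suite and acceptance script use n_null = 10, which leaves the group-level
contrasts unchanged while keeping whole-study reruns fast.  The
Floyd–Warshall closure runs through a small compiled kernel (numba) and is
checked against an independent per-source Dijkstra implementation in the
test suite.

**Interaction complexity.** The recording is segmented into non-overlapping
windows of 5 frames (remainder dropped).  For ROI sets S1, S2 with windowed
series X1, X2 (frames × ROIs), the interaction matrix M = X1ᵀX2 is centered
by its scalar global mean and decomposed by SVD.  Complexity is the
normalized singular-spectrum entropy

    C = −(1/log₂K) Σ_k p_k log₂ p_k,   p_k = s_k / Σ_j s_j,   K = min(|S1|, |S2|)

so C ∈ [0, 1]: low C = few dominant interaction modes, high C = many
comparable modes.  All K singular values of the economy decomposition enter
the normalization; zeros contribute nothing to the sum but keep the scale
fixed, so C is comparable across set sizes and is not inflated by rank
truncation.  Because a window holds only 5 frames, at most 5 (+1 after
centering) singular values are nonzero.  Windows whose centered M is exactly
zero have undefined C and are skipped; per-recording complexity is the mean
over valid windows.  Windowed series are not re-standardized within windows —
the whole-run standardization is relied upon, and centering is applied to M
only.

**Paired effects.** Every altered recording is compared with the same
subject's baseline.  Cohen's d for paired samples uses the d_z convention,
d = mean(diff)/sd(diff) with the n−1 sample SD; t = d√n with n−1 degrees of
freedom, two-sided; se(d) = √(1/n + d²/2n) (the standard large-sample
approximation).  Benjamini–Hochberg FDR is applied within each
metric × level family by default (one family per results panel); `fdr_family`
can widen the family to a whole metric or to all rows.  Zero-variance
difference vectors yield an undefined-effect flag (NaN row), not a crash.

**Ordering.** For each of the 27 analysis × metric pairs (3 metrics × 9
global/hierarchy analyses) the nine states are ranked by signed d (rank 1 =
most negative; average ranks on ties).  The composite rank is the mean over
all 27 pairs with equal weight.  Kendall's tau-b (tie-corrected) measures
each pair's agreement with the composite.  Network-level d values form an
84 × 9 feature matrix (3 metrics × 28 upper-triangular network pairs,
diagonal included, metric-major order) that is decomposed by *uncentered*
PCA — zero means "no effect" and is a meaningful origin, so the raw matrix
is decomposed by SVD with states as observations.  Explained variance is
s_k²/Σs², i.e. a fraction of the total sum of squares rather than of
variance about a mean; this differs from the centered convention and is the
reason PC1 fractions here can exceed what a centered PCA would report.  Each
component's sign is fixed by making its largest-magnitude loading positive;
the orientation of a principal axis is otherwise arbitrary.

## Synthetic cohorts

The generator emulates the paired multi-dataset study design: nine altered
states (four psychedelic agents; two non-REM sleep stages; three propofol
effect-site concentrations), each with its own cohort of subjects, every
subject contributing a baseline and one altered recording.  Defaults:
70 ROIs in seven 10-ROI networks, 150 frames, 20 subjects per state,
baseline block correlations w = 0.50 within and b = 0.15 between networks,
and a per-subject scalar coupling effect (SD 0.03, truncated at ±2.5 SD to
keep covariances positive definite) shared across that subject's conditions
— which is what makes the paired contrasts sharper than unpaired ones.

State effects have two ingredients:

1. **Coupling shifts.**  Signed deltas on the within- and between-network
   block correlations: psychedelics raise between-network coupling and lower
   within-network coupling (integration up, segregation down); sleep and
   sedation lower both, with the between-network drop proportionally larger
   and all magnitudes dose-graded (N1 < N2 < PPF1.9 < PPF2.4 < PPF2.7).
   The block-constant structure (one w, one b) is the simplest covariance
   that reproduces the headline directions; network-pair-specific deltas are
   a configuration extension point, not a default.
2. **Temporal smoothness.**  A per-state AR(1) coefficient on the latent
   dynamics (baseline 0.30; psychedelics 0.13–0.27; sleep/sedation
   0.34–0.62).  This carries the dynamical component of the state effects:
   pilot simulations showed that with i.i.d. frames the windowed complexity
   statistic is a function of the correlation matrix alone and *rises* when
   coupling falls, so a purely static model cannot reproduce reduced
   complexity alongside reduced connectivity.  Slower dynamics reduce the
   effective number of independent frames per 5-frame window, concentrating
   the interaction spectrum and lowering C — the physiologically expected
   slowing under sedation and sleep, and the reverse under psychedelics.

Positive definiteness of each state covariance is verified by Cholesky
factorization with a diagonal jitter fallback capped at 1e−6; larger jitter
would silently distort the target correlations, so beyond the cap the
generator fails loudly.  `noise_scale` adds white observation noise of
variance noise_scale² − 1 on top of the unit-variance signal (default 1 =
none); in the infinite-noise limit all correlations vanish.  Because every
series is standardized per ROI, noise acts through the realized correlation
structure only.

All randomness flows through label-addressed streams derived from the master
seed (state/subject/condition labels hashed into child seeds), so cohorts
are bit-reproducible and adding a state or stage never perturbs another's
draws.

**What the synthetic cohorts do not emulate:** hemodynamic response shapes,
scanner and physiological noise spectra, motion artifacts, heterogeneous TRs
and scan durations across datasets, region-specific coupling topography, and
any voxel-level structure.  Passing recovery tests therefore shows that the
pipeline's statistics respond correctly to controlled integration–
segregation and dynamical-tempo shifts of known direction and grading — not
that real fMRI effect sizes will match.

## Study sizes used in tests and the acceptance script

Unit tests run on 14–28-ROI cohorts.  The calibration study uses 500
zero-delta cohorts (70 ROIs, 100 frames, 20 subjects) and checks that the
raw paired test rejects at the nominal 5 % within binomial 99 % bounds.  The
recovery study uses 20 replicate nine-state cohorts at the default study
conditions with n_null = 10; it requires the between-network effect signs,
the composite-rank class placement, and the no-overlap PC1 separation in at
least 95 % of replicates, and requires the PC1 ordering to match the
composite ordering (up to axis orientation) on the replicate-averaged effect
table — single replicates can swap adjacent same-class doses in one
representation but not the other, which is rank noise, not signal.  The
acceptance script reruns one full default cohort plus a 300-replicate
calibration in a few minutes.

## Known limitations

* The efficiency null uses weight-multiset permutation only; degree-
  preserving nulls are out of scope, so Eg_norm conflates degree and weight
  topology by design.
* Within-network efficiency on very small node sets is degenerate (a 2-node
  set's null equals the data exactly; 3-node triangles are permutation-
  isomorphic), so within-network efficiency requires networks of ≥ 4 ROIs.
* Between-network efficiency saturates when between-coupling falls below the
  edge-estimation noise floor: shortest cross-set paths then route through
  within-network edges and the statistic stops responding to further
  coupling reductions.
* With tied effect sizes Kendall's tau-b is undefined for constant rankings;
  such pairs are flagged NaN rather than imputed.
* Under the null, the raw paired test is slightly anticonservative on longer
  synthetic recordings (empirically ~0.06 at α = 0.05 with 100-frame
  cohorts, calibrated at 60 frames): subjects with larger coupling random
  effects also have larger FC-estimation variance, and the resulting
  scale-mixture of per-subject differences is heavier-tailed than normal.
  Real cohorts share this property whenever baseline coupling varies across
  subjects; the FDR-corrected inferences the pipeline reports are based on
  p-values that inherit it.
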