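# Methods

`connet` benchmarks pre-processing choices for interictal intracranial-EEG
(iEEG) functional connectivity: two re-referencing schemes crossed with 24
connectivity measures, evaluated by pipeline similarity, robustness to
electrode subsampling, a common-reference spurious-correlation simulation,
and seizure-onset-zone (SOZ) lateralization. This note records the models,
estimators, parameter choices and their rationale, what the synthetic cohort
does and does not emulate, and known limitations.

## Signal ingestion and cleaning

Recordings are channels × samples matrices in microvolts with per-contact
metadata (electrode name, contact index, hemisphere, tissue class). Channel
labels are parsed as maximal non-numeric prefix + trailing integer
(`LA01 → (LA, 1)`), with whitespace/hyphen separators stripped; this covers
depth/grid naming without a site dictionary. Contacts localized to
cerebrospinal fluid are excluded up front.

Power-line removal uses a 4th-order IIR notch at 60 Hz, realized as a
2nd-order Butterworth band-stop (two second-order sections, 2 Hz wide),
applied forward–backward. Zero-phase filtering matters here because a phase
shift that differed across channels would bias the phase-based connectivity
measures downstream. Band-pass filters are 4th-order Butterworth,
forward–backward. A band whose upper edge reaches Nyquist (e.g. the ripple
band on a 256 Hz recording) is clipped to 0.9 × Nyquist with a warning
rather than rejected.

Interictal epochs (default five × 2 min) are drawn uniformly at random
without overlap from a 13:00–15:00 clock window, rejection-sampled over
feasible placements and reproducible from a mandatory seed. Artifact
channels are flagged by two configurable rules evaluated over all epochs
pooled: absolute amplitude above `amp_thresh_uv` (default 500 µV) in more
than 1% of samples, or 60 Hz-band power above `line_ratio_thresh` (default
0.5) of broadband power. The defaults are explicit configuration, not
claims about any particular clinical dataset.

## Montages

*Common average (CAR)*: the per-sample mean over retained grey/white
channels is subtracted; output channels are the retained set and their mean
is exactly zero at every sample. *Bipolar (BR)*: within each electrode,
retained contacts are paired with the next retained contact when the index
gap is at most `max_skip + 1` (default `max_skip = 1`, i.e. one missing
contact may be bridged: LA01–LA03 is allowed when LA02 is rejected). Pairs
never cross electrodes. Polarity is lower index minus higher index; the sign
convention only matters for signed Pearson and is fixed for
reproducibility. A derived channel inherits hemisphere and tissue from its
lower-numbered (anchor) parent. Both montages cancel any signal added
identically to all channels, which is the machine-reference contamination
they exist to remove.

## Connectivity measures

All measures are computed per channel pair inside non-overlapping 2-s
windows (a 2-min epoch yields 60), averaged over windows, then averaged
element-wise over epochs. Six families:

- **Pearson** (signed) and **squared Pearson**: per-window correlation,
  averaged; squared Pearson averages the per-window r².
- **Cross-correlation**: maximum over lags |τ| ≤ 200 ms of the absolute
  normalized cross-correlation (demeaned signals, divided by the overlap
  length and the product of full-window standard deviations). Values are
  clipped to [0, 1]; the overlap normalization can marginally exceed 1 on
  strongly nonstationary windows.
- **Magnitude-squared coherence**: Hann-tapered periodograms per 2-s
  window; auto-/cross-spectra averaged across all windows of the epoch
  before the ratio |Sxy|²/(Sxx·Syy) is formed per frequency bin and averaged
  over the bins inside the band. Averaging spectra first is essential: a
  single-segment coherence is identically 1. This is the one place the
  estimator is genuinely underdetermined by a "2-s windows" prescription,
  and the choice is exposed (the simulation module uses shorter pooled
  segments, below).
- **Phase locking value (PLV)**: band-pass, analytic phase, per-window
  |mean exp(iΔφ)|, averaged over windows.
- **Relative entropy (RE)**: per window and pair, both band-passed signals
  are histogrammed into 10 equal-width bins spanning the pooled min–max of
  the pair, counts get add-one-half smoothing, and the Kullback–Leibler
  divergence Σp·log(p/q) (natural log) is evaluated in both directions with
  the larger value kept (RE is asymmetric). Higher RE means *lower*
  functional connectivity. Bin count, smoothing and the positivity
  transforms (|w| and 1/(1+w)) are configuration.

Band-limited measures (coherence, PLV, RE) are evaluated over seven
canonical bands — delta 0.5–4, theta 4–8, alpha 8–12, beta 12–30, gamma
30–80, ripple 80–250, broadband 0.5–250 Hz — giving 3 + 3×7 = 24 measures
and 48 (montage × measure) pipelines.

One deliberate implementation choice: for PLV and RE the band-pass (and the
Hilbert transform for PLV) is applied to the whole epoch before windowing.
Filtering 2-s chunks individually leaves the low bands dominated by filter
edge transients (a 0.5 Hz delta edge barely completes a cycle in one
window); filtering the continuous epoch is the standard practice and leaves
the per-window statistics unchanged in definition. Per-window estimator
nulls follow from this definition: e.g. the alpha-band PLV of independent
noise sits near √(π/4m) ≈ 0.31 for m ≈ 8 independent phase samples per 2-s
window, independent of how many windows are averaged.

## Pipeline similarity, clustering, stability, embedding

Each network is flattened to its upper-triangle edge vector in canonical
node order. Comparing across montages requires aligning different node
sets: every bipolar derivative is identified with its anchor contact
("LA01-LA02" ↔ "LA01") and cross-montage comparisons are restricted to the
common contact set, with unmatched edges dropped symmetrically. This
anchor-contact identification is the largest interpretive decision in the
module and is isolated behind the `node_map` argument so alternatives can
be swapped in.

Pipeline similarity is the Pearson correlation between edge vectors,
computed per patient and averaged element-wise across patients (plain mean,
no Fisher z). Clustering is agglomerative with average linkage on distance
1 − r, cut at k = 3. Cluster stability resamples patients with replacement,
re-averages, re-clusters, and records the per-reference-cluster maximum
Jaccard overlap (mean over 1000 resamples); cluster-number selection sweeps
candidate k with 20 resamples. Whether the original stability analysis
resampled patients or edges is not determinable from its description;
patient resampling is this package's documented choice. Two-dimensional
visualization uses t-SNE (perplexity 10) on 1 − r; note t-SNE's point-wise
repulsion keeps even duplicate pipelines a small finite distance apart, so
"duplicates coincide" is asserted as nearest-neighbourhood, not zero
distance.

## Subsampling reliability

For a network with n nodes, a fraction f ∈ {0.2, 0.4, 0.6, 0.8} of channels
is removed uniformly at random (1000 iterations) and node strength — the
sum of absolute edge weights to the other retained nodes — is recomputed.
Absolute weights keep signed Pearson and RE networks on a comparable scale.
Reliability is R = σ_T/(σ_T + σ_E): σ_E is the variance of a contact's
strength across the iterations in which it is retained, averaged over
contacts; σ_T is the variance across retained contacts, averaged over
iterations. Because channels are removed outright, a removed channel simply
has no strength that iteration; conditioning on a fixed retained core is
available via configuration. An `exhaustive=True` mode replaces sampling by
full subset enumeration; there σ_E is the exact population variance over
subsets (ddof 0) while sampling estimates the same quantity unbiasedly
(ddof 1). Degenerate inputs (all-equal weights) make both components vanish
and R is reported as undefined with a warning.

Group comparisons: montages are compared by paired Wilcoxon signed-rank
tests on per-patient scheme means; measures and bands by Friedman tests on
per-patient group means with post hoc pairwise rank tests under a Šidák
correction (z = Δmean-rank / √(k(k+1)/6n), two-sided normal, adjusted
1−(1−p)^m). No installed package provides Friedman post hocs, so the
post hoc is implemented directly.

## Common-reference spurious-correlation simulation

Eight contacts of one depth electrode are simulated for 100 trials of 2 s
at 512 Hz: latent unit-variance Gaussian white sources (independent, or
coloured to corr(sᵢ,sⱼ) = exp(−|i−j|) via the Cholesky factor in correlated
mode) plus a single shared white reference source of variance 1/3, added
identically to every channel. Coherence is estimated from Hann 0.25-s
segments with 50% overlap pooled across all trials, averaged over
0.5–250 Hz, as *magnitude* coherence (√MSC; a `squared` flag restores MSC).
Magnitude coherence of white signals equals |ρ|, which is what puts the
analytic anchors on the right scale:

- machine reference: every pair shares only the reference, ρ = v/(1+v)
  = 0.25 at v = 1/3 (the calibrated variance ratio);
- common average: the reference cancels and mean subtraction of n i.i.d.
  channels induces ρ = −1/(n−1) = −0.143;
- bipolar, derivatives sharing a parent: corr(s₂−s₁, s₃−s₂) = −1/2;
- bipolar, derivatives sharing no parent: true coherence zero, so the
  measurement is the estimator's zero-coherence floor, ≈ √(π/4K_eff) ≈ 0.02–
  0.03 for ~1500 pooled (50% overlapping) segments, and shrinks as more
  segments are pooled.

The 0.25-s segment length and overlap are configuration; they set the floor.
Paired t-tests between schemes are computed within adjacency strata, with
unequal-length strata truncated to the common canonical order.

## Synthetic cohorts and planted ground truth

The generator produces seed-reproducible bilateral SEEG-like patients (up
to 3 electrodes × 12 contacts per hemisphere, mirrored LA↔RA naming) as a
sum of variance-budgeted components:

1. pink (1/f) background and optional band-limited oscillations, both
   coloured across each electrode's contacts by a spatial correlation
   profile — exponential exp(−λd) (AR(1)-like) or Gaussian exp(−λd²)
   (smooth spread). With other components off, the adjacent-contact
   correlation equals the profile by construction;
2. a widely shared source whose gain varies smoothly along each electrode
   (volume-conduction-like): retained by CAR, cancelled by bipolar
   derivation;
3. "network" sources coupling random contact patches on two electrodes with
   equal member gains: genuine positive cross-electrode edges for CAR,
   invisible to bipolar (except at patch boundaries), and a near-uniform
   negative common-average bias;
4. per-electrode rhythms with a linear gain gradient along the shaft
   (dipolar-sheet-like): every bipolar derivative on the electrode shares
   the same slope × rhythm term, keeping derivative correlations
   predominantly positive;
5. static per-electrode and per-channel lognormal amplitude gains and a
   per-2-s-block gain jitter. Static gains are exactly invisible to
   correlation-, coherence- and phase-based measures but drive relative
   entropy; an alternating ±δ log-gain offset on SOZ-side channels
   (δ = `channel_gain_sigma · (re_effect − 1)`) plants an RE-specific
   laterality whose bounded magnitude keeps the realized effect size stable
   across cohort draws;
6. a common reference source added identically to all channels (cancelled
   exactly by both montages — gains are applied to the neural part only);
7. spike-like transients (70 ms biphasic + 300 ms slow wave) at a Poisson
   rate, and artifact channels (strong line noise + amplitude bursts) at a
   configurable fraction.

Two named constructions freeze the study conditions for the evaluation
benchmarks. `similarity_benchmark_config` (3 patients, 3×4 mirrored
montage, five 40-s epochs at 256 Hz, Gaussian profile λ=0.1, network 0.45 /
gradient 0.25 / pink 0.3, electrode gains σ=1.0) is built so that RE
networks carry their own montage-independent structure while all other
measures split by montage; k=3 clustering of the cohort-mean similarity
matrix then recovers {RE}/{CAR}/{bipolar}. `lateralization_benchmark_config`
(20 patients, 2×4 montage, five 20-s epochs, `re_effect = 2.6`, i.e.
δ = 0.24) plants the SOZ-side amplitude offset at a realized paired Cohen's
d of roughly 1–1.7 on the common-average RE pipelines; with `re_effect = 1`
it is an exact null. Design notes that came out of building these: an
exponential (AR(1)) spatial profile forces adjacent bipolar derivatives
into negative correlation, which strands signed Pearson away from the
unsigned measures; window-wise gain jitter biases pooled coherence downward
(Cauchy–Schwarz), so it is unsuitable as an RE-only laterality mechanism —
static gains are; and large static offsets (δ ≳ 0.35) leak into bipolar
networks, whose derivative signals mix parent gains, so δ is kept moderate.

What the generator does not emulate: biophysical seizure dynamics, sleep
staging, realistic spike morphology diversity, non-stationary artifacts,
volume conduction geometry beyond gain profiles, and heterogeneous montage
sizes across patients. Passing the recovery benchmarks therefore shows that
the estimators and statistics behave correctly on signals with the planted
covariance/amplitude structure at clinical channel counts — not that any
particular clinical effect size will replicate.

## Problem sizes and runtime

The evaluation benchmarks run at reduced problem sizes chosen to keep a
full test cycle on one CPU core in the tens of minutes: 24-channel montages
and 100–200 s of data per synthetic patient (vs. up to 72 channels and 10
min in a full clinical workflow), 1000 subsampling iterations, 20 seeds for
partition recovery, 5 planted + 3 null cohorts for lateralization. The
spurious-correlation simulation runs at its full stated size (8 × 100 × 2 s,
ten seeds) in seconds.

## Known limitations

- Coherence estimation pools spectra across an epoch's windows; per-window
  "coherence" is undefined, so the window count sets the zero-coherence
  floor and short epochs inflate it.
- The per-window PLV null floor is band-dependent (≈0.31 in alpha) and does
  not shrink with more windows; between-pipeline comparisons are unaffected
  but absolute PLV values near the floor are not interpretable as coupling.
- RE with pooled-range equal-width binning is invariant to a common scaling
  of both signals but not to separate scalings; that asymmetry is exactly
  what makes it sensitive to amplitude-distribution differences.
- Cross-montage similarity via anchor contacts discards bipolar edges whose
  anchor has no CAR counterpart; alternative alignments can be injected via
  `node_map`.
- EDF input is supported (via MNE); the array-container (.npy + CSV + JSON)
  is the native interchange format, and EDF export is not provided.
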