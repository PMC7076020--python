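# Methods

## The generative model

The synthetic-study generator emulates a probe-sampled audiovisual
attention experiment. Its defaults are the study conditions throughout the
package: 23 controls (CTRL) and 22 patients (SZQ); four 300-s videos per
participant, two with synchronized audio/image tracks and two mismatched;
probe gaps uniform on [50, 70] s (so a 300-s video yields 4–5 probes and a
participant 16–20); answers drawn from a multinomial over (Audio, Image,
Full, MW) per (group, synchrony); and 50-s pre-probe EEG segments at
500 Hz over the 31-electrode 10–20 montage.

EEG segments are built channel-wise from exact fractional Brownian motion
(Davies–Harte circulant embedding of the fGn covariance, not filtered
noise), standardized to unit variance, plus white observation noise. The
Hurst exponent of each (group, synchrony, answer, area) cell fixes the
segment's theoretical fractal dimension at 2 − H, which is the ground
truth all complexity tests are checked against.

Default cell table: baseline H of 0.45 in frontal areas, 0.50 in
central/temporal, 0.55 in occipito-parietal (complexity decreasing front
to back), with mind-wandering segments 0.03 lower in H (0.03 higher in
FD) **only** for controls under synchrony and only outside the
occipito-parietal areas. Default answer probabilities make controls
Full-attention-dominant (0.64 under synchrony) and patients MW-elevated
(0.42–0.48), with desynchronization raising MW in both groups. These
defaults encode the qualitative pattern of the study design this package
models; they are illustrative conditions, not estimates of any real
sample. Cognitive scores use standardized group deficits of the magnitude
studies of this design report (t around 2.4–3.9 at n = 45, d ≈ 0.36–1.14);
omission/commission errors are negative-binomial so that the normality
screen genuinely routes them to the median test. PANSS subscales are drawn
at clinically typical subscale means/SDs (14/6.08, 18.85/7.60, 32.41/9.33).

Randomness is hierarchical (`SeedSequence([root, stream, participant,
...])`): adding a participant never perturbs another participant's data,
and identical configurations reproduce every CSV bit for bit.

### Two levels of synthesis

Signal-level synthesis (45 participants × ~18 segments × 31 channels ×
25 000 samples) costs minutes per study, so simulation studies of the
*statistics* (parameter recovery, type-I calibration, 100–200 replicates)
use a record-level shortcut, `simulate_hfd_records`: one draw per
(response, area) of `hfd = (2 − H_cell) + b_participant + ε`, with
`b ~ N(0, 0.05²)` and `ε ~ N(0, 0.05²)`. The shortcut shares its mean
structure with the signal path through the FD = 2 − H identity; the signal
path itself (fBm → sliding Higuchi → area averaging) is validated
separately at small n and in the `analysis/` scripts at full scale. What
the record-level tests therefore demonstrate is the correctness and
calibration of the statistical machinery under the declared mixed model —
not that real EEG complexity follows that model.

## Higuchi fractal dimension

For a series x(1..N) and lag k, offsets m = 1..k:

    L_m(k) = [ Σ_{i=1}^{⌊(N−m)/k⌋} |x(m+ik) − x(m+(i−1)k)| ] · (N−1) / (⌊(N−m)/k⌋·k) / k

and L(k) is the mean over offsets. HFD is the negative OLS slope of
ln L(k) on ln k over k = 1..k_max. Choices:

- **k_max = 10** (configurable). The common regime for ~1000-sample
  windows is 8–16; results are always reported with the k_max used.
- All k in 1..k_max enter the fit unweighted (no geometric subsampling).
- Offsets are 1-based as in the original formulation; arrays are 0-based
  internally with an explicit conversion.
- Segment-level estimates use sliding windows of 2000 ms with 90 %
  overlap; the step is `round(window·(1−overlap))` (round-half-to-even),
  the trailing partial window is discarded, and window estimates are
  averaged arithmetically. A 50-s segment at 500 Hz yields 241 windows.
- Degenerate inputs fail loudly: zero-variance signals (log of a zero
  curve length) and windows shorter than 2·k_max + 1 raise errors rather
  than returning values.

The estimator is exactly invariant to affine amplitude changes, agrees
with a naive triple-loop transcription to 1e−10, and on exact fBm at
25 000 samples lands within ~0.005 of 2 − H for H in [0.2, 0.8].

**Noise sensitivity.** HFD's small lags probe 2–20 ms timescales. On a
unit-variance fBm path the fine-scale increments are of order n^−H, so
even ~1 % broadband observation noise dominates those lags, inflates the
estimate toward 2 and can invert the H-ordering. The generator default is
therefore `noise_sd = 0.002`. For the same reason the 1–30 Hz protocol
band-pass is **not** applied to synthetic segments in the pipeline
defaults: removing all content above 30 Hz empties exactly the band the
k = 1..10 lags at 500 Hz measure and compresses HFD to ≈ 1.08 regardless
of H. The filter stage exists (zero-phase 4th-order Butterworth,
`sosfiltfilt`) and is the intended path for real recordings, where it
removes drift and line noise rather than the signal's own fractal
structure; `filter_eeg=True` enables it.

## Segmentation conventions

Segments are the 50 s immediately preceding each probe ([t−50, t),
half-open, 0-based sampling), labeled with the probe's answer and the
clip's synchrony. Probes earlier than 50 s into a video are skipped with a
logged warning. Extraction never reads outside the recording. Artifact
handling on synthetic data is an amplitude screen (any-channel |z| > 6
flags the segment); component-based cleaning of real data is out of scope
because it is manual and irreproducible.

## Design construction

`build_clip_set(n)` enumerates all n² (image, audio) pairings. Version
construction is a randomized backtracking search (budget 10 000 node
expansions) over: 2 synchronized + 2 mismatched experimental clips per
version; no film in two clips of the same version; each film synchronized
exactly 2·n_versions/n_films times across versions; mismatched image and
audio usage exactly balanced. A separate validator re-checks every
constraint on the constructed versions — the validator, not the
constructor, is the source of truth. The practice clip is a synchronized
clip of a dedicated seventh film, exempt from the uniqueness constraint
(including it would make the six-film balance unsolvable). Only 12 of the
30 mismatched clips fit in six versions; the search records the balanced
subset it selected.

## Statistical models

**State frequencies.** Counts per (participant, synchrony, answer) are
modeled by a Poisson log-link GLM with log(n_probes) offset and
Group × State × Synchrony fixed effects (sum-to-zero coding), tested by
type-III Wald χ² — seven effects with dfs (1, 3, 1, 3, 1, 3, 3). Poisson
with exposure was chosen because probe totals vary with the ±10-s jitter;
the family is switchable. Post-hoc group contrasts are two-sample t tests
(Student by default, Welch by config) on relative frequencies, one per
synchrony × answer cell, BH-corrected across the 8.

**Mixed model.** `hfd ~ Group × Answer × Synchrony × Area +
(1 | participant)`, REML, restricted to MW/Full (the Audio/Image states
are too rare), type-III F via sum-to-zero coding. The random-intercept
REML fit is profiled in closed form: Sherman–Morrison reduces all GLS
quantities to per-participant row sums, leaving a 1-D criterion in
λ = σ²_b/σ²_e optimized by bounded scalar search. Satterthwaite dfs use
ν = 2(l′Cl)² / (g′Wg) with g the central-difference gradient of l′C(θ)l in
θ = (σ²_b, σ²_e) (relative step 1e−6) and W the inverse negative Hessian
of the REML log-likelihood (relative step 1e−4); multi-df effects combine
eigenvector-wise one-df values via E = Σ ν_m/(ν_m−2), df = 2E/(E−q). The
implementation is cross-checked against lme4/lmerTest (F to 1e−4,
dfs to ~2 %, variance components to 1e−3) and, at the variance-component
estimates, against dense-matrix GLS. Simple effects are the 40 MW−Full
Wald contrasts (per group × synchrony × area), BH-corrected jointly
across all 40 — the conservative reading, declared because the published
correction scope for such decompositions is typically unstated.
Brown–Forsythe (median-centered Levene) across the 80 design cells is
reported only; modeling proceeds regardless of its outcome.

**Cognitive scores.** D2 derived scores are exact integer arithmetic.
Variables are screened per group by Shapiro–Wilk at α = .05 (flagged if
either group rejects — so the flag rate under normality is ≈ 1−0.95², not
α itself); flagged variables get Mood's median test in its Pearson-χ²(1)
form, others a pooled-variance t test. BH is applied within the 5-variable
SCIP family and the 7-variable D2 family.

**Associations.** Spearman, pairwise-complete, per group; p from the t
approximation for n ≥ 10 and exact permutation enumeration below that;
cells with fewer than 4 complete pairs are NA with the count kept.
Medication screens are Mann–Whitney U per outcome for antidepressant use,
mood-stabilizer use, and antipsychotic dose split at the median
chlorpromazine equivalent; subgroups under 3 are skipped and flagged; BH
within each factor's outcome family. No correction is applied across the
full correlation matrix.

## Numerical and engineering choices

- BH adjustment delegates to `statsmodels.multipletests("fdr_bh")`; a
  brute-force step-up oracle in the tests pins it exactly.
- The GLM and design matrices come from statsmodels/patsy; the mixed-model
  REML/Satterthwaite layer is in-house because no installed Python package
  provides type-III Satterthwaite tests on a REML mixed model, with
  statsmodels `MixedLM` and R `lmerTest` as independent cross-checks.
- EDF reading goes through MNE; writing uses a minimal in-house EDF+
  writer (16-bit, 1-s records, annotation channel) whose output is
  round-tripped through MNE in the tests.
- Simulation sizes in the test suite: statistics-level studies run at the
  full 45 × ~18-probe scale (records are cheap); signal-level tests use
  10-s, 100-Hz segments, which preserve every structural property
  (window counts scale, FD = 2 − H is sample-rate free). Replicate counts
  are 100–400 per calibration suite, chosen so Monte-Carlo error is well
  inside the asserted bands.

## Known limitations

- Synthetic EEG is fBm: no alpha peaks, no 1/f-beyond-fBm spectral shape,
  no eye-blink/muscle artifacts, no cross-channel correlation (channels
  within an area share H but have independent noise — the analysis
  averages within areas, so correlation would change efficiencies, not
  means). Passing tests demonstrate the pipeline's correctness under this
  model, not the neurophysiological claims themselves.
- The electrode-to-area map is an anatomically conventional
  left/midline/right split; published designs often specify membership
  only graphically, so the map is a declared approximation and
  overridable via CSV.
- Heteroscedastic mixed models and random slopes are not implemented; the
  Brown–Forsythe check is diagnostic only.
- Exact Spearman permutation enumeration is used only below n = 10
  (9! ≈ 3.6e5 permutations); above that the t approximation is standard.
- At full study scale the sliding Higuchi estimator's replicate SD on clean
  fBm is tiny (~0.005), so with ~6 500 records even minute estimator
  biases (order 0.003, e.g. from noise interacting with the Hurst level)
  reach significance in the mixed model. On real EEG, within-cell
  variability is orders of magnitude larger and dominates such biases.
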