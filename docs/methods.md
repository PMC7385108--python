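# Methods

This note documents the models, defaults, and numerical choices behind
`cardioema`, and what the synthetic-data suites do and do not establish.

## Signal model and feature extraction

**ECG.** The raw ECG is band-passed 0.5–45 Hz with an order-6 elliptic
filter (0.1 dB ripple, 80 dB stopband) applied forward–backward, so fiducial
timing carries no group delay; the two passes leave DC below 10⁻⁶ and 60 Hz
mains below 0.3% of input amplitude. R peaks are detected with a
Hamilton/Pan-Tompkins-class rule: candidate maxima must exceed 40% of the
typical QRS amplitude (median of 2-s block maxima) and be ≥ 250 ms apart.
The detector assumes upright R waves, which the simulated lead-II-like
templates provide.

**IBI QC.** An IBI is rejected when outside 300–2000 ms or when it differs
from the last *accepted* IBI by more than 300 ms (configurable ectopy rule).
Rejected data are excluded everywhere; nothing is interpolated or
corrected. The return to baseline after an excluded artifact is compared
against the last accepted value, so a single artifact costs one beat.

**RSA.** Within a window, accepted IBIs (timestamped at the second beat of
each pair) are cubic-spline interpolated to 4 Hz, linearly detrended,
Hamming-tapered, and Fourier transformed; RSA is the natural log of the
power-spectral-density area over 0.12–0.4 Hz (ms² units), floored at 10⁻¹²
ms² before the log. A sinusoidal IBI modulation of amplitude *a* in-band
yields band power ∝ a², so doubling the amplitude raises RSA by ln 4 —
the property test asserts exactly that. Out-of-band modulation leaves only
spectral leakage; its level is checked against an independently coded
periodogram oracle rather than against the floor, because Hamming sidelobe
leakage from a strong 0.05 Hz modulation sits far above 10⁻¹² ms².

**ICG.** dZ/dt windows spanning R−250 ms…R+500 ms over eight consecutive
accepted beats are averaged into overlapping ensembles advancing one beat
per step. The B point is the curvature maximum (centered second difference)
between R+10 ms and the dZ/dt peak, requiring curvature above 10⁻⁴ of the
ensemble amplitude so featureless windows return "absent"; the X point is
the curvature-qualified deepest local minimum after the peak. The search
starts at R+10 ms rather than a hard 30 ms floor so that implausibly early
B points are *detected* and then rejected by the PEP range check instead of
being silently clamped into validity. B-point series are cleaned by
forward and reverse AR(3) least-squares fits: points whose residuals exceed
3 robust SDs (1.4826·MAD) under both directions are replaced by the mean of
the two predictions, iterating up to three passes so adjacent outliers are
caught. PEP/LVET QC: 30–200 ms / 100–500 ms, and ≤ 30 ms change between
consecutive accepted ensembles. SV uses Kubicek's equation with defaults
ρ = 135 Ω·cm, L = 30 cm (per participant-day in practice), Z₀ from the
recording mean; CO = SV·HR/1000 holds as an identity at output precision.

## Trigger engine

All candidates — accepted beat times and the per-half-day random-prompt
schedules — are processed on one merged chronological queue, so refractory
interactions are deterministic and an offline brute-force scan reproduces
the online engine exactly (tested on 100 scripted days). The IBI rule
compares the current beat's IBI against *every* accepted beat in the
trailing 8 s and fires on the maximum absolute difference exceeding the
threshold — the most sensitive reading of a sustained change; endpoint
comparison is available by configuration. Stillness requires every
accelerometer channel *and* the vector magnitude ≤ 10 cm/s² over 30 s;
posture stability requires < 15° change in torso–thigh relative angle
(the tolerance is a package choice; posture classes: torso > 60° reclining,
else thigh > 45° sitting, else standing). Missing stream coverage fails
both gates safe. Random prompts draw one uniform time per 4-h half-day and
fire at the first whole second satisfying gates and refractory. Threshold
adaptation is multiplicative, `new = thr·(count/target)^0.21` clamped to
65–266 ms; the exponent makes a day at twice the 20-prompt target move a
167 ms threshold by ≈ +26 ms, matching the reported average adjustment
magnitude.

## Events and standardization

Change scores are post-window minus pre-window features over half-open
30 s windows anchored at the prompt time (anchoring at the detected IBI
onset is a config switch). Any missing feature on either side flags the
event as artifact; artifact events never enter statistics (verified with
poisoned sentinels). Standardization is within person with the sample SD
(n−1); a zero-variance feature raises an error naming the feature.
Participants with fewer than 70 usable events are excluded (70 itself is
included).

## Clustering

Each participant's n×6 z-matrix is fit with sklearn's variational
Bayesian Gaussian mixture with a stick-breaking (Dirichlet-process) weight
prior: full covariances, truncation = n (every event could be its own
cluster), concentration prior 1/truncation, tol 10⁻³, ≤ 2000 iterations.
Because a truncation-n k-means initialization starts every point in its own
singleton component and variational inference then stalls in fragmented
local optima, restarts are instead seeded from k-means partitions at a grid
of granularities (1, 2, 3, 5, 8, …; five restarts by default) and the best
*converged* evidence lower bound wins — the model and its ELBO are
unchanged, only the starting points differ. Cluster size is soft mass
(membership column sum / n); clusters at ≥ 5% are retained, and events
whose most probable component is unretained are "UC". A standard-GMM + BIC
selector is included as an independent cross-check utility, not a pipeline
stage.

**What recovery tests show.** On unit-covariance mixtures constructed
directly on the standardized scale (`generate_zspace_mixture`, equal
weights, minimum pairwise mean distance = the stated separation), the
default configuration recovers the exact component count and ARI ≈ 1.0 at
10 SD separation (n = 200). At 5 SD separation the variational ELBO
*genuinely prefers* merging the closest component pairs — the forced
correct solution scores several nats below the merged one — so exact count
recovery drops to roughly 50%; this is a known underfitting bias of
variational Bayes with full covariances in six dimensions at these sample
sizes, not an optimization failure, and it is reported as-is. In the full
pipeline the effect is amplified: within-person standardization divides
each feature by total (within + between cluster) SD, so a raw-space
separation of s shrinks by ≈ √(1 + between-variance share), and
participants with many clusters are under-segmented at realistic event
counts. Recovery suites use n = 200 events per replicate (the plausible
upper range of a ~14-day, ~20-prompts/day protocol); equal mixture weights
are used for count-recovery tests because components whose true weight
falls below the 5% retention floor make "retained count = true K"
ill-posed.

## Association and patterns

Word weights: weight(w, k) = Σ over events containing w of membership
p(event, k), with unretained mass pooled in UC; per-word mass therefore
equals the number of events containing the word (a conservation law in the
tests). Words are lowercased and punctuation-stripped; no stemming. A word
"labels" a cluster at ≥ 1 soft event-equivalent; Table-style summary means
are unweighted over unique words. Kruskal–Wallis tests on valence and
arousal group events by hard max-probability retained cluster (UC excluded,
≥ 2 groups of ≥ 2), uncorrected for multiple comparisons; identical-value
degenerate groups are reported as H = 0. Context uses hard-cluster ×
category χ² with Cramér's V, and V = 0 for degenerate tables.

Effect sizes are d = m/σ with m the probability-weighted mean raw change
and σ the participant's change-score SD. d is rounded to one decimal half
away from zero *before* classification, so 0.15 → 0.2 → "+"; `nc` is the
open interval (−0.2, 0.2) and the 0.2/0.5/0.8 cuts grade magnitude.
Pattern mining is exact-string grouping of the 6-symbol codes, with
relative frequency against the total cluster count (2 dp). RSA maps
directly to PNS classes and PEP inversely to SNS classes at the same ±0.2
rule; modes follow the autonomic-space quadrants, with "uncoupled" when
exactly one branch is negligible. The branch-proportion χ² uses hard
per-cluster classes on the 2×3 branch-by-class table (df = 2 when all
columns are populated); empty columns are dropped with the df reduced
accordingly.

## Synthetic data

The generator emulates the study conditions: 3–8 clusters per participant
(uniform), mixture weights Dirichlet(5) (equal on request), component means
at random directions scaled so the minimum pairwise Mahalanobis distance
equals the requested separation in pooled-SD units, diagonal covariances
at realistic per-feature scales (40 ms IBI, 0.5 RSA log-units, 8 ms PEP,
15 ms LVET, 6 mL SV, 0.6 L/min CO, jittered ±30%). Vocabularies are
9–147 words (log-normal around a median of 29) with Zipf frequencies and
near-uniform cluster affinity by default — a many-to-many word–cluster map;
a `specificity` knob (0–1) sharpens affinity to disjoint blocks and spreads
per-cluster rating means up to 1.5 rating-SD apart for power tests, with
specificity 0 (no true association, matching the study's findings) as the
default. Ratings are Gaussian per cluster around grand means 10.16
(valence) and 6.40 (arousal) with SDs chosen so overall SDs are ≈ 17–19
and 10⁴ draws span beyond ±40 on the −50…+50 scale; posture is
sitting-dominant (73.9/12.5/8.3/5.4%). Raw recordings place Ricker-wavelet
QRS complexes at cumulative IBI times and build each dZ/dt beat from
half-cosine segments whose curvature maxima sit exactly at the scripted
B (R + PEP) and X (B + LVET) offsets, with ground-truth annotations in a
JSON sidecar; RSA ground truth is sinusoidal IBI modulation inside
0.12–0.4 Hz. All streams share one clock, windows are half-open, and every
generator is bit-reproducible given its seed.

**What passing tests do not show.** The simulations contain no real ECG
morphology variation, motion artifact on ECG/ICG, respiration coupling
beyond the scripted sinusoid, missing data bursts, or word semantics;
recovery and calibration results bound behavior under the generative model
only, not on field recordings.

## Determinism and problem sizes

Every stochastic stage receives a child of the master seed through
`numpy.random.SeedSequence` spawning; identical configs produce
byte-identical outputs. Default suite sizes — 200-replicate calibration
cohorts, 50-replicate recovery sweeps at n = 200, 100 scripted 1-h trigger
days — were chosen as the smallest sizes at which the binomial/recovery
bounds being asserted are statistically meaningful, and run in a few
minutes on one CPU.

## Known limitations

- Variational DP-GMM under-segments at ≤ 5 SD component separation (see
  above); conclusions about cluster *counts* at moderate separation should
  rely on the BIC cross-check or larger samples.
- The B/X detectors are tuned to ensemble-averaged, low-noise dZ/dt; the
  derivative thresholds are configuration points expected to need
  re-tuning on hardware data.
- Posture classification uses two inclination angles, not full
  quaternions; fine-grained postures (slouching, lying prone vs supine)
  are out of scope.
- The word model treats words as tokens; normative valence/arousal of
  words is intentionally not modeled.
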