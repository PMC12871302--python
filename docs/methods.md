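# Methods

This note documents the models behind the synthetic-data generators, the
analysis algorithms, the parameters that matter, and the limits of what the
round-trip tests demonstrate.

## Genotype presets

`config.PRESETS` fixes one parameter set per genotype (WT, C92X, P305L,
R350G). Entries with a reported value are fixed: anterograde flux 5 min⁻¹
and v̄₅ ≈ 4 μm/s in wild type, retrograde v̄₅ 2.8 μm/s (WT) vs 3.5 μm/s
(R350G), SVP⁺ site densities 0.6 / 0.6 / 0.72 / 0.31 per 10 μm, relative
KIF1A mRNA 1.0 / 0.15 / 0.48 / 0.36, and a 100-fold mean-firing-rate
increase in astrocyte co-culture. The remainder are calibration choices,
flagged in the source: the retro/antero flux ratio 0.6 shared by all
genotypes; the motile-intensity multiplier 0.7 for C92X and P305L (the
reduction is reported only graphically, so 0.7 is a placeholder magnitude);
comet rate 0.05 μm⁻¹·min⁻¹ with association probability 0.8 (0.4 for the
site-poor R350G); monoculture baseline firing 0.3–0.6 Hz with 0.1–0.3
bursts·min⁻¹ per electrode. Pixel size is 0.16 μm (typical 100× sCMOS),
frame intervals 0.2 s (SVP movies) and 1 s (comet movies); MEA wells have
12 electrodes sampled at 20 kHz for 600 s.

## SVP track generator and kymograph rendering

Track counts per axon and direction are Poisson(flux × duration/60). Each
track enters the 100 μm window at a uniform random time and traverses at a
constant speed, optionally interrupted by one pause (probability 0.3,
1–4 s, drift < 0.05 μm/s); the post-pause run moves at 0.75× the peak
speed so that each track's fastest segment is unambiguous. Per axon and
direction, five tracks are designated speed leaders with peaks drawn from
Normal(v̄₅, 0.08 v̄₅); all other tracks stay strictly below the slowest
leader. This construction makes the per-axon mean of the five fastest
segment speeds an unbiased estimator of the preset — with i.i.d. speeds the
top-5 mean would sit systematically above the distribution mean, which is a
property of order statistics, not of the biology being emulated.
Intensities are log-normal (σ = 0.3) around 500 AU × intensity_scale.

Rendering paints each track as a 3-pixel-wide anti-aliased streak
(triangular kernel, half-width 1.5 px) of its intensity; overlaps take the
maximum rather than summing, so crossings do not double brightness.
Background is a constant 100 AU plus Gaussian read noise (default SD 10);
cytoplasmic signal is assumed photobleached before acquisition, so no
bleach-recovery gradient is modelled.

## Automated kymograph tracing

Per-time-row local maxima above the robust background (median + 3 robust
SDs, where robust SD = 1.4826 × MAD; the unscaled MAD would put the
threshold at ≈ 2 Gaussian SDs and flood the detector) are refined to
sub-pixel positions by intensity-weighted centroiding. Linking is
nearest-neighbour against a constant-velocity prediction, with claims
resolved globally nearest-first, a 6 μm per-step displacement cap, and gap
closing across ≤ 2 missed rows. Three refinements keep dense scenes
honest, all visible as parameters:

* **Occlusion coasting** — when two predictions fall within 4 px the
  underlying streaks are unresolvable (3-px line width); the losing track
  extends along its own prediction (up to 12 rows) instead of grabbing the
  merged detection, and trailing coasted points are trimmed.
* **Deceleration window** — a moving cargo may brake into a pause anywhere
  short of its prediction, so detections near the last position are
  accepted alongside detections near the prediction; near-stationary
  tracks get a wider reacquisition margin so a resuming run is recaptured.
  Claims implying a hard direction reversal of an established track are
  rejected (the generator contains pauses, not reversals; real reversing
  cargo would require relaxing this).
* **Fragment stitching** — fragments whose constant-velocity extrapolation
  meets a later fragment (gap ≤ 25 rows, deviation ≤ 4 px + 1 px/row,
  slope difference ≤ 2 px/row) are rejoined, and track candidates whose
  median sampled intensity sits below background + 8 robust SDs are
  discarded as noise chains.

Paths are simplified to inflection points by Douglas–Peucker (tolerance
1 px). On noise-free renders the tracer recovers track counts exactly with
sub-pixel error; on the default noisy renders, 50-axon runs recover preset
fluxes and velocities within 10 % for every genotype. Measured flux runs
1–8 % above the preset (residual fragment double-counting at crossings),
and tracks entering in the last ~3 s of a movie are lost to the 10 μm
net-displacement rule (< 1 %).

## SVP⁺ sites and comets

Generated sites are Poisson in number (density × length/10) with uniform
positions under a 3 μm hard-core minimum separation — discrete
protosynaptic accumulation zones rather than an unconstrained Poisson
process — so the detector's 1 μm column-merge rule cannot fuse distinct
ground-truth sites. Extents are 1–2 μm, intensities log-normal around
400 AU. Comets grow at Normal(0.1, 0.02) μm/s (truncated positive) for
20–60 s, 80 % anterogradely; a fraction assoc_prob starts within 10 μm of
a site centroid (drawn inside ±9.5 μm to avoid boundary ambiguity).

Site detection thresholds at the grid median + 3 robust SDs and requires a
column to exceed it in ≥ 95 % of rows — "persisting the entire movie" with
tolerance for noise dropouts; comets (0.1 μm/s) drift too far to satisfy
it. Adjacent site columns within 1 μm merge; centroids are
intensity-weighted. Association is tested against any point of the comet's
spatial span (a start-only mode is available), and the regression of site
density on comet activity is plain OLS via the normal equations, verified
against an independent implementation to 1e-10.

## MEA model and analysis

Per electrode: homogeneous Poisson background at mfr_base plus burst
epochs (Poisson onsets; size 3 + Geometric(½); within-burst ISIs
exponential with mean 20 ms). Network events (co-culture only) recruit
6–12 electrodes with ≤ 20 ms onset jitter and denser bursts (size
5 + Geometric(½), ISI mean 15 ms) — recruiting at least half the array
keeps events detectable by the ≥ 4-electrode rule even when individual
electrode bursts fall below the 3-spike minimum. Voltage synthesis places
a biphasic 1 ms template (amplitude 10× the 5 μV noise SD) at each spike
time on Gaussian noise.

Filtering applies the high-pass, low-pass and notch (Q = 30) as a single
zero-phase second-order-section cascade — identical magnitude response to
filtering each stage zero-phase in sequence, at a third of the cost. Spike
detection estimates the baseline SD as median(|x|)/0.6745 (robust to the
spikes themselves), takes the extremum of each ±5 SD excursion, and
enforces a 1 ms dead time.

The two stated burst constants conflict for gaps in (50, 100] ms; the
resolution here is: a burst is *seeded* by two spikes ≤ 50 ms apart,
*continues* through any gap ≤ 100 ms, and *terminates* at the first longer
gap (≥ 3 spikes total). The detector is verified against an independent
cluster-based re-derivation on thousands of random trains. Burst frequency
is the per-well total over active electrodes per minute (the alternative —
per active electrode — is not normalised here). At co-culture rates
(≈ 50 Hz) the 50/100 ms definition degenerates: almost the whole train is
one burst. That is a property of the stated definition, not of the
implementation; the co-culture comparison therefore rests on the mean
firing rate. The measured co/mono MFR ratio lands at ≈ 0.91 of the
generated 100-fold because the 1 ms dead time clips ~5 % of 50 Hz spikes
(collision loss ≈ λτ) while monoculture bursts add ~4 % over the baseline
rate — both inherent to the measurement chain, and well inside the 15 %
acceptance band.

## Synapse fields

Exactly ⌊apposed_frac × n_pre⌋ presynaptic puncta receive a partner at a
3-D centroid gap ≤ 0.9 × max_gap; lone post puncta are kept > 3 × max_gap
from every pre punctum, and pre puncta are spaced so that pairs are
isolated — in this regime greedy nearest-first matching provably equals
maximum bipartite matching (asserted in tests against the Hungarian
algorithm). The matching gap of 0.5 μm stands in for SynapseJ's
dilation-overlap criterion, which has no single printed distance. Puncta
detection is a simplified reimplementation of the described SynapseJ
settings: Otsu-seeded components define the provisional puncta whose mean
intensity sets the final ⅔-mean threshold; components are filtered to the
channel's equivalent-diameter window computed from anisotropic voxel
volume. Plugin internals ("default" noise and Find-Maxima settings) are
not reproduced.

## ΔΔCt

Livak form: ΔCt per sample, averaged per genotype, differenced against the
reference, rel = 2^(−ΔΔCt); per-sample exponentiation before averaging is
available as an option (slightly upward-biased under noise, by Jensen's
inequality — visible in the round-trip tests at 0.2-cycle noise, where
single-run estimates scatter ~17 % around an essentially unbiased mean).
No amplification-efficiency correction.

## SuperPlot aggregation

Replicate mean over units within (genotype, replicate); grand mean as the
unweighted mean of replicate means; dispersion as their SD (n−1).
Single-replicate genotypes yield an undefined SD with a warning rather
than silently pooling units. Statistical genotype comparisons beyond the
χ² contingency test (mixed models, Kruskal–Wallis, ANOVA) are exported as
analysis-ready tidy tables rather than re-implemented.

## Problem sizes and determinism

Default validation scales — chosen to exercise every code path at
meaningful statistical power — are 50 axons per genotype for transport and
site-density recovery, 15 axons per arm for the replicate-mean genotype
comparison, five well pairs (600 s, 12 electrodes) for the co-culture
ratio, and 10–20 wells for burst/network-burst recovery. Every generator
is a pure function of (parameters, seed); identical seeds give
byte-identical outputs, and the pipeline manifest records seed, parameters
and package version for every run.

## What the tests do and do not show

The generators reproduce the summary statistics the analyses measure; they
contain no motor biophysics, microtubule lattice chemistry, spike-waveform
diversity, electrode drift, or imaging artefacts beyond Gaussian read
noise and streak crossings. Passing round-trip tests therefore
demonstrates that the measurement chain is unbiased and correctly scaled
under the stated noise model — not that it is robust to out-of-model real
data (uneven illumination, cargo direction reversals, overlapping synapse
puncta, bursting at rates where the 50/100 ms definition saturates).
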