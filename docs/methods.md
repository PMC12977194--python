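# Methods

This note records the scientific and numerical choices behind `hglock`:
what the pipeline computes, what the synthetic generator emulates, where
the design was genuinely open and which option was taken, and what a green
test suite does and does not establish.

## Signal chain

**Downsampling.** Recordings (typically 2000 or 2034.5 Hz) are resampled to
1000 Hz with `scipy.signal.resample_poly` (anti-aliased polyphase FIR). The
rational resampling factor is derived with a denominator cap of 10⁵, which
represents the 2034.5→1000 ratio exactly.

**Band filtering.** 70–150 Hz bandpass, 100th-order (101-tap) FIR designed
with the window method (Hamming). Phase handling is not dictated by the
two-window procedure itself; the filter is applied forward–backward
(`filtfilt`), so band-limited events are not delayed and window timing is
unbiased. The cost is squared passband ripple and doubled attenuation —
gain at the 110 Hz band center is 1.000, at the 70/150 Hz band edges 0.25
(half-amplitude edges of the design, squared). Envelope accuracy in the
passband interior is better than 5 %.

**Envelope and log power.** Hilbert analytic amplitude (FFT length padded to
the next fast size, then truncated). ERBP(t) = 10·log10(env² + ε) minus the
per-trial mean of the same quantity over the baseline window. ε is 10⁻¹² of
the peak block power — it only matters for identically-zero input and is
~120 dB below signal otherwise.

**Baseline.** −200 to −50 ms relative to stimulus onset, per trial. Whether
the original procedure pooled baselines across trials is not stated in the
task description this mirrors; per-trial is the simplest reading of
"normalization to a prestimulus baseline" and makes the baseline-window
ERBP identically zero per trial (a tested invariant). A pooled-across-trials
variant is exposed as `AnalysisConfig.baseline_mode = "pooled"`. Press-
aligned ERBP uses the *same* per-trial stimulus-anchored baselines, so both
alignments of a trial are on one scale.

**Epochs.** Stimulus-aligned −500…+2000 ms, press-aligned −750…+500 ms:
wide enough to contain every analysis/display window plus filter edges.
All windows are half-open `[start, end)` in ms; sample k of an epoch sits at
`start + k·1000/fs`. Filtering happens on the continuous signal *before*
epoching, so epochs have no filter edge artifacts.

**Artifact screen.** A trial is dropped when any raw sample in either of its
epochs deviates > 5 SD, or any band-filtered sample > 10 SD, from the
within-block mean of that site. Masks are computed on both alignments and
intersected, so the identical trial set feeds both window tests (the
alternative — independent per-alignment masks — would let the two t-tests
see different n). Degenerate recordings (zero block SD) are an error.

**Optional denoising.** The original acquisition chain used a demodulated
band transform for line-noise removal; that is out of scope here. A standard
substitute (linear detrend + 60/120/180 Hz IIR notches) is available via
`AnalysisConfig.notch_denoise` and off by default — the synthetic generator
produces no line noise.

**Referencing.** No re-referencing is applied; recordings are analyzed
against whatever reference they were acquired with (the emulated setup used
a subgaleal reference). This is documented rather than configurable.

## Behavior

Press attribution is row-wise: the events-table contract stores at most one
press per stimulus row, a press belonging to the most recent onset. Hits =
target + press; misses, false alarms, correct rejects accordingly. d′ =
Z(hit rate) − Z(FA rate) with rates clipped to [1/(2N), 1−1/(2N)] before the
normal quantile (the standard log-linear correction; the boundary behavior
is otherwise undefined). The RT exclusion boundary: "below 550 ms excluded"
vs "RT > 550 ms included" conflict at exactly 550 ms; the strict rule
(retain iff RT > 550) is adopted, so 550.0 ms is excluded. With the 50–300
and −250–0 ms windows this guarantees the windows never overlap within a
retained trial.

## Site classification

One-sample one-tailed t-tests (H1: mean window ERBP > 0), df = n−1, on the
identical retained trial set in both windows. Significance is strict
p < α (α = 0.05); the boundary semantics are a convention, recorded here.
No multiple-comparison correction at the site level by design — the
procedure deliberately favors sensitivity for detecting responsive sites;
the cost (≈5 % false positives per window on silent sites) is visible in
the synthetic recovery tests. Zero-variance window means (possible only on
degenerate input) map to p = 0 or 1 with a logged warning.

## Regional statistics

**Fisher tests.** 2×2 tables `[pattern, other] × [L, R]`, two-sided exact
p. The odds ratio convention puts left-hemisphere odds in the numerator.
Published tables of this analysis mix OR estimators (most printed values
match the sample cross-product OR; at least one matches the conditional
MLE), so both are emitted — `odds_ratio` (sample, primary) and
`odds_ratio_cmle`.

**FDR family.** The ROI-group analysis corrects across all cells × patterns
in one family (8 groups × 3 patterns = 24 tests); whole-brain tests form
their own 3-test family. A per-pattern family option
(`fdr_family="per_pattern"`) is provided since the original family
definition is unstated.

**SB index.** (n_behav − n_stim)/(n_behav + n_stim); undefined (NaN) when
both counts are zero. Eligibility: at least 5 sites with either pattern,
spanning at least 2 participants — read as a condition on the *pooled*
pattern sites of the ROI × hemisphere cell. Alternative readings (≥5 sites
per pattern, or ≥5 in each of ≥2 participants) were considered and
rejected as stricter than the stated rule's plain reading.

**Coordinate asymmetry.** Pooled-variance two-sample two-tailed t-test on
z-MNI (dorsoventral) coordinates of sensorimotor sites, left vs right.

## Power–RT correlation

Sites with significant post-stimulus activation (patterns `stimulus` and
`intermediate`) contribute a Spearman rho between per-trial post-window
ERBP and RT. ROIs with ≥ 10 such sites are tested (median rho, two-tailed
Wilcoxon signed-rank against zero, BH-FDR across tested ROIs). Zero rhos
are dropped (classical signed-rank convention); the exact null distribution
is used for n ≤ 25 when magnitudes are tie-free, otherwise the normal
approximation with tie correction.

## ROI envelopes

Trials-then-sites averaging, in that fixed order: each qualifying site is
first averaged across its retained trials, then sites are averaged within
ROI (≥ 10 sites). Stimulus-aligned display window −100…+300 ms; the
press-aligned extent is not numerically fixed by the emulated analysis and
defaults to −400…+200 ms (configurable). The 95 % band is an across-site
t-interval; a bootstrap percentile option exists (the CI method was
unstated).

## Synthetic generator

The generator is a stated world, not a tuning knob:

| parameter | default | basis |
|---|---|---|
| ISI | Gaussian, mean 2 s, SD 10 ms | task design |
| stimulus duration | 300 ms | task design |
| RT | lognormal, median 819 ms, σ_log 0.22, truncated ≥ 400 ms | observed grand median; σ chosen so ~3 % of hits fall below 550 ms, matching observed fast-hit rates |
| trials/block | 140; target fraction 0.5 | yields ≈ 60 retained hits/site, the scale of the recovery tests |
| miss / FA rate | 0.05 / 0.03 | high-performing participants |
| noise | 1/f (exponent 1), 20 µV RMS total | conventional broadband iEEG background |
| bursts | 70–150 Hz carrier (110 Hz), Gaussian envelope SD 60 ms | centered +150 ms post-onset and −125 ms pre-press so bursts sit inside the analysis windows |
| burst level | 6 dB window-mean ERBP | robustly detectable at 60 trials without being trivial |
| artifacts | 2 % of trials, ±(8–12)·SD square pulses, 20 ms | exercises the 5 SD screen |

**Burst calibration.** "6 dB" is defined as the *measured* window-mean ERBP
of the analysis chain, not a raw amplitude. For a tone of envelope SNR ρ in
Rayleigh-envelope noise, the expected log-power excess over the mean-log
noise baseline is (10/ln 10)(ln ρ + E₁(ρ) + γ) dB — this accounts for the
−2.5 dB Jensen bias of the log transform on both ends. The generator solves
for the burst amplitude such that the mean of this expression over the
analysis window equals the requested dB, using (i) the in-band noise power
after the analysis filter, computed in closed form from the synthesis
spectrum and the filter response, and (ii) the burst envelope *as analyzed*
(passed through the actual resampler + filter + Hilbert chain, which smears
the synthesis Gaussian slightly). Verified unbiased to ±0.1 dB.

**Power–RT coupling.** A Gaussian copula ties per-trial stimulus-burst
amplitude to the RT draw: the normal scores are correlated with
r = 2·sin(π·ρ_s/6) for a target Spearman ρ_s, and the amplitude is
log-normally modulated (σ_ln = 0.35). Envelope noise attenuates the
recovered site-level Spearman (≈ −0.18 recovered for −0.3 injected at
default SNR), which is why the recovery criterion tests detection, not
point recovery.

**Default site plan.** 20 sites per pattern over 3 participants: stimulus →
STGP (with coupling −0.3), intermediate → MTGP, behavior → MFG, none → OG.
STGP is the coupled ROI and MTGP the uncoupled comparison in the recovery
tests.

**What the generator does not emulate** — and hence what green tests do not
establish: acoustic/phonetic structure, semantic novelty effects, spatially
correlated noise across electrodes, line noise, non-stationary epileptiform
activity, volume conduction, or any relation between MNI coordinates and
signal content (coordinates are plausible placeholders). Recovery results
certify the *pipeline arithmetic and inference machinery*, not claims about
cortex.

## Known limitations and conventions

* EDF support is a minimal built-in reader/writer (int16, single common
  rate, uV/mV/V); it exists so real recordings can be ingested, and
  round-trips within 16-bit quantization.
* Sites with fewer than two usable trials are skipped with a warning and
  reported in the manifest, not classified.
* The intermediate pattern is inherently ambiguous (prolonged stimulus
  response vs early behavior-related activity); on generator data it is a
  planted label, on real data it is not interpretable beyond "both windows
  significant".
* A silent site passes both windows at ≈ 90 % (1−α)²; per-class recovery
  accuracy for `none` sits near that ceiling by construction.
* CLI stage verbs recompute upstream stages from the dataset rather than
  caching intermediates; at the scales this package targets a full
  recompute is cheaper than cache invalidation.
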