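# Methods

## What the package computes

Two estimators of the latency difference Δτ between reticular-lamina (RL)
and basilar-membrane (BM) vibration at one basal cochlear site, plus the
surrounding descriptive analyses. All phases are kept in **cycles**
(1 cycle = 360°) so that a pure delay τ contributes phase −f·τ and latency
estimation needs no 2π bookkeeping; conversion to degrees happens only at
interfaces.

**Tone pathway.** Per animal-by-level record: Δφ(f) = φ_RL − φ_BM on the
shared sweep grid; OLS of Δφ against f over a fit band; Δτ = −slope.
The default band is [0.1·BF, BF] with BF measured per animal as the peak of
its BM response at 30 dB SPL (ties → lowest frequency). The band is a free,
logged parameter because no canonical choice exists; with the linear phase
law any band recovers the same slope, and with real (curved) phase data the
choice matters and must be reported. Points below the recorded noise floor
of either structure are excluded from the fit (they remain in the data,
flagged). Records are grouped as mean ± SEM (sd/√n) treating each
animal × level estimate as one observation; level invariance is tested by
one-way fixed-effects ANOVA at 50–80 dB SPL; the species contrast is a
two-sample t on per-record estimates — Student's pooled t by default with a
Welch option, and both are always reported because the two variants can
differ materially when group sizes and variances differ.

**Click pathway.** Records are uniformly sampled displacement waveforms
(200 kHz). The first peak is the first strict local extremum (either sign)
at t ≥ 0 whose amplitude clears max(threshold_mult × pre-stimulus RMS,
0.1 × record max), refined by a three-point parabola (needed: at 5 µs
sampling, ~30 µs differences must resolve to ~1 µs). The pre-stimulus
window is the first 10 % of the record; synthetic records therefore carry a
0.5 ms pre-trigger baseline before the stimulus at t = 0, as averaged
evoked recordings do. A record whose global maximum is below twice the
noise threshold is declared undetectable — this reliability gate is what
makes "the initial peak was too small to be reliably detected" an actual
error state rather than a chance noise pick, and it reproduces the ~70 dB-p
usability boundary. Δτ = T_B − T_A. First periods (T_BM, T_RL) are the
spacing of the first two same-sign extrema (partner extremum must reach
20 % of the first-peak magnitude, to skip noise wiggles). The in-phase time
T_C has no standard operational definition (it is judged by eye in
practice); here it is the first time after max(T_A, T_B) at which the
analytic-signal (Hilbert) phase difference, unwrapped in time, crosses an
integer number of cycles, searched only where both envelopes exceed 5 % of
their maxima, with linear sub-sample interpolation.

**Decomposition.** D_OHC(f) = D_RL(f) − D_BM(f) as complex phasors; the
subtraction refuses to mix sound levels or sensitive/postmortem states,
since phasors share a reference only within one condition. The dominance
index |D_OHC|/|D_RL| reads ~1 where the OHC-driven component carries the RL
motion (low level) and falls toward 0 where the RL rides the BM passively.

**Place map.** d% = a − b·log₁₀(f/kHz), x = L·d%/100, with an exact inverse.
The `gerbil_mueller` preset could not be transcribed from the original
frequency-position study (not available here); it is instead anchored to
the one constraint this data set provides — 26 kHz at 2.05 mm from the
base — with a literature-typical gerbil slope of 38.2 %/decade and BM
length 11.1 mm (a = 72.52). Positions far from the anchor should not be
over-interpreted. Snapshots use W(x; t) = mag(x)·cos(2π(f·t + φ(x))): phase
enters with a plus sign so that a larger lag (more negative φ) shifts the
local oscillation later in time.

## The synthetic cochlea

`corti.synth` is a **descriptor model**: it encodes the measured summary
statistics of basal-turn vibrometry directly, because the measurements
themselves (not model equations) are what the analyses consume. All
functional forms are plumbing; the calibration constants are the physiology.

BM magnitude (dB) = scale + level + passive(f) + A(level)·w(f), with
passive(f) a quadratic in log₂ f centered at 0.6·BF (curvature
6.8 dB/oct², extra high-side rolloff 40 dB/oct² above BF) and w(f) a
log-Gaussian active weight of width 0.12 oct whose center is offset so the
total curve is stationary exactly at BF at 30 dB SPL (the offset is solved
at construction; the BF then sits on the sweep grid). A(level) falls
linearly from 35 dB at 30 dB SPL by c_bm = 23 dB over 30→80 dB SPL, giving
exactly 23 dB compression at BF, linear growth well below BF, and an
emergent broadening/downward shift of the peak with level. The narrow
active width makes the 30 dB response occupy ~0.2 mm of place. BM phase =
−f·τ₀ − s·(f/BF)³ cycles (τ₀ = 30 µs, s = 0.57): a traveling-wave-like
accumulating lag whose group delay grows toward BF.

Sensitive RL = BM × R(f, level) × exp(i2π(0.5 − f·Δτ_tone)). The ratio law
R interpolates log-linearly in level between exactly 10 (30 dB SPL) and
1.5 (80 dB SPL) at BF, plus a low-frequency term growing with level
(largest ratios far below BF at high level). These endpoints force RL
compression of 23 + 20·log₁₀(10/1.5) ≈ 39.5 dB — the ~40 dB measured. The
phase law gives exactly half-cycle opposition at DC decaying at the fixed
latency slope; Δτ_tone defaults: gerbil 17.9 µs, mouse 12.1 µs. Stapes:
flat, linear, 15 µs delay. Postmortem: the active terms vanish — BM loses
A(level) (broad, low-shifted, linear-growth response), RL = 0.7 × BM ×
exp(−i2πf·5 µs): passive following with a small lag, no opposition.

Clicks are synthesized by inverse FFT of the frequency response times a
10 µs rectangular-pulse spectrum, sampled at 200 kHz for 5 ms including the
0.5 ms pre-trigger, with a bulk stimulus-path delay t_me = 371.6 µs chosen
to put the 90 dB-p RL first peak at 0.40 ms. The overall sign encodes the
rarefaction polarity (sensitive BM first peak positive = toward scala
vestibuli). The RL click response uses Δφ(f) = 0.5 − f·Δτ_click
(Δτ_click = 32.6 µs, gerbil; tone and click delays are separate parameters
because the two stimuli measure different values) times an 8-fold ratio
with a mild low-frequency tilt (exponent 0.3, pivoted at ~13.7 kHz so the
first-peak ratio stays 8). The tilt makes the RL ringing start at a
slightly lower frequency (T_RL > T_BM) at the cost of a ~−0.3 µs bias in
the first-peak latency difference, well inside the 1 µs sub-sample
resolution. Known limitation: with this phase law the in-phase time T_C
lands ~0.44 ms (≈40 µs after T_B, where the instantaneous frequency passes
0.5/Δτ_click ≈ 15.3 kHz), somewhat earlier relative to the first peaks
than is observed in vivo; reproducing a later T_C would require a downward
frequency glide, inconsistent with the upward glide implied by the tone
phase curves. T_C is therefore reported but not treated as a calibrated
quantity.

Noise and variability: per-point log-normal magnitude noise
(σ = 0.05 log₁₀-units), Gaussian phase noise (σ = 0.02 cycles), a constant
recorded noise floor (0.005 nm), additive click noise (0.05 nm — this sets
the ~70 dB-p detectability boundary), and per-animal BF jitter (log-normal,
σ = 3 %). A per-animal latency-jitter knob exists (`tau_jitter_rel`) but
defaults to 0: with independent per-point noise the grouped estimator is
unbiased and its naive SEM (~0.07 µs at n = 28) is consistent; correlated
per-animal jitter would be needed to reproduce the ±0.6 µs SEM reported for
real cohorts, but then the naive SEM across the 28 correlated records
understates the uncertainty of the cohort mean about twofold. The default
therefore favors statistical consistency of the recovery tests over
matching the field-typical SEM magnitude; simulations of between-animal
heterogeneity should switch the knob on and group by animal.

Randomness is fully reproducible: every measurement stream is seeded by
(seed, CRC32(animal id), level, state, kind), so datasets are byte-identical
across reruns and independent of generation order.

## What passing tests do and do not show

The generator emulates the *statistical structure* of the measurements:
ratios, compressions, phase laws, polarities, delays, noise levels. It does
not emulate frequency glides of real click responses, level-dependent phase
curvature, spatial coupling along the partition, or instrument artifacts
(carrier leakage, drift). Parameter-recovery results therefore validate the
pipeline's correctness and calibration — an injected delay is recovered
unbiased at the stated precision — not the biological interpretation of any
particular real data set.

## Numerical choices

Grids: gerbil sweep 1.8–40 kHz step 0.2 kHz; mouse 3–63.9 kHz step 0.3 kHz
(BF on-grid in both). Clicks: 1000 samples at 5 µs, FFT size 2048.
OLS via `scipy.stats.linregress` (matches the closed form to 1e−12);
ANOVA `scipy.stats.f_oneway`; t tests `scipy.stats.ttest_ind`.
Unwrapping: `numpy.unwrap(period=1)`, anchored at the lowest frequency; no
absolute phase reference is attempted. Ties in peak picking break toward
the lowest frequency / earliest time. TSV floats use 17 significant digits
and `float_precision="round_trip"` on read, making write→read lossless.
Problem sizes in tests and the acceptance script follow the study design
(7×4 tone records, 10 click animals, 5 mouse animals; 100-replicate
simulation properties), which run in seconds.
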