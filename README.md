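# corti

Timing analysis of reticular-lamina (RL) and basilar-membrane (BM) vibration
in the cochlear base, for auditory biophysicists working with in-vivo
interferometric vibrometry. The package covers the full analysis chain for
two measurement modes — tone-evoked transfer functions and click-evoked
displacement waveforms — together with a calibrated synthetic-cochlea
generator so that every stage can be verified end to end with known ground
truth, no instrument data required.

## The science in brief

Outer hair cells (OHCs) insert into the reticular lamina; whether their
cycle-by-cycle force leads or lags the basilar-membrane traveling wave
decides between competing models of cochlear amplification. The package
quantifies that timing two independent ways:

* **Phase-slope latency.** A structure vibrating with latency τ accumulates
  phase lag φ = −f·τ (cycles). The RL−BM phase difference Δφ(f) = φ_RL − φ_BM
  therefore falls with frequency at slope −Δτ, and an ordinary least-squares
  line fitted to Δφ versus f over [0.1·BF, BF] yields the latency difference
  Δτ = −slope. In the basal gerbil cochlea Δφ approaches half a cycle
  (~180°) at low frequency — the two ends of the OHCs move in opposite
  directions — and decays to ~0 at the best frequency (BF ≈ 26 kHz), giving
  Δτ ≈ 18 µs with the RL moving *after* the BM.
* **Click first-peak latency.** In click responses (200 kHz sampling, 5 µs
  steps) the first displacement peaks T_A (BM, toward scala vestibuli) and
  T_B (RL, toward scala tympani) are located with quadratic sub-sample
  interpolation; Δτ = T_B − T_A (~33 µs at 90 dB-p).

Around these sit the supporting analyses: transfer ratios and compressive
growth (`compression_db = ΔL − 20·log₁₀(fold)`), DPOAE-based sensitivity QC
(drop < 5 dB), complex vector subtraction isolating the OHC-driven RL
component (D_OHC = D_RL − D_BM), one-way ANOVA for level invariance of Δτ,
two-sample species comparison, and a log-frequency place map
(d% = a − b·log₁₀ f) for re-plotting frequency sweeps as longitudinal
traveling-wave snapshots W(x; t) = mag(x)·cos(2π(f·t + φ(x))).

The synthetic generator (`corti.synth`) is a descriptor model, not a
hydrodynamic simulation: its defaults encode the measured summary statistics
(BF 26 kHz; RL/BM ratio 10 → 1.5 from 30 → 80 dB SPL; BM compression 23 dB;
Δφ(f) = 0.5 − f·Δτ; opposite click polarities with an 8-fold peak ratio;
postmortem loss of every active term). See `docs/methods.md`.

## Worked example

```python
from corti import make_cohort, gerbil_params
from corti.report import report

cohort = make_cohort(gerbil_params(), 7, levels=(50, 60, 70, 80), seed=1,
                     click_levels=(90.0,))
res = report(cohort.spectra, cohort.clicks, levels=(50, 60, 70, 80))
g = res["tone_group"]
print(f"tone delta-tau: {g.mean:.1f} +/- {g.sem:.1f} us (n={g.n})")
print(f"level ANOVA: F={res['anova_f']:.3f}, p={res['anova_p']:.3f}")
c = res["click_group"]
print(f"click delta-tau: {c.mean:.1f} +/- {c.sem:.1f} us (n={c.n})")
```

prints

```
tone delta-tau: 17.9 +/- 0.1 us (n=28)
level ANOVA: F=0.572, p=0.639
click delta-tau: 32.4 +/- 0.2 us (n=10)
```

i.e. the reticular lamina moves ~18 µs after the basilar membrane under
tones (28 animal-by-level records, no significant level dependence) and
~32 µs after it under clicks.

The same pipeline is laid out as a narrative sequence under `analysis/`
(simulate → tuning/compression → tone latency → click timing →
decomposition/snapshots); each script prints its findings and writes tables
under `results/`. A thin CLI wraps the stages:

```
corti simulate --preset gerbil --n-animals 7 --seed 1 --out-dir results/data
corti latency --spectra results/data/spectra.tsv --out latency.tsv
corti report --spectra results/data/spectra.tsv --out report.txt
```

## File formats

Tab-separated UTF-8 with header, `.` decimal, floats at 17 significant
digits (lossless round trip). Spectrum dialect: `animal_id species state
structure level_db_spl frequency_hz magnitude_nm phase_cycles
noise_floor_nm` (optional `wrapped` 0/1 column → unwrapped on load).
Time-series dialect: `animal_id species state structure level_db_p time_s
displacement_nm`, uniform sampling enforced.

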