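# cardiokit

Quantitative functional phenotyping of isolated cardiomyocytes, built as a
single tested pipeline: stimulus-locked Ca²⁺-transient and sarcomere-shortening
beat analysis, 3-D quantification of the transverse–axial tubular system
(TATS), dual-dye mitochondrial ratiometry, patch-clamp current and
action-potential metrics with model fits, and an equivalence-statistics layer
based on the two one-sided tests (TOST).

The package targets studies that must show two cell populations are *the
same* — for example, myocytes isolated immediately versus after cold storage
of the donor heart — where classical null-hypothesis testing cannot
distinguish "no evidence of a difference" from "evidence of no difference".
Every analysis stage is validated by parameter recovery against a
synthetic-data generator with known ground truth, so the whole chain is
testable without any external dataset.

## What it computes

**Beat analysis** (`cardiokit.beats`). Stimulation times come from peak
detection on the recorded stimulus voltage. The signal (Fura-2 340/380 ratio
or sarcomere length in µm) is filtered with a moving median (radius 10) then
a moving mean (radius 5), the global minimum (offset) is subtracted, and the
noise amplitude A_noise is the maximum of the signal over the 200 ms windows
preceding stimuli at pacing rates ≤ 1 Hz. A stimulus is *captured* iff a peak
at least 2·A_noise above the beat's diastolic level follows it. Captured
beats yield diastolic level, amplitude, TTP₉₀ (10 %-of-amplitude upstroke
crossing → peak), TTBL₉₀ (peak → 10 % crossing on decay), and
CATD₉₀ = TTP₉₀ + TTBL₉₀; the last six captured beats of each pacing interval
are averaged into the per-frequency summary. Sarcomere length itself is
estimated from the dominant striation frequency of a brightfield intensity
profile (Fourier analysis with sub-bin refinement).

**TATS imaging** (`cardiokit.tats`). From a membrane-dye confocal stack:
cell segmentation, interior tubule segmentation outside a 0.5 µm
sarcolemmal rim, then four metrics — volume density and 3-D skeleton density
(% of cell volume), mean Euclidean distance of every intracellular voxel to
its nearest tubule (anisotropic voxel spacing, µm), and a spectral
regularity score (power in the 1.5–2.5 µm period band of the longitudinal
occupancy profile over total non-DC power).

**Mitochondrial ratiometry** (`cardiokit.mito`). Cell masks from cytosolic
(auto)fluorescence; mitochondrial voxels above the within-cell histogram
mode + 2·SD of the MTG channel; mean channel intensities; ΣTMRM/ΣMTG as the
membrane-potential index; Pearson colocalization of the two channels.

**Electrophysiology** (`cardiokit.ephys`). AP metrics from the 30th paced
beat (RMP, dV/dt_max, overshoot, APD₂₀/₅₀/₉₀ and APD₀mV); I_to as
peak-minus-end-of-pulse density, I_K as end-of-pulse density, I_K1 as the
Ba²⁺-sensitive end-of-pulse difference current (pA/pF); Boltzmann fits of
activation/availability `y = 1/(1+exp(±(V50−V)/k))`; bi-exponential I_to
decay `I(t) = A_f e^(−t/τ_f) + A_s e^(−t/τ_s) + C` with c₁ = A_f/(A_f+A_s);
bi-phasic recovery from inactivation
`y(t) = 1 − a e^(−t/K_fast) − b e^(−t/K_slow)` on a paired-pulse protocol
whose interval grows by a factor of 1.5.

**Statistics** (`cardiokit.stats`). Welch's t test, Holm–Bonferroni
correction, and TOST equivalence with relevance bounds of ±30 % of the
control mean at α = 0.05: equivalence is declared when both one-sided tests
reject, equivalently when the (1−2α) confidence interval of the effect lies
inside the bounds. Relative bounds are tested as Welch comparisons against
the scaled control group, which keeps the test calibrated at the equivalence
boundary (see `docs/methods.md`).

**Synthetic data** (`cardiokit.synth`) generates every input modality with
machine-readable ground truth; `cardiokit.study` runs a complete two-group
synthetic equivalence study end-to-end.

## Worked example

```python
from cardiokit.synth import TransientSimSpec, gen_transient_trace
from cardiokit import beats, stats

rec, truth = gen_transient_trace(TransientSimSpec(seed=42))
noise, per_beat, per_freq = beats.analyze_recording(rec)
print(f"A_noise = {noise.a_noise:.4f}")
print(per_freq[["frequency_hz", "n_beats_used", "diastolic_level",
                "amplitude", "ttp90_s", "ttbl90_s", "catd90_s"]]
      .round(4).to_string(index=False))

est = stats.troponin_release_bound(0.045, 0.040, total_content_ug=0.35)
print(f"released <= {est.released_upper_bound_ug:.4f} ug; "
      f"damage fraction <= {100*est.damage_fraction_upper_bound:.2f}%")
```

prints

```
A_noise = 0.0719
 frequency_hz  n_beats_used  diastolic_level  amplitude  ttp90_s  ttbl90_s  catd90_s
       0.5000             6           1.0002     0.4985   0.0259    0.1592    0.1851
       1.0000             6           0.9997     0.5010   0.0261    0.1617    0.1878
       1.5004             6           1.0018     0.4966   0.0255    0.1610    0.1864
       2.0000             6           1.0036     0.4899   0.0248    0.1611    0.1859
       2.5000             6           1.0102     0.4913   0.0246    0.1538    0.1784
       2.9985             6           1.0368     0.4661   0.0244    0.1308    0.1552
       4.0000             6           1.1111     0.3988   0.0223    0.0975    0.1199
released <= 0.0018 ug; damage fraction <= 0.51%
```

The simulated cell is paced through the 0.5–4 Hz ladder (each interval at
least 24 stimuli or 12 s). All stimuli are captured; the diastolic level
rises and the apparent amplitude and transient duration shrink at fast
pacing as consecutive transients summate — the frequency response the method
is designed to resolve. The troponin lines bound cell damage during cold
storage: an assay that never reaches its 0.045 µg/L detection limit in 40 ml
of storage solution caps released troponin at 0.0018 µg, ≈ 0.5 % of a
heart's total content.

A command-line interface mirrors the library:

```bash
cardiokit simulate --kind transient --seed 7 --out trace.tsv
cardiokit beats trace.tsv --out mycell
cardiokit study --seed 7 --n-cells 10 --out study_out/
```

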