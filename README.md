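# fluorsense

Low-cost chlorophyll-fluorescence stress detection for plants, as a tested
Python pipeline.

## The problem

Most chlorophyll-fluorescence imaging (CFI) rigs quantify photosynthesis
with pulse-amplitude-modulated (PAM) fluorometry — accurate, but expensive.
A much cheaper alternative is to simply *image* the fluorescence a plant
emits under blue light through a long-pass filter with an ordinary 8-bit
monochrome camera. When a stressor such as the PSII-inhibiting herbicide
atrazine blocks photochemistry, the absorbed energy that can no longer
drive electron transport is re-routed to heat and to chlorophyll-*a*
fluorescence, so damaged tissue literally glows brighter — before any
visible symptoms appear.

`fluorsense` implements the analysis that turns three cheap measurement
streams into a stress verdict:

- **spectral**: leaf reflectance/fluorescence scans on a 450–770 nm grid,
  normalized to the scan at treatment time. The **nARFS** statistic is the
  mean normalized value over the chlorophyll-fluorescence waveband
  (669.8–760.7 nm). The per-wavelength standard deviation of the normalized
  series drives a two-band index, the **FBSI**:

  FBSI = (R_signal − R_reference) / (R_signal + R_reference)

  where the signal band is the most treatment-responsive channel best
  correlated with ΦPSII (far-red, ≈741 nm) and the reference is the least
  responsive channel (green, ≈549 nm) — the same normalized-difference form
  as NDVI or PRI, so a two-filter field sensor could measure it.
- **imaging**: mean pixel intensity of a 50 × 50 px region of interest in
  the 8-bit fluorescence frames, tracked over time.
- **fluorometry**: PAM yields ΦPSII = (Fm′ − Fs)/Fm′ and
  NPQ = (Fm − Fm′)/Fm′.

Per replication (never pooled), the pipeline reports Pearson correlations
between pixel intensity, ΦPSII, nARFS and FBSI, plus a dark-relaxation
study in which NPQ decays after a light exposure while ΦPSII and pixel
intensity recover.

Because the original raw data are not publicly accessible, the package
ships a first-class mechanistic simulator (`fluorsense.simulate`) that
generates all three streams with the physiological structure the analysis
assumes: a logistic ΦPSII collapse after an uptake lag, 680/740 nm emission
peaks shaped by within-leaf re-absorption growing on a realistic leaf
baseline, vein-first spatial spread of damage in the image stacks, and a
Stern–Volmer NPQ relaxation experiment.

## Worked example

```python
from fluorsense.report import atrazine_study_correlations

table = atrazine_study_correlations(base_seed=1, n_replications=3)
print(table.to_string(index=False))
```

```
replication_id  seed  n  r_pixel_phi  r_pixel_narfs  r_narfs_phi  r_fbsi_phi  signal_nm  reference_nm
            R1     1 33    -0.967425       0.976593    -0.998108   -0.997450 739.882353    591.803922
            R2     2 33    -0.970432       0.975986    -0.997971   -0.996006 738.627451    560.431373
            R3     3 33    -0.966253       0.976805    -0.997695   -0.994266 753.686275    502.705882
```

Each row is one simulated plant followed for 8 h at 15-min cadence
(33 timepoints). Reading R1: as atrazine shuts PSII down, ROI pixel
intensity rises while ΦPSII falls (r = −0.97), the rise in pixel intensity
tracks the rise of in-band reflectance/fluorescence (r = 0.98 against
nARFS), and both spectral indices are strong inverse proxies of ΦPSII
(r ≈ −0.99). The wavelength-selection procedure independently rediscovers a
far-red signal band (≈740 nm) and a green reference band in every
replication.

The same machinery is available from the shell:

```bash
fluorsense simulate atrazine --seed 1 --out-dir out/sim      # CSV + TIFF frames
fluorsense analyze spectra --spectra out/sim/R1/spectra.csv \
    --select-index --pam out/sim/R1/pam.csv --out out/spec
fluorsense analyze images --frames out/sim/R1/frames --roi 215,130,50,50 \
    --out out/intensity.csv
fluorsense run --seed 1 --out-dir out/report                 # full pipeline
```

`fluorsense run` writes per-replication time-course and variability CSVs,
a correlation table with OLS fits and p-values, a JSON summary, and the
report figures (normalized-spectra fan, variability curve, time courses,
correlation scatter panels).

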