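# echofish

Turns screen-captured echogram frames from an uncalibrated recreational
fish-finder into quantitative fish-school data, cross-calibrated against a
scientific echo-sounder:

- **Frame ingestion** — indexed-colour PNG frames + a CSV sidecar log
  (capture time, position, displayed depth range per frame); overlapping
  duplicate columns between contiguous frames are removed and every ping
  column is georeferenced by interpolation between frame fixes.
- **Noise mitigation** — seabed tracing by dynamic programming over an
  upper-edge map (exact optimum, tunable anti-vertical penalty, bounded
  per-column transition), sub-seabed masking, median-filter despeckling,
  and robust removal of vertical noise columns.
- **School extraction** — 8-connected candidate detection, exclusion rules
  (nearfield depth < 3 m, altitude < 0.5 m, size < 1×1 m, mean S_v <
  −65 dB), linking-ellipse aggregation (10×2 m) with a 10×5 m minimum
  school size, and extraction of the full descriptor schema (depths,
  altitudes, areas with/without vacuoles, perimeter, calliper diameters
  and orientation, georeference, per-colour pixel histogram) to CSV.
- **Pixel calibration** — affine colour-index → S_v mappings, grid search
  of (starting value, colour step) against matched reference schools for
  three pixel-skewness scenarios, and a log10 least-squares correction
  that de-saturates the fish-finder's compressed dynamic range, plus 4 dB
  binning, Wilcoxon signed-rank comparisons and depth-dependence checks.
- **Relative abundance** — nautical area scattering coefficients (s_A)
  per 500 m elementary distance sampling unit, presence contingency
  between systems, matched-descriptor regressions, and rolling-window
  concordance across spatial scales (0.5–18 km).
- **Synthetic surveys** — a ground-truthed generator (seabed, schools,
  speckle, noise columns, frame overlap, display saturation) that closes
  the test loop without any external data.

## CLI

```sh
echofish simulate  --seed 1 --n-schools 5 --speckle 0.01 --out sim/
echofish process   --frames-dir sim/ --sidecar sim/sidecar.csv --out proc/
echofish calibrate --matched-values S5_File.csv --matched-params S6_File.csv --out cal/
echofish abundance --ses-table S3_File.csv --rff-table S4_File.csv \
                   --matched-values S5_File.csv --matched-params S6_File.csv --out ab/
```

## Layout

```
src/echofish/
  echogram_model.py     frame/track/school data model and I/O
  seabed_noise.py       edge detection, DP seabed trace, despeckle, noise columns
  school_extraction.py  candidates, filters, linking ellipse, descriptors
  pixel_calibration.py  colour->Sv mapping, grid search, saturation correction
  abundance.py          EDSUs, s_A, contingency, rolling-scale concordance
  synthetic_echogram.py ground-truthed fixture generator
  pipeline.py           end-to-end frame processing
  report.py             headline quantities from deposited tables
  cli.py                click entry points
```
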