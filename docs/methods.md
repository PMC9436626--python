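# Methods

## Scope and model

`qamsherb` implements a complete quality-evaluation computation for a
four-alkaloid HPLC assay of Berberidis Cortex: linear calibration with
LOD/LOQ from signal-to-noise, external-standard quantification (ESM),
single-marker quantification (QAMS) through relative correction factors
and relative retention times, their comparison by the signed standard
method difference (SMD), method-validation statistics, common-peak
fingerprints with similarity scoring, and batch classification by
hierarchical clustering and correlation-matrix PCA.

QAMS assumes each analyte's detector response is proportional to its
on-column amount within the working range, so the ratio of response
factors — the relative correction factor

    f_{s/i} = (A_s · C_i) / (A_i · C_s)

— is a constant of the method, estimated once by multipoint correction
over a six-level injection-volume series (1, 2, 4, 6, 8, 10 µL of the
mixed standard, modeled as on-column fractions 0.1–1.0 of stock) and
then applied to unknown samples as W_QAMS,i = f·(A_i/A_s)·W_s. The
internal standard (berberine hydrochloride) is quantified by its own
calibration line; the extraction factor (20.0 mL extract per 0.5 g
powder, ×40) cancels in the ratio. Relative retention time
RRT = t_R(i)/t_R(s) locates targets across instruments and columns;
per-analyte assignment takes the peak minimizing |RRT − expected|
within a tolerance (default 0.03, about the spread of published RRTs
across six instrument×column conditions), and two analytes claiming one
peak is an error rather than a silent choice.

All relative standard deviations use the sample SD (n−1). This
convention was fixed by recomputing the published multipoint-f,
RRT and robustness tables from their per-level entries: sample-SD RSDs
reproduce the printed summary rows (verified programmatically by
`verify_reference_tables` / `analysis/06_verify_published_tables.py`).
One printed RSD (0.38 % for the palmatine correction factor) is not
reproducible from its own six printed values (sample SD gives ≈ 0.44 %);
it is carried in the reference tables but marked non-binding.

### A note on the published calibration intercepts

The published calibration lines carry large intercepts (for
magnoflorine the intercept exceeds the slope·concentration term over
the whole linear range). Combined with ratio-based single-marker
quantification these would make f strongly level-dependent, which the
published per-level f values (RSD < 1 %) contradict. The synthetic
sample system therefore uses proportional response (the published
slopes, zero intercept), under which the true correction factors are
the slope ratios f_{s/i} = k_s/k_i — within a few percent of the
published f values, confirming the proportional reading. The full
published lines are retained wherever the calibration fit itself is the
object under test.

## Synthetic data

The generator emulates the study design, not detector physics:

* **Peaks** are pure Gaussians (no tailing); the integrated area is the
  linear response `slope·conc + intercept` and the height follows as
  `area/(σ√2π)`. An exponentially-modified shape is out of scope — the
  Gaussian keeps the integration oracle closed-form.
* **Per-run randomness**: i.i.d. Gaussian intensity noise (default SD
  150 detector units, arbitrary scale — no real mAU scale is claimed),
  retention-time jitter (SD 0.02 min), and an optional polynomial
  baseline drift. One explicit integer seed per call; identical seeds
  give bit-identical traces.
* **Acquisition**: 35-min runs at 60 points/min; peak σ = 0.08 min,
  typical of well-retained peaks on a 250 mm column. With the published
  response slopes this puts every quantified peak at S/N ≳ 80, the
  regime the published sub-percent RSDs imply.
* **Elution positions** reproduce the published mean RRTs on a 27.0-min
  internal-standard peak; seven unidentified matrix peaks complete the
  11-peak fingerprint, with the four alkaloids 4th, 9th, 10th and 11th
  in elution order as observed.
* **Batches**: ten batches in a 6-vs-4 origin split. Alkaloid mass
  fractions per group follow the published ten-batch table (e.g.
  berberine ≈ 30.5 vs 23.9 mg/g); unknown-peak means shift 15–60 %
  between origins, mirroring the origin-driven block structure of the
  published heatmap; within-group variation is log-normal with CV 5 %
  (the published same-origin pairs differ by 2–4 %). Between-group
  contrast is geometric (`effect` interpolates group 2 between group
  1's profile and its own; 0 = identical groups).

What the generator does **not** emulate: peak tailing and co-elution
shoulders, gradient-dependent baseline structure, detector saturation,
inter-day drift, or real spectral noise. Passing tests therefore show
the computations are correct and robust under idealized chromatography;
they do not certify performance on degraded real-world traces.

## Numerical choices

* **Peak detection** runs on a lightly smoothed trace (7-sample moving
  average when noise is present): candidate apices must exceed
  `min_snr` × noise SD in height and prominence and a minimum width
  (default 0.05 min), which suppresses single-sample noise excursions.
  The apex rt is refined by parabolic interpolation over the three top
  samples, decoupling rt resolution from the sampling rate.
* **Bounds** sit at flanking valleys of the smoothed trace
  (perpendicular drop between fused peaks; ties break to earlier time),
  tightened toward the apex to where the signal returns to the local
  baseline level — the region median, capped by the valley floor —
  so long flat stretches are excluded while tails are kept.
* **Integration** is trapezoidal above a straight line between the
  bounds. With noisy data the line is anchored on the median intensity
  just *outside* each bound (capped by the at-bound level): anchoring
  on the bound samples themselves would sit on the peak tail and
  subtract a constant area from every peak, biasing small peaks
  relatively hardest. A `baseline="none"` mode integrates the raw
  signal (exactly additive over adjacent bounds).
* **Noise estimation** is the SD of linearly detrended intensity in a
  stated blank window (≥ 20 points), so baseline drift does not inflate
  it. S/N is peak height over noise SD, not peak-to-peak noise.
* **LOD/LOQ** come from the height-response slope: the concentration
  whose predicted height reaches 3 (10) × noise SD, hence
  LOQ/LOD ≡ 10/3. A bisection "dilution search" mode cross-checks the
  closed form. Negative implied ESM concentrations are clipped to zero
  with a warning (blanks legitimately produce them).
* **Fingerprint alignment** is multipoint: a first grouping pass on
  internal-standard-scaled retention times, then a per-batch linear
  time correction fitted on groups shared by at least half the batches,
  then regrouping. The 0.1 "time window" is interpreted in minutes on
  the reference time axis (configurable); common peaks are the strict
  all-batch intersection, with a presence-fraction mode for exploration.
* **Clustering** defaults to Ward linkage on Euclidean distances of the
  column-z-scored matrix (peak areas differ by orders of magnitude).
  The linkage is not dictated by the published account; average and
  complete are selectable. Merge heights can be rescaled to the 0–25
  dendrogram axis used by common statistics packages so that cuts
  quoted on that axis (e.g. 15) are interpretable. Cluster labels and
  dendrogram leaf order are canonicalized by each subtree's lexically
  smallest row id, making results invariant to input row order.
* **PCA** eigendecomposes the correlation matrix — the convention
  pinned by the published eigenvalue table, whose % variance equals
  100·λ/11. Loading signs are fixed by making each component's
  largest-magnitude loading positive. Rank-deficient inputs yield
  trailing zero eigenvalues, not errors; constant columns are dropped
  with a warning before standardization.
* **Similarity** defaults to cosine against the column-mean reference
  fingerprint, with Pearson also reported (the pharmacopoeial software
  computes both; which one the published value used is unstated).
* **Rounding** in report tables is half-away-from-zero on the decimal
  representation (4 decimals for f and RRT, 2 for RSD %); internal
  arithmetic is full precision.
* **Purity correction**: certified standard purities (85.7–98.0 %) are
  carried in the reference data but applied only behind a config flag
  (off by default), since the published tables do not state whether
  they were applied.

## Problem sizes

The default study is 6 standard injections + 10 sample injections of
2101 points each (plus 24 injections for the four simulated robustness
conditions); the full pipeline runs in well under a second per seed.
Multi-seed metrics (cluster recovery, QAMS bias) use 100 replicates at
the peak-area level, where chromatogram synthesis adds nothing to what
is being measured.

## Known limitations

* Co-eluting peaks are split at the valley, not deconvolved; severely
  fused peaks will bias both areas.
* The published raw chromatograms are not available, so
  chromatogram-dependent published results (the 11 common peaks, the
  >0.993 similarity, the specific two-cluster split, the eigenvalue
  magnitudes) are validated as properties on synthetic data with known
  truth, not reproduced numerically; everything computed from published
  per-level tables is reproduced exactly.
* ESM quantification near the bottom of the calibrated range is
  sensitive to intercept estimation error; the QAMS route is less so.
  The pipeline reports both so the difference is visible as SMD.
* The simulator's intensity units are arbitrary; LOD/LOQ values from
  simulated noise are internally consistent but not comparable in
  absolute terms to the published mg/mL limits.
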