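# Methods

## The measurement model

A pulse of black dye (solvent black 5) is injected at the inlet of a
twin-screw wet granulator at time T0. Granules leaving the outlet are
collected bottom-up in a glass tube until the tracer has cleared (time
T1), and the filled tube is photographed once. Because the collection
rate is assumed constant, the height coordinate of the tube is linear in
collection time: the tube bottom holds the material that exited first.
A single still image therefore encodes the full outlet concentration
history, which is what makes the method fast relative to sampling-based
residence-time measurements.

The analysis chain is:

1. **Detection region.** A vertical strip of fixed width (default
   100 px) centred on the tube axis, from the tube bottom to the granule
   top. The central strip avoids specular reflections off the glass.
   The granule top can be given manually or found automatically as the
   topmost image row whose blank-corrected darkness exceeds 2.0 (on the
   0–100 scale) for at least 3 consecutive rows; the run-length
   requirement rejects isolated noisy rows. Manual bounds always win.
2. **Grid division.** The region height is split into `n_grids`
   (default 200) contiguous row intervals differing in height by at most
   one pixel; when the height does not divide evenly the extra rows are
   assigned from the tube bottom up. Grid 0 is the tube bottom and maps
   to the earliest time bin.
3. **Lightness profile.** Each pixel is converted RGB → XYZ → Lab and
   the grid statistic is the arithmetic mean of L* over the grid
   rectangle (mean by default because it averages pixel noise; a median
   option exists for images with impulsive artifacts).
4. **Blank correction.** A tracer-free tube of the same formulation is
   photographed identically; the working signal is
   `max(0, (100 − L*_sample) − (100 − L*_blank))` per grid, removing the
   intrinsic color of the granules. Clipping at zero means a sample
   lighter than the blank reads as no tracer rather than negative
   concentration.
5. **RTD functions and moments.** With bin centers
   `t_i = T0 + (i + 1/2) Δt`, `Δt = (T1 − T0)/n`, the discrete density
   is `E_i = C_i / Σ_j C_j Δt_j`, the cumulative `F_i = Σ_{j≤i} E_j Δt_j`,
   and the moments `t_m = Σ t_i E_i Δt_i`,
   `σ² = Σ (t_i − t_m)² E_i Δt_i`, `σ_θ² = σ²/t_m²`. Rectangle-rule
   quadrature is used throughout to match the discrete sums of the
   defining equations.
6. **Regime label.** `σ_θ² = 0` is ideal plug flow and `σ_θ² = 1` an
   ideal perfectly mixed vessel; the classifier labels `plug_flow` for
   `σ_θ² ≤ tol`, `mixed_flow` for `|σ_θ² − 1| ≤ tol`, otherwise
   `intermediate`. The tolerance defaults to 0.05: only the ideal
   endpoints are defined by theory, so the band is a practical choice
   roughly matching the rounding precision of reported values.

## Color conversion choices

The RGB → XYZ step uses the standard linear-RGB/D65 matrix

    [0.412453 0.357580 0.180423]
    [0.212671 0.715160 0.072169]
    [0.019334 0.119193 0.950227]

applied to channel values normalized to [0, 1] (by 255 for 8-bit input,
65535 for 16-bit). Two deliberate choices:

* **White-point normalization.** XYZ values are divided by the row sums
  of the matrix (the image of pure white) before the companding
  function, so (255, 255, 255) maps exactly to (L*, a*, b*) =
  (100, 0, 0) and any gray is achromatic. Without this step white would
  not reach L* = 100.
* **Gamma handling.** The default `paper_literal` mode applies the
  matrix directly to the stored channel values with no gamma decoding.
  Camera files are usually sRGB-encoded and the matrix is strictly a
  linear-RGB matrix, so an `srgb_linearized` mode (decode with the sRGB
  EOTF first) is provided. Either mode is valid for RTD work as long as
  the blank, the sample and any concentration calibration go through the
  same pipeline, because the E(t) normalization cancels consistent
  monotone rescalings of the signal; the literal mode is the default.

The Lab companding function is `f(t) = t^(1/3)` for `t > (6/29)³` with
the matched linear segment `t/(3(6/29)²) + 4/29` below; L* is clamped to
[0, 100] after computation.

## Calibrations

Three straight lines back the workflow, all fitted by ordinary least
squares with `R² = 1 − SS_res/SS_tot` and a validity domain
`[min x, max x]`:

* concentration vs lightness, `C = −10.431 L* + 86.731` (wt%), used
  optionally — the default RTD runs on blank-corrected darkness because
  the normalization in E(t) cancels the slope, and the blank correction
  plays the role of the intercept;
* feeder mass flow vs opening percentage, `y = 0.2843x − 0.5803` g/min;
* pump liquid flow vs rotational speed, `y = 0.5822x − 0.5756` g/min.

Predictions outside the fitted domain raise an `ExtrapolationWarning`;
negative flow or concentration predictions are clipped to zero with a
warning (the concentration line crosses zero near L* ≈ 8.31).

`LinearCalibration` follows the scikit-learn estimator contract
(`fit`/`predict`, `get_params`, fitted attributes with trailing
underscores) so it composes with sklearn pipelines and model selection.

## Feed auditing

The feeder/pump audit works on cumulative delivered mass: the error
series is `err(t_i) = actual(t_i) − set_rate (t_i − t_0)/60` (g), split
into maximal signed runs outside a dead band (default 0 g; raise it to
suppress sensor noise). Episode end times extend one sample past the
last in-run sample, so a rectangular excursion's duration is recovered
to within one sampling interval. The normalized error of an episode is
its peak absolute mass error as a percentage of the set-point mass due
over the episode, `100·peak/(set_rate·duration/60)`. This definition
was chosen because it makes feeders running at different rates directly
comparable, which is the stated purpose of normalization; an
alternative normalization by total delivered mass is available via
`mode="total_delivered"`. Loss-in-weight recordings are converted to
delivered mass by subtracting from the initial hopper mass.

## Synthetic fixtures: what they emulate and what they do not

No experimental photographs ship with the method, so validation runs on
synthetic fixtures that invert the measurement pipeline:

* **Ground-truth RTD family.** Tanks-in-series (gamma) densities with
  shape N and mean `t_m`: closed forms (mean `t_m`, `σ_θ² = 1/N`) make
  the family self-checking, and N = 2–3 spans the intermediate mixing
  regimes (σ_θ² ≈ 0.3–0.6) typical of twin-screw granulation.
* **Tube renderer.** Per grid, the concentration
  `c_i = amplitude·E(t_i)/max E` is mapped to a target L* through an
  inverted linear calibration and then to a gray byte by bisecting the
  scalar gray → L* map to 1e−6 (numeric inversion keeps the renderer
  valid under either gamma mode). Gaussian pixel noise of configurable
  standard deviation (in gray levels) is added under a fixed seed; the
  blank image is rendered at the blank lightness.
* **Synthetic concentration line.** Round-trip tests use a calibration
  with slope −0.05 wt% per L* unit and intercept tied to the blank
  lightness so that zero concentration reads exactly zero after blank
  correction. A gentle slope spreads the working range over ~40 L*
  units, keeping 8-bit gray quantization far below the round-trip
  tolerances; a steep line would compress all concentrations into a few
  gray levels and the quantization would dominate.

The fixtures emulate per-pixel sensor noise and 8-bit quantization.
They do **not** emulate granule texture, uneven illumination, glass
reflections, perspective, or tube-filling irregularities — so passing
round trips demonstrate correctness of the computation chain, not
robustness to real-world imaging artifacts, which must be controlled
experimentally (centered region, blank correction, fixed camera
geometry).

### Problem sizes used in validation

Round trips use a 3-tank truth with `t_m = 100 s`, 200 grids over a
collection window of [0, 400] s (the window covers the gamma tail to
<1e−3 mass so truncation does not bias the moments), rendered at
1100 × 300 px with a 1000-row detection region (5 rows per grid). The
zero-noise round trip recovers `t_m` within 2% and `σ_θ²` within 0.02 of
the closed forms; with 2-gray-level pixel noise, within 5% and 0.05.
Closed-form limit checks discretize at `dt = t_m/1000`.

## Numerical notes and degenerate inputs

* An all-zero concentration (sample identical to blank) raises
  `NoTracerError` rather than returning NaNs.
* A single-bin series is legal: E integrates to 1, `σ² = 0`, plug flow.
* Reported `σ_θ²` is rounded to 2 decimals in summaries, matching the
  precision of published tables; full precision is kept on the result
  object.
* Published moment pairs were cross-checked by recomputing
  `σ²/t_m²` from tabulated `(t_m, σ²)`: one tabulated row (screw speed
  200 r/min) disagrees with its own printed `σ_θ²` by 0.01, presumably
  from unrounded intermediates; the self-consistent rows are the ones
  asserted in tests.
* Grid-to-time mapping assumes a constant collection rate; if the fill
  rate varies, times are distorted monotonically and the moments are
  biased accordingly. This is a physical assumption of the method, not
  a numerical choice.

## Known limitations

* The concentration calibration is linear only over the fitted dosage
  range; strong tracer loadings saturate darkness and would need a
  nonlinear model (out of scope).
* Flow-regime labelling with `tol = 0.05` is a convention; values near
  the band edges should be read as a continuum, not a hard class.
* The auto granule-top detector assumes the tracer-free head space is
  clearly lighter than filled tube; heavily soiled glass defeats it
  (use manual bounds).
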