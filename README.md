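# granulab

Image-based residence-time-distribution (RTD) measurement for
continuous twin-screw wet granulation (TSWG).

## The problem

The RTD of a continuous granulator — the probability distribution of
times material spends inside the barrel — characterizes its mixing
behavior and underpins quality-control decisions (disturbance tracking,
material traceability, diversion of off-spec product). Conventional
tracer methods need repeated sampling and offline assays. The method
implemented here needs a single photograph: a pulse of black dye is
injected at the inlet at time T0, the exiting granules are collected
bottom-up in a glass tube until T1, and the tube is photographed once.
Tube height is linear in collection time, so the per-height darkness of
the photograph *is* the outlet concentration history.

`granulab` is for process engineers and PAT (process analytical
technology) developers who want that pipeline as an auditable library
and command line tool.

## The model

From the photograph, a 100-px-wide central detection region is divided
into 200 grids along its height; each grid's mean CIELAB lightness L*
(computed via RGB → XYZ → Lab with D65 white-point normalization) gives
a darkness signal `100 − L*`, blank-corrected against a tracer-free
sample. With bin centers `t_i` and widths `Δt_i` over [T0, T1]:

```
E(t_i)  = C_i / Σ_j C_j Δt_j            (RTD density, 1/s)
F(t_i)  = Σ_{j≤i} E(t_j) Δt_j           (cumulative RTD)
t_m     = Σ_i t_i E_i Δt_i              (mean residence time, s)
σ²      = Σ_i (t_i − t_m)² E_i Δt_i     (variance, s²)
σ_θ²    = σ² / t_m²                     (dimensionless variance)
```

`σ_θ² = 0` is ideal plug flow, `σ_θ² = 1` an ideal perfectly mixed
vessel; intermediate values are labelled accordingly. Supporting
modules fit and apply the linear feeder/pump/concentration calibrations
and audit feeder delivery accuracy (signed deviation episodes with
normalized errors). See `docs/methods.md` for the full account.

## Worked example

Render a synthetic tube photograph from a known 3-tanks-in-series RTD
(true `t_m = 100 s`, true `σ_θ² = 1/3`), add 2 gray levels of pixel
noise, and measure it back:

```python
from granulab.rtd import image_to_rtd
from granulab.synth import (TanksInSeriesSpec, TubeImageSpec,
                            render_tube_image,
                            synthetic_concentration_calibration,
                            tanks_in_series_E)

tanks = TanksInSeriesSpec(n_tanks=3, t_m_true=100.0)
spec = TubeImageSpec(noise_sigma=2.0, seed=7)
cal = synthetic_concentration_calibration(spec.blank_lstar)
sample, blank, _ = render_tube_image(
    lambda t: tanks_in_series_E(tanks, t), cal, spec, t0=0.0, t1=400.0)

res = image_to_rtd(sample, blank, spec.region(), t0=0.0, t1=400.0)
s = res.summary()
print(f"t_m = {res.moments.t_m:.1f} s, sigma2 = {res.moments.sigma2:.0f} s^2, "
      f"sigma_theta2 = {s['sigma_theta2']:.2f} ({s['regime']})")
```

prints

```
t_m = 99.3 s, sigma2 = 3158 s^2, sigma_theta2 = 0.32 (intermediate)
```

i.e. the measured mean residence time is within 1% of the 100 s truth,
the dimensionless variance 0.32 sits on the 1/3 closed form, and the
flow is correctly classified between plug and mixed flow.

The same pipeline runs from the shell:

```bash
granulab simulate --out sim --n-tanks 3 --t-m 100 --noise-sigma 2
granulab analyze --sample sim/sample.png --blank sim/blank.png \
    --t0 0 --t1 400 --center-column 150 --row-bottom 1050 --row-top 50 \
    --out rtd_out
granulab audit-feed sim/feedlog.csv --set-rate 15
```

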