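# Methods

## Problem and model

Short-term PM2.5 exposure risk depends on where pollution exceeds the
health guideline *and* on where people actually are at that hour. Survey-
derived population rasters describe residents but have no diurnal signal;
mobile-activity ("social media") density rasters resolve the hour but
systematically miss older adults, who generate little smartphone activity.
This package maps the *total* hourly exceedance PM2.5 exposure (HEPE) by
combining both sources.

For each hour and each population source, the indicator at grid cell *i* is

```
HEPE_i = share_i × EP_i
```

* `EP_i = max(c_i − T, 0)` is the exceedance concentration (µg/m³) above the
  guideline threshold `T` (default 25 µg/m³, the WHO short-term level);
  `c_i` is the PM2.5 concentration interpolated to the cell.
* `share_i` is the cell's normalized population share: raster values are
  min-max normalized to [0, 1] and then divided by their sum, so
  `Σ share_i = 1`. The two-step normalization makes sources with different
  units comparable, and makes HEPE exactly invariant under positive
  rescaling of a population raster — the raster's absolute magnitude
  (persons vs relative activity counts) is irrelevant, only its spatial
  pattern matters. A constant raster degenerates to equal shares `1/n`.

`HEPE_sm` uses the hourly ambulatory-population raster; `HEPE_psd` uses the
static modelled older-adult raster. HEPE is a relative risk surface
(share × µg/m³), not an absolute head-count burden.

The **contribution** of the older-adult component at a cell is
`100 × HEPE_psd / (HEPE_psd + HEPE_sm)`, undefined exactly where both are
zero; complementary contributions sum to 100% at every defined cell, and a
cell whose risk is carried entirely by one source reads 0% or 100%.

Hourly spatial pattern is summarized by the **weighted standard-deviational
ellipse (SDE)**: cell centers weighted by their HEPE value give a weighted
mean center, the orientation θ of the major principal axis (degrees
clockwise from north, in [0, 180)), and weighted SDs along the major/minor
axes. θ comes from the tan-2θ closed form for the direction of maximum
weighted second moment; variances are normalized by Σw. This is identically
the eigen-structure of the weighted covariance matrix, and the test suite
enforces agreement between the two routes to 1e-9. Common printed forms of
the SDE equations circulate with inconsistent squaring/normalization; the
covariance-eigen equivalence is the self-consistent reading and is the one
implemented. Diameters default to 2σ; some GIS tools inflate the axes by
√2, so the multiplier is a configurable `diameter_factor`.

## Pipeline

QC → interpolation → thresholding → normalization → HEPE (both sources) →
daily accumulation → contribution → SDE → center trajectories.

* **Station QC** deletes invalid/missing entries; a station with no valid
  hour is dropped; an hour with no valid station is skipped (never imputed)
  and listed in the run report.
* **Interpolation** is inverse-distance weighting with power 2
  (configurable). A cell center within half a cell of a station takes the
  station value exactly, which also guards the 1/d² weight against
  near-zero distances. IDW output is always bounded by the station min/max
  (no extrapolation). Concentration is interpolated first and thresholded
  second; thresholding per station and then interpolating would differ in
  boundary cells, and the chosen order keeps EP a deterministic function of
  a single interpolated surface.
* **Grids.** All computation happens on the fine analysis grid (north-up,
  projected meters, cell centers for all coordinate math). The coarse
  older-adult raster is disaggregated mass-preservingly — each coarse count
  split equally among its nested fine cells — because no finer-scale
  covariate is assumed; aggregation (fine→coarse) sums. Total population is
  conserved to < 1e-9 relative in both directions.
* **Rasters on disk** are ESRI ASCII grids (plain-text, georeferenced
  header, 17-significant-digit floats so read(write(x)) is bit-exact) with
  a `.prj` sidecar naming the CRS. Degree-unit CRS labels are rejected with
  an instruction to reproject; nodata and negative cells are zeroed on
  ingestion (a populated-or-zero reading of every cell) with a logged count.
* **Lon/lat** appear only at the reporting boundary (station CSV input,
  ellipse centers). A local equirectangular projection anchored at a
  reference coordinate converts between degrees and analysis meters; over a
  ~10 km domain its distortion is orders of magnitude below the cell size.

## Synthetic study scenario

The generator produces all three inputs with the structure the analysis
assumes, so every stage is testable without proprietary data:

* **Stations** (default 11) over a 10 × 10 km, 200×200-cell, 50 m grid,
  hours 10:00–23:00 — a window chosen so the guideline is first crossed at
  its opening hour. Each series is
  `(T + 0.5) + 0.87·(t − 10) + Σ bumps + tilt + noise`: trend slope
  0.87 µg/m³/h; Gaussian-in-time bumps at 13:00, 18:00, 22:00 (amplitude
  6 µg/m³, width 0.75 h — amplitudes that keep the planted local maxima
  detectable above station-mean noise); a fixed NW-high spatial tilt of
  1.5 µg/m³ across the domain; iid N(0, 2²) noise, truncated at 0 (a
  config switch marks negatives missing instead, exercising the QC path).
* **Ambulatory population**: hourly mixture of a "work" Gaussian blob
  (σ = 1.2 km) and a "home" blob (σ = 1.8 km); the work share is
  work-heavy through midday and drains monotonically toward home from late
  afternoon, so the population centroid — and with it the HEPE_sm ellipse
  center — commutes across the domain.
* **Older-adult population**: a single static, tighter blob (σ = 0.8 km)
  over an "old downtown" south-east of the work center, generated on a
  100 m grid deliberately so the disaggregation path always runs.

Masses (100 000 ambulatory, 20 000 elderly) are arbitrary by the
scale-invariance of the indicator. Fixed seed ⇒ byte-identical bundles.

What the generator does *not* emulate: urban morphology, road networks,
multi-day meteorology, spatially correlated measurement error, or any
absolute population magnitudes. Passing tests therefore demonstrate the
correctness and the qualitative behavior of the method (aggregated,
home-anchored elderly risk vs mobile ambulatory risk; planted diurnal
peaks recovered), not quantitative agreement with any real city's exposure
numbers, which require the proprietary inputs.

One estimator caveat: the planted diurnal bumps are not zero-mean over the
finite 14-hour window, so a raw OLS slope of the full series is biased
upward by construction (≈ +0.17 µg/m³/h at the defaults). The
trend-recovery statistic is therefore evaluated on the trend+noise
component (peak amplitude set to 0), which is the planted linear model the
estimator is meant to recover.

## Numerical choices and edge cases

* Thresholding is exact arithmetic `max(c − T, 0)`; EP is monotone in c.
* Isotropic or single-point weighted clouds have no defined orientation:
  θ is set to 0 and flagged `isotropic`; a single nonzero cell yields a
  degenerate ellipse (σ = 0) at that cell center; an all-zero field yields
  no ellipse and the hour is logged and skipped.
* Peak detection on temporal profiles = strict local maximum of the hourly
  mean; endpoints qualify against their single neighbor.
* Contribution values are clipped to [0, 100] to remove ~1 ulp float
  overshoot at pure-single-source cells.
* Equal-share degeneracy for constant rasters uses a relative tolerance of
  1e-12 on max − min.
* All problem sizes in the default tests and the acceptance script
  (200×200 fine grid, 14 hours, 200 Monte-Carlo replicates, 100
  oracle point sets) are the package's default study scale; the full
  pipeline completes in a few seconds on one CPU.

## Known limitations

* Relative risk only; no exposure head counts or health-outcome modelling.
* IDW is a deterministic interpolator with no uncertainty; kriging could be
  swapped in behind `interpolate_hour`.
* The older-adult raster is assumed static within the day.
* Hot/cold-spot classification of contribution surfaces is out of scope.
* The equirectangular lon/lat conversion is for city-scale reporting only.
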