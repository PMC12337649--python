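# Methods

## The measurement problem

Three protocols sample the same bottom-ice algal community and disagree by
construction. A *scrape* sample takes the bottommost soft layer into
near-freezing filtered seawater (FSW), concentrates cells on a filter and
extracts the intracellular (IC) pool with hot water — the least stressful
route, and the only direct one. An *FSW-diluted core melt* buffers the
bottom 3 cm against osmotic shock for particulate measurements (chl a,
abundance, biovolume), and every concentration measured on it must be
multiplied by (V_fsw + V_melt)/V_melt. A *bulk melt* (no FSW) dilutes brine
conservatively along the line C(s) = C_ref·s/s_ref and osmotically shocks
the cells, releasing a fraction ρ of each IC pool into the meltwater.

The estimation chain links them through chl a as the common currency:

1. IC^B = (C_filtrate − C_blank) · V_extraction / m_chla, µmol (mg chl a)⁻¹.
   Replicate scrapes for a site-day are blank-corrected first, then averaged,
   then chl-normalised (this ordering minimises the leverage of blank noise).
2. Bottom-ice IC = IC^B · [chl a]_bottom-ice / 1000, µmol L⁻¹ of melted ice.
3. Per-cell-volume concentration = bottom-ice IC / biovolume · 10¹²,
   mmol L⁻¹; per-cell content = bottom-ice IC / abundance · 10⁹, fmol cell⁻¹.
   These satisfy content/concentration ≡ biovolume/abundance (the community
   mean cell volume) exactly, which the tests assert to 1e-9 relative.

Blank correction clips negative differences to zero and flags the sample
rather than propagating negative concentrations.

Season summaries support two averaging orders: per-sample quantities
averaged last (default) or ratio-type rows recomputed from season-mean
numerator and denominator. They differ because a mean of ratios is not the
ratio of means; only the second makes the per-cell and per-cell-volume
summary rows exactly consistent with the mean cell volume.

## Retention inference

Bulk-melt concentration is modelled as brine background plus the released
fraction of the bottom-ice IC pool. `RetentionModel` subtracts the
background predicted by the water-column dilution line at each sample's
bulk salinity (switchable off) and fits a standardized major axis (SMA)
regression of bulk on bottom-ice IC. SMA is used because both axes are
estimated with error from independent measurements; its slope is
sign(r)·s_y/s_x, its p-value that of the Pearson correlation. The slope
estimates the release fraction ρ; 1/slope is the apparent dilution of the
pool in a bulk measurement. The generator's defaults are full release for
nitrate+nitrite (ρ_N = 1) and ρ_Si = 1/11 for silicic acid, whose uptake,
binding and vesicle transport machinery plausibly resists osmotic release.

Because multiplicative measurement noise inflates the variance of both
axes, the SMA slope carries a small attenuation/inflation trade-off; at the
default 10% instrument noise the recovered N slope is biased low by ~4%
(median ≈ 0.96–0.97 across campaigns) and the Si reciprocal slope high by
~5% (median ≈ 11.5), both comfortably inside the 20% recovery band the
tests require.

## Tidal forcing and time series

Currents are built from the two semidiurnal constituents, u(t) = A_M2
sin(2πt/12.42 h) + A_S2 sin(2πt/12.00 h) + ε; the daily maximum of |u|
carries the spring–neap beat with period 1/(1/12.00 − 1/12.42) ≈ 355 h ≈
14.8 d. Defaults A_M2 = 0.12, A_S2 = 0.06 m s⁻¹ give daily maxima of
~0.06–0.18 m s⁻¹, typical of landfast-ice channel flows.

`TidalTrendModel` works on site-averaged series (mean ± SD across the snow
classes per date; SD flagged undefined for single-site dates). It fits OLS
trends against fractional days from campaign start, correlates the
detrended residuals with the daily maximum current at lags of 0 and 1
*sampling cycles* (one row of the 3–4-day grid, not a fixed day count;
same-day matching by default, linear interpolation as an option), and fits
the exponential decay of the IC N:Si ratio by OLS on its natural log.
Significance uses the two-level convention: p < 0.01 "significant",
p ≤ 0.1 "weak". No multiple-testing correction is applied anywhere, and the
report footer says so.

In the generator, coupling is parameterised by a target correlation r*
rather than an oscillation amplitude (only correlations are observable at
these sample sizes): both IC series receive a·F_std with
a = r*/√(1−r*²)·σ_process on top of Gaussian process noise σ_process
(defaults 1.5 and 6 µmol (mg chl a)⁻¹ for N and Si, ~10% of the seasonal
means). Measurement noise then attenuates the observed correlation
slightly; with r* = 0.5 on the 12-date grid the median recovered lag-0
correlation is ≈ 0.55. Note the finite-sample floor: with 12 dates the
*null* correlation has sd ≈ 0.3, so individual null campaigns routinely
show |r| up to ~0.5 — only the median across campaigns (≈ 0.08 magnitude
under the null) is a sharp diagnostic, which is how the tests phrase it.

## What the generator emulates — and what it does not

Emulated: the linearly declining bloom (areal chl a 90 → ~7 mg m⁻² over
41 d, site factors 1.2/1.0/0.8 for thin/medium/thick snow), opposing linear
IC^B trends (N 16 → ~10, Si 40 → ~78 µmol (mg chl a)⁻¹; an exponential
mode makes ln(N:Si) exactly linear), abundance proportional to chl a
(1.72×10⁵ cells L⁻¹ per mg m⁻³, matching observed season scales),
biovolume = abundance × 1890 µm³ mean cell volume, water column at
N = 7.67, Si = 14.7 µmol L⁻¹ and salinity 32, bulk salinities uniform in
4–12, daily hot-water blanks (0.3/0.5 µmol L⁻¹), unit-mean lognormal
instrument noise (cv 0.1) and Poisson counting error with 400 cells
enumerated (cv 5%).

Not emulated: taxon-level composition and geometric biovolume formulas
(abundance/biovolume are supplied directly), brine drainage and mushy-layer
physics, uptake kinetics, biofilm retention, spatial structure beyond the
three-site factor, and serially correlated instrument drift. Passing
recovery tests therefore show the *estimator chain* is correct and unbiased
under a plausible error model — not that real field data meet that error
model; in particular chl a per cell varies with acclimation in ways the
generator's fixed proportionality does not capture.

## Numerical and design choices

* The brine relation's validity is enforced as −22.9 °C ≤ T < 0 °C, its
  customary range; out-of-range temperatures raise errors naming the bound.
* "On the dilution line" means within 15% of the line's prediction with an
  absolute floor of 0.2 µmol L⁻¹ (the floor keeps near-origin samples from
  being classified by a vanishing relative band). Classification is
  invariant under common rescaling of sample and reference concentrations.
* Acidification fluorometry uses a default maximum acid ratio of 2.2,
  typical of the instrument class; it is a per-reading parameter.
* SMA with exactly zero correlation has an undefined slope sign; the
  positive root is returned with a `sign_undefined` flag. Pearson on a
  zero-variance input returns NaN with a `zero_variance` flag rather than
  raising.
* Kruskal–Wallis switches to exhaustive permutation below 11 total
  observations (≤ 12,600 partitions), chi-square above; both use the
  tie-corrected H.
* The exact inversion property (noise off ⇒ analysis output equals
  generator truth, retention slopes exactly 1 and 1/11) pins the unit
  bookkeeping of the entire chain and is asserted in the tests.
* Recovery experiments use ~54 site-day campaigns (59-day season, decline
  −1.3 mg m⁻² d⁻¹ so the bloom stays positive throughout); the 12-date
  41-day grid (`SimConfig.grid_2010()`) is used for the time-series
  experiments.

## Known limitations

Retention is treated as a constant fraction per nutrient, not a function of
melt duration or salinity shock magnitude. Residual-correlation inference
ignores serial correlation in the forcing (the beat is smooth), so its
p-values are mildly anticonservative on short grids. The loader validates
the package's own CSV schema; mapping externally named columns is left to
the caller.
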