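# Methods

## Scope and data flow

The package analyses cross-sectional two-genotype (wildtype vs homozygous
transgenic, "WT"/"HOM") mouse cohorts at 4, 6 and 14 months. Four input
streams exist: multi-flash ERG waveform families, segmented OCT
boundary/thickness rasters, per-lane densitometry tables, and a per-animal
cohort table joining the endpoints. Upstream acquisition and segmentation
(Ganzfeld stimulation, the scanner's layer segmentation, gel imaging) are
out of scope: the package consumes their outputs. Because no public dataset
accompanies this design, the `cohortsim` module simulates all four streams
with known ground truth; everything the analysis claims is checked against
those planted values.

## ERG generation

A sweep is 640 ms sampled at 4 kHz (2560 samples) with the flash 20 ms into
the sweep, leaving a pre-stimulus baseline. Each flash response is the sum
of:

* **P3**: `-RmP3·(1 - exp(-i·S·(t-td)²))` after the delay `td`, zero before.
  Defaults (healthy rod pathway): RmP3 = 450 µV, S = 900 (cd·s·m⁻²)⁻¹·s⁻²,
  td = 3.5 ms; cone pathway RmP3 = 120 µV, S = 600, td = 3 ms. The cone
  a-wave is genuinely small in mouse, which matters for its noise behaviour
  (below).
* **P2**: a unit-peak gamma kernel `(t/4τ)⁴·exp(4 - t/τ)` scaled by the
  Naka–Rushton value `Vmax·i/(i+K)`. Rod: Vmax = 600 µV, K = 0.05 cd·s/m²,
  τ = 22 ms (peak 88 ms); cone: Vmax = 150 µV, K = 25 cd·s/m², τ = 15 ms
  (peak 60 ms). Only the kernel's peak is measured downstream, so the
  kernel shape is a modelling convenience; its time constants are chosen so
  the b-wave's rise does not intrude into the a-wave fit window.
* **Oscillatory potentials**: a 135 Hz tone under a Gaussian envelope
  (centre 35 ms, SD 8 ms), scaled by the same Naka–Rushton fraction so OPs
  vanish at dim flashes.
* **pSTR**: a positive Gaussian bump (peak 110 ms, SD 25 ms, default
  12 µV), present only at the two dimmest dark-adapted flashes.
* **Noise and acquisition**: white Gaussian noise plus a zero-phase
  band-pass with net −3 dB corners at 0.3 and 1000 Hz, mirroring the
  recording chain. The 0.3 Hz high-pass visibly sags sustained a-wave
  plateaus (a few percent of RmP3 over a 600 ms sweep); this is a fidelity
  feature of the simulator, and parameter-recovery checks are therefore run
  with the acquisition filter disabled so they measure the estimator, not
  the recording chain.

Flash protocols default to 12 dark-adapted energies spanning −5.01 to
2.07 log cd·s/m² (including the pSTR pair −5.01/−4.90 and the rod P3 pair
1.55/2.07) and 6 light-adapted energies from 0.3 to 2.72 (including the
cone P3 pair 2.20/2.72). Every stochastic call takes an explicit seed;
there is no global random state.

## ERG decomposition

**Filters.** All filters are Butterworth applied forward–backward
(zero-phase). Because the two-pass magnitude is the square of the
single-pass response, corners are solved numerically so that the *net*
response is −3 dB at the nominal corner; the b-wave extraction filter is a
4th-order low-pass with net −3 dB at 46.9 Hz (DC gain exactly 1, ~0.1%
attenuation of the b-wave kernel itself, OPs at 135 Hz suppressed below
0.2%).

**P3 fit.** One `(RmP3, S, td)` triple is fit jointly (shared parameters,
stacked least squares) to the leading edges of the two brightest flashes of
a pathway. The fit window starts at flash onset and initially ends at the
a-wave trough, located as the *first local minimum* of a 46.9 Hz-smoothed
copy (the global minimum is wrong for unfiltered saturating responses,
which return to −RmP3 late in the sweep). After an initial fit the window
is capped at the time the model reaches 90% saturation and the fit is
repeated twice: the limb past that point is flat, so those samples carry
little information about the parameters while being increasingly
contaminated by the rising b-wave (uncapped windows bias RmP3 down by
2–5%). The optimizer is seeded from a coarse grid over S and td, bounded
below by zero, and its solution is cross-checked against a grid search in
the tests. Traces with no negative deflection deeper than 1 µV raise a
degenerate-fit error.

**P2 and Naka–Rushton.** The fitted P3 (evaluated at each flash's own
energy) is subtracted from every flash of the pathway; each residual is
low-passed and the baseline-corrected positive peak after onset is the
per-flash amplitude. The Naka–Rushton fit runs across all energies with
the exponent fixed at 1 (a flag frees it); all-zero amplitude maps return
Vmax = 0 with K undefined and flagged, negative amplitudes are clipped to
zero with a warning.

**pSTR.** Mean of the two baseline-corrected positive peaks at −5.01 and
−4.90 log cd·s/m², searched 60–200 ms after onset on a 46.9 Hz-smoothed
copy. The smoothing passes the ~6 Hz-bandwidth bump unchanged but removes
the upward bias that the running maximum of wideband noise would otherwise
add (~30% at single-sweep noise levels).

**Timing endpoints are deliberately absent**: the acquisition band-pass
distorts implicit times, so only amplitudes are reported.

Recovery performance (all measured by the tests and `scripts/acceptance.py`):
on noiseless families, RmP3 and Vmax recover within 1% and S, td, K within
5% for both pathways; with 20 µV additive noise the median error over 200
seeded runs is a few percent for the rod pathway. The cone a-wave is only
120 µV, so at 20 µV noise its median RmP3 error is ~11–12% — an
signal-to-noise property of the small cone response, not an estimator
defect, and consistent with cone P3 being the noisiest endpoint in
practice.

## OCT summarization

Thickness grids hold per-layer µm values on a shared regular raster (mm,
scan centre at the origin); boundary surfaces can be differenced into
layers, with crossing surfaces rejected pixel-count-first. The annulus mean
uses a pixel-centre inclusion rule on the half-open radial interval
[inner/2, outer/2) — unambiguous and testable — with NaN pixels excluded
but counted. Defaults: 3–6 mm diameters centred on the optic nerve head
(the outer ETDRS ring; the inner bound is configurable since only the
outer 6 mm diameter is canonical). On a 768-pixel-wide raster the annulus
mean of a linear radial profile matches the closed-form area-weighted
integral to well under 0.5% (measured ~0.001%). TRT is derived as the sum
of the five layer means (ILM→OLM), never stored, so additivity is exact on
NaN-free grids.

## Densitometry

Band density is normalized within-lane to the automated total-protein
measurement (scale-invariant to per-lane gain). Abundances are expressed
relative to the 4-month WT cohort mean; when that mean is indistinguishable
from zero — detected against a configurable epsilon (1e−12 of the cohort
maximum) because real densitometry never returns exact zeros, though the
simulator does for WT human/pSer129 α-synuclein — the 4-month HOM mean is
used and the switch is recorded. The composite "ALL" α-synuclein is the sum
of mouse, human and pSer129 species computed on the percent-of-reference
scale, since the three species carry different references; this is a
documented approximation of a composite that could equally be built on the
normalized scale.

## Statistics

* **ROUT** (per group): the regression-based outlier screen reduced to a
  constant model — robust centre = median, RSDR = 68.27th percentile of
  absolute residuals × n/(n−1), two-tailed t p-values (df = n−1) screened
  with the Benjamini–Hochberg step-up rule at rate Q (default 1%, the
  method's published default). Zero spread flags nothing. On clean Gaussian
  n = 20 groups the family-wise flag probability measures ~1% at Q = 1%.
* **ANOVA**: fixed-effects genotype × age with interaction, sum-to-zero
  contrasts and Type-III sums of squares (matching mainstream practice for
  the unbalanced cell sizes, 9–29 per cell); balanced designs reproduce the
  textbook decomposition to 1e−10. Zero residual variance with real group
  differences is reported as F = ∞, p = 0 with a degenerate flag.
* **Sidak**: `p_adj = 1 − (1 − p)^m`; per-age WT-vs-HOM contrasts use the
  pooled residual mean square, with m = number of ages.
* **Deming**: closed form with λ = Var(y-error)/Var(x-error), default 1
  (orthogonal regression; no error-variance information is assumed).
  Degenerate inputs (zero variance, zero covariance) raise.
* **Spearman**: mid-rank Pearson via scipy with the asymptotic p by
  default; a seeded permutation option exists for small n. Pooling both
  genotypes in correlation panels is the default (a per-genotype subset is
  a one-line filter on the cohort table).
* **Percent-relative**: values scaled to the age-matched WT mean; the
  reference band is the t-based 95% CI of the 4-month WT mean on the
  percent scale.

Mixed-effects/repeated-measures modelling is out of scope; animals are the
units of analysis.

## Cohort simulator

Endpoints are Gaussian around genotype × age means specified as
baseline-SD-unit shifts. Default effects mirror the qualitative pattern the
analysis is designed to detect — earliest/largest HOM deficits in ONL
thickness and cone b-wave Vmax, OPL thinning, slightly thicker GCIPL, late
RNFL thinning, spared pSTR and INL, elevated TH and mouse α-SYN, and
HOM-only human/pSer129 α-SYN rising with age; magnitudes are configuration,
not claims. A single per-animal latent severity factor `s ~ N(0,1)` adds
`+0.8·SD·s` to HOM α-SYN species and `−0.8·SD·s` to ONL and cone Vmax,
inducing the negative α-SYN ↔ structure/function correlations. Noise is
otherwise independent across endpoints — the simplest structure that is
analytically checkable; real data have richer covariance (bilateral eyes,
shared sessions), so passing tests demonstrate correctness of the
estimators under the stated model, not robustness to every real-world
dependence. Sex is recorded but has no effect by default.

Raw materialization: per-animal waveform families reuse the generator with
the animal's endpoints as parameters and 3 µV noise (the residual noise of
an averaged sweep — peak-picking endpoints would be biased by single-sweep
noise); thickness grids are flat per-layer profiles plus 1.5 µm pixel noise
so annulus means recover the planted endpoints within SE. With the
acquisition band-pass on, decomposed rod RmP3 sits a few percent below the
planted value (the high-pass sag described above); the attenuation is
genotype-balanced and does not disturb group inference.

Problem sizes used by the verification battery: 200 seeded runs for noisy
recovery and for power/correlation rates, 500 for the null-uniformity
check, 1000 for the outlier flag rate, and one full raw-waveform study at
2 genotypes × 3 ages × 16 animals; these sizes give stable rates while
keeping the whole battery to a couple of minutes.

## Known limitations

* The P3 window refinement assumes a b-wave that rises after the a-wave
  trough; pathologies with inverted or absent b-waves would need explicit
  windows.
* The Naka–Rushton fit with free exponent is weakly identified on sparse
  energy grids; the exponent is fixed at 1 by default.
* The simulator's OPs are a single-tone proxy; OP quantification is not an
  endpoint.
* Percent-composite "ALL" α-SYN depends on the reference convention (see
  Densitometry).
* Eye-level replication (two eyes per animal) is not modelled; each animal
  contributes one value per endpoint.
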