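# retinerg

Structure–function analysis of the rodent retina, built for cross-sectional
genotype × age studies: full-field electroretinogram (ERG) waveform
decomposition, OCT layer-thickness summarization over an annulus,
western-blot densitometry normalization, and the accompanying statistics
(ROUT outlier screening, two-way ANOVA with Sidak contrasts, Deming
regression, Spearman correlation). A first-class synthetic-data module
simulates whole cohorts — down to raw waveforms and thickness grids — with
known ground truth, so every stage of the pipeline is verifiable without any
instrument data.

The package is aimed at visual-electrophysiology and retinal-imaging groups
who need a scripted, testable version of an analysis that is usually spread
across spreadsheets and GUI statistics packages.

## Models

**Photoreceptoral P3 (a-wave).** The leading edge of the first
electronegative component is modelled by the delayed-Gaussian saturation
function (Hood–Birch / Lamb–Pugh form):

```
P3(i, t) = -RmP3 · {1 - exp[-i · S · (t - td)²]},   t > td
```

with `i` the flash energy (cd·s/m², linear), `RmP3` the saturated amplitude
(µV), `S` a sensitivity scaling ((cd·s·m⁻²)⁻¹·s⁻²) and `td` a short delay.
One `(RmP3, S, td)` triple is fit jointly to the two brightest flashes of a
pathway (dark-adapted 1.55/2.07, light-adapted 2.20/2.72 log cd·s/m²).

**Bipolar-cell P2 (b-wave).** The fitted P3 is subtracted, the residual
P2–OP complex is low-pass filtered (zero-phase, net −3 dB at 46.9 Hz) to
remove oscillatory potentials, and the per-flash baseline-corrected positive
peaks are fit across all energies with the Naka–Rushton saturated
hyperbola:

```
V(i) = Vmax · iⁿ / (iⁿ + Kⁿ),   n = 1 by default
```

**Ganglion-cell pSTR.** The positive scotopic threshold response is the
mean positive peak at the two dimmest flashes (−5.01 and −4.90 log cd·s/m²,
60–200 ms after onset).

**OCT.** Layer thicknesses (RNFL, GCIPL, INL, OPL, ONL) are averaged over
an ETDRS-style annulus (default 3–6 mm diameters) centred on the optic
nerve head; total retinal thickness is the sum of the five layer means.

**Statistics.** Per-group ROUT screening (constant-model Motulsky–Brown at
Q = 1%), genotype × age fixed-effects ANOVA (Type-III sums of squares, sum
contrasts), Sidak-adjusted per-age contrasts, percent-of-reference scaling
(4-month wildtype, with a homozygous fallback for wildtype-null blot
targets), and Deming (λ = 1) plus Spearman association.

## Worked example

`python examples/simulate_and_decompose_erg.py` simulates a noiseless
18-flash session and decomposes it:

```
endpoint              planted   measured   err %
rod RmP3 (uV)         450.000    445.616    0.97
rod Vmax (uV)         600.000    595.435    0.76
rod K (cd.s/m2)         0.050      0.050    0.26
cone RmP3 (uV)        120.000    118.981    0.85
cone Vmax (uV)        150.000    149.272    0.49
pSTR (uV)              12.000     12.069    0.58
```

Each row compares a planted generator parameter with the value the
decomposition measures from the waveforms alone; sub-percent errors show
the pipeline inverts the generator. The other examples cover the annulus
summary (`oct_annulus_summary.py`), densitometry scaling
(`blot_normalization.py`) and a complete simulated study with ANOVA tables
and structure–function correlations (`cohort_study_end_to_end.py`).

A thin CLI mirrors the library (`retinerg simulate-erg`, `decompose`,
`oct-thickness`, `blot`, `stats`, `correlate`, `simulate-cohort`,
`run-study`); run `retinerg --help`.

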