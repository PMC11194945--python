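# Methods

## The assay and its estimator

A pooled competition assay measures, for every (prey variant, bait partner)
plasmid in a library, the growth rate of the yeast cells expressing it under
methotrexate selection. Input and output samples are sequenced to a fixed
depth; with population optical densities OD_in at inoculation and OD_out at
harvest, and growth time T hours, the per-variant estimate is

    g_hat_v = [ log2( fOut_v / fIn_v ) + log2( OD_out / OD_in ) ] / T

with f the within-sample frequencies. The frequency ratio measures enrichment
relative to the population; the OD term restores the population's own
doublings; division by T converts to generations per hour. Because harvest is
triggered at a fixed number of population doublings G (OD_out/OD_in = 2^G),
the estimator satisfies an exact algebraic identity on any unfiltered sample
pair:

    Σ_v fIn_v · 2^(g_hat_v · T) = OD_out / OD_in

which the test suite asserts on every expected-value simulation (tolerance
1e-9). Frequencies are always computed over the full matched variant set
*before* count filtering so that denominators describe the sequenced
population and are stable under filter-threshold changes.

Replicates are merged per variant as the mean over the replicates in which
the variant survived filtering (n recorded per variant; this maximises
retention); the standard error is the sample standard deviation over
replicates divided by √n, undefined (NaN) at n = 1.

## Forward model

The simulator composes five stages, each with known ground truth.

**Thermodynamic map.** Binding free energy dG maps to fraction bound
f = 1/(1 + exp(dG/RT)) (two-state model; RT = 0.593 kcal/mol, ~25 °C) and
then linearly to a growth rate r = r_min + (r_max − r_min)·f, floored at a
dose-dependent background r_bg(dose) = r_bg0 · dose^(−0.6), clipped to
[r_min, r_max]. Defaults r_min = 0, r_max = 0.23 gen/h, r_bg0 = 0.016 gen/h
at 1X methotrexate (200 µg/mL) place the upper mode near 0.23 and the
background floor near 0.016, the scale of observed rate distributions in
such screens; the power-law exponent 0.6 reproduces the observed ~6-fold rise
of background growth between 1X and 1/20X dose. Dose 0 (solvent control)
means no selection: every cell grows at r_max. These are stated simulator
defaults, not values fitted to any dataset.

**Library.** The default prey is a 32-residue segment of the human JUN
leucine zipper, giving 19 × 32 = 608 single substitutions plus the wild type.
Bait panels: balanced (FOS/ATF7/NFE2), slow (ATF2/ATF7/NFE2), fast
(FOS/ATF7/JDP2), with illustrative baseline energies ΔG0 of −4 (JDP2), −3
(FOS), 0 (ATF7), +1 (ATF2), +2 (NFE2) kcal/mol spanning non-interactor to
strongest interactor. Mutations act additively on the free energy of every
complex: dG(v, p) = ΔG0_p + δ_v with one shared perturbation per variant,
δ ~ Normal(1.0, 1.0) kcal/mol (mostly destabilising, as single substitutions
typically are) and δ_WT = 0. Each prey variant carries one or more random
24 bp barcodes, each bait a 20 bp barcode; injectivity is enforced by
rejection-resampling.

**Transformation.** Each of n_founders cells draws a plasmid multiplicity
m ~ zero-truncated Poisson(λ) (untransformed cells are invisible to
selection) and m plasmids i.i.d. from the pool. λ is proportional to DNA
mass; the default calibration puts λ(1 µg) ≈ 0.05, the regime in which the
double-transformant fraction grows linearly with DNA. Sampling is exact
inverse-CDF through the untruncated Poisson.

**Growth and harvest.** For t_lag hours (default 2.5 h) every clone grows at
a common lag rate r_lag (default 0.23 gen/h — full unselected growth on
stored metabolites); afterwards each clone grows exponentially at the
*maximum* rate over its plasmids (the strong pair dominates; an optional
multiplicative penalty, default 1.0, models interference between
co-transformed plasmids). Harvest time T solves

    Σ_c a_c · 2^(r_lag·t_lag + r_c·(T − t_lag)) = 2^G · Σ_c a_c

by bisection to 1e-10, matching the OD-triggered protocol; if the lag alone
reaches G doublings, T = G/r_lag. Two protocols: *standard* takes the input
sample before methotrexate, so T includes the lag and the closed-form bias
g_hat = (r_lag·t_lag + g·(T − t_lag))/T applies exactly (verified to 1e-9
against the simulator over a 100-point grid, and invertible by
`invert_lag_bias`); *pre-incubation* takes the input after t_lag hours in
methotrexate and re-inoculates, removing the lag from the recorded time so
g_hat = g in the deterministic limit.

**Sequencing.** A variant's read weight sums, over clones carrying it,
abundance × (copy count / clone multiset size): each plasmid copy contributes
an equal, copy-number-neutral share. Counts are one multinomial draw at the
configured depth (stochastic mode) or exact expectations (expected-value
mode, used by the oracle tests; with `force_single_plasmid` the whole run is
deterministic). An optional FASTQ writer emits 50 bp error-free reads
(24 bp prey barcode + 20 bp bait barcode + 6 bp constant spacer, Phred 'I');
this layout is a convention of the package, documented in `ReadLayout`.

**Plasmid loss.** Off by default (measured double fractions are stable over
selection); the `loss_rate` knob retains each plasmid copy beyond a
guaranteed one with probability (1 − loss)^G — a crude device for exploring
sensitivity, not a calibrated kinetic model.

## Read counting

A read is counted iff its mean Phred score is ≥ 20, the constant region
matches exactly, and the barcode pair matches the map exactly (no fuzzy
matching, no UMIs). The Phred criterion is applied per read; a per-sample
mean interpretation also exists in the field and can be emulated by setting
the threshold to 0 and inspecting the QC summary. Barcodes of the same
variant are summed; variants with < 10 reads in any input or < 1 read in any
output sample are dropped, with a per-variant reason report.

## Mode finding

Rate distributions are summarised by a Gaussian kernel density (Silverman's
bandwidth, 512 grid points, grid extended 3 bandwidths beyond the data range
— all four choices config-exposed) and modes are grid points whose density
strictly exceeds both neighbours; plateaus are therefore not modes, and the
smallest/largest mode positions are reported as the lower/upper mode. Mode
positions on plateau-free densities are stable to grid refinement within one
grid step (tested 512 → 2048).

## Double-transformant estimation

Two-marker plating: culture-level counts per plate class are pooled with the
ratio-of-sums estimator Σ colonies / Σ plated fraction (robust to low-count
plates; per-plate ratios would overweight small plates). The
post-transformation estimate is 2·n_AB/(n_A + n_B − n_AB)·100% and the
post-selection estimate 2·n_AB/(n_A − n_AB)·100%. The factor 2 assumes
double transformants split 25/50/25 across marker compositions, exact for
cells with exactly two plasmids. Under the full zero-truncated Poisson
model, cells with m ≥ 3 plasmids are over-counted: the estimator's exact
expectation is Σ_m P(m|m≥1)·2·(1 − 2^(1−m)), which at λ = 0.2 is 9.99%
against a true ≥ 2-plasmid fraction of 9.67%. The package implements the
estimators exactly as defined and reports this bias analytically
(`eq1_expectation`, `DoubleTransformantResults.expected_bias`) rather than
correcting it. Estimates above 100% are flagged invalid, not clipped — they
signal violated assumptions.

## Diagnostics

Curvature between two conditions is summarised by the coefficient b2 of a
least-squares fit y = b0 + b1·z + b2·z² on z-scored x — a single signed,
testable number (spline alternatives would describe more but summarise
less) — with a seeded 1000-resample bootstrap CI; no multiple-testing
adjustment is applied across condition pairs (the diagnostics are
descriptive). Error profiles bin variants into rate deciles and average
replicate SEs per bin. Cross-library concordance reports, per shared
component (e.g. bait partner), the Pearson correlation and mean paired rate
difference between library compositions.

## What the simulator does and does not emulate

It reproduces the mechanisms behind the assay's characteristic distortions —
co-transformation compression (rate IQR strictly decreasing, bottom-quartile
rates strictly increasing in λ), lag bias (larger at early harvests),
dose-dependent background (lower mode tracks r_bg(dose) while the upper mode
moves < 10%), count-noise error inflation for slow growers at late harvests,
and exact composition invariance in the ideal regime (showing that observed
composition dependence requires non-ideal effects — a depth/distortion knob
is exposed via per-library pool frequencies and depths, but no specific
mechanism is asserted). It does not model PCR-cycle amplification bias,
sequencing errors, colony morphology, media chemistry, marker-specific
transformation efficiencies, or three-state thermodynamics, and it performs
no inverse fitting of free energies to data. Passing tests therefore
demonstrate correctness of the estimators and the stated mechanisms under
this generative model, not the absence of other artefacts in real data.

## Problem sizes and numerics

Default desk-scale runs use the 1827-pair balanced library with 2×10^5
founders and 10^6 reads per sample; the plating simulation uses 10^6 cells;
the replicate-error comparison uses 50 independent 3-replicate assays per
harvest condition. Bisection tolerances are 1e-10 (harvest time); algebraic
identities are asserted at 1e-9; degenerate inputs (all-zero rates, zero
column sums, empty clones, constant rate vectors) raise named errors rather
than returning silently wrong values. One top-level seed drives every random
stage through deterministically spawned substreams; expected-value mode
bypasses read sampling entirely for oracle tests.
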