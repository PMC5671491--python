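# Methods

## Scientific setting

Archaea build membrane-spanning glycerol dialkyl glycerol tetraether
(GDGT) lipids whose number of cyclopentane rings increases with growth
temperature. The TEX86 index,

    TEX86 = ([GDGT-2] + [GDGT-3] + [Cren']) /
            ([GDGT-1] + [GDGT-2] + [GDGT-3] + [Cren'])

(bracketed terms are fractional abundances; Cren' is the crenarchaeol
regioisomer), is calibrated against sea-surface temperature on global
core-top sediments as

    SST (°C) = 68.4 · log10(TEX86) + 38.6.

The calibration presumes the GDGT pool derives from Marine Group I
Thaumarchaeota responding to temperature alone. Marine Group II (MG-II)
Euryarchaeota — planktonic heterotrophs abundant in estuaries and coastal
water — are a suspected second source of cyclopentane-ring GDGTs, which
would bias the thermometer. This package quantifies that hypothesis on
tabular field data and on simulated data where the truth is known.

## Indices and screening

Two ring indices (abundance-weighted mean ring numbers) are computed:

- `ri1` = ([1] + 2[2] + 3[3] + 4[Cren] + 4[Cren'])/100 — the variant the
  core-top calibration uses, dominated by crenarchaeol;
- `ri2` = ([1] + 2[2] + 3[3] + 4[GDGT-4] + 4[Cren'])/100 — crenarchaeol
  replaced by GDGT-4, removing the thaumarchaeotal biomarker so the index
  responds to ringed GDGTs from other archaea.

Across core-tops, RI_1 tracks TEX86 along the parabola
`RI = 3.32·TEX86² − 0.77·TEX86 + 1.59` with a ±2σ envelope of ≈0.3 ring
units. The screen reports `delta_ri` (measured − predicted) and an
in-zone boolean; samples outside the zone carry a GDGT pool whose ring
distribution is not controlled by temperature alone. RI_1 enters the
zone test by default because the parabola was fitted with it; the
variant is caller-selectable but RI_2 sits on a different scale (it
drops the ~40–80 % crenarchaeol term) and a sample on the calibration
curve has RI_2 far below the parabola, so zone-testing RI_2 is not
meaningful without refitting the curve.

Advisory QC flags use strict inequalities from the screening literature:
BIT > 0.2, GDGT-2/Cren > 0.4, Methane Index > 0.5, GDGT-0/Cren > 2,
%GDGT-2 > 45. Boundary values do not flag. `%GDGT-2` is implemented as
100·[2]/([1]+[2]+[3]); the literature states only the threshold, so the
denominator choice (no Cren') is isolated in one function and documented.
Any index with a zero denominator is *undefined* and carried as NaN — an
explicit marker, not an exception, because field data legitimately contain
zero crenarchaeol; flags over undefined indices are indeterminate
(`None`). Flags never cause samples to be dropped: deviating samples are
the scientifically interesting ones.

## The regression screen (core model)

`RingEnrichmentModel` regresses, by OLS, each lipid variable (RI_2,
per-compound fractional abundances, GDGT-2/GDGT-3, ...) in each lipid
pool (core lipids CL; acid-hydrolysis total-IPL; base-hydrolysis
phospho-IPL, the best proxy for living biomass) on the qPCR gene-copy
ratio [MG-II 16S]/[Archaea 16S] across water-column samples. A
significant positive slope for a ringed variable is the evidence that
MG-II contribute ring-bearing GDGTs. R² is the squared Pearson
correlation; the slope p-value is the two-sided t-test with n−2 degrees
of freedom. Undefined values are dropped pairwise per cell; cells with
fewer than 3 complete pairs are marked not computable. Two-group
comparisons use Welch's unequal-variance t-test (the robust default at
n = 6 vs 4 with unequal spread; Student's pooled test is available via
`scipy.stats.ttest_ind(equal_var=True)` for sensitivity). No
multiple-testing correction is applied; the matrix is a screen, not a
family of confirmatory tests.

Group summaries report mean, sample SD (n−1) and population SD (n); both
SDs are emitted because published "±" values do not always state their
convention.

The SPM–sediment correspondence (`paired_station_correlation`) supports
three pairing strategies — station-mean, surface-only, per-sample — and
records which was used, because published water-column/sediment
correlations rarely state the pairing and the three can differ
substantially on small station counts.

## Packaged transect table

`load_table1_fixture()` ships a 26-sample estuarine transect (8 river SPM,
6 estuarine-mixing SPM, 4 coastal-sea SPM, 8 surface sediments) with
per-pool TEX86 and RI_2, GDGT concentrations, environmental metadata, and
archaeal/MG-II 16S qPCR abundances for 12 SPM samples. The table prints
derived indices but not the underlying fractional abundances, so only
downstream statistics (regressions, group means) — not index
recomputation — are possible from it; profile-level behaviour is
exercised with the simulator. Gene abundances in the table are rounded
to two significant figures, which propagates to ≈1 unit in the last
printed digit of recomputed group means.

## Two-endmember mixing simulator

`simulate_transect` emulates the study design: n samples along a salinity
gradient, three lipid pools each, plus qPCR counts.

**Thaumarchaeotal endmember.** Constructed exactly on the calibration:
given a target temperature T (default 24.7 °C, a coastal annual-mean
surface temperature typical of the subtropical settings the proxy
targets), t\* = 10^((T−38.6)/68.4); a share S (default 30 %) of the
profile is allocated to the TEX86 denominator with GDGT-1 = (1−t\*)·S and
(GDGT-2, GDGT-3, Cren') = t\*·S·(0.55, 0.25, 0.20); GDGT-4 gets 0.5 %;
crenarchaeol solves RI_1 = predicted RI(t\*); GDGT-0 absorbs the rest.
The construction is exact to rounding (TEX86 = t\*, ΔRI = 0 to 1e-9) and
feasible for T ∈ [5, 35] °C with the defaults; infeasible targets (any
negative abundance — unavoidable at T ≥ 38.6 °C, where the parabola
predicts more than the 4-ring maximum) raise a constructive error naming
the violated field.

**MG-II endmember.** Ring weights (0.20, 0.35, 0.20, 0.15, 0.10) over
GDGT-0..4, no crenarchaeol, no regioisomer by default (RI_2 = 1.60,
TEX86 = 0.5). The weights are illustrative — GDGT-1-dominated to match
the strongest observed gene–lipid correlation — and configurable; the
true MG-II lipid profile is unresolved pending a pure culture.

**Mixing and noise.** Sample i is the componentwise mixture
(1−f_i)·thaum + f_i·MG-II (f defaults to an even grid on [0, 0.4], the
range producing estuary-like gene ratios). Each pool independently
resamples the mixture from a Dirichlet with mean equal to the mixture
and concentration 500 (≈1–2 % relative compositional noise). Archaeal
16S counts are lognormal around 10^9 copies/L; MG-II counts are
f_i·archaea with independent lognormal error, so the noiseless gene
ratio is exactly f_i. The qPCR noise default σ = 0.1 log10 units (ratio
error factor ≈1.26, consistent with qPCR efficiencies of 87–99 %) was
set so simulated RI_2-vs-ratio R² spans ≈0.55–0.85, the band observed in
the field regressions; it is the single dial folding together assay
error, lipid-per-cell and gene-copy-number variation. All draws come
from one seed through spawned, independent substreams; identical seeds
reproduce datasets bit for bit.

**Identities the simulator guarantees** (tested): RI_2 of a mixture is
exactly linear in f (ring indices are linear in abundances), so a
noiseless regression of RI_2 on f recovers slope = RI_2(MG-II) −
RI_2(thaum) to 1e-9; TEX86 of the mixture strictly decreases in f for
the default (GDGT-1-rich) endmember, i.e. the simulated MG-II admixture
produces exactly the cold-biased TEX86 the screen is designed to catch;
ΔRI is strictly monotone in f. Note the *direction* of ΔRI under the
default endmembers is negative: an endmember without crenarchaeol can
reach at most 4 ring units of RI_1, and at its TEX86 of 0.5 the default
endmember's RI_1 (1.2) lies below the parabola (2.035), so admixture
pulls ΔRI down. Samples plotting *above* the zone require an endmember
whose RI_1 exceeds the parabola at its own TEX86 — achievable with a
regioisomer-bearing composition (e.g. 50 % GDGT-1 + 50 % Cren'), which
the tests exercise. The simulator is a validation harness, not a claim
about which direction real MG-II input moves ΔRI.

**What the simulator does not emulate:** crenarchaeol dilution is
mechanical (cren falls linearly with f, creating a spurious negative
cren–ratio correlation stronger than field data show); no depth/tide
structure, no sediment diagenesis or differential IPL degradation, no
spatial autocorrelation; qPCR error is sample-independent. Passing
recovery tests therefore demonstrates correctness of the pipeline
arithmetic and power under idealized mixing, not robustness to those
real-data features.

## Numerical choices

- Profile validation tolerates |sum − 100| ≤ 0.5 (rounding in published
  tables); `normalize_profile` rescales exactly and is idempotent.
- Missing-value tokens {"–", "-", "", "NA"} map to *absent*, never zero.
- "log" in the temperature calibration is log10 (the convention of the
  calibration used); the base is a config constant.
- Zero-variance Welch inputs short-circuit (equal means → p = 1, unequal
  → p = 0) rather than dividing by zero.
- Results TSVs carry 9 significant digits (lossless at 6); presentation
  tables round to 2 decimals, so a p of 0.004 prints as 0.00.
- Reported problem sizes: simulator defaults n = 50 samples × 3 pools;
  property tests use 19–25-point f grids and 20 seeds — sizes at which
  every statistic is stable to well inside the asserted tolerances.

## Known limitations

- The fixture cannot validate index arithmetic against the published
  per-sample indices (fractional abundances unprinted); arithmetic is
  validated against closed-form examples and the simulator instead.
- f conflates lipid share with gene-copy share; any systematic
  lipid-per-cell ratio between the two groups would rescale slopes but
  not change signs or significance structure.
- The BIT flag uses only the three major branched GDGTs (Ia, IIa, IIIa);
  5/6-methyl isomers and OH-GDGT variants are out of scope, as are
  alternative TEX86 calibrations (TEX86^L, Bayesian) and subsurface
  calibrations.
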