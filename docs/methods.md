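# Methods

This note records the models, numerical choices and validation design
behind `cbxscreen`, in the order the pipeline runs.

## The screening problem

2-cyanobenz'X'azoles (CBX nitriles: benzimidazole, 1-methylbenzimidazole,
benzothiazole and benzoxazole cores) condense with the 1,2-aminothiol of
an N-terminal cysteine to an irreversible thiazoline, eliminating one
ammonia; internal thiols instead add reversibly to the nitrile as open
thioimidates.  Selecting usable bioconjugation reagents from a compound
library requires, per compound: (i) buffer stability over the assay
window, (ii) reactivity restricted to cysteine (not Lys/Ser/TCEP, ideally
not plain thiols), (iii) a second-order rate constant k2 with cysteine,
and (iv) labeling selectivity on model peptides.  The package implements
the desk side of that screen plus a synthetic-data generator so every
stage is testable by parameter recovery.

## Stability statistic and classification

For each compound-in-buffer well the screen takes the spectral time
series A(t, λ) (default: 49 reads over 4 h starting at the 3 min
instrument dead time; 250–490 nm in 2 nm steps), finds the most
responsive wavelength λ* = argmax_λ |A(t_last, λ) − A(t_first, λ)|
(exact ties break toward the longer wavelength), and computes

    rel_diff = |A(t_last, λ*) − A(t_first, λ*)| / A(t_first, λ*).

Classes: rel_diff < 0.1 stable, 0.1 ≤ rel_diff ≤ 0.2 intermediate,
rel_diff > 0.2 unstable.  The boundaries are assigned to intermediate;
the published cut points leave the closed ends open, and inclusive
intermediate keeps the partition total.  Because the statistic divides by
the first-read absorbance, the screen only considers wavelengths whose
baseline is at least `min_first_absorbance` (0.05 AU by default); at
wavelengths below that the ratio is noise over noise.  Results computed
at a sub-threshold baseline carry `low_signal_flag`.

## Mechanism diagnosis

Two instability mechanisms are distinguished for non-stable wells:

* **Plate-wall binding** removes compound from solution: every spectrum
  is a scaled copy of the first.  Each timepoint spectrum is regressed on
  the first-read spectrum by a least-squares scale factor; the series is
  proportional when the worst relative residual is below
  max(2%, 3·σ̂·sqrt(2W)/‖A(t_first)‖), the second term being the residual
  that the noise floor alone produces on a W-wavelength grid.
* **Isosbestic degradation** converts the parent chromophore into a
  product with a different spectrum under conservation of moles, so the
  two absorptivities cross at some wavelength where the absorbance is
  time-invariant.  The series is called degradation when it is *not*
  proportional, the overall change exceeds the unstable threshold, and
  some wavelength with real absorbance (baseline ≥ 0.05 AU) has temporal
  standard deviation below 3·σ̂.

σ̂ is the per-cell noise estimated from first differences in time at the
flattest decile of wavelengths (sd of differences over sqrt 2).  A series
whose overall change is below the stable threshold has no mechanism to
diagnose and returns `undetermined` — a constant series is trivially
proportional to itself, so the order of the tests matters.

## Reactivity and hyperreactivity

Compound + reagent wells are blank-subtracted (reagent-only well matched
by reagent and replicate — blanks are explicit series, never implicit
baselines) and the same rel_diff statistic is evaluated on the
difference; reactive means rel_diff > 0.2.  For reduced DTNB the readout
is the released 5-mercapto-2-nitrobenzoate chromophore, so the statistic
is evaluated at a fixed 412 nm rather than the argmax.  Hyperreactivity
(reaction over before the first read) is called when the first-read
spectrum already differs from the compound-alone reference by more than
the reactivity threshold at the wavelength of largest first-read
difference.

## Kinetics

Pseudo-first-order decays are fitted as A(t) = plateau + (A0 − plateau)
e^(−k_obs t), three free parameters (the plateau absorbs product
absorbance; it can be fixed to a blank value).  Initialization: plateau
from the last read, k from a log-linear fit of the baseline-subtracted
signal, A0 by extrapolating that line to t = 0.  The optimizer is
lmfit's Levenberg–Marquardt.  Failure is reported, never raised:
`converged=False` when the fit fails, when the span is within 3× the rms
residual of zero (no decay to fit), or when the fitted model puts more
than 95% of the reaction before the first read — the hyperreactive case,
which carries the honest lower bound k_obs ≥ −ln(0.05)/t_first instead
of a point estimate.

k2 comes from k_obs/[Cys] at a single concentration or from the
unweighted OLS slope of k_obs against [Cys] over ≥3 (typically 7)
concentrations, intercept free.  Temperature is metadata only; no
Arrhenius correction is attempted.

Labeling conversions are predicted by the closed-form second-order
progress law for dx/dt = k2 (a0 − x)(b0 − x):

    x/b0 = a0 (1 − e^(−(a0−b0) k2 t)) / (a0 − b0 e^(−(a0−b0) k2 t)),

with the a0 = b0 limit c·k2·t/(1 + c·k2·t); the implementation divides
through by the growing exponential so large exponents cannot overflow.

## Mass arithmetic and adduct enumeration

Monoisotopic (principal-isotope) masses are used throughout — the data
to interpret are sub-ppm high-resolution m/z.  Element masses come from
the NIST table shipped with pyteomics; peptide compositions are residue
sums plus one water.  Charging uses the electron-corrected proton mass
1.007276 Da; mass accuracy is reported as signed ppm, negative when the
observation is low.

For a peptide and a compound formula, candidate species at n = 0..N
labels are: all labels reversible (mass = peptide + n·compound) and,
when the peptide has an N-terminal cysteine, the variant with one
thiazoline (additionally −17.02655 Da, one NH3).  The thiazoline count
is capped at one — a peptide has one N-terminus — and reversible labels
are deliberately left site-unresolved: internal-cysteine thioimidate
cannot be distinguished by mass from Ser/Tyr additions.  The
intermolecular peptide disulfide (2·peptide − 2H) is a built-in
candidate, matched but excluded from conversion arithmetic.  Peak
matching assigns each observed m/z to the candidate minimizing |ppm|
within tolerance (default 5 ppm); two candidates within 0.1 ppm of each
other are reported ambiguous, never silently resolved.

## Labeling interpretation

Conversion is parent-depletion only: 100·(1 − AUC_parent/AUC_blank) at
280 nm, clamped to [0, 100] with a flag on negative raw values
(injection variability); product peaks are not used because adduct
response factors at 280 nm are unknown.  Complete conversion means no
parent peak at all.  A cysteine treatment after labeling is expected to
strip every thioimidate species (free cysteine both scavenges excess
nitrile and displaces the open adduct); survivors are flagged anomalous.
A DTT treatment is expected to change nothing — DTT lacks the
1,2-aminothiol needed for the condensation — and any change is flagged.

## Global score

The published screen combines reactivity, selectivity and derivatization
capability into one score but does not state the formula.  The package
ships a transparent default, labeled `default-v1` in every output:
reactivity = UP1 conversion/100 (else min(k2/5, 1), the pivot being the
k2 ≈ 5 s⁻¹M⁻¹ complete-labeling threshold), selectivity = 1 − UP2
conversion/100, derivatization = 1 for NH2/OH/CO2H substituents, total =
weighted sum with default unit weights.  No attempt is made to
reproduce specific published score values; the qualitative behavior
(monotonicity, derivatizable compounds with complete conversion scoring
above 1.5) is what the tests pin down.  The reactivity–selectivity
trade-off statistic is the Pearson correlation of UP2 conversion against
log10 k2 (k2 spans three orders of magnitude); note the relation under
the second-order model is sigmoidal, so even a noiseless monotone cohort
gives r ≈ 0.96, not 1.

## Synthetic data: what it emulates, what it does not

Spectra are Beer–Lambert mixtures of species whose absorptivities are
sums of Gaussian bands; reaction progress is exponential or exactly
second-order; degradation conserves moles (exact isosbestic point);
plate binding scales spectra uniformly; measurement noise is additive
i.i.d. Gaussian per (time, wavelength) cell, default sd 0.003 AU (~30σ
below the 0.1 threshold on a 1 AU signal).  Same seed, bit-identical
output.  LCMS runs emit peak tables (no chromatographic peak shapes)
with theoretical m/z perturbed within half the matching tolerance and
areas proportional to the model conversion.

Deliberately not emulated: correlated/heteroscedastic detector noise,
baseline drift, wavelength miscalibration, overlapping chromatographic
peaks, adduct response-factor differences at 280 nm, in-source
fragmentation, and isotope patterns.  Passing the recovery suites
therefore shows the analysis is correct under its stated model, not that
the model exhausts real plate-reader or LCMS pathology.

### Labeled stability cohort

The recovery suite plants the value the (noiseless) statistic will take
and keeps margins from the decision boundaries, because boundary cases
are undecidable at any finite noise: stable 0.03–0.07 (realized as a
slight uniform drift — truly constant wells would make the argmax pick a
pure-noise wavelength), intermediate 0.125–0.175, unstable 0.25–0.9
(binding) / 0.25–0.45 (degradation; the two-chromophore geometry caps
the statistic at the most responsive wavelength).  Peak absorbance is
uniform in [0.3, 1.2] AU.  Degradation wells use an equal-width,
asymmetric Gaussian pair whose crossing is solved analytically onto the
2 nm grid (a grid crossing has exactly zero noiseless temporal
variance); the asymmetry keeps the most responsive wavelength on the
high-baseline parent side.  The degradation rate that yields a requested
statistic is found by bisection on the analytic expression — the argmax
wavelength of a two-species interconversion is k-independent, which
makes that expression closed-form in everything but k.

### Kinetics recovery experiment

Seven cysteine concentrations at 10–70× excess over a 50 µM compound
share one read schedule, as wells on a real plate do: 97 reads across
about five half-lives of the median well with a dead time of 1% of the
window.  This is the fast-assay regime; the 4 h / 3 min-dead-time
stability cadence cannot resolve rate constants in the tens of
s⁻¹M⁻¹ (the reaction is over before the first read), which is why such
compounds are triaged to this assay in the first place.  Scaling the
window with 1/k2 lets one routine span k2 from 0.5 to 50 s⁻¹M⁻¹.
Observed performance: noiseless recovery at machine precision; at the
0.003 AU noise floor, within ~1% (the validation asserts 5%).

### Labeling cohort

Twenty compounds with k2 log-spaced from 0.1 to 100 s⁻¹M⁻¹ (shared
2-cyanobenzothiazole core formula C8H4N2S) are incubated in silico with
each model undecapeptide (UP1 CGKGCGSGYGW with N-terminal Cys, UP2
AGKGCGSGYGW without) at 2 equivalents, 50/25 µM, 30 min.  Compounds
above k2 = 5 also emit di-adducts, above 50 tri-adducts (UP1), mirroring
multi-labeling by the most reactive electrophiles.

## Validation problem sizes

The shipped validation runs (tests and `scripts/acceptance.py`) use:
200-series stability suites (noiseless and at 0.003 AU), 3×7 kinetic
wells per noise level, 6 excess ratios for the pseudo-first-order
validity study, and the 2×20-compound labeling cohort.  All complete in
seconds; they are statistical summaries, not exhaustive sweeps.

## Known limitations

* One wavelength drives the stability statistic; bands crossing near
  their own peak, or compounds with negligible absorbance above 250 nm,
  can defeat it (flagged low-signal rather than guessed).
* Mechanism diagnosis assumes a single parent and a single effective
  product; multi-step degradations land in `undetermined`.
* The decay fit reports standard least-squares diagnostics only — no
  confidence intervals beyond OLS, no global multi-well fitting.
* Conversion ignores product peaks entirely; co-eluting parent and
  adduct would bias it (real chromatography concern, not modeled).
* The global score formula is a documented default, not a reconstruction
  of the published one.
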