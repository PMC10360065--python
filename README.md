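# cbxscreen

Screening analysis for heteroaromatic nitrile ("CBX",
2-cyanobenz'X'azole) bioconjugation reagents that click onto N-terminal
cysteine.  The package takes the raw outputs of a UV–vis microplate
screen and an LCMS peptide-labeling experiment and turns them into the
decisions a reagent hunter needs:

* **Stability** — classify each compound from its 4 h spectral time
  series by the relative absorbance difference at the most responsive
  wavelength (stable < 0.1, intermediate 0.1–0.2, unstable > 0.2), and
  diagnose *why* unstable compounds change: chemical degradation shows
  an isosbestic point (two chromophores interconverting under mole
  conservation), plate-wall binding scales the whole spectrum uniformly.
* **Reactivity** — flag compound–reagent pairs (Lys, Ser, TCEP, NAC,
  Cys, reduced DTNB at 412 nm) whose blank-subtracted change exceeds
  0.2, including hyperreactive compounds that finish before the ~3 min
  first read.
* **Kinetics** — fit one-phase decays A(t) = plateau + (A₀−plateau)
  e^(−k_obs·t) and estimate the second-order rate constant either as
  k₂ = k_obs/[Cys] or as the slope of k_obs vs [Cys] over several
  concentrations (pseudo-first-order conditions, ≥10× Cys excess);
  predict labeling conversions with the exact second-order progress law.
* **Labeling** — enumerate peptide–compound adducts (irreversible
  N-terminal thiazoline = +compound −NH₃, 17.0265 Da; reversible
  thioimidate = +compound), assign LCMS peaks by accurate mass at 5 ppm,
  semiquantify conversion from parent-peptide AUC depletion at 280 nm,
  and audit Cys/DTT treatments for adduct reversibility.
* **Scoring** — combine reactivity, selectivity and derivatization
  capability into a transparent global score.

A synthetic-data generator (Beer–Lambert spectra from Gaussian bands,
exponential / exact second-order progress, conserved isosbestic points,
uniform-scaling plate binding, Gaussian plate noise, adduct-true LCMS
peak tables) carries recorded ground truth, so every stage is validated
by parameter recovery.  See `docs/methods.md` for models and numerical
choices.

## Worked example

Simulate a kinetics plate (compound 50 µM, seven Cys concentrations,
planted k₂ = 10 s⁻¹M⁻¹), then recover k₂ from the k_obs-vs-[Cys] slope:

```bash
$ cbxscreen simulate --scenario kinetics --seed 4 --out kin
wrote kin/plate.csv
$ cbxscreen kinetics --plate kin/plate.csv --layout kin/layout.csv \
      --mode regression --out k2.json
k2 = 9.977 s^-1 M^-1 (multi_conc_slope, n=7)
```

The recovered slope is within 0.3% of the planted constant; `k2.json`
also records the free intercept and r².  The same works from Python:

```python
from cbxscreen import (simulate_labeling_experiment, assign_peaks,
                       enumerate_adducts, peptide_formula, parse_formula)

sim = simulate_labeling_experiment({"c1": 8.0}, "UP1", {"c1": "C8H4N2S"},
                                   seed=2)
peaks, truth = sim["c1"]
cands = enumerate_adducts(peptide_formula("CGKGCGSGYGW"), True,
                          parse_formula("C8H4N2S"), max_labels=3,
                          peptide_id="UP1", compound_id="c1")
result = assign_peaks(peaks, cands, blank_area=1000.0)
print(result.conversion_pct)        # 46.4  (truth: 46.4)
print(result.species_assignments)   # parent, mono- and di-thiazoline adducts
```

A compound at k₂ = 8 s⁻¹M⁻¹, 2 equivalents, 30 min converts 46.4% of
the Cys-terminal undecapeptide; every simulated peak is assigned to its
true adduct species, and the mono/di adducts show the NH₃-loss signature
of N-terminal labeling.

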