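# cdsom

Secondary-structure estimation from far-UV circular dichroism (CD)
spectra for proteins with substantial unfolded content — partially
melted proteins, natively disordered domains, or mixed folded/unfolded
populations.

Standard CD deconvolution fits an experimental spectrum against a
reference set of spectra from well-folded proteins, and fails when a
large random-coil component drags the spectrum away from anything in
the reference set. `cdsom` addresses this with three pieces:

1. **Self-organising-map (SOM) fitting.** A Kohonen map (default
   50 × 50 nodes) is trained on reference spectra Δε(λ) (per molar
   residue, 240–190 nm at 1 nm, 51 points), each annotated with five
   secondary-structure fractions (α-helix, β-sheet, bonded turn, bend,
   loop). Each map node carries a prototype spectrum and a structure
   annotation inherited from the reference proteins occupying its
   neighbourhood. An unknown is fitted by its *k* = 5 best matching
   units (BMUs): the predicted structure and spectrum are
   inverse-distance weighted averages over those nodes, with fit
   quality measured by

   NRMSD = √( Σ_λ (Δε_exp − Δε_calc)² / Σ_λ Δε_exp² ).

2. **Derandomization.** Model the spectrum as a mixture
   Δε_exp = (1−f)·Δε_core + f·Δε_RC of a folded core and a
   random-coil (RC) reference spectrum. For trial fractions
   f = 0%, 10%, …, 90%, invert the mixture,
   Δε_derand = (Δε_exp − f·Δε_RC)/(1−f), fit every derandomized
   spectrum on the map, discard fits with NRMSD > 0.03, and take the
   lowest-NRMSD survivor (near-ties are flagged "co-optimal" for human
   review, with shape diagnostics over 190–210 nm). The winning core
   structure is then **regenerated** to the original protein:
   helix′ = (1−f)·helix, sheet′ = (1−f)·sheet,
   other′ = (1−f)·other + f.

3. **β_II inspection.** β_II-class proteins have CD spectra nearly
   identical to unfolded/polyproline-II spectra, so a β-sheet
   prediction routed through β_II references is ambiguous. Whenever a
   BMU neighbourhood contains a β_II-listed reference, the inspection
   report raises a flag and attaches the caveat that β-sheet, random
   coil and polyproline II cannot be distinguished spectroscopically.

Because annotated reference spectra are experimental data that cannot
ship with the package, `cdsom.synth` generates synthetic reference
sets, RC spectra and thermal melting series from Gaussian band models
of the canonical far-UV shapes, with ground truth recorded — the whole
pipeline installs and tests with no downloads.

## Worked example

Train a map on a 60-protein synthetic reference set, simulate a melt
whose random-coil fraction grows from 0 to 60% between 20 and 100 °C,
and analyse it:

```python
from cdsom import (SOMConfig, analyze_series, default_basis,
                   make_melting_series, make_rc_spectrum,
                   make_reference_set, train_som, write_results_table)
from cdsom.synth import DEFAULT_MELT_CORE, DEFAULT_MELT_SCHEDULE

basis = default_basis()
refset = make_reference_set(60, seed=1, basis=basis)
rc = make_rc_spectrum(basis)
trained = train_som(refset, SOMConfig(seed=2))

series = make_melting_series(DEFAULT_MELT_CORE, DEFAULT_MELT_SCHEDULE,
                             noise_sd=0.07, seed=11, basis=basis)
rows = analyze_series(series, rc, trained)
write_results_table(rows, "results.csv")
```

`results.csv`:

```
temperature_C,best_nrmsd,rc_added_pct,derand_helix,derand_sheet,derand_other,regen_helix,regen_sheet,regen_other,status
20.0,0.0157,0,,,,0.57,0.19,0.24,ok
30.0,0.0203,0,,,,0.57,0.19,0.25,ok
40.0,0.0187,10,0.57,0.19,0.25,0.51,0.17,0.32,ok
50.0,0.0196,20,0.57,0.18,0.25,0.46,0.15,0.4,ok
60.0,0.0192,20,0.57,0.2,0.23,0.46,0.16,0.39,ok
70.0,0.0221,30,0.57,0.18,0.25,0.4,0.13,0.47,ok
80.0,0.0256,40,0.57,0.17,0.25,0.34,0.1,0.55,ok
90.0,0.0247,50,0.57,0.19,0.25,0.28,0.09,0.62,ok
100.0,0.0294,60,0.57,0.18,0.25,0.23,0.07,0.7,ok
```

Reading the table: `rc_added_pct` is the selected random-coil fraction
(it recovers the simulation's schedule at every temperature); the
`derand_*` columns are the three-class structure of the folded core
(empty at 0% RC, where the "core" is just the original spectrum); the
`regen_*` columns are the original protein after the coil is added
back — regenerated helix falls from 0.57 to 0.23 as the protein melts,
while the core's composition stays constant, exactly the behaviour the
series was generated with. `best_nrmsd` rises with temperature but
stays inside the 0.03 acceptance gate.

## Command line

The same workflow as shell commands (files use a column-oriented CSV
dialect: one spectrum per column, wavelengths descending, reference
files carrying five structure rows):

```
cdsom synth --what refset --n 60 --seed 1 --out refset.csv
cdsom synth --what rc --out rc.csv
cdsom synth --what melt --noise-sd 0.07 --seed 11 --out melt.csv
cdsom train --refset refset.csv --seed 2 --out map.json
cdsom melt --map map.json --series melt.csv --rc rc.csv \
      --out results.csv --inspect-out reports.json
```

`cdsom predict` fits spectra without derandomization, `cdsom derand`
prints the full sweep for each spectrum. Exit codes: 0 success, 2
input/usage error, 3 no fit passed the NRMSD gate.

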