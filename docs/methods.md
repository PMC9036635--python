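# Methods

## The model

A far-UV CD spectrum of a protein with unfolded content is treated as a
two-component mixture on a per-molar-residue scale,

    Δε_exp(λ) = (1 − f)·Δε_core(λ) + f·Δε_RC(λ),

where `core` is the folded remainder, `RC` a measured random-coil
reference spectrum, and f the molar-residue fraction of unfolded
chain. Because every spectrum is normalised per molar residue, chain
lengths cancel and the mixture is a plain convex combination; the
inversion used for derandomization,

    Δε_derand(λ) = (Δε_exp(λ) − f·Δε_RC(λ)) / (1 − f),

is exact whenever the model holds. Derandomized spectra at high f are
amplified (the 1/(1−f) factor also scales measurement noise) and may be
non-physical for wrong trial fractions; no clipping is applied — the
NRMSD gate is the filter.

Structure fitting itself is done by a self-organising map rather than a
basis-regression method: similar spectral shapes cluster on a 2-D grid
of prototype spectra, an unknown is characterised by its k nearest
prototypes (best matching units, BMUs), and — crucially for the
ambiguity analysis — the identity of the reference proteins around
those BMUs is always available, so a prediction can be interrogated,
not just accepted.

## SOM training and prediction

Training uses the classical online Kohonen rule. Per presented sample:
winner = node with minimal Euclidean distance over the 51 spectral
points; every node is then updated by
lr(t)·exp(−d²_map/2σ(t)²)·(x − w). Both the learning rate and the
neighbourhood radius decay exponentially from initial to final values
over the whole run. Defaults:

| parameter        | default            | rationale |
|------------------|--------------------|-----------|
| map size         | 50 × 50            | standard map size for ~10²-protein reference sets; plenty of interpolation capacity |
| k (BMUs)         | 5                  | standard BMU count for CD fitting |
| epochs           | 100 passes         | converges the quantisation error for sets of this size |
| learning rate    | 0.5 → 0.01         | conventional online-SOM schedule |
| radius σ         | max(rows, cols)/2 → 1 | global ordering early, local refinement late |
| initialisation   | uniform in the per-wavelength min/max envelope | scale-appropriate, deterministic under the seed |

Determinism is a contract: a fixed seed yields a bit-identical map, and
all distance ties break lexicographically by (row, col).

Node structures are attached after training: each node receives the
inverse-map-distance-weighted mean of the structures of its
n = 5 nearest reference entries (nearness measured between the node and
the entries' winning nodes in map coordinates; spectral distance breaks
map-distance ties; a hosted reference at distance 0 takes all the
weight). Prediction weights BMUs by inverse spectral distance,
w_i = (1/d_i)/Σ(1/d_j), with a zero distance taking weight 1. Inverse
(not inverse-squared) distance was chosen as the mildest standard
weighting; with k = 5 and well-separated BMU distances the choice has
little leverage, and it is fixed for testability.

## Sweep, gate and selection

The sweep tries f = 0, 0.1, …, 0.9 (0 included so the plain fit always
competes; an optional refinement pass adds 0.05-step fractions around
the winner). Fits with NRMSD > 0.03 are discounted — the gate is
inclusive at the boundary. Among survivors the minimum-NRMSD candidate
is selected automatically, but candidates within 15% (relative) of the
best NRMSD are marked co-optimal: the final choice between near-ties is
expert judgement (overlay shape between 210 and 190 nm, zero-crossing
position, extrema alignment), which the inspection report supports but
does not replace. The report also lists the reference proteins
occupying nodes within 3 map units of any BMU and raises a β_II flag
when any of them is on the β_II list (default: α-chymotrypsin,
chymotrypsinogen, elastase; configurable sidecar file), because a β_II
BMU makes β-sheet, random coil and polyproline II mutually
indistinguishable in CD.

## Synthetic data: what it emulates and what it does not

The generator replaces two experimental inputs: a structure-annotated
reference set and melting series. Spectra are Gaussian-band
combinations of four basis shapes (helix, sheet, turn, coil) with the
canonical far-UV features (helix 208/222 nm double minimum and strong
193 nm positive band; sheet minimum near 218 nm; coil deep minimum near
198 nm). Band parameters are package constants tabulated in
`cdsom/synth.py`. Reference compositions are Dirichlet-sampled to
favour folded proteins (low loop mass), plus two fully helical and four
fully unfolded entries — the augmentation a CD reference set needs to
span the shape space. Melting series mix a fixed folded core with a
scheduled coil fraction; the default schedule (0 → 0.6 over
20–100 °C) follows a gradual serum-albumin-style melt. Core "other"
content is rendered with the turn basis, not the coil basis: if "other"
were spectrally identical to coil, f would be mathematically
unidentifiable (any split between core-other and coil gives the same
spectrum).

What passing tests on these data show: the mixture inversion, the
sweep's model selection, the regeneration arithmetic and the SOM
machinery are correct, and the pipeline recovers known ground truth
under realistic noise. What they do not show: performance on real
proteins, whose spectra are not exact band-model mixtures, whose
"other" class is heterogeneous, and whose noise grows steeply below
200 nm (the generator uses wavelength-independent Gaussian noise — a
known simplification).

## Numerical choices and degenerate inputs

- NRMSD normalises by Σ Δε_exp² (the CD-field convention; good fits
  ~0.01). The statistic is undefined for an identically zero observed
  spectrum (error). An alternative normalisation by max−min exists in
  other fields; it is not used here.
- Wavelength grids are stored descending (240 → 190 nm); all
  arithmetic is order-agnostic. Resampling is linear interpolation
  only; extrapolation is refused with the missing wavelengths named.
- Test problem sizes: suite-wide maps are 50 × 50 on 40–60-entry
  synthetic sets (seconds to train); parameter recovery uses 20 seeded
  series of 9 temperatures.
- Degenerate maps (1 × 1, single reference) are supported; the default
  initial radius clamps to at least the final radius.

## Known limitations

- f is only identifiable while the folded core contributes a
  distinctive spectral signature. For coil fractions ≳ 0.7 the
  un-derandomized spectrum already sits in the map's unfolded region
  and fits well at 0% RC, so the sweep's minimum no longer pins f —
  the same degeneracy seen with real proteins late in a melt. The
  regenerated helix fraction is far more robust: under-derandomizing
  by δ leaves a legitimate mixture whose fitted helix scales by
  exactly the factor that regeneration undoes, so helix estimates
  survive a misidentified f.
- The identifiability of f also depends on reference-set coverage: a
  sparse set raises the quantisation floor toward the 0.03 gate. The
  melting tests use 60-entry sets (real reference collections hold
  ~70 proteins); 40 entries suffice for self-fitting but leave the
  floor near the gate for unseen cores.
- With noise at 2% of the spectral maximum, the best attainable NRMSD
  can exceed the 0.03 gate even for a correct model (the gate reflects
  instrument-grade noise of a few tenths of a percent); the recovery
  analysis therefore ranks the full sweep rather than the gated
  subset.
- Absolute random-coil percentages depend on the intensity calibration
  of the supplied RC spectrum; derandomization and fitting are
  unaffected, so results are internally consistent even if the RC
  reference is imperfectly scaled.
- No conversion from instrument units, baseline handling, or smoothing:
  inputs are assumed calibrated Δε per molar residue.
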