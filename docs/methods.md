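# Methods note

This note describes the models and algorithms implemented in `cysadc`, the
assumptions they rest on, and the numerical choices that matter for the
results.

## 1. Conjugate model

### Masses from formulas

Average molecular masses are computed from an explicit table of standard
(IUPAC conventional) atomic weights rather than a third-party backend, so
that the drug-mimic C23H24N2O3 evaluates to 376.46 ± 0.01 Da — the value
the rest of the mass model is calibrated against. (pyteomics' average-mass
table gives 376.449 Da, just outside that window; it is retained as a
loose cross-check in the tests and as the mzML reader.)

### Topology

A conjugate assembly is a set of chain instances (role `light` or `heavy`,
a fully reduced average base mass, optional heavy-chain glycoforms as mass
deltas), a set of inter-chain disulfide bonds (each with two
`(chain, site-class)` endpoints), a drug-linker, and symmetry generators.
The bundled IgG1 fixture has chains L1, L2, H1, H2 and four bonds: two
light–heavy (site class `LC-HC`) and two heavy–heavy hinge bonds.

Mass bookkeeping: an intact disulfide removes 2.016 Da (two hydrogens)
from the sum of its chains' reduced masses; a reduced bond leaves two free
cysteines that each gain one drug-linker by full Michael addition
(+376.46 Da each, no leaving group). Glycoforms add their delta per heavy
chain (G0F is the +0 reference; G1F is +162.14 Da, one hexose).

### Positional-isomer enumeration

A reduction state is the subset of bonds that were reduced (and hence
conjugated); with 4 bonds there are 16 states, and the drug load is twice
the number of reduced bonds. States that differ only by a symmetry of the
molecule are chemically indistinguishable, so isomer classes are the
orbits of the 16 subsets under the symmetry group.

Two generators are configured for IgG1: the two-fold molecular flip
(L1H1 ↔ L2H2, hinge-1 ↔ hinge-2) and the hinge-bond exchange alone (the
two hinge cystine bridges sit side by side and are not
distinguishable even without flipping the molecule). Their closure is a
Klein four-group; the orbit partition yields exactly 9 classes with DAR
multiplicities {0: 1, 2: 2, 4: 3, 6: 2, 8: 1}. With only the molecular
flip, states such as {LC-HC-1, hinge-1} and {LC-HC-1, hinge-2} would
wrongly remain distinct, giving 12 classes. Enumeration is verified in the
tests against a brute-force orbit oracle (all subsets × full group).

Classes are labelled by drug load plus a letter ordered by decreasing
number of reduced light–heavy bonds: 0, 2a, 2b, 4a, 4b, 4c, 6a, 6b, 8.
Thus 6b is the DAR-6 class with one LC-HC and both hinge bonds reduced.

### Dissociation signatures

Under denaturing RP conditions only covalent bonds survive. The sub-units
of an isoform are the connected components of the chain graph whose edges
are the *intact* bonds (union–find); each component's mass is the sum of
its chains' base masses, minus 2.016 Da per internal intact bond, plus one
drug per reduced-bond endpoint on its chains, plus glycan deltas. Masses
within 0.5 Da are merged into one "unique mass" (the two light+1-drug
sub-units of DAR-8 are identical by symmetry). Mass is conserved: the
sub-unit masses of any isoform sum to its intact mass (asserted to 1 µDa
in the tests).

Key predictions for the fixture (G0F): DAR-8 → {23,580.0; 51,630.6};
6b → {23,580.0; 51,630.6; 74,455.7}. All nine signatures are pairwise
distinct, but 8 ⊂ 6b and 4c ⊂ 6b as sets — a co-elution confound the
library analysis reports explicitly.

## 2. HIC quantitation

Peaks are detected on a baseline-corrected trace (baseline = median of the
first and last 5 % of points) with `scipy.signal.find_peaks` (prominence
default 10⁻³ of the maximum), bounded valley-to-valley (outer bounds where
the signal falls to 25 % of the prominence floor), and integrated with the
trapezoidal rule. Labels A, B, C, … follow elution order.

The per-load area percents are the grouped relative areas (a peak-label →
drug-load map; grouping is an analyst input, with MS confirmation via the
heart-cut branch). The total DAR is the area-weighted mean
Σ (area % × load) / 100; per-load contributions are the summands. Replicate
statistics use the sample (n−1) standard deviation; RSDs are undefined
(`None`, flagged) for n = 1.

Heart-cuts: the transferred volume is the full valve window times the
flow rate (0.20 min × 0.500 mL/min = 0.100 mL); the protein *composition*
of the cut is integrated over the window trimmed by the purge delay at
both ends, using per-species profiles when available (simulation).

## 3. Mass spectrometry tools

### Charge-comb deconvolution

An ESI envelope of a neutral mass M appears at m/z = (M + z·1.00728)/z for
a run of charge states z. For each candidate mass on a grid (default
0.1 Da) the comb score is the sum of interpolated spectrum intensities at
the predicted m/z of every charge in the search range. Local maxima of the
score are accepted if at least `min_supporting_charges` charges contribute
individually above 2 % of the base peak (default 2; the pipeline uses 3 —
see below). The apex is refined by a least-squares parabola fitted over
the contiguous region above 60 % of the local apex (capped at half the
minimum peak separation), which is robust to point-level noise where a
3-point quadratic vertex is not.

With the fixture envelope shapes this recovers noise-free masses exactly
on the grid and seeded noisy masses to ≈ 0.4 ppm — comfortably inside the
10 ppm acceptance bound.

**Harmonics.** A strong envelope at mass M also produces comb alignments
at other masses whose predicted m/z coincide with a *few* of M's charge
states (e.g. a light-chain envelope at z = 15 and 20 aligns with a
~51,876 Da candidate at z' = 33 and 44). These spurious masses are
supported by exactly 2 isolated charges, whereas a genuine in-window
sub-unit spans many; requiring ≥ 3 supporting charges in the pipeline's
library-windowed deconvolution removes them without touching real species.

### Modification deltas

Observed−predicted mass deltas are looked up in a small non-overlapping
table: dehydration (−18.02 ± 1.5 Da; covers the ~17 Da water-loss
satellite seen on one sub-unit peak) and hexose (+162.14 ± 0.8 Da; the
G0F/G1F spacing).

## 4. Isoform assignment

The signature library holds, per isoform, one expected mass per unique
sub-unit, expanded over glycoform combinations of that sub-unit's heavy
chains (combinations with repetition; any variant satisfies the
expectation). Matching is two-sided:

1. every observed mass must be explained — directly (within
   max(1.0 Da, 10 ppm); the Da floor matters because 10 ppm of a light
   chain is only 0.24 Da, below grid resolution), as a glycoform variant,
   or as a single-modification satellite of a directly matched mass;
2. every expected unique mass of the candidate must be observed.

Candidates are ranked by defect count then mean |ppm|; the assignment is
*unique* only when exactly one candidate has zero defects. A library-wide
uniqueness analysis reports identical signature pairs (none among the nine
fixture isoforms) and subset pairs (8 ⊂ 6b, 4c ⊂ 6b).

## 5. Synthetic data generators

Generators emulate the statistical structure of the measurements, not the
physics; ground truth always travels in a manifest so tests never read
truth from the code path under test.

**HIC.** Eight Gaussian peaks (σ = 0.07 min) in elution order A–H over a
10 min run sampled at 20 Hz. Per-load target areas follow the three
published batch profiles (low/medium/high). Within a load, areas split by
fixed fractions: the DAR-6 group uses the observed, batch-stable E/F/G
proportion 43.7 : 14.1 : 42.2; the DAR-4 C : D split defaults to 80 : 20
(a configuration choice — the study does not print it). Replicates apply
unit-mean lognormal area jitter (CV 0.3 %) per peak plus additive baseline
noise (10⁻⁴ AU). Simulated peak identities: C = 4a, E = 6a, F = 6b, H = 8
follow the MS-confirmed assignments; B = 2a, D = 4b and G = 6a are
configuration choices where the study leaves individual labels open (G
shares 6a's signature class with E in the simulation; only its load, not
its label, affects DAR).

**ESI envelopes.** Per charge state, Gaussian peaks whose width is set in
*mass* space, σ_mass = 0.015·√M Da (≈ 2.3 Da at the light chain, 4.8 Da at
a heavy–heavy pair), mimicking the growth of the unresolved isotope
envelope; σ_m/z = σ_mass/z. A Gaussian charge bell weights the states;
charge windows are 15–25 (< 30 kDa), 30–45 (30–70 kDa), 45–60 (above), all
inside the m/z 500–4000 acquisition window on a 0.02 Th grid. Additive
Gaussian noise at 0.5 % of the base peak approximates summed-scan QTOF
signal-to-noise. Heart-cut spectra mix glycoforms (default G0F : G1F =
60 : 40, multinomial across multi-heavy sub-units) and can add satellites
(the dataset generator puts a −18.02 Da, 25 % dehydration satellite on
peak C's heavy–heavy sub-unit).

All generators are deterministic in (seed, replicate index); seeds are
kept below 2³¹.

## 6. Numerical choices

- Trapezoidal integration on the native sampling grid (20 Hz ⇒ ~0.001 %
  area error on σ = 0.07 min Gaussians).
- Sample (n−1) standard deviations for replicate RSDs.
- Deconvolution grid 0.1 Da; parabola refinement recovers sub-grid apexes.
- Unique-mass merging and signature comparison at 0.5 Da; matching at
  max(1.0 Da, 10 ppm).
- DAR values are computed at full precision and rounded only for display.

## 7. Problem sizes and runtime

Everything is desk-scale: 16 reduction states, 9 isoform classes,
chromatograms of 12,000 points, spectra of 175,000 points, deconvolution
windows of a few thousand candidate masses × ≤ 16 charges. The full
three-batch pipeline runs in ≈ 0.3 s; the complete test suite in ≈ 1 min;
the acceptance script in ≈ 1 s.
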