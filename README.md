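# cysadc

Multidimensional characterization of cysteine-conjugated antibody–drug
conjugates (ADCs): positional-isomer enumeration, drug-to-antibody ratio
(DAR) quantitation from hydrophobic-interaction chromatography (HIC), and
isoform identification from dissociated sub-unit masses measured by
reversed-phase LC/MS after heart-cutting.

## Scientific background

Conjugating drugs to the cysteines freed by partial reduction of an IgG1's
four inter-chain disulfides (two light–heavy, two hinge) produces a mixture
of species with 0, 2, 4, 6 or 8 drugs per antibody. HIC resolves these by
drug load, so the area-weighted mean of the per-load peak areas gives the
average DAR. Species with the *same* drug load but drugs at *different*
cysteine sites — positional isomers — can also separate in HIC, but their
intact masses are identical, so identity cannot come from intact MS.

The discriminating observable is the *dissociation signature*: under
denaturing reversed-phase conditions an isoform falls apart into the
covalent fragments held together by its remaining intact disulfides. The
multiset of fragment masses differs between positional isomers. For
example the fully conjugated DAR-8 species yields exactly two unique
masses (light chain + 1 drug; heavy chain + 3 drugs), while the DAR-6
isoform with one light–heavy and both hinge bonds reduced yields three
(light + 1 drug; heavy + 3 drugs; the still-linked light–heavy pair + 2
drugs). A heart-cut of one HIC peak, run on a second-dimension RP column
into an ESI-QTOF, therefore identifies which isomer the peak contains.

`cysadc` implements this workflow end to end:

- **`conjugate_model`** — chemical formulas and average masses from
  standard atomic weights; the conjugate topology (chains, inter-chain
  bonds, drug-linker); enumeration of positional-isomer classes as orbits
  of reduction states under the molecule's symmetry group; dissociation
  into covalent sub-units and their masses (glycoform-aware).
- **`hic_quant`** — chromatogram peak detection/integration (trapezoidal,
  valley-to-valley), per-load grouping, DAR arithmetic, replicate
  statistics, heart-cut window accounting.
- **`ms_tools`** — continuum spectrum peak picking and charge-comb
  deconvolution of multiply-charged ESI envelopes to neutral average
  masses; ppm errors; known single-modification deltas (dehydration,
  hexose).
- **`assignment`** — predicted signature library; two-sided matching of
  observed masses (every observation explained AND every expected mass
  observed) with glycoform variants and satellite co-explanation;
  library-wide uniqueness analysis.
- **`synthetic_data`** — seeded generators for HIC chromatograms of three
  conjugation batches, heart-cut ESI spectra of any isoform, and complete
  datasets with ground-truth manifests.
- **`pipeline` / `cli`** — orchestration and a `cysadc` command-line tool.

The bundled conjugate fixture is **synthetic**: the real mAb sequence
behind the study system is proprietary, so the chain base masses are
back-derived from the published conjugated sub-unit masses (light + 1 drug
= 23,580.0 Da; heavy(G0F) + 3 drugs = 51,630.6 Da) with a 376.46 Da
maleimide drug-mimic (C23H24N2O3).

## Worked example

List the nine positional-isomer classes of the bundled IgG1 fixture and
their dissociation signatures:

```text
$ cysadc enumerate
  0  DAR 0  1 state(s)  unique masses: 147401.5
 2a  DAR 2  2 state(s)  unique masses: 23580.0, 124576.4
 2b  DAR 2  2 state(s)  unique masses: 148156.4
 4a  DAR 4  1 state(s)  unique masses: 23580.0, 101751.3
 4b  DAR 4  4 state(s)  unique masses: 23580.0, 125331.3
 4c  DAR 4  1 state(s)  unique masses: 74455.7
 6a  DAR 6  2 state(s)  unique masses: 23580.0, 102506.3
 6b  DAR 6  2 state(s)  unique masses: 23580.0, 51630.6, 74455.7
  8  DAR 8  1 state(s)  unique masses: 23580.0, 51630.6
note: signature of 4c is a subset of 6b (co-elution confound)
note: signature of 8 is a subset of 6b (co-elution confound)
```

Simulate a medium-load batch (triplicate HIC runs plus one heart-cut
spectrum per peak, with a ground-truth manifest) and quantify the DAR:

```text
$ cysadc simulate --batch medium --seed 7 --out demo
wrote 3 chromatograms, 8 spectra to demo

$ cysadc quantify --chrom demo/hic_medium_rep0.csv \
                  --chrom demo/hic_medium_rep1.csv \
                  --chrom demo/hic_medium_rep2.csv --out demo/dar.csv
total DAR 4.44 (3 replicate(s)) -> demo/dar.csv

$ cat demo/dar.csv
batch,drug_load,area_percent,rsd_percent,dar_contribution,total_dar,total_rsd_percent
,0,2.8,0.42,0.0,4.44,0.05
,2,18.79,0.31,0.38,4.44,0.05
,4,41.79,0.22,1.67,4.44,0.05
,6,26.86,0.32,1.61,4.44,0.05
,8,9.77,0.02,0.78,4.44,0.05
```

Deconvolve the heart-cut spectrum of the last-eluting peak (H) in the
light- and heavy-scale mass windows, then assign the isoform:

```text
$ cysadc deconvolve --spec demo/heartcut_medium_H.csv \
    --mass-min 23300 --mass-max 23900 --z-min 15 --z-max 25 --out demo/light.csv
3 mass(es) -> demo/light.csv
$ head -3 demo/light.csv
mass_da,score,n_charges
23580.0,6.107558370208987,11
23468.5,0.42416519901649047,2

$ cysadc deconvolve --spec demo/heartcut_medium_H.csv \
    --mass-min 51300 --mass-max 52100 --z-min 30 --z-max 45 --out demo/heavy.csv
3 mass(es) -> demo/heavy.csv
$ head -4 demo/heavy.csv
mass_da,score,n_charges
51630.6,5.4392116528033245,16
51792.7,3.624859778532455,16
51876.0,1.1452010829940942,2
```

The heavy window recovers both glycoforms of the same sub-unit — 51,630.6
(G0F) and 51,792.7 (G1F, +162.1 Da, one hexose) — plus a weak charge-comb
harmonic at 51,876.0 supported by only 2 charge states; the pipeline's
library-driven deconvolution requires ≥3 supporting charges and discards
it. Matching the two true masses against the signature library:

```text
$ printf 'mass_da\n23580.0\n51630.6\n' > demo/masses.csv
$ cysadc assign --masses demo/masses.csv --out demo/assign.json
assignment: 8 -> demo/assign.json
```

Peak H is the fully conjugated DAR-8 species — the only isoform whose
complete signature is {23,580.0; 51,630.6}. The whole workflow (all three
batches, quantitation, deconvolution, assignment, report files) also runs
as one command: `cysadc run --seed 7 --out report/`.

## Key parameters

| Parameter | Default | Where |
|---|---|---|
| Drug-linker formula / mass | C23H24N2O3, 376.46 Da | conjugate config |
| Disulfide mass decrement | 2.016 Da per intact bond | conjugate config |
| Glycoforms (heavy chain) | G0F (+0), G1F (+162.14 Da) | conjugate config |
| Unique-mass merge tolerance | 0.5 Da | `dissociate` |
| Deconvolution mass grid | 0.1 Da | `deconvolve` |
| Min supporting charges | 2 (bare), 3 (pipeline) | `deconvolve` / pipeline |
| Matching tolerance | max(1.0 Da, 10 ppm) | `match_observed` |
| Replicate area jitter CV | 0.3 % (lognormal) | HIC generator |
| Spectrum noise | 0.5 % of base peak (Gaussian) | envelope generator |
| Acquisition window | m/z 500–4000, 0.02 Th grid | envelope generator |

## Scope and limitations

- The generators emulate the *statistical* structure of the measurements
  (elution order, relative areas, replicate variability, charge envelopes),
  not retention or ionization physics; retention times are plumbing.
- Chain masses are synthetic back-derivations, not a real mAb sequence;
  absolute masses are internally consistent but not sequence-derived.
- Deconvolution assumes average-mass (isotopically unresolved) peaks, as
  appropriate for intact sub-units on a QTOF; it is not an isotope-resolved
  algorithm.
- Instrument-dependent figures (absolute ppm errors of a real QTOF, real
  replicate RSDs) cannot be reproduced at desk scale and are covered by
  property-based substitutes in the test suite.

See `docs/methods.md` for the full methods note.
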