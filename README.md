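# einscan

Analysis of **elastic incoherent neutron scattering (EINS)** temperature
scans of hydrated protein powders: data reduction, mean-square-displacement
(MSD) extraction, harmonic force constants, dynamical-transition detection —
plus a forward simulator so that every stage can be validated by parameter
recovery.

## Who this is for

Fixed-window elastic scans on backscattering / time-of-flight spectrometers
(e.g. ILL IN6, IN13, IN16) measure the elastic intensity S(Q, ω=0) of a
powder as it is heated from ~20 K. Because hydrogen's incoherent
cross-section (80.27 barn) dominates everything else in a protein, the decay
of S with momentum transfer Q tracks the mean square displacement of the
protein's hydrogens on the instrument's timescale t ≈ ħ/δE. This package
implements the standard analysis chain for such scans and quantifies when
each approximation holds.

## The models

1. **Gaussian (Debye–Waller) approximation**

       S(Q, 0) = I₀ exp(−⟨u²⟩ Q² / 6)

   fitted as weighted linear regression of ln S on Q², valid while
   Q²⟨u²⟩ ≤ 2. ⟨u²⟩ is the full 3-D amplitude relative to the 20 K
   reference; the per-atom displacement scale is ⟨u²⟩/6.

2. **Bimodal two-population model** — hydrogens split into mobile methyl
   (fraction a₁) and stiffer non-methyl non-exchangeable hydrogens
   (a₂ = 1 − a₁):

       S(Q, 0) = I₀ [a₁ e^(−⟨u²⟩₁Q²/6) + a₂ e^(−⟨u²⟩₂Q²/6)],   ⟨u²⟩₁ ≥ ⟨u²⟩₂

   with a₁ computed from the sequence (0.26 for a P2-like 132-residue
   chain) or refitted.

3. **Einstein oscillator** for the low-temperature harmonic regime:

       ⟨u²⟩/3 = (hν / 2k) [coth(hν / 2k_B T) − 1]

   giving a mean force constant k (N/m) and frequency ν (ps⁻¹) per
   hydrogen population.

4. **Slope-change detection** on the summed elastic intensity
   (piecewise-linear fit of the log-sum, modified-BIC model selection) to
   locate the resolution-dependent methyl-group activation and the
   hydration-dependent protein dynamical transition near 240 K.

The fitters are scikit-learn style estimators (`GaussianElasticModel`,
`BimodalElasticModel`, `EinsteinOscillatorModel`, `PiecewiseLinearModel` in
`einscan.models`) with thin domain-level wrappers in `einscan.fitting` and
`einscan.reduction`.

## Worked example

Generate a synthetic wild-type-like scan on the 1-ns instrument, a "hinge
mutant" that is softer above the dynamical transition, and compare:

```bash
einscan generate --instrument IN16 --out wt.csv --seed 11
printf 'pdt_slope_methyl: 0.016\npdt_slope_nonmethyl: 0.007\n' > mutant.yaml
einscan generate --instrument IN16 --out mutant.csv --seed 12 --scenario mutant.yaml
einscan analyze --instrument IN16 --scan wt.csv --scan mutant.csv \
                --label wt --label mutant --out results
```

prints

```
[wt] transitions: [240.0] K
[wt] gaussian: k = 2.41 N/m, nu = 1.27 1/ps
[wt] bimodal-methyl: k = 0.64 N/m, nu = 3.87 1/ps
[wt] bimodal-nonmethyl: k = 3.49 N/m, nu = 3.50 1/ps
[mutant] transitions: [240.0] K
[mutant] gaussian: k = 1.86 N/m, nu = 0.00 1/ps
[mutant] bimodal-methyl: k = 0.68 N/m, nu = 3.77 1/ps
[mutant] bimodal-nonmethyl: k = 5.53 N/m, nu = 1.96 1/ps
outputs written to results
```

Reading this: both samples show the slope change at **240 K** (the
dynamical transition built into the generator). The bimodal fit assigns the
methyl population a soft force constant (**k ≈ 0.6 N/m**, matching the
generator truth 0.6) and the non-methyl population a much stiffer one —
its MSD sits near the instrument's sensitivity floor below 130 K, so its k
is recovered only as "large" at this noise level, with correspondingly wide
errors in the written tables. The single-Gaussian k is a population average
and sits in between. `results/` contains tidy CSVs (`msd_*.csv`,
`summed_*.csv`, `msd_difference.csv`) and a JSON report with the fit
parameters, transition report, validity flags and convention metadata; the
per-temperature `msd_difference.csv` shows the mutant exceeding the wild
type only above 240 K.

Composition and scattering budget of the bundled 132-residue stand-in
sequence (a *synthetic* P2-like composition — see `docs/methods.md`):

```bash
$ einscan composition
sequence_file: .../einscan/data/p2_human_synthetic.fasta
n_residues: 132
element_counts: {'C': 684, 'H': 1064, 'N': 176, 'O': 199, 'S': 5}
hydrogen_fraction_of_atoms: 0.5
hydrogen_classes: {'methyl_h': 213, 'nonmethyl_nonexch_h': 608, 'exchangeable_h': 243}
a1_methyl_fraction: 0.2594
solvent_incoherent_share: 0.0124
coherent_share: 0.1532
ligand_h_share: 0.0291
cross_section_table: einscan-xs-1
```

i.e. hydrogen is 50% of all atoms, methyls carry a₁ = 0.26 of the
non-exchangeable hydrogens, D₂O solvent at 0.28 g/g contributes ~1% of the
incoherent signal, and a bound palmitate only ~3% of the protein hydrogens
— the quantitative basis for treating the elastic signal as protein-H
incoherent scattering with fixed population fractions.

## Library surface

```python
import einscan as es

profile = es.builtin_profile("IN16")
truth = es.TruthProfile()                      # two-population ground truth
raw = es.generate_scan(truth, profile, noise=es.NoiseModel(5000, seed=1))
scan = es.normalize_to_reference(raw, 20.0)
methyl, nonmethyl = es.msd_vs_temperature(scan, profile, model="bimodal")
osc = es.fit_oscillator(methyl, profile.oscillator_fit_t_max)
print(osc.force_constant_k, osc.frequency_nu)
```

See `docs/methods.md` for the model conventions, noise calibration, the
treatment of unidentified population splits, and known limitations.
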