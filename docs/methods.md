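# Methods

## The measurement being modelled

An elastic fixed-window scan on a neutron backscattering or time-of-flight
spectrometer records the intensity scattered with (nominally) zero energy
transfer, S(Q, ω=0), as a hydrated protein powder is heated from cryogenic
temperature. Motions slower than t ≈ ħ/δE (δE = energy resolution, FWHM)
appear static and scatter elastically; faster motions leak intensity out of
the resolution window. The decay of the elastic intensity with momentum
transfer Q therefore measures the mean square displacement (MSD) of the
scattering atoms on the instrument's timescale — dominated by hydrogen, whose
incoherent cross-section (80.27 barn) exceeds every other element in a
protein by two to five orders of magnitude.

Three ILL instrument profiles are built in: IN6 (70 μeV, ≈10 ps,
0.3 < Q < 2 Å⁻¹), IN13 (8 μeV, ≈100 ps, 0.2 < Q < 4.9 Å⁻¹) and IN16
(0.9 μeV, ≈1 ns, 0.19 < Q < 1.89 Å⁻¹). The timescale convention is
t = ħ/δE; the accessible amplitude window is (2π/q_max, 2π/q_min).

## Models

**Gaussian (Debye–Waller) approximation.** S(Q,0) = I₀ exp(−⟨u²⟩Q²/6),
fitted as a weighted linear regression of ln S on Q². ⟨u²⟩ is the *full
three-dimensional amplitude* relative to the 20 K reference scan; the
per-atom displacement scale is ⟨u²⟩/6, and the common literature convention
exp(−Q²⟨u²⟩/3) differs by a factor 2 on ⟨u²⟩. All tables carry this
convention string. The approximation is trusted while Q²⟨u²⟩ ≤ 2 (isotropic
motion; ≤ 3 for ellipsoidal local motion), checked per fit and flagged.
Each instrument profile carries the Q² ceiling of its Gaussian window
(IN6 4, IN13 3.5, IN16 0.77 Å⁻²) so it can be overridden per run.

**Bimodal (two-population) model.** Protein hydrogens are split into methyl
hydrogens (fraction a₁) and non-methyl non-exchangeable hydrogens (a₂ = 1 −
a₁), each class fluctuating homogeneously:
S = I₀ [a₁ e^(−⟨u²⟩₁Q²/6) + a₂ e^(−⟨u²⟩₂Q²/6)], with the ordering
constraint ⟨u²⟩₁ ≥ ⟨u²⟩₂ (methyls are the mobile class), enforced by the
parametrisation ⟨u²⟩₁ = ⟨u²⟩₂ + δ, δ ≥ 0, which also prevents label
swapping. Fractions default to 0.26/0.74 — the value computed from the
composition module for a P2-like 132-residue chain — and can be refitted
(`free_fractions`) or recomputed from any FASTA. Solved by bounded
trust-region least squares with a four-point multistart (collapsed and
strongly separated starts) because the collapsed solution ⟨u²⟩₁ = ⟨u²⟩₂ is
a stationary point that can trap a single start.

*Unidentified splits.* When the fitted δ is at its bound (collapse), only the
population average u_avg = a₁⟨u²⟩₁ + a₂⟨u²⟩₂ is identified and the
per-population Jacobian is singular, so naive standard errors would be
dishonestly small. The estimator flags these fits (`separated_ = False`) and
widens the reported uncertainties to span the feasible interval
(⟨u²⟩₁ ∈ [u_avg, u_avg/a₁], ⟨u²⟩₂ ∈ [0, u_avg]). When the temperature sweep
assembles MSD series, each population is quoted at the midpoint of its
feasible interval — a choice that preserves a₁⟨u²⟩₁ + a₂⟨u²⟩₂ = u_avg
exactly and encodes only the model's own ordering constraint. Without this
treatment, collapsed points enter the downstream harmonic fits with
near-zero error bars and bias the methyl force constant several-fold stiff.

**Einstein oscillator.** At low temperature the MSD follows
⟨u²⟩/3 = (hν/2k)·[coth(hν/2k_BT) − 1], with k the mean force constant (N/m)
and ν the mean frequency (ps⁻¹); the bracketed −1 removes the zero-point
term so ⟨u²⟩(0) = 0. Because measured MSDs are referenced to the 20 K scan,
the fitted model is ⟨u²⟩(T) − ⟨u²⟩(T_ref); the offset is ≈3×10⁻⁴ Å² for
typical parameters but including it keeps noise-free round trips exact.
Planck's constant is named `planck_h` and hydration `hydration` throughout,
since the field's conventional symbol h is overloaded. Fits are weighted
nonlinear least squares with a 5×5 multistart over k ∈ [0.1, 50] N/m,
ν ∈ [0.1, 20] ps⁻¹ (geometric grids), solver tolerances 10⁻¹⁴, standard
errors from the Jacobian. coth(x) − 1 is evaluated as 2/(e²ˣ − 1) via
`expm1` for stability at large x. The default fit windows are 20–150 K
(IN6, IN13) and 20–130 K (IN16); for a truth known to be purely harmonic
(validation scenarios with no anharmonic onsets) the full scanned range is
appropriate and `recovery_experiment(fit_t_max=...)` exposes that choice.

**Transition detection.** The summed elastic intensity over 0.2 < Q < 2 Å⁻¹,
renormalised to 1 at 20 K, decreases with temperature; the activation of a
new class of motion (methyl-group activation, whose apparent onset moves
with instrument resolution; the hydration-dependent dynamical transition
near 240 K) appears as a change of slope. Detection fits a continuous
piecewise-linear model to **ln(summed intensity)** — the log scale is
natural because the intensity decays exponentially with the MSD, so a
piecewise-linear MSD law gives near-linear log segments, whereas on the raw
scale the detector spends breaks on exponential curvature. Breaks are
restricted to observed bin centres (≥3 points per side), searched
exhaustively for 0–2 breaks, and the break count is selected by a modified
BIC, n·ln(RSS/n) + p·ln n with p = 2 + 3·n_breaks: each break is charged
its slope-change and location parameters plus one extra ln n location term
(changepoint-BIC in the spirit of Zhang & Siegmund). Plain BIC over-detects
on ~40-point series because of the exhaustive location scan (measured ≈10%
false positives on a permuted-residual null); the extra term brings the
null false-positive rate to ≈0% while leaving the located breaks unchanged
on break-bearing series. The search starts at 100 K, below which quantum
saturation of harmonic motion curves the series.

## Reduction conventions

- Empty-cell subtraction: I′ = I − transmission·I_empty (default
  transmission 0.95), errors in quadrature; negative cells are clipped to
  zero (counting data) and the clip count is logged and recorded.
- Normalisation: every detector column is divided by its value in the scan
  row nearest the reference temperature (20 K; matching tolerance half a
  temperature bin). Relative errors add in quadrature, which induces a
  correlated error component shared by all temperatures of one column.
- Binning: greedy consecutive [T₀, T₀+width) bins (default 5 K; 10 K is
  used for the thermal backscattering data to improve statistics),
  inverse-variance weighted means, bin temperature = mean of members. A scan
  already on the target grid passes through unchanged.
- Q windows are open intervals; temperatures are bin centres.

## Composition and scattering budgets

Chains are built from free amino-acid formulas minus one water per peptide
bond, so both termini are explicit. Hydrogen classes: exchangeable = every
H bonded to N, O or S (backbone amides, side-chain OH/NH/SH, termini);
methyl = 3 H per side-chain CH₃ (Ala 1, Val 2, Leu 2, Ile 2, Thr 1, Met 1);
the remainder is non-methyl non-exchangeable. The bimodal fractions are
a₁ = methyl / (methyl + non-methyl non-exchangeable).

Budgets use a versioned cross-section table (incoherent, barn: H 80.27,
D 2.05, N 0.5, C and O 0.001, S 0.007; coherent from the standard bound-atom
table). D₂O exchange replaces the exchangeable H by D (complete exchange by
default; a partial-exchange fraction is exposed). Solvent D₂O is
2·(hydration · protein mass / 20 g mol⁻¹) deuterons per molecule. The
solvent share is reported within the incoherent channel, where it is ≈1% at
hydration 0.28 g/g. The coherent share (coherent / total, over protein +
exchanged D + solvent) is a diagnostic only: it is strongly sensitive to the
exchange model (≈9% with no exchange, ≈15% under full exchange for a
P2-like chain), so no invariant pins it.

**Bundled sequence.** The package ships
`data/p2_human_synthetic.fasta`, a *synthetic stand-in*: a 132-residue chain
whose amino-acid composition was constructed to match the published
composition characteristics of a human myelin P2-like FABP (hydrogen ≈50%
of all atoms; methyl fraction a₁ = 0.26 of non-exchangeable H; bound
palmitate contributing ≈3% of protein H; ≈1% solvent incoherent share at
0.28 g/g). It is not a database record — the residue order is arbitrary and
only composition-level quantities computed from it are meaningful. Users
analysing real data should supply the authentic sequence via `--fasta`.
Whether published fractions were computed with or without expression tags
or bound ligand is not documented; the stand-in models the mature chain
without ligand, with the ligand handled separately.

## The synthetic generator

`TruthProfile` defines ground truth as, per population, an Einstein
oscillator baseline (referenced to 20 K) plus hinge (piecewise-linear)
anharmonic terms: a methyl-activation onset acting on the methyl population
only (defaults 180/150/130 K for IN6/IN13/IN16 — resolution dependence
enters *only* through this per-instrument onset) and a dynamical-transition
onset at 240 K acting on both populations. Hinges, not Arrhenius rotor
kinetics, because slope changes are exactly what the detector is scored
against. Defaults: harmonic parameters from the published 1-ns-instrument
two-population fits (methyl k = 0.6 N/m, ν = 2.3 ps⁻¹; non-methyl k = 20
N/m, ν = 2.8 ps⁻¹), fractions 0.26/0.74, mga_slope 0.004 Å²/K, pdt slopes
0.010 (methyl) / 0.004 (non-methyl) Å²/K — chosen so the 300 K MSDs and the
summed-intensity decay are on the scale of published hydrated-powder data.

Scans are generated on 16 evenly spaced detectors across the instrument's Q
range, over 20–305 K in 5-K steps. Counts = S(Q,T) · counts_per_point ·
efficiency(Q), with per-detector efficiencies drawn once from U(0.8, 1.2)
and Poisson noise, both from the same seed; reference normalisation must
therefore genuinely cancel the efficiencies, and the correlated
reference-row error structure is exercised downstream. `noise=None` gives
the exact forward model with zero errors.

**Noise calibration.** No published noise magnitude exists for these scans,
so the default is a convention: "2% effective noise" means 2% relative
uncertainty on the *normalised* intensities entering the fits; since sample
and reference rows contribute in quadrature, that is counts_per_point =
5000 (≈1.4% per raw point). Published parameter uncertainties (±8–10% on
the force constants) imply real counting statistics substantially better
than this, so the default is a conservative emulation. What passing
recovery tests show is that the *pipeline* is unbiased and correctly
weighted at that noise level — not that any particular real dataset has
this noise structure; real detectors have Q-dependent efficiency drift,
multiple scattering and self-shielding that the generator does not emulate.

`recovery_experiment` runs generate → normalise → sweep → oscillator fits
per replicate (child seeds spawned from one seed, fully deterministic) and
reports bias, RMSE and median relative error per population, the fraction
of replicates preserving the methyl < non-methyl force-constant ordering,
and breakpoint-location errors. A replicate whose MSD series is identically
zero within the fit window is reported as k = +∞ ("rigid beyond the
instrument's sensitivity") — on the 1-ns instrument the non-methyl
population sits near the sensitivity floor below 130 K, so this outcome is
expected and counted separately (`n_rigid`).

## Numerical choices and degenerate inputs

- Weights are inverse-variance throughout; ln S errors are σ_S/S. When all
  errors are zero (noise-free data), unit weights are used and parameter
  variances are scaled by residual variance instead of taken as χ².
- Solver: scipy trust-region reflective least squares, ftol = xtol = gtol =
  10⁻¹⁴; bounds I₀ ∈ (0, 10], ⟨u²⟩ ∈ [0, 60] Å².
- Gaussian fits require ≥3 points, oscillator fits ≥5; an all-zero MSD
  series is rejected as unidentifiable.
- Negative post-subtraction counts clip to zero so downstream log fits stay
  defined; zero-count cells are excluded from log fits (S > 0 mask).
- Per-temperature fits are independent — no smoothing across temperature.
- Breakpoint ties in the exhaustive search resolve to the earliest
  candidate (strict BIC improvement required to switch).

## Validation scale

The default validation scenarios (used by the test suite and
`scripts/acceptance.py`) run 100 replicates of the stochastic recovery
experiments and 200 replicates of the null-calibration check on the default
58×16 scans — a few minutes on one core. Noise-free round trips recover all
generator parameters to better than 10⁻⁴ relative on all three instrument
profiles.

## Known limitations

- Delta-function resolution: quasielastic broadening and resolution line
  shapes are not modelled (elastic channel only, as in standard
  fixed-window analysis).
- No multiple-scattering, absorption or self-shielding corrections; real
  reductions handle these upstream.
- The bimodal split below ~100 K at realistic noise is weakly identified on
  narrow-Q instruments; the reported feasible-interval uncertainties make
  this explicit rather than hiding it.
- The composition stand-in supports composition-level statements only; any
  residue-order-dependent analysis needs the authentic sequence.
- The heating-rate schedule of real scans (slower ramps at high T) is not
  modelled; counting statistics are uniform per bin.
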