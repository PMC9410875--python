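# Methods

`foxcoop` models how forkhead-box (FOX) transcription factors occupy a
homotypic two-site cluster on a promoter fragment — two adjacent binding
elements (a canonical FBE, 5′-RYAAAYA-3′, plus a second non-canonical site)
on one DNA duplex — and provides the quantitative machinery used to
characterise that occupancy in vitro: consensus scanning, gel-shift
(EMSA) band-fraction statistics, titration calorimetry (ITC), solution
stoichiometry from light-scattering masses, and minor-groove geometry.

## The two-site lattice model

A duplex carries two sites with microscopic association constants K₁ and K₂
(M⁻¹) and a cooperativity factor ω weighting the doubly-bound state.  At
free protein concentration *p*:

    Z  = 1 + (K₁ + K₂)·p + ω·K₁K₂·p²
    f₀ = 1/Z          (free DNA)
    f₁ = (K₁+K₂)·p/Z  (monomer shift)
    f₂ = ω·K₁K₂·p²/Z  (dimer shift)

ω > 1 is positive cooperativity, ω = 1 independent sites, ω < 1 negative.
EMSA lanes run at micromolar DNA, so free protein is solved from mass
conservation, `p_total = p + d_total·(f₁ + 2f₂)`, by bracketed Brent
iteration on [0, p_total]; the bound term is strictly increasing in *p* so
the root is unique.  The conservation residual is held below 10⁻¹⁰
relative.

**Lane estimator.** The statistical-factor-corrected ratio
ω̂ = 4·f₀·f₂/f₁² equals ω exactly for equivalent sites (K₁ = K₂) and
reads low by the fixed, concentration-independent factor
4K₁K₂/(K₁+K₂)² ≤ 1 otherwise — this bias is part of the contract and is
regression-tested at K₁ = 10K₂.  A lane contributes only when *all three*
band fractions exceed ε = 0.05: all three bands enter the ratio, and a
band below the densitometry noise scale gives the estimator unbounded
bias, not merely variance (noise is clipped at zero, so a near-zero band
is systematically inflated).  `epsilon_bands=0` restores an f₁-only rule.
The series estimate is the mean over usable lanes with its SEM;
classification against ω = 1 uses a 2·SEM band (minimum ±0.05).

**Identifiability.** The observable fractions depend on (K₁, K₂, ω) only
through K₁+K₂ and ω·K₁K₂, so one titration cannot separate all three.
`fit_affinities` therefore ties K₁ = K₂ by default (log-space, five
fixed-seed multi-starts, full depletion solved inside the objective);
the `fix` mask pins any parameter from outside information (e.g. an
ITC-derived K) and unties the rest.  Fitted outputs are canonicalised to
K₁ ≥ K₂.  Macroscopic stepwise constants follow the standard mapping
Ka₁ = K₁+K₂, Ka₂ = ω·K₁K₂/(K₁+K₂) (equal independent sites give the pure
statistical factor Ka₁/Ka₂ = 4).

## ITC

Cell bookkeeping uses the constant-volume displacement convention: an
injection of volume v dilutes cell contents by (1 − v/V₀) and delivers
syringe material at c·(v/V₀)·(1 − v/2V₀); injected, in-cell and expelled
moles balance to machine precision.  Cumulative heat is
Q = V₀·d·(f₁·ΔH₁ + f₂·(ΔH₁+ΔH₂)) for the sequential two-site model
(mapped to the lattice via K = Ka₁/2, ω = 4Ka₂/Ka₁) and
Q = V₀·d·n·θ·ΔH₁ for n identical sites; per-injection heats carry the
mid-injection displacement correction and are normalised per mole of
injectant.  The one-site simulator agrees with the closed-form Wiseman
isotherm in the no-dilution limit to 10⁻⁸, and the sequential model with
ω = 1, K₁ = K₂ collapses onto one-site n = 2 to 10⁻⁸.

Fits minimise squared residuals of normalised heats (log-space Ka, free
constant dilution offset, five fixed-seed starts).  Model choice uses
AICc; a comparison is flagged indeterminate when |ΔAICc| < 2 *or* when a
constant-heat null model beats both binding models (with unequal
parameter counts, pure noise never yields ΔAICc ≈ 0 — the null baseline
is the meaningful "no signal" test).  The biphasic index counts sign
changes of the first differences after 3-point median smoothing; a
two-site isotherm with opposing-sign stepwise enthalpies scores ≥ 1.

Default protocols follow the published bench settings: 200 µl cell with
50 µM duplex; 20 × 2.5 µl of 750 µM protein (single-site runs) or
40 × 2 µl of 850 µM (two-site probe).  Cell volume is instrument-typical
and configurable; heats of dilution default to zero in simulation and to
a free offset in fits.

## Stoichiometry from solution masses

`duplex_mass` sums average dNMP residue masses (dAMP 331.2218, dCMP
307.1971, dGMP 347.2212, dTMP 322.2085 Da) over both strands minus one
water (18.0153 Da) per phosphodiester bond; the printed 16-mer duplex
computes to 9.916 kDa.  `infer_stoichiometry` rounds
(complex − DNA)/protomer to the nearest integer and reports the residual;
the published masses (12.4 kDa protomer; 20.1 and 32.7 kDa complexes)
yield 1:1 and 2:1 calls with residuals ≈ −2 kDa, well under half a
protomer.

## Minor-groove geometry

Widths use the phosphate-distance convention: at each backbone level the
minimum cross-minor-groove P–P distance to partner phosphates at register
offsets −5…−1 relative to the Watson–Crick partner level, minus 5.8 Å
(two phosphate radii).  Two levels are excluded at each end (end fraying);
missing phosphates leave gaps, never interpolation.  The published
comparison used spline-based Curves+; the phosphate convention is fully
specifiable, reproduces the canonical 5.7 Å B-DNA baseline, and is the
basis for a ±0.5 Å tolerance when comparing against deposited crystal
structures (7VOU/7VOV/7VOX), which must be downloaded separately — the
shipped tests use only generated coordinates.

The ideal fiber generator places P atoms on two antiparallel helices:
radius 8.91 Å, twist 36°/bp, rise 3.38 Å/bp, inter-strand phosphate phase
144°; each strand's 5′ residue carries no phosphate.  The interior width
has the closed form √(2r²(1−cos 36°) + (3·3.38)²) − 5.8 = 5.739 Å,
verified against brute-force minimisation, and shrinking the phase angle
narrows the groove monotonically.  All widths are rigid-motion invariant.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (parameters, seed).  EMSA noise is
Gaussian on each fraction (σ = 0.03 default), clipped to [0, 1] and
renormalised — a stand-in for densitometry error; it does not model gel
smearing, lane-to-lane loading bias, or correlated background.  ITC noise
is Gaussian on normalised heats (default 2% of the largest heat); no
baseline drift or injection artefacts.  Promoter backgrounds are i.i.d.
uniform ACGT, so passing scan tests demonstrate correctness of window
logic, not power on real genomic composition.

The wild-type demo parameter set (K₁ = K₂ = 1.27×10⁶ M⁻¹ from the
published single-site K_D of 0.79 µM; ω = 3; 2.5 µM probe; protein:DNA
ratios 0.25–8) is a documented convention for tests and demos, not a
fitted description of the two-site probe.  Scenario conventions:

| scenario | overrides | emulates |
|---|---|---|
| WT | none | cooperative wild-type probe |
| mut1 | K₁ ×0.002, K₂ ×0.02, ω=1 | first site dead; weak residual second-site binding; dimer lost |
| mut2 | K₂ ×2/3, ω=1 | cooperativity abolished; lane estimator reads 4f/(1+f)² = 0.96, the reported residual value |
| mut3 | both ×0.002, ω=1 | no occupancy at assay concentrations |
| spacer_S1 / S2 | ω → 1 + 0.25/0.05·(ω−1) | half-site spacing insertions degrading the allosteric register |
| Mg_depleted | ω → 1 + 0.1·(ω−1) | loss of the cation-mediated protein–protein contribution |

The mut2 weakening factor comes from inverting the estimator's bias
formula at the reported residual cooperativity, not from fitting.

## Numerical choices

Root finding: Brent with rtol = 4·eps.  Least squares: scipy `trf`,
ftol = xtol = gtol = 10⁻¹⁴ (EMSA) / 10⁻¹² (ITC).  Ties K₁↔K₂ broken by
canonical ordering.  Degenerate inputs fail loudly: empty sequences, `N`
in mass computations, fractions off-simplex by more than 2%, fewer than
four lanes or eight injections, injections exceeding the cell volume.
Problem sizes in the shipped tests (1000 parameter draws for the
enumeration oracle, 50 noise seeds × 3 ω values, 100 model-selection
runs, 500 random sequences for the scan oracle, 16–20 bp duplexes) keep
the full suite around two minutes on one core while leaving the binomial
and median-based assertions well-powered.

## Known limitations

Two sites only; one protein species (no heterotypic clusters); no
kinetics; no gel-image quantification; consensus matching only (no PWM /
log-odds scoring, so genome-scale scanning statistics are out of scope);
no Curves+-style helicoidal analysis beyond minor-groove width; spacer
and cation-depletion effects are represented as parameter scenarios, not
predicted from structure.
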