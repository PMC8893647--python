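# Methods

## Model structure and assumptions

The cell is modeled as two well-mixed, isothermal, isobaric compartments.
Seven pools evolve by mass-action kinetics: cytoplasmic amino acids (A_C),
non-ribosomal proteins (P_C, P_N), free ribosomal proteins (RP_C, RP_N)
and mature ribosomes (R_C, R_N). Bimolecular steps (translation,
carrier-mediated transport, assisted degradation) divide by the
compartment volume because reaction propensities are concentration-based
even though the state variables are counts. Ribosome maturation is
collapsed into a single nuclear assembly step — subunit (40S/60S)
resolution, nucleolar phase separation, DNA osmotic contributions and
mechanical coupling are out of scope. Amino acids are not tracked in the
nucleus: of every import or recycling flux only the cytoplasmic fraction
V_C/(V_C+V_N) enters the modeled pool; the remainder is considered lost
to the unmodeled nucleoplasmic pool.

Units are fixed throughout: counts in 10⁶ molecules, volumes in μm³
(≡ fL), time in hours, bimolecular coefficients in μm³/10⁶ h. With these
units the shipped parameter tables apply without conversion.

Compartment volumes are algebraic functions of composition,
V_C = (P_C+RP_C+R_C)/r₁ and V_N = (P_N+RP_N+R_N)/r₂ with
r₁ = r₂ = 0.6×10⁶/μm³. This is the coarse-grained consequence of ionic
homeostasis: water content tracks impermeable macromolecule number, while
free amino acids and ions equilibrate across the nuclear envelope and do
not contribute to either volume.

## Growth regimes

- **Rich medium** — uptake is cargo-saturated: t̄₁ = t₁·P_C. All pools
  converge to balanced exponential growth; the C/N ratio is constant.
- **Poor medium** — uptake is transporter-saturated: t̄₁ constant
  (2850×10⁶/h yeast, 15000×10⁶/h mammalian). Volume growth becomes
  asymptotically linear and the C/N ratio oscillates within each cycle.
- **Quiescence** — constant uptake, reduced assembly (s₃ → 5 h⁻¹ yeast,
  0.3 h⁻¹ mammalian), and saturated degradation machinery: every
  degradation/disassembly term becomes first-order at a single rate d
  (0.8 h⁻¹ yeast, 0.05 h⁻¹ mammalian). The sign convention is decay for
  every pool, ribosomes included: a positive ribosome term would
  contradict the synthesis–degradation balance that defines the regime.
  The mass-flow structure of the growing regimes is preserved under the
  first-order replacement — disassembly still returns n₃ ribosomal
  proteins per ribosome and degraded protein still recycles into the
  amino-acid pool with the V_C/(V_C+V_N) partition factor. Dropping
  either recycling pathway changes the quiescent fixed point
  substantially (C/N ≈ 4.8 instead of ≈ 3 for yeast), so this structural
  choice is part of the model definition, not a numerical detail.

## Parameter values and provenance

The yeast table is derived in `cngrowth.calibration` from physiological
constraints: a 2 h cycle, a 27 + 3 fL newborn, 200 mM free amino acids,
3×10⁷ proteins per newborn of which 45% are ribosomal, 2000 ribosomes
assembled and 150000 ribosomal proteins imported per minute, and
degradation at 1/10 of synthesis. Derivations are evaluated at the
average (cycle-mean) state, ≈1.3× the newborn content; the ribosome
assembly balance uses the equivalent divisor 0.75 on the newborn pool.
Both factors are honored per-derivation so the published constants are
recovered exactly; the small inconsistency (1.3 vs 1/0.75 ≈ 1.33) is
inherited from the published derivation and documented here rather than
harmonized.

Three deliberate choices in the calibration:

- The cytoplasmic non-ribosomal residual of the partition is 14.85×10⁶;
  the literature estimate quotes it as 1.5×10⁷ and all downstream coefficient
  estimates use the quoted two-significant-figure value (this is what
  makes t₁ come out at exactly 400 h⁻¹).
- The amino-acid pool-growth term in the t₁ balance (1800×10⁶/h) is a
  constraint input, not a derived quantity: the naive bookkeeping
  (A_C doubling over 2 h) gives 1600, and the published 1800 cannot be
  reproduced from the stated bookkeeping.
- The raw protein-synthesis budget gives s₁+s₂ ≈ 288 μm³/10⁶ h; the
  published total of 280, split 155/125 by the 11:9 proteome ratio, is
  used in the fixture, and the raw value is exposed in the
  `CalibrationReport`.

**t₅ (non-ribosomal nuclear export).** The calibration sets export 10%
below import, t₅ = 0.9·t₄, giving 0.72 μm³/10⁶ h for yeast and 0.09 for
the mammalian cell. The rounded tabulated alternatives (0.75 / 0.05) are
not used: 0.75 shifts the yeast steady C/N from 10.6 to 13.1, and 0.05
makes nuclear import overwhelm export in the mammalian cell so strongly
that it never reaches its doubling volume. Both fixtures document this in
place; the values remain configurable.

Mammalian parameters are a literature-informed scale-up shipped as a
fixture and reported as-is by `calibrate("mammalian")`; the tabulated
mammalian volumes (1500/500 fL) are inconsistent with r = 0.6 applied to
the tabulated counts, so volumes are always derived from counts
(1210/302.5 fL at the fixture state) and never read from a volume row.

## Numerical choices

- **Integrator**: LSODA (stiff-capable, adaptive) at rtol 1e-8 /
  atol 1e-10, with root-found division events at V_cell = 2·V_birth;
  division timing accuracy feeds directly into C/N estimates. The
  integrator is cross-checked in the test suite against fixed-step
  explicit Euler (dt = 1e-4 h) on short horizons.
- **Growth-rate fit**: least squares on log V_cell vs t with division
  discontinuities stitched out; the first 3 generations are discarded as
  transient; 8 generations are simulated by default. Shrinking lineages
  (λ < 0) never divide, so the fit falls back to the trailing half of the
  trajectory; scans report negative rates rather than clamping.
- **Quiescent steady state**: integration in chunks until the largest
  relative rate |Ẋ/X| < 1e-6 h⁻¹, horizons 200 h (yeast) / 2000 h
  (mammalian); non-convergence returns a flagged partial result.
- **C/N steady value**: time-average over the final full cycle, flagged
  steady when the cycle-to-cycle drift is below 1e-4 per hour; in poor
  medium the per-cycle min/max are reported because the series
  oscillates.
- **Gradients**: central differences at ±1% of each parameter's baseline,
  taken with respect to normalized parameters (x/x⁰) and scaled to unit
  Euclidean norm. The step balances truncation error against the noise
  floor of event-located division times. In the poor/quiescent regimes
  "t1" refers to the constant uptake t̄₁ and, in quiescence, "s3"/"d" to
  the overridden assembly and decay rates.
- **Scan grids**: logarithmic, default 1/10× to 10× the fixture value.

## Population simulator and the synthetic data it generates

Each cell advances by explicit Euler with dt = 0.02 h (interpreted as
hours; fine enough that a cell traverses its division-volume distribution
in many steps). Division is a survival process over traversed volume:
a cell divides in a step with probability 1 − exp(−k(V_C)·ΔV_C), with
hazard k = ω/(1 − CDF_ω) computed by cached trapezoidal quadrature from
an arbitrary division-volume density ω. The default ω is Normal with
mean 2·V_C(birth) and CV 0.1, truncated to positive support — this
reproduces division-at-doubling in the zero-noise limit; the distribution
is not otherwise constrained by measurements and is configurable. Partition
noise is parametrized by the relative daughter-volume difference
δ = ΔV_new/V_div ~ N(0, 0.125), truncated to (−1, 1) by resampling;
daughters receive fractions (1±δ)/2 of every pool, so division conserves
each constituent exactly. 0.125 is taken as a standard deviation.

Ensembles start from N cells sharing the fixture composition at sizes
uniformly spread between 1× and 2× the newborn state (one shared scale
factor per cell — cross-variable correlation at
initialization is not constrained; preserving composition is this package's
choice). Populations exceeding a cap are randomly subsampled with the
cumulative factor recorded.

Two-species runs split the non-ribosomal pool into P₁ and P₂ sharing all
transport and degradation coefficients; regulation enters only through
the synthesis coefficient of species 2, s₁,₂ = const + slope·P₁ clamped
at zero (P₁ in 10⁶ molecules, consistent with the global units). The
four canonical cases are equal (s₁,₁ = s₁,₂ = 77.5, so the pair sums to
the one-species coefficient), unequal (65/90), enhancement
(s₁,₂ = 6·P₁) and suppression (s₁,₂ = 145 − 5·P₁); where only the regulated
coefficient is specified, s₁,₁ = 65 (the unequal-case value)
is used. Within one cycle the enhanced species follows
P₂ = a + b·P₁² exactly (a set by the birth size), so proteome-correlation
diagnostics compare the equal-degrees-of-freedom laws a + b·P₁ versus
a + b·P₁²; the signed curvature of a degree-2 fit is reported alongside
(positive for enhancement, negative for suppression). Because division
keeps the size distribution stationary, the population-level log-log
slope of P₂ vs P₁ stays near 1 in every case — the quadratic/concave
signature appears as curvature of the joint cloud, not as a power-law
exponent, and the fit comparison discriminates it only modestly
(stably across seeds, but not by a wide margin) at the default noise
levels.

## What the synthetic ensembles do and do not emulate

The generator reproduces cell-cycle dilution, division-timing noise and
partition noise — the dominant sources of extrinsic covariation in
single-cell proteome data. It does not model transcriptional bursting,
mRNA copy-number fluctuations, or measurement noise, so passing
distribution tests shows the division-driven covariation structure is
correct, not that real single-cell proteomics data would match
quantitatively.

## Known limitations

- Division is symmetric halving; budding asymmetry is not modeled (it
  does not affect λ or the steady C/N, which are the reported outputs).
- The poor-regime C/N ratio has no steady value in the strict sense; the
  reported number is a final-cycle time average.
- Euler stepping in the population module can undershoot tiny pools;
  negative counts beyond float-noise tolerance raise, noise-level ones
  are clipped to zero.
- The quiescent first-order decay uses one rate d in both compartments;
  compartment-specific quiescent rates are not resolved by available estimates.
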