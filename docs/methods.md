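# Methods

`metallosense` implements the quantitative analyses used to characterize a
copper(I)-sensing transcriptional repressor — a homodimer whose operator-DNA
binding is activated by Zn(II) and inhibited by Cu(I). Each analysis stage is
a small model with explicit assumptions; this note records those models, the
defaults, the numerical choices, and what the synthetic-data tests do and do
not demonstrate.

## Mass-action speciation and chelator competition (`equilibria`)

**Model.** A system is a set of free components (metal, chelator, protein
site) and complexes with integer stoichiometries and log10 cumulative
formation constants β (units M^(1−Σν)). Given total concentrations, the
solver finds free concentrations satisfying mass balance and mass action.

**Solver.** Unknowns are ln(free) of components with positive totals, so all
concentrations stay positive even with β spanning 10^19.8 (the
Cu(I)–bis-BCS chromophore). A damped Newton iteration with analytic Jacobian
(step capped at 3 log units, backtracking line search) converges in a few
dozen iterations; if it stalls — which can happen at extreme trial constants
during profile scans — a trust-region least-squares fallback on the same
parameterization takes over. Mass balance is enforced to 1e−9 relative and
verified against a brute-force bisection oracle in the tests. Consecutive
titration points warm-start from the previous solution.

**Competition fitting.** The optical model per experiment is
`signal = b + s·[chromophore]` with per-experiment baseline `b` and response
scale `s` as nuisance parameters — the molar response of the Cu(BCS)₂ or
Zn–mag-fura-2 chromophores is not treated as a known constant (a fixed-ε
mode is available by passing the observable map directly). Because the
optical model is linear in (b, s), the nuisances are profiled out exactly
(variable projection) and the outer least squares runs over the shared
log10 K only; standard errors come from the Jacobian of the profiled
residuals. The "two identical independent sites per dimer" model is encoded
as site concentration = 2 × dimer concentration with a single per-site K.

**Lower-bound detection.** When binding is stoichiometric relative to the
competitor, the objective is flat in log K above the optimum. If the
residual sum of squares (RSS) rises by less than 4 × residual variance
(≈2σ) over +4 log units, only a bound is reported: the largest log K at
which the RSS exceeds the optimum by that threshold (grid scan plus
bisection). Note this χ²-profile bound is tighter than the classical
competition dynamic-range rule of thumb (K ≲ 10·K_chelator·[chelator]/[P]):
at 1% signal noise the synthetic Zn/mag-fura-2 data support a bound two
orders of magnitude above the conservative literature-style "≥10⁹ M⁻¹"
statement. The bound therefore depends on the assumed noise level, which is
reported alongside it.

**Stoichiometry breakpoints.** Equivalence points of stoichiometric
titrations come from a continuous two-segment piecewise-linear fit (grid
search over the break abscissa), requiring ≥3 points per side and a
post-break slope below half the pre-break slope; the CI is a seeded
residual bootstrap.

## DNA binding and allosteric coupling (`dnabinding`)

The dimer is treated as non-dissociable, so dimer–duplex binding is 1:1
with the exact quadratic solution for the bound fraction of DNA. The
rationalized root `fb = 2KaP / (b + √(b² − 4Ka²PD))`, `b = KaP + KaD + 1`,
avoids catastrophic cancellation at small KaP and yields the Dtot→0 limit
`KaP/(1+KaP)` without branching (checked against a root-finder oracle to
1e−10 over 10⁴ random draws).

Anisotropy is modeled as linear in bound fraction, `r = r_free + Δr·fb`,
with no fluorescence-intensity correction; Ka is fit in log10. The
allosteric coupling free energy is ΔG_c = −RT·ln(Ka_state/Ka_ref) with
R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ and T defaulting to 298.15 K. **Sign
convention: negative ΔG_c = activation** (the queried state binds more
tightly than the reference); only magnitudes are usually quoted in the
literature. For the published Ka pair (2.8×10⁶ apo, 1.0×10⁷ Zn₁) the
formula gives |ΔG_c| = 0.75 kcal mol⁻¹; the value printed alongside those
constants in the source figure (0.6) is not reproducible from them and is
not asserted anywhere.

**Estimator precision.** At the reference design (20 log-spaced protein
points, DNA 10 nM, σ_r = 0.001, Δr ≈ 0.014–0.017) the Cramér–Rao bound for
ln Ka is ≈0.17–0.20, i.e. a one-sigma factor of ~1.2 in Ka. Single seeded
replicates therefore scatter up to and occasionally beyond ±20% around the
truth; recovery tests use either a fixed seed or a median over seeds.

## Pulsed-alkylation MS (`rpams`)

Masses are monoisotopic (pyteomics residue table; water 18.010565, proton
1.007276) with an average-mass mode available. The NEM Michael adduct adds
its full composition C₆H₇NO₂ = 125.04768 Da; d5-NEM adds 130.07906 Da
(²H = 2.014102), an isotope-coding shift of 5.0314 Da per site. The
published calc'd masses of the d5-labeled peptides run 0.01–0.02 Da above
this standard computation (their deuterium convention is unstated); the
package reports the standard values and the tests document the gap. b/y
fragment masses satisfy the complementarity identity
bᵢ + y_{n−i} = [M+H]⁺ + proton exactly.

The pulse-chase kinetic model treats each cysteine as an independent
pseudo-first-order site with an ideal instantaneous chase: per-site
deuteration probability fᵢ(t) = 1 − exp(−kᵢt), species fractions are
products over sites summed within isobaric mass classes. MS-level species
of a multi-Cys peptide cannot say *which* site is fast (the likelihood is
permutation-symmetric), so fitted rates are returned sorted and site
assignment comes from MS/MS diagnostic-ion partitioning, where per-site d5
occupancy is Σd5/Σ(d5+H5) over each site's diagnostic ions, normalized to
sum to 1 for the singly-labeled peptide. A site with undetectable labeling
is reported as k = 0 with a finite upper bound from the 2σ objective
profile. Equal ionization efficiency of isotopologues — the ratiometric
premise — is assumed throughout.

## SAXS shape analysis (`saxs`)

*Guinier.* The q·Rg ≤ 1.3 window is chosen self-consistently (iterate until
the fitted Rg and the window agree). Within the window, ln I is fit in q²
including a q⁴ term when ≥8 points are available, and **Rg is taken from
the limiting low-q slope**: a plain straight line over qRg ≤ 1.3 is biased
~2% high for a sphere by form-factor curvature, while the corrected slope
is accurate to ~0.1%. Significant *positive* curvature (t > 3 and a ≥2%
effect on the slope at the window edge) flags a heterogeneous sample —
mixtures of sizes make ln I convex in q², monodisperse globules do not —
and raises a warning rather than an error.

*IFT.* I(q) = 4π∫₀^Dmax p(r) sinc(qr) dr is discretized on a 101-point
r-grid (trapezoid weights, hard zeros at both endpoints) and solved by
penalized weighted least squares with a second-difference roughness
penalty, scaled so the regularization weight α is dimensionless. α = "auto"
picks the maximum-curvature corner of the L-curve over α ∈ 10⁻¹⁰…10².
Negative p(r) is permitted but quantified (|negative area|/total area) and
reported. Real-space Rg and I0 follow from the moments of p(r).

*Dmax.* A candidate grid (0.6–1.8 × 2.6·Rg) is scored by mean χ² — with σ
floored at 0.1% of the peak intensity so noiseless profiles score on a
bounded scale — times a (1 + 10×negativity) penalty, using a fixed scan
α = 10⁻⁶ so scores are comparable across candidates. The smallest Dmax
within 5% of the best score (or indistinguishable from the large-Dmax
plateau, whose 90th percentile absorbs numerical scatter) is returned;
under-estimates degrade the fit sharply, over-estimates do not, hence the
parsimony rule. If even the smallest candidates fit, or the best χ² is
poor, a low-confidence flag is set. Dmax at a few-percent precision is
intrinsically soft once noise is present.

*Porod MW.* The invariant Q = ∫q²I dq uses the measured range plus a
Guinier extrapolation to q = 0 and a K/q⁴ tail beyond q_max (K averaged
over the last 20% of the range); Vp = 2π²I0/Q and MW = Vp/1.66 ų Da⁻¹
(divisor overridable). The profile must reach q_max·Rg ≥ 4, otherwise the
tail extrapolation dominates and an error names the required reach.

## IM-MS (`imms`)

Peaks are assigned the (n-mer, charge) minimizing |m/z − (nM + z·1.00728)/z|
within tolerance, ties toward smaller n (reducible pairs such as (2, 8) are
exactly isobaric with their reduced form and resolve to the monomer).
Mobility envelopes are decomposed into k = 1, 2, … Gaussians fit by least
squares with deterministic quantile-based initialization (a seeded
sub-grid-scale jitter breaks exact symmetry); k grows while adding a
component reduces the RSS by ≥5% (default), which operationalizes "the
minimum number of Gaussians required to describe the envelope". When a
richer model is rejected and its components overlapped within one combined
sigma, a warning records that the extra component was unresolvable.
Compact/extended fractions sum component areas on either side of a CCS
boundary (on-boundary means count as compact, with a warning). CCS
calibration is accepted as precomputed input; a linear drift-time helper is
provided.

## Synthetic data (`synth`)

Generators reproduce the statistical structure each fitter assumes, with
ground truth embedded in output metadata so recovery tests never restate
it. Defaults are the study conditions: three Cu/BCS competition schedules
(22 µM Cu/60 µM BCS, 25/75, 29/90; protein titrated to 2× the Cu total),
Zn into 12 µM dimer + 16 µM mag-fura-2 (K_Zn = 5.0×10⁷ M⁻¹), anisotropy
isotherms at 10 nM DNA over a 10⁻⁹–10⁻⁵ M dimer grid with the Zn₁
(Ka = 1.0×10⁷, Δr = 0.014) and apo (2.8×10⁶, 0.017) parameter pairs,
two-site alkylation time courses over 15–600 s with the C-terminal site
faster, sphere scattering to q = 0.5 Å⁻¹, and bimodal CCS envelopes at
2500/3200 Ų (areas 0.6/0.4, widths 120 Ų). Noise defaults: 1% of signal
amplitude for titrations, 0.001 absolute for anisotropy, 3% for MS
intensities, σ ∝ √I for SAXS; Gaussian, seeded, overridable.

What the synthetic tests show: that each estimator recovers the parameters
of its own generative model at the stated noise, and that the closed-form
and transform machinery matches independent oracles. What they do not
show: robustness to the systematic errors of real instruments — MALDI
ionization bias, SAXS buffer-subtraction and smearing artifacts,
electrospray charge-state effects, chelator impurities or drifting
baselines — none of which the generators emulate.

## Known limitations

- No cooperative/Hill or sequential-site binding models; no
  monomer–dimer coupling in the DNA-binding model.
- The alkylation model assumes site independence and an ideal chase.
- The IFT is an unconstrained ridge solution; negativity is reported, not
  forbidden, so very noisy profiles can yield oscillatory p(r).
- The χ²-profile lower bound on stoichiometric affinities scales with the
  assumed noise; it is a statement about the synthetic data, not a
  universal constant.
- Dmax estimation reports a parsimony choice on a discrete grid; its
  resolution is the grid spacing (~4% of the scan center).
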