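# Methods

## Scope and assumptions

`mutfep` implements the *analysis* layer of an OSP + TPF saturation-mutagenesis
study: it consumes per-frame perturbation energies, end-state means and
fluctuations, correction components and interaction-energy averages, and
produces relative binding free energies and classifier validation metrics.
It does not run molecular dynamics; trajectory generation, pairlist
machinery, constraint algorithms and the continuum-electrostatics evaluation
of the charging-correction components are out of scope, and the correction
components (ΔG_pol + ΔG_dir, ΔG_dsm) are consumed as numbers per leg.

Units follow GROMOS conventions throughout: kJ/mol for energies, nm for
lengths, elementary charges, K for temperature, with
k_B = 0.00831451 kJ mol⁻¹ K⁻¹ and T = 298.15 K as configurable defaults.

## One-step perturbation

The Zwanzig estimator is evaluated with a log-sum-exp reformulation, so no
intermediate exponential can overflow for any |ΔH|; overflow is treated as an
implementation error, never a warning. Conformer occurrences enter as
ΔG_i′ = ΔG_i − k_B T ln P_i and the library is collapsed with a second
exponential average, ΔG = −k_B T ln Σ_i exp(−βΔG_i′). This composition is
algebraically identical to the one-shot occurrence-weighted average
−k_B T ln Σ_i P_i⟨e^{−βΔH_i}⟩_R (checked numerically in the tests); whether a
1/n normalisation is folded in is immaterial, since any constant factor
shifts both legs equally and cancels in bound − unbound differences.

The contributing-frame diagnostic counts frames with ΔH strictly below the
free-energy estimate, per conformer against that conformer's own per-leg
estimate, and reports the mean over conformers, both legs and both protease
dimers. The per-conformer threshold was chosen because the published
percentages are reported per reference state, not per conformer; the
alternative (thresholding on the combined per-leg value) changes the
percentages but not the variant ranking in the shipped dataset.

Dimer averaging and His-tautomer averaging are arithmetic means of free
energies, not of Boltzmann factors — the two dimers and tautomers are treated
as replicate estimates, not as members of one ensemble. Glycine, which has no
side chain, uses the same estimator on side-chain-*removal* series; such
series carry a `removal` flag so cycle assembly can recognise them.

## Third-power fitting

Charging couples the electrostatic Hamiltonian linearly in λ, so
V = ∂H/∂λ is configuration-wise the difference of charged and neutral
interaction energies, and the Gaussian (second-cumulant) approximation gives
the free-energy curvature at an endpoint as −β Var(V). The "fluctuation" of
V is read as its standard deviation, so variance = rmsd². The cubic
dG/dλ through the four endpoint derivatives is fixed by a closed-form 2×2
solve (always uniquely solvable) and integrated analytically as
a + b/2 + c/3 + d/4. The trapezoidal TI quadrature (`ti_oracle`, with a
Gauss–Legendre option for smooth profiles) serves as the independent
reference: TPF equals it exactly whenever the true profile is a polynomial of
degree ≤ 3, which the tests verify to 1e-9 kJ/mol on constructed cubics.

The total artifact correction for a net-charge-changing mutation is
(bound-leg sum) − (unbound-leg sum); the direction is fixed by the shipped
reference dataset, where it reproduces the published totals. Corrected =
raw + total holds exactly in every result object.

The LIE baseline uses α = 0.161 for the van der Waals term and 0.5 for the
electrostatic term; only α was calibrated in the source study, so the
electrostatic coefficient defaults to the standard value and is configurable.

## Reference-state energetics

The unphysical side chains are collinear chains grown from the Cα along the
former side-chain direction at cumulative bond lengths (RDR: dummy at
0.153 nm, soft sphere at 0.306 nm; R2R: soft spheres at 0.252 and 0.603 nm).
Only bond lengths are published; collinear placement is the symmetric minimal
assumption. Soft atoms carry (C6)^½ = 0.27322, (C12)^½ = 0.056143 (GROMOS
geometric combination), zero charge, and a soft-core interaction
C12/(s + r⁶)² − C6/(s + r⁶) with s = α_sc (C12/C6) λ_sc², α_sc = 1.51 and
λ_sc fixed at 1 for the reference atoms; s → 0 recovers plain 12-6
Lennard-Jones. The quoted 0.662 nm effective van der Waals radius is the
self-pair LJ minimum distance (2C12/C6)^{1/6} and is informational only.

Electrostatics use the Barker–Watts reaction field with ε_RF = 61 and
R_c = 1.4 nm: E = f q₁q₂ [1/r + C_rf r²/(2R_c³) − (1 + C_rf/2)/R_c] with
C_rf = 2(ε−1)/(2ε+1); the shift makes the energy exactly zero at the cutoff
and pairs beyond it contribute nothing. All energies are direct pair sums
over explicit selections — the twin-range pairlist of production MD affects
efficiency, not the estimator definitions, and is not reproduced. Toy
systems are non-periodic.

Rotamer placement is a rigid transform: translate the conformer's Cα onto
the frame's, then apply the minimal rotation carrying the Cα→side-chain-COG
unit vector onto the Cα→soft-centroid unit vector. For R2R the target is the
*centroid* of the two soft spheres (the published objective does not state
the aggregation; the centroid reduces to the single atom for RDR and is the
rotation-invariant choice). The residual torsion about the aligned axis
keeps its library value. The fit provably reaches the global rotational
optimum of the COG-to-centroid distance, which the tests confirm against a
brute-force SO(3) grid search.

## Synthetic generators

Each generator returns its own ground truth, so no test consults the
estimator under test for truth values:

- **Gaussian ensembles** (exact ΔG = μ − βσ²/2) probe estimator bias; at
  10⁶ frames with σ = 2 kJ/mol the Zwanzig error is below 0.05 kJ/mol.
- **Discrete systems** are fully enumerable; frames are drawn from the exact
  reference-state Boltzmann weights and the truth is a partition-sum ratio.
- **Polynomial λ-profiles** encode endpoint curvatures into fluctuations via
  the cumulant relation (requiring G″ ≤ 0), exercising the whole TPF path
  without sampling; optional seeded noise makes the sampled variant.
- **Toy complexes** (≤ 20 particles) are sampled by seeded Metropolis Monte
  Carlo with the package's own energy function, with an optional harmonic
  tether whose position variance must satisfy equipartition (kT/k).

All generators are bit-reproducible under a fixed seed. What they do *not*
emulate: correlated frames, conformational bottlenecks, protein-scale
energy landscapes, or force-field inaccuracies — a passing synthetic test
validates the estimator arithmetic, not the adequacy of reference-state
sampling for a real protein.

## Problem sizes and numerical choices

Statistical tests use 2×10⁵–10⁶ frames (Gaussian recovery, CDF checks,
discrete sampling within three standard errors) and 2×10⁵ Metropolis steps
for the equipartition check (10% tolerance at that length); these sizes put
Monte-Carlo noise well below the asserted tolerances while keeping the whole
suite around ten seconds. Exact algebraic paths are asserted at 1e-9–1e-12.
Comparisons against the shipped one-decimal reference tables use a
0.15 kJ/mol tolerance to absorb rounding of pre-rounded intermediates.
Reference-state selection ties break to RDR (arbitrary but fixed);
classification treats ΔΔG = 0 as favorable (boundary inclusive), which is
the convention consistent with the published cross tables; a zero marginal
in the MCC denominator returns 0 by convention.

## Known limitations

- The shipped caspase-2 OSP/TPF raw values are transcribed study inputs;
  regenerating them requires production MD and is out of scope. Everything
  downstream of them is recomputed.
- The Gly rows of the published relative-energy table follow a side-chain
  removal convention that is not fully specified; `mutfep` closes the Gly
  cycle like any other mutation and the reproduction checks skip those rows.
- In the shipped dataset three 105/Ile rows use the larger reference state
  although the stated contributing-frame rule would pick the smaller one;
  the dataset records the published per-row choice explicitly, while
  `select_reference_state` implements the stated rule.
- No uncertainty estimates are produced (block averaging of correlated MD
  frames is not modelled), and MCC confidence intervals are not computed.
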