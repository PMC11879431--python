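# Methods

This note records the models, conventions and numerical choices behind
`poremech`, and the limitations a user should know about. Everything the
package computes is exercised against analytic values or seeded generators
with known truth; no claim below rests on unverified output.

## Units and constants

Lengths in nm, energies in kJ/mol, temperatures in K. k_B = 0.00831446
kJ/mol/K; default temperature 310 K. Line tensions are reported in pN with
1 kJ mol⁻¹ nm⁻¹ = 1.66054 pN; CNT energies convert back with
1 pN·nm = 0.602214 kJ/mol.

## Synthetic data generators

The generators exist to give every estimator a ground truth. They are
deliberately minimal coarse-grained models, not force fields:

- **Flat membrane**: lipids on a jittered lattice, one head bead at
  z = z_c ± d_hc/2 and two tail beads uniform in the corresponding half of
  the hydrophobic core; water beads fill slabs outside the core at bulk
  number density. The core is strictly dry, so the flat state has exactly
  ξ_chain = 0.
- **Water wire**: the flat frame (bit-identical, drawn from a separate RNG
  stream) plus a thin polar column through the core, spaced 0.08 nm in z so
  every 0.1 nm occupancy slice is hit.
- **Open pore**: bulk lipids excluded from a disk, rim head groups placed on
  the inner half-torus (tube radius d_hc/2) with area sampling proportional
  to the true torus metric, and the lumen filled with water at v̄ = 0.030 nm³
  per polar particle so the radius estimator is consistent by construction.
  Rim composition follows prescribed per-species enrichment factors with the
  rim head count renormalized, so measured factors are the prescribed ones up
  to a species-independent window constant — cross-species ratios are exact.
- **Boltzmann samples**: tilt components and pair splay drawn Gaussian with
  variance kT/(modulus · A_l), the equipartition result for quadratic
  energies.
- **Synthetic PMF**: smooth rise to (0.92, ΔG_nuc), a flat plateau to
  ξ = 3.5 (optionally carrying a Gaussian metastable dip at ξ = 2.5,
  σ = 0.35), then an exactly linear tail of slope 2πγR0. The default grid
  (np.linspace(0.04, 6.52, 163)) places ξ = 0.92 on a grid point. The flat
  plateau is idealized — real profiles have structure there — and was chosen
  so a prescribed dip is detectable by construction and the tail slope is
  exact.
- **Stress profile**: a z-symmetric structured profile built from a
  moment-free cosine base plus a moment-carrying term scaled so the leaflet
  first moment equals κ·J_s exactly under the trapezoidal rule. Both
  leaflets are identical; the estimator flips the moment sign for the lower
  leaflet.

## Reaction coordinate ξp

Polar particles (water and polar-role beads) inside a cylinder of radius
1.2 nm are binned into ≈ 0.1 nm z-slices spanning the tail extent. Each
slice contributes δ_s = min(1, count/n_sat); ξ_chain is the mean δ_s. Once
ξ_chain ≥ 1 − 0.01 the defect spans, and the coordinate switches to the pore
radius branch ξp = max(1, R̂/R0) with R̂ = √(N_p·v̄/(πh)), v̄ = 0.030 nm³,
R0 = 0.4 nm. The cylinder center can be given or found automatically as the
densest polar column (periodic 2-D histogram at 0.2 nm resolution,
circularly convolved with a disk kernel via FFT). For a thin wire the
maximizer is degenerate — any center whose disk covers the column ties — so
auto-centering guarantees capture, not pixel-exact location; ξp is invariant
under that degeneracy.

## PMF analysis

Profiles are anchored so the minimum over ξ < 0.5 is zero. ΔG_nuc is the
linear interpolation of G at ξ = 0.92. The line tension is the OLS slope of
G against R = ξ·R0 over ξ ∈ [4, 6.5], divided by 2π; fit R² < 0.9 sets a
warning flag rather than raising. Metastable minima are strict local minima
at ξ > 1 whose depth to the lower flanking maximum exceeds
max(min_depth, 2·SE); on noisy profiles a lowess pre-smooth (`smooth_frac`,
0.1 works well at ≲ 1 kJ/mol noise) suppresses spurious wiggles, and
`min_depth` should be raised to a multiple of the noise level.

Bootstrap errors: with ≥ 3 replicate profiles, whole replicates are
resampled (case bootstrap); with a single profile, residuals around a lowess
smooth (frac 0.12) are resampled i.i.d. (residual bootstrap). The lowess
smooth cannot follow the kink at ξ = 0.92, so single-profile residuals carry
a smoothing-bias floor (≈ 1.8 kJ/mol on a noiseless profile) and the
resulting SEs are conservative — in seeded round-trip studies the 2 SE
interval covered the truth in 100% of cases, above the nominal ~95%.

## Continuum elastics

`hkh_energy` integrates (κ/2)(H − J_s)² + (κθ/2)t² + κ̄K_G over quadrature
nodes. H is the sum of principal curvatures. The closed-form rim line
tension γ_bend = κ·d_hc·(π/4)(2/d_hc − J_s)² assumes a half-toroidal rim
whose tube curvature is 2/d_hc while the azimuthal curvature is neglected
(large-pore limit). `rim_quadrature_line_tension` therefore drops the
azimuthal principal curvature by default, converging to the closed form with
only an O(d_hc/R) area-bookkeeping correction (≈ +0.2% at R = 100·d_hc);
with `azimuthal_curvature=True` the full toroidal director field is used and
the inner rim's negative saddle curvature lowers the result by a further
O(d_hc/R) term (≈ 0.5–1.2% at R = 100·d_hc, growing at small R).

The shipped table `poremech/data/elastic_parameters.csv` lists J_s, κ and κθ
(with 1 SE columns) for nine model membranes alongside their bending-theory
rim line tensions. Those tabulated tensions were computed with per-membrane
hydrophobic thicknesses that are not part of the table; evaluating the
closed form at the generic default d_hc = 2.8 nm reproduces them to within
a few percent for POPC-like membranes but up to ~20% for the thicker
sterol-rich mixture.

Pore probability uses exp(−ΔG/kT) with the decimal order reported as
floor(log10). Note the stability-factor order for an 80 kJ/mol difference is
13 at 300–310 K but crosses to 14 just below 300 K; the package default is
310 K.

## Moduli estimation

Directors run from the tail-bead centroid to the head bead; the reference
normal is ±z by leaflet (planar membranes only); tilt is the in-plane part
of d/(n·d) − n, so |t| = tan θ. Lipids with n·d ≤ 0.1 are excluded.
κθ = kT/(var_per_component(t)·A_l) per leaflet; κ = kT/(var(S)·A_l) with S
the neighbor-pair splay over 0.5–1.0 nm in-plane separations. J_s comes from
the leaflet stress first moment divided by κ. Hydrophobic thickness is the
distance between the two crossings of the max-normalized tail and water
density profiles; normalization matters because the raw water density far
exceeds the two-bead tail density in the toy frames and would bias the
crossing inward by ~0.07 nm.

## Lateral sorting

Cylindrical (r, z) density maps are accumulated around the pore axis
(auto-centered per frame), truncated at the periodic half-box. Relative
density divides each bin by the volume-weighted bulk density (outer quarter
of the radial range) at the same z, falling back to the species' overall
bulk mean for z rows without bulk signal. Radial profiles and rim
enrichment factors should be evaluated over the z window actually carrying
head markers — rows without markers are genuine zeros and dilute
volume-weighted averages (the `sort` CLI command windows automatically).
Absolute enrichment values carry a common window-geometry factor; ratios
between species cancel it and recover the prescribed factors.

## Limitations

- The generators are geometric toys: no forces, no dynamics, no
  protrusions, undulations or composition-curvature coupling. They validate
  estimators, not membranes.
- The residual bootstrap is a stand-in for resampling umbrella histograms,
  which are not modeled; its SEs are conservative (see above).
- `compute_directors` assumes a planar bilayer with a ±z normal; it is not
  applicable to vesicles or to frames containing a pore.
- The Gaussian-curvature modulus κ̄ defaults to 0 and no estimator for it is
  provided.
- Metastability detection is heuristic (local minima after optional
  smoothing); at noise levels well above ~1 kJ/mol the classifier degrades
  and `min_depth` must be raised accordingly.
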