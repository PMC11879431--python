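# poremech

Analysis toolkit for the energetics of transmembrane pore formation in lipid
membranes: a pore reaction coordinate, potential-of-mean-force (PMF)
post-processing, continuum elastic theory of the pore rim, fluctuation-based
estimation of monolayer moduli, and lateral lipid sorting at the rim.

## The science

Electroporation, antimicrobial peptides and membrane fusion all proceed
through a transmembrane pore. Its formation has two stages with distinct
physics:

1. **Nucleation.** A column of water and polar head groups first connects the
   two leaflets across the hydrophobic core. The cost of reaching this
   thin-water-wire state is the nucleation free energy **ΔG_nuc**, read off a
   PMF at reaction-coordinate value ξp = 0.92. For complex biological
   membrane mimics ΔG_nuc spans roughly 90 kJ/mol (Golgi-like compositions)
   to 180 kJ/mol (plasma-membrane-like, sterol- and sphingomyelin-rich).
2. **Expansion.** Past nucleation the pore opens and its free energy grows
   linearly with radius: each nanometer of rim costs the **line tension γ**
   (≈ 40–100 pN across the same compositions), so dG/dR = 2πγ. Under a
   lateral tension σ this competition gives the classical nucleation theory
   (CNT) energy ΔG(R) = 2πRγ − πR²σ.

Both numbers are governed by monolayer elasticity. In the
Helfrich–Kozlov–Hamm (HKH) description a monolayer patch pays
(κ/2)(H − J_s)² + (κθ/2)t² + κ̄·K_G per unit area — bending away from the
spontaneous curvature J_s, tilting the lipids, and Gaussian curvature.
Bending a monolayer around the strongly curved pore rim (tube curvature
≈ 2/d_hc, with d_hc the hydrophobic thickness) costs per unit rim length

```
γ_bend = κ · d_hc · (π/4) · (2/d_hc − J_s)²
```

so membranes made of positive-curvature lipids (lyso-PC) porate easily while
stiff sterol-rich membranes resist. The same lipid shapes drive **lateral
sorting**: lyso-lipids enrich at the rim, cholesterol and sphingomyelin are
depleted or excluded. Finally, because pore formation is a Poisson process in
membrane area, a simulated barrier transfers to a macroscopic membrane as
ΔG_exp = ΔG_sim − kT·ln(A_exp/A_sim); a rescaled barrier of 48 kJ/mol
corresponds to a pore probability of order 10⁻⁹, and an 80 kJ/mol barrier
difference separates two membranes by a stability factor of order 10¹³.

## What the package provides

| module | contents |
| --- | --- |
| `poremech.synthetic` | generators for coarse-grained membrane frames (flat, water-wire, open-pore with prescribed rim sorting), Boltzmann tilt/splay samples, synthetic PMFs and lateral stress profiles — all seeded and with known ground truth |
| `poremech.chain_coordinate` | the joint reaction coordinate ξp: polar-defect connectivity below 1, pore radius in units of R0 = 0.4 nm above 1 |
| `poremech.pmf` | PMF I/O (XVG/CSV), ΔG_nuc, line tension from the linear large-pore regime, metastable-minimum detection, bootstrap errors, hysteresis |
| `poremech.continuum` | HKH energies on parameterized surfaces, closed-form and quadrature rim line tensions, CNT, area rescaling, pore probabilities, a shipped table of nine model-membrane parameter sets |
| `poremech.moduli` | equipartition estimators for κθ and κ from tilt/splay fluctuations, J_s from the stress-profile first moment, hydrophobic thickness |
| `poremech.sorting` | cylindrical density maps around the pore axis, bulk-normalized relative densities, rim enrichment factors |
| `poremech.cli` | `poremech xi / pmf / continuum / rescale / moduli / sort` |

## Worked example

Extract pore energetics from a noisy PMF with Golgi-scale truth
(ΔG_nuc = 90 kJ/mol, γ = 40 pN), then rescale to a GUV-sized membrane
(`examples/02_pmf_analysis.py`):

```python
import poremech as pm

spec = pm.SyntheticPMFSpec(gamma_true=40.0, dG_nuc_true=90.0, noise_sd=2.0,
                           seed=7)
profile = pm.make_synthetic_pmf(spec)
result = pm.analyze_pmf(profile, n_boot=200, seed=7, smooth_frac=0.1,
                        min_depth=3.0)
```

Running the script prints:

```
Golgi-scale membrane (truth: dG_nuc = 90 kJ/mol, gamma = 40 pN)
  dG_nuc =   89.2 +/- 3.1 kJ/mol
  gamma  =   39.9 +/- 0.3 pN   (fit R^2 = 0.9983 on xi in [4, 6.5])
  metastable minima: none

lyso-lipid-like membrane: local PMF minimum at xi_p = 2.52 (5.5 kJ/mol deep) -> metastable open pore

Rescaled to a GUV-sized membrane (1e7 x larger area):
  dG_nuc = 47.7 kJ/mol -> pore probability ~ 10^-9
```

The reaction coordinate on generated frames (`examples/01_reaction_coordinate.py`):

```
flat membrane       xi_chain = 0.000  spanning = False  R_hat = --        xi_p = 0.00
thin water wire     xi_chain = 1.000  spanning = True   R_hat = 0.35 nm   xi_p = 1.00
open 0.8 nm pore    xi_chain = 1.000  spanning = True   R_hat = 0.80 nm   xi_p = 2.01
```

And rim sorting recovery (`examples/05_rim_sorting.py`):

```
Ratios between species cancel the common window geometry:
  LPC / POPC  = 1.98  (prescribed 2.0)
  CHOL / POPC = 0.50  (prescribed 0.5)
  PSM         = 0.00  (excluded from the rim)
```

The other examples cover continuum elasticity (`03`) and moduli estimation
(`04`). The same workflows are available from the shell, e.g.:

```sh
poremech rescale --dg 90 --area-exp 1e9 --area-sim 1e2
poremech pmf --in profile.xvg --boot 200 --smooth 0.1
```

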