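# Methods

This note records the models, conventions and design choices behind
`fuzzycoat`, in the spirit of a package's own methods documentation: what is
computed, under which assumptions, and what the synthetic tests do and do
not demonstrate.

Units are nm and ps internally everywhere; file boundaries convert (PDB and
MRC are written in Å). Energies are in units of k_B T unless stated.

## Synthetic filaments

A toy filament is a stack of identical chains per protofilament. The
cross-β core (a residue interval of the sequence) is built on an idealized
parallel-β backbone template (φ = −119°, ψ = 113°, standard peptide bond
lengths/angles, trans peptides) and replicated exactly along the fibril
axis with a configurable axial rise. The default rise is 0.48 nm — the
canonical cross-β stacking distance; with the template above, the stacked
chains form the inter-chain hydrogen-bond ladder that the secondary-
structure module recognizes as parallel β sheet, as in real fibrils. Two
protofilaments are related by a C2 rotation about the fibril axis.

Tails (the fuzzy coat) are grown residue-by-residue off the core anchor as
torsion-space random coils: base angles (−100°, 120°) with Gaussian jitter
whose SD is the `tail_flexibility` parameter (radians, converted to
degrees). Self-avoidance is enforced by a hard-sphere clash check (0.20 nm)
against the core of all chains and the chain's own tail, with up to 30
re-draws per residue before the draw is accepted regardless — a bounded-
effort scheme that keeps generation deterministic in (arguments, seed).
Side chains are coarse-grained to one pseudo-atom ("SC") along the Cα–Cβ
direction with residue-specific offset and radius; its nominal element
follows the side-chain chemistry (N for Lys/Arg, O for Asp/Glu, S for
Cys/Met, C otherwise) so that interaction typing and scattering weights
behave sensibly at this resolution. Full rotamer chemistry is out of scope.

Planted contacts: `sample_tail_ensemble` can be asked to realize a
tail-residue/core-residue contact (residue-COM distance < 1 nm) with a given
probability. Per frame, the desired indicator is drawn Bernoulli(p) and the
tail is rejection-sampled until the geometric indicator matches, which
yields exact Bernoulli marginals — the property the contact-map tests rely
on. If the indicator cannot be realized within the attempt budget (2000)
the generator raises rather than silently biasing the ensemble; planted
probabilities should therefore be chosen with non-negligible prior mass,
which the test fixtures do.

Charge bookkeeping uses integer formal charges near neutral pH (Asp/Glu −1,
Lys/Arg +1, His 0, zwitterionic termini cancel); for the Aβ42 sequence this
gives −3 per chain, hence 72 monovalent cations for a 24-chain system.

## Density maps and Gaussian mixtures

`DensityMap` is a regular grid with origin and voxel size; `values[i,j,k]`
is the density at the voxel center. MRC/CCP4 I/O goes through gemmi
(mode-2 float32); axis order is normalized on load and the ORIGIN header
words carry the origin. Synthetic maps place one isotropic Gaussian of
width `resolution_sigma` per atom, weighted by atomic number × occupancy,
truncated at 6σ; the grid pads the atomic extent by 3σ, so total mass is
conserved to well under 1%.

Map segmentation zeroes voxels whose centers are farther than a cutoff
(default 0.6 nm in the pipeline, the 6 Å convention for trimming
low-information halo density) from every model atom, leaving the grid
extent unchanged.

GMM fitting runs expectation–maximization over density-weighted voxel
centers: negative densities are clipped to zero (count logged), voxels at
or below the threshold (default 0) are excluded, initialization is seeded
k-means++ (via scikit-learn's weighted KMeans), covariances are full with a
small regularizer (10⁻⁴ × voxel²), and iteration stops at 500 iterations or
a 10⁻⁶ relative log-likelihood change. Component weights are scaled so the
mixture integrates to the map's total mass, making rendered mixtures
directly comparable to the input map. The fit reports the achieved
real-space correlation; it is a local optimum of a seeded EM, so the
component placement is reproducible but not canonical, and the
nested-model test allows 10⁻³ slack on the correlation monotonicity.

Real-space correlation is the Pearson correlation over a mask (default:
voxels where either map is positive). FSC divides Fourier space into
uniform shells up to Nyquist (default one shell per half-grid frequency
step; non-cubic grids are zero-padded) and reports the normalized
cross-correlation of coefficients per shell.

## Metainference

The model GMM assigns each heavy atom an isotropic Gaussian (default σ =
0.15 nm) weighted by atomic number. Overlaps use the closed-form Gaussian
product integral; mixture-level evaluation supports the two production-style
shortcuts — a distance cutoff at 5·√(largest eigenvalue of Σ_a+Σ_b) and an
absolute overlap-magnitude cutoff (default 0.01) — both configurable and
harmless at toy scale.

ov_DD,i is defined as the overlap of the *entire* data mixture with
component i (the same convention used for ov_MD,i), so a model mixture
identical to the data gives exactly zero residuals. An alternative
normalization by the component's self-overlap alone is available behind a
flag on the relative-error computation, because the printed definition of
the relative error admits both readings.

σ_SEM,i is the standard error of the replica mean of ov_MD,i (zero by
convention, logged, for a single replica). The error energy is

    E_σ = k_B T Σ_{r,i} [ log σ_{r,i} + ½ log(σ_{r,i}² + σ_SEM,i²) ]

— a Jeffreys prior per sampled parameter plus the Gaussian-likelihood
normalization. The normalization term matters: without it the conditional
posterior of σ is asymptotically flat in log σ and the sampled error
parameters drift to the upper bound, making the relative-error diagnostic
meaningless. With it, zero residual concentrates σ at the lower bound
(density ∝ 1/σ²) and large residuals pull the posterior mean up with
|residual|, which is what the error-parameter tests check against analytic
conditionals. σ values are hard-bounded to [10⁻⁴, 10²] × ov_DD,i and
sampled by log-scale random-walk Metropolis (the log-space Jacobian cancels
the Jeffreys factor, which is accounted for in the implementation).

The toy posterior sampler alternates Metropolis moves on tail torsions with
error-parameter Monte Carlo. The "prior" of the hybrid energy is realized
structurally: the core never moves and bonded geometry is fixed by the
internal-coordinate move set, which is the cheapest faithful rendering of a
rigid-core/mobile-tail prior; an additional energetic prior over torsions is
pluggable (the prior-recovery test uses a harmonic one). When two reference
conformers are supplied, the sampler mixes local Gaussian torsion moves with
a symmetric reflection through their midpoint — an involution, hence a valid
Metropolis proposal — so replicas can hop between well-separated basins.
The restraint is evaluated on the movable tail atoms only; the rigid core
would contribute identical constants to every replica. With 8 replicas the
ensemble fraction of a planted 70/30 conformer mixture is recoverable only
in multiples of 1/8; the sampler settles at 6/8 = 0.75, within the ±0.1
band the recovery test uses. The restraint update stride is 1 at toy scale
(a config knob; production-style runs use sparser updates).

## Metadynamics

Hills are Gaussians per CV in a shared list (multiple walkers append to the
same list, making walker alternation exactly equivalent to a single
walker). Well-tempered deposition scales the height by exp(−V/(k_B ΔT)),
γ = 1 + ΔT/T (default γ = 10). Parallel-bias mode combines per-CV biases as
V_PB = −k_B T ln[(1/N) Σ_j exp(−V_j/k_B T)] — the 1/N keeps the zero-bias
value at 0 so the bias energy is non-negative; reweighting is invariant to
the constant — and scales each deposited hill by the conditional weight
exp(−V_j/k_B T)/Σ_k exp(−V_k/k_B T). Hill widths are fixed by default
(adaptive-width schemes trade determinism for convenience and are not
needed at toy scale). Unbiasing uses the converged final bias,
w_t ∝ exp(+V(s_t)/k_B T); a time-dependent c(t) estimator is deliberately
out of scope. Free-energy profiles are −log weighted histograms shifted to
min 0, with empty bins masked (NaN), never interpolated. Block averaging
reports the SE of block means per block size; for AR(1) data the plateau
reproduces the √((1+φ)/(1−φ)) effective-sample-size inflation, which is the
diagnostic's purpose.

The CV library covers center-of-mass distance (DCM), radius of gyration and
torsions; DCM between a tail and the core is the natural fuzzy-coat CV and
per-selection bias masks allow biasing only one side of a filament, as
asymmetric protocols do.

## Structural analyses

Contacts: residue centers of mass (heavy atoms, mass-weighted) closer than
1 nm. Analyses default to the two central chains of each protofilament
stack (chains ⌈n/2⌉ and ⌈n/2⌉+1) to avoid finite-size effects at the stack
ends. Contact typing is geometric: salt bridge — charged-group N–O pair
< 0.40 nm between oppositely charged side chains; hydrogen bond —
donor–acceptor heavy atoms < 0.35 nm with donor–H–acceptor angle > 120°,
the amide H built geometrically, and distance-only for side-chain donors
whose H position is undefined at this resolution; hydrophobic — apolar
side-chain carbons < 0.45 nm between apolar residues. The thresholds are
standard geometric criteria and all configurable.

SASA uses the Shrake–Rupley point method with a golden-spiral quasi-uniform
sphere (default 960 points) and element van-der-Waals radii (SC pseudo-atoms
use their residue-specific radius). The probe radius default is 0.34 nm,
the water-probe scale in nm-based toolkits; pass 0.034 for an Å-convention
probe ÷ 10 if matching Å-based tools. Shielding ΔSASA re-computes SASA with
a residue set deleted on the same frames; point-based SASA is monotone in
the atom set, so Δ ≥ 0 holds exactly, per frame.

Secondary structure implements the Kabsch–Sander electrostatic hydrogen-bond
energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol (distances
in Å; bonded if E < −0.5), with H-bond bookkeeping in the CO(a)←NH(d)
convention, n-turn patterns (3,4,5) for helix, parallel/antiparallel bridge
patterns for strand, and a 3-state reduction (helix/strand/coil); residues
missing backbone atoms are left unassigned. Populations are weighted frame
fractions. An optional first-half/second-half split of the frame sequence
can be used as a convergence error bar.

Solubility aggregation draws a seeded subset of conformations (default 20)
without replacement and scores each with and without the fuzzy-coat atoms.
The scorer is pluggable; the built-in stand-in — explicitly NOT CamSol — is
an intrinsic hydropathy/charge propensity scaled by solvent exposure,
s = (−KD/4.5 + 0.8|q|)·SASA/(SASA + 0.5 nm²), which reproduces the
qualitative effect of interest: burial by the coat pulls hydrophobic
penalties toward zero, so removing the coat lowers the core's average
score.

## Solvent diffusion

Regions are cylinders (default radius 1 nm, height 3.6 nm — groove-scale
around a filament surface) with fixed centers or centers re-anchored per
frame to a residue selection's COM. MSD averages over time origins and over
the particles inside the region at the origin frame, tracking them even if
they later exit; an inside-at-both-ends rule is available behind a flag.
Positions are assumed unwrapped; a minimum-image unwrapping helper handles
wrapped input (valid when no physical step exceeds half the box). D comes
from the least-squares slope over a fit range (default 10–50% of the
maximum lag, excluding the short-lag regime), divided by 2·dim; the error
combines the fit covariance with replica scatter, and non-positive slopes
are flagged, never clamped. The Brownian generator draws per-axis steps of
variance 2·D·dt and reflects steps crossing a confining cylinder wall, so
the confined-versus-free slowdown measured by the tests is a pure
confinement effect with known ground truth.

## Synthetic-data scope

The generators emulate: rigid-core/flexible-tail architecture, exact axial
stacking, coarse side-chain geometry, ensemble-averaged density with
optional white noise, and ideal (memoryless, uniform-mobility) Brownian
solvent. They do not emulate force-field energetics, rotamer chemistry,
map anisotropy or B-factor variation, solvent structure, or hydrodynamic
interactions. Tests passing on these synthetics therefore validate the
*estimators and algorithms* (recovery of planted contacts, mixtures and
diffusion constants; oracle equivalence of overlaps, SASA, DSSP and FSC),
not the physical realism of any particular filament model.

## Numerical choices and problem sizes

Toy problems run on one CPU in minutes by construction: the demo filament
is 3–4 chains × 14 residues with 4-residue tails; the metainference
recovery uses 8 replicas × 400 sweeps; the double well uses 10⁵ MC steps
with hills every 100; diffusion uses 300–500 particles × 2500 steps,
three replicas. Degenerate inputs are handled explicitly: zero-variance
maps raise on correlation, empty selections raise, empty free-energy bins
are masked, single-replica σ_SEM is zero by convention with a log message,
and tail planting failures raise rather than bias.

## Known limitations

- The EM fit's component placement is seed-dependent; only the rendered
  density (not individual components) is meaningful.
- The toy sampler's conformer fraction is quantized at 1/N_R.
- Interaction typing on coarse side chains reduces to pseudo-atom
  distances; it is meaningful for fixtures with explicit side-chain atoms
  and indicative, not quantitative, for coarse models.
- The solubility stand-in shares only the sign convention and the
  burial-correction idea with structure-corrected solubility predictors;
  absolute values are not comparable.
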