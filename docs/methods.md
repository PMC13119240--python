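# Methods

## Model

The system is a cubic periodic box of semi-rigid molecules. Each molecule
is a rigid template plus a small set of torsions: for nifedipine, the two
ester groups, the two ring methyls and the nitro group (five rotations);
for felodipine, the two ester groups, the two ring methyls and the
terminal ethyl methyl (five rotations). The aryl ring orientation is *not*
a torsion — the ring-flipped arrangement is supplied as a separate
conformer template, so conformer populations are composition variables,
not dynamical ones, and stay fixed during a run (as they do in the glass
on the experimental timescale).

Template geometries were generated once from the molecular graphs with a
distance-geometry embedding plus force-field relaxation, after which the
aryl rings were snapped to idealized planar-hexagon geometry: ring C–C
1.39 Å with exocyclic bonds radial (C–H 1.09 Å, C–Cl 1.73 Å, C–N 1.47 Å).
This makes the rigid dichlorophenyl Cl···Cl separation exactly
2·(1.39 + 1.73)·sin 30° = 3.12 Å. Templates are shipped as plain-text YAML
(atoms, bonds, rotatable groups) and validated on load: connected bond
graph, bond lengths within 0.9–1.9 Å, and for every torsion the moved set
must equal the fragment cut off by deleting the axis bond.

### Reference potential

Pairwise Lennard-Jones + Coulomb with Lorentz–Berthelot combining
(arithmetic σ, geometric ε). Charges and like-type LJ parameters are
tabulated per force-field type (dihydropyridine core, ester, nitro,
dichlorophenyl); atoms without a tabulated type get zero charge and
neutral per-element defaults of OPLS-like magnitude (H 2.50/0.125,
C 3.55/0.29, N 3.25/0.17, O 2.96/0.21, Cl 3.40/1.09; σ in Å, ε in
kJ/mol). The type→atom assignment for ambiguous table rows (e.g. which
carbons count as ring carbons) is fixed in the bundled templates and is
part of the model definition.

Because the tabulated charges do not sum to zero on any of the drugs, a
uniform neutralizing correction is spread over each molecule's zero-charge
atoms. Neutral molecules let the engine use a 12 Å cutoff-shifted Coulomb
term (no Ewald) without box-size-dependent artifacts; the public
`lj_coulomb_energy` defaults to the bare 1/r sum so that hand-checked
closed forms hold exactly, while the Monte Carlo engine always uses the
shifted form (cutoff min(12 Å, L/2)). Intramolecular 1-2 and 1-3 pairs are
excluded; 1-4 and beyond count at full strength. These are conventions,
not fits.

### Empirical potential

The data-derived correction u_ep(r) is tabulated per *element* pair (the
X-ray experiment cannot distinguish finer type resolution) on a 0.05 Å
grid and applied to intermolecular pairs only. One update step transforms
the residual ΔS(Q) = S_model − S_target to r-space,

  Δg(r) = (1 / 2π²ρ r) ∫ Q ΔS(Q) sin(Qr) dQ,

multiplies by k_B T × feedback (feedback 0.3), apportions it to element
pairs in proportion to their Q→0 X-ray weights (max-normalized), smooths
with a 0.3 Å Gaussian, tapers to zero over the outer 15% of the r range,
adds to the stored table, and clips to ±15 kJ/mol. This is a direct
Fourier-feedback scheme rather than a Poisson-function expansion; it
shares the essential fixed point (S_model = S_target ⇒ zero update) and
the sign convention that excess model structure at r gains a repulsive
bump there. Updates driven by a noisy S_model random-walk the potential,
so the model pattern fed to each update is itself an average over several
snapshots.

### Monte Carlo

Metropolis NVT with symmetric proposals: molecular translations (0.2 Å),
whole-molecule rotations (10°) and single-torsion rotations (15°), all
auto-tuned every 1000 proposals toward 30–50% acceptance. Hard constraints
reject moves outright: a generic hard core at 0.5 × the element-default
Lorentz–Berthelot σ for every intermolecular pair, plus explicit floors —
by default the 2.9 Å N···O minimum for the amine donor, taken from the
crystal-phase hydrogen-bond geometry. A single seeded generator drives
everything; identical seeds give bit-identical trajectories.

### Scattering

Partial g_ab(r) come from minimum-image histograms (default bin 0.02 Å,
intermolecular pairs only unless asked otherwise); raw integer counts are
kept alongside for oracle tests. S_X(Q) uses the Faber–Ziman construction
with embedded Cromer–Mann form factors for H, C, N, O, Cl (cross-checked
against gemmi's IT92 table; hydrogen is kept at its true weak weight).
When S(Q) is computed directly from configurations, the intramolecular
part is evaluated as a Debye sum — accumulated into 0.002 Å element-pair
distance histograms with linear-split binning, which is second-order
accurate (≲3×10⁻⁴ at Q = 25 Å⁻¹) and lets one transform serve a whole
ensemble — while the intermolecular part is the Fourier transform of the
histogram partials. D(r) = (2/π)∫Q[S−1]sin(Qr)dQ with an optional Lorch
window; the input pattern must be normalized (high-Q mean within 1±0.05)
unless explicitly overridden.

FSDP metrics: the lowest-Q local maximum of S(Q) in a search window
(default 0.6–2.0 Å⁻¹) with prominence ≥ 0.02 and S > 1 — both guards
exist because finite-r_max truncation ripples and measurement noise
otherwise masquerade as peaks — refined by three-point parabolic
interpolation; width is the FWHM of S − 1.

### Box compression to the FSDP

Starting below the target density, the box edge shrinks by 1% steps with
re-equilibration, measuring the ensemble FSDP height at each density.
Once the target height is bracketed, additional measurements are spread
across the bracket and a local linear fit of height against density is
solved for the target. The regression matters: a single ensemble height
carries appreciable sampling noise at the benchmark sizes, and bisecting
on individual noisy heights stalls at a density error several times larger
than the pooled fit's.

### Conformer-fraction scans

For each candidate fraction a mixture box is built (largest-remainder
rounding to integer molecule counts), equilibrated, given a fixed small
refinement budget, and scored by the ensemble R-factor and fitted
normalization scale. Small boxes pack differently run to run, so each
fraction is averaged over several independently seeded replicas, and the
reported best fraction is the vertex of a quadratic fit through R(f)
(falling back to the grid argmin if the fit is not convex). Keeping the
per-fraction empirical-potential budget minimal is deliberate: a long
refinement partially compensates a wrong conformer mix and flattens the
discrimination.

## Synthetic data and what it does (not) show

The generator emulates the study conditions: instrument Q range
0.6–25.0 Å⁻¹, constant Gaussian noise σ = 0.005 (visually comparable to
high-energy synchrotron S(Q)), random low-density insertion followed by
compression, equilibration detected by a statistically flat energy trend
(slope within two standard errors of zero), and decorrelated snapshot
ensembles. Desk-scale problem sizes are 16 molecules for molecular
recovery benchmarks and 100 sites for the single-site fluid benchmarks,
with production ensembles of a few hundred snapshots; these sizes were
chosen so the full benchmark suite runs in minutes on one core while the
recovery tolerances (2% density, ±0.05 fraction, 0.1 in g) stay above the
measured sampling-noise floor. Paper-scale conditions (64 molecules,
≥50,000-configuration ensembles, experimental densities near
0.105 atoms/Å³) are reachable through the same code paths by
configuration.

Passing recovery tests show the inverse machinery is unbiased at these
conditions with a known-complete forcefield and exactly matched molecular
templates. They do not show that real beamline data are free of
normalization or correction artifacts, nor that the reference potential
is accurate for the real compounds — with measured data those remain the
user's responsibility (the fitted scale factor and the R-factor history
are reported for exactly that reason).

## Numerical choices and degenerate inputs

- Trapezoidal quadrature throughout; transforms on explicit grids, no FFT
  (grids are small and non-uniform ranges are common).
- Coordination thresholds (n(r) crossings) by linear interpolation.
- Histogram normalization uses N_a·N_b ordered-pair counting; the a = b
  diagonal doubles unordered counts.
- Zero interatomic distance raises immediately in the energy kernels.
- `compress_box` reports non-convergence and bound violations in a status
  field and always returns the last valid configuration.
- Peak finding raises a typed error on featureless patterns.
- Disordered CIF sites collapse to the highest-occupancy alternative;
  missing donor hydrogens are placed at riding geometry (N–H 1.01 Å along
  the heavy-atom bisector) and flagged, since H-dependent angles then
  reflect that placement.

## Hydrogen-bond criteria

The census is geometric: d(N···O) ≤ 3.5 Å and ∠N–H···O ≥ 120° by default,
both explicit parameters echoed in every output. Reported crossing
distances (e.g. where n_NO reaches 0.4) depend on the acceptor-class
convention; the default for felodipine counts the ester carbonyl oxygens,
with a switch to widen to all oxygens.

## Known limitations

- No Ewald summation; charged species beyond neutralized molecules are
  out of scope.
- The empirical-potential scheme is a simplified Fourier feedback;
  amplitudes are not comparable to EPSR program outputs, only the refined
  structures are.
- Molecule counts, not chemical potentials, fix composition: no
  insertion/deletion moves.
- Crystal comparators need user-supplied CIFs for the real polymorphs;
  only synthetic toy crystals are bundled.
- Single-threaded; the O(N·n) per-move energy makes ~64-molecule drug
  boxes the practical interactive ceiling.
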