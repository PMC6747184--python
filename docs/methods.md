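# Methods

## Scope and philosophy

`boostmd` implements the analysis chain used in accelerated-MD (aMD)
studies of small membrane-active peptides, exercised entirely on
synthetic systems whose ground truth is exact.  Nothing here runs
atomistic MD: the point is to make the *machinery* — boosting,
reweighting, landscape construction, convergence diagnostics, membrane
statistics — individually verifiable.  Chemistry is out of scope;
statistics are in scope.

## The boost potential and its parameter rules

The aMD modification raises the potential below a threshold E:

    ΔV(V) = (E − V)² / (α + E − V),  V < E;   ΔV = 0,  V ≥ E.

ΔV is non-negative, continuous at V = E, and monotone decreasing in V
on the boosted branch.  The modified force follows from the chain rule,
d(V + ΔV)/dV = α²/(α + E − V)², which the engine applies analytically
(verified against finite differences at 10⁻⁵ relative tolerance).

A *dual boost* applies the form twice: first to a designated dihedral
component (E_dihed, α_dihed), then to the total energy including that
extra boost (E_total, α_total).  Thresholds come from the standard
per-residue / per-atom rules,

    E_dihed = V_avg,dihed + b₁·N_res,    α_dihed = b₂·N_res / 5,
    E_total = V_avg,total + a₁·N_atoms,  α_total = a₂·N_atoms,

with V_avg taken from an unboosted calibration run.  The per-residue
coefficients b (typically 4–4.5 kcal mol⁻¹) drive the dihedral boost
and the per-atom coefficients a (typically 0.16–0.20 kcal mol⁻¹) the
total boost — the assignment that standard aMD practice and the usual
coefficient magnitudes imply.  On a 1-D toy potential with no separate
dihedral component, a dual boost degenerates to a total-only boost; a
2-D double well with a designated component exercises the genuine dual
code path.

## Langevin engine

BAOAB splitting with unit reduced mass (1 kcal mol⁻¹ ps² Å⁻²), kT =
0.0019872 kcal mol⁻¹ K⁻¹ × T, default 300 K, friction 1 ps⁻¹.  The
default step is 2 fs, but the toy double well (stiffness ω ≈ 6.3 ps⁻¹
at the minima) is integrated accurately at 10 fs, which the closure
analyses use: a 10⁶-step budget then spans 10 ns and yields ~400
barrier crossings of the boosted well, which is what controls the
well-to-well balance error of the recovered PMF.  Divergence (overflow
or |x| > 10⁸) aborts with a diagnostic rather than returning garbage.

## Reweighting estimators

Frame weights w = exp(βΔV) recover unbiased ensembles exactly but
amplify noise when βΔV is large.  Three estimators are provided:

* **maclaurin** — w = Σ_{k≤K} (βΔV)^k/k!, default K = 10 (the commonly
  used truncation order; configurable).  Truncation
  damps the largest weights; consequently probabilities are only
  *approximately* invariant to adding a constant to all ΔV, converging
  to exact invariance as K grows.  The exponential and cumulant
  estimators are exactly invariant; the test suite asserts each
  behaviour separately.
* **exponential** — the exact weight (clipped at exp(700) against
  overflow).
* **cumulant2** — a bin-level correction exp(β⟨ΔV⟩_b + β²σ²_b/2),
  exact when ΔV is Gaussian within a bin; it is rejected at the
  frame-weight interface because it has no per-frame form.

PMFs are −kT ln p on 50 bins per axis (1-D) or 60 × 60 (2-D) by
default, minimum-shifted to zero; empty bins are reported as missing
(NaN), never as zero energy.  "Well-sampled" in recovery tests means
≥ 100 visits per bin.

### Closure error budget

On the 5 kcal mol⁻¹ double well the dominant error in a 10⁶-step
boosted run is not per-bin noise but the relative weight of the two
wells, which equilibrates only through barrier crossings (σ of the
log-mass-ratio ≈ √(2/round-trips)).  The closure analyses therefore
use a boost with α = 0.4 (threshold V_avg + 4), the 10 fs step, and
saving every 100 steps; both estimators then recover the
bin-integrated analytic PMF within ~0.2–0.3 kT on all well-sampled
bins, against a 0.5 kT acceptance band.

### Boltzmann check of the plain integrator

A Kolmogorov–Smirnov test of unboosted sampling against the exact
Boltzmann CDF (quadrature) is only meaningful where plain Langevin is
ergodic on the test's timescale.  At 300 K the 5 kcal mol⁻¹ barrier is
8.4 kT and a 10⁶-step run makes zero well crossings — that
non-ergodicity is precisely the motivation for boosting.  The KS check
therefore runs at 900 K (barrier ≈ 2.8 kT, hundreds of crossings),
with samples thinned to ~40 ps spacing so the test is calibrated, and
α = 0.01 as the rejection level.

## Synthetic two-state helix

A 20-residue backbone (N, CA, C) is built from ideal internal
coordinates (NeRF chain construction; φ = −57°, ψ = −47°, ω = 180°,
rise ≈ 1.5 Å/residue).  Bending uses a 3-residue hinge window centred
on residue 11 whose (φ, ψ) interpolate toward a chain-reversing turn
template (120°, 80°); the interpolation fraction is solved (Brent) so
the terminal CA–CA distance hits the requested target — 10 Å for the
bent state, 25 Å for the linear state by default.  This keeps all
bonded geometry ideal, so backbone torsions stay numerically
well-conditioned under coordinate noise.  A rigid-arm construction
(`hinged_helix`, explicit inter-arm rotation about the hinge CA) is
retained for geometric oracles such as bend-angle tests; it is not
used for the ensemble because rotating a rigid arm stretches the hinge
peptide bond and makes the hinge torsion ill-conditioned.

Frames are drawn independently bent with probability `p_bent`
(default 0.5) and carry Gaussian coordinate noise (default σ = 0.1 Å
per axis; a warning fires when the noise blurs the two end-to-end
states to within 3σ).  The generator returns the realized per-frame
state labels as ground truth.

What this emulates: a peptide in fast two-state equilibrium with a
glycine-like hinge.  What it does not: continuous interconversion
pathways, side chains, solvent friction memory, or correlated frames —
so passing tests demonstrate estimator correctness, not kinetic realism.

## Synthetic membrane, waters and pore

* **Lipid chains** are straight runs of `chain_length` carbons
  (spacing 1.25 Å) anchored at leaflet planes, with a fresh tilt drawn
  each frame from a Watson-type axial distribution p(u) ∝ exp(κu²),
  u = cos θ.  With C–H vectors reconstructed perpendicular to the
  C(i−1)–C(i+1) axis, averaging the two reconstructed hydrogens gives
  per-carbon S_CD = (1 − 3cos²θ_axis)/4 exactly, so |S_CD| =
  ⟨P₂(cos θ)⟩/2 and κ is solved by quadrature + Brent for any feasible
  target; |S_CD| targets outside [0, 0.5) are rejected as infeasible
  for this geometry.  The default target 0.16 mimics a moderately
  disordered mixed bilayer.
* **Waters** are single oxygens performing an exact Brownian walk:
  per-step Gaussian displacements of variance 2DΔt per axis (default
  D = 0.03 Å² ps⁻¹).  Ground truth for D is exact by construction;
  there is no hydrodynamic interaction or caging.
* **The pore** is a rigid cylinder of wall atoms (rings of 24 atoms,
  1.5 Å apart, default radius 11 Å, length 30 Å, wall vdW 1.5 Å), so
  the free radius at the mid-plane is exactly R − r_vdW = 9.5 Å.

## Membrane estimators: numerical choices

* **Electron density**: per-frame z-histograms of per-atom electron
  counts divided by slab volume; group profiles add exactly to the
  total, and the profile integrates back to the group's electron count.
* **MSD/diffusion**: origin-averaged MSD via the FFT algorithm;
  D = slope/(2N) in Å² ps⁻¹ from a least-squares fit over the
  [1 %, 10 %] window of the maximum lag.  Short lags are used because
  MSD estimates at long lags are both noisier and strongly correlated
  between lag points; with the long-window alternative ([10 %, 50 %])
  the recovery error on exact Brownian input roughly triples.  The
  conventional scaled value slope × 10/(2N) is reported alongside.  A
  log-log exponent ≈ 2 flags ballistic (non-diffusive) input; wrapped
  coordinates (inter-frame jumps > box/2) are rejected with an unwrap
  hint.
* **Pore radius**: per z-slice, the largest circle around an in-plane
  grid point (0.25 Å deterministic grid — reproducible, unlike a
  stochastic search) clearing every wall atom's vdW radius.  Candidate
  centres are constrained to lie inside the wall ring; without that
  constraint the max–min search escapes narrow pores and reports the
  open volume outside.  Empty slices return the cap radius and are
  flagged.
* **Pore water occupancy**: KD-tree count of water oxygens within
  3.4 Å of any pore atom; tested for exact agreement with the O(n²)
  brute-force scan on every frame.
* **Helicity**: a residue is α-helical when (φ, ψ) ∈ [−100°, −30°] ×
  [−67°, −7°] (dihedral-window criterion, configurable; no
  hydrogen-bond/DSSP assignment, since the synthetic backbone carries
  no carbonyl oxygens).
* **Bend angle**: terminal direction = difference of the half-window
  centroids of the first/last 6 residue centers (≈ 1.7 helical turns
  per window), oriented away from the chain midpoint.  A raw
  least-squares line through 5 CA points of an ideal helix is tilted
  up to ~16° off-axis by the helical winding; the half-centroid
  estimator suppresses that to a few degrees.  Convention: straight
  helix ≈ 180°, bending decreases the angle.
* **Field conversion**: 1 kcal (mol·Å·e)⁻¹ = 4184/(N_A·e) V Å⁻¹ ≈
  0.4336 V nm⁻¹; a 70 mV potential across 3.5 nm is 0.02 V nm⁻¹, and
  efz = 0.080 kcal (mol·Å·e)⁻¹ is 0.0347 ≈ 0.03 V nm⁻¹.

## Conformational analysis choices

* **dPCA** embeds each defined (φ, ψ) as (cos, sin) pairs, drops
  all-NaN (terminal/broken) columns, and eigendecomposes the centred
  covariance (full SVD).  Zero-variance input returns zero eigenvalues
  and projections rather than failing.
* **Clustering** is k-means on the leading 2 PCs with 10 restarts and
  a fixed seed; k is an input, not discovered.  Representatives are
  the frames nearest their centroids.
* **RMSD** uses proper-rotation Kabsch superposition
  (`Rotation.align_vectors`); cross-checked in tests against
  derivative-free numeric minimization over rotations.
* **KLD** between two runs' projections on a shared PC basis (basis of
  the concatenated runs) uses 100 shared bins spanning the pooled
  range with a mandatory 10⁻⁶ pseudo-count (finite divergence on
  disjoint support), growing time windows, and declares convergence at
  the first window from which KLD stays below 0.025.  A Gaussian-KDE
  backend evaluated on the same bin centers is provided; the binned
  estimator carries an O(bins/n) positive bias, so backend agreement
  is asserted on the convergence verdict, not on raw values.

## Known limitations

* Frames are independent by construction; nothing here validates
  autocorrelation-aware error estimates.
* The membrane surrogate has no packing, electrostatics, leaflet
  coupling or lipid–water interaction: density profiles and order
  parameters test bookkeeping and statistics, not physics.
* The Maclaurin estimator's truncation bias is only negligible when
  βΔV stays within roughly the truncation order; the engine's boost
  parameters in the shipped analyses keep βΔV ≲ 7.
* Reported pore radii are capped at the search radius; funnel mouths
  wider than the cap saturate.
* Real trajectories' headline numbers (μs-scale folding RMSDs,
  absolute diffusion constants in membrane pores, per-helix helicity
  traces) depend on systems this package deliberately does not
  simulate; the synthetic-recovery results bound estimator error, not
  simulation accuracy.
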