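# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `contactfes`, in the spirit of a methods section for the
package itself.

## Units and constants

Lengths are Å, times ps, energies kcal/mol, temperatures K throughout.
Quantities stated in kJ/mol at input boundaries (notably the initial
hill height, 5 kJ/mol = 1.1950 kcal/mol) are converted once on entry
(`kj_to_kcal`, thermochemical calorie).  k_B = 0.0019872041 kcal/mol/K.
A single internal unit system avoids silent mixing; nothing downstream
ever re-converts.

## Contact-map collective variables

The switching function D(r) = W·(1−(r/r₀)⁶)/(1−(r/r₀)¹⁰) has a removable
singularity at r = r₀ (limit n/m = 0.6); within |r/r₀ − 1| < 10⁻⁶ both
value and derivative switch to a first-order series, which keeps the
function and the analytic gradient continuous without catastrophic
cancellation.

The normalization constant is N = Σ_γ W_γ².  Since 0 < D ≤ W for every
finite distance, each squared difference is < W², so both CVs are bounded
in [0, 1) — matching the ~0–0.9 range such CVs span in practice.  The
alternative (N = number of contacts) would leave salt-bridge-heavy sets
unbounded above 1.

Both CVs sum over the *full* contact set, differing only in the
reference against which D_γ is compared; D_γ(R_ref) is evaluated from
the reference structure's actual coordinates rather than assumed equal
to W_γ.  Two consequences are exact by construction and are asserted in
tests: CV = 0 at its own reference, and the mirror identity
CV1(active ref) = CV2(inactive ref).

Contact selection: candidate pairs are Cα/Cβ/backbone-O atoms within a
5 Å cutoff in either reference structure; a pair is state-specific when
it is within cutoff in ≥ `min_presence` (default 5) members of one
10-member ensemble and fewer of the other; pairs passing the presence
test in both ensembles are discarded as common.  Salt-bridge pairs are
an explicit input list (appended with weight 3): which pairs deserve the
higher weight is a judgment about chemistry, not something the geometry
rules can decide.  Glycine contributes Cα and backbone O only (it has no
Cβ).

The Cartesian gradient is the chain rule through each pair distance:
∂CV/∂x_a = (2/N)(D_γ − D_ref,γ)·dD/dr·(x_a − x_b)/r, accumulated over
contacts; atoms in no contact have exactly zero rows.

## Sampling engine

Dynamics is overdamped (Brownian) Langevin,
x ← x − (Δt/γ)∇(U+V) + √(2k_BTΔt/γ)·ξ.  The all-atom integrator of a
production MD code is deliberately out of scope: at desk scale only the
sampling statistics matter, and the overdamped map has a known discrete
stationary distribution (for a harmonic well, variance
k_BT/k · 1/(1 − kΔt/2γ)) that the tests exploit.  Defaults
Δt = 0.05 ps, γ = 50 kcal·ps (CV units) put ~40 steps between hills at
the 2 ps deposition period and keep Δt·k/γ ≤ ~0.5 for the stiffest
default landscape curvature.

Well-tempered hill heights follow W = W₀·exp(−V/(k_B(f−1)T)).  The
denominator is read as k_B(f−1)T in energy units — the standard
well-tempered law; writing it without k_B would be dimensionally
inconsistent.  With f → 1⁺ deposition collapses to zero for any positive
accumulated bias (no runaway), and at a fixed CV point heights are
non-increasing by construction.

Hills are deposited from the lowest-temperature replica only (a
`multiple_walkers` flag deposits from all).  The engine accumulates the
bias and its two analytic gradient components on a regular grid
(spacing 0.01, domain slightly wider than [0,1]² so soft walls can be
crossed) with hills truncated at 6σ; bilinear interpolation supplies
value and force in O(1) per step.  The public
`bias_potential_and_force` evaluates the exact truncated sum over the
hill list and serves as the oracle the grid is tested against.

Replica exchange uses p = min(1, exp[(βᵢ−βⱼ)(U⁺ᵢ−U⁺ⱼ)]) on alternating
even/odd neighbor pairs (default every 1 ps), where U⁺ adds any static
bias terms to the potential energy.  The temperature ladder defaults to
the 10-rung 300–400 K protocol; a tuner bisects the geometric ratio of a
ladder toward a target exchange rate ±5%, which operationalizes the
rate-targeted spacing protocol (30% for the tuning stage, ~10% for
production).

Randomness: one root seed expands into per-replica counter-based streams
(`SeedSequence(seed, spawn_key=(replica,))`) plus a separate exchange
stream, so trajectories are bit-reproducible and replica 0's dynamics is
independent of the ladder size.  The swap-decision draw is consumed even
when acceptance is certain, keeping streams aligned across branches.

Well-tempered ensemble: a preliminary stage deposits gentle 1-D
well-tempered hills along the potential energy (width = the unbiased
energy fluctuation, initial height W₀/4).  The frozen table rescales the
conservative force by 1 + s·dB/dE (clamped to [0.05, 20] for numerical
sanity) and adds s·B(E) to exchange energies; s = 0 reproduces unbiased
PT bit-for-bit, and s < 1 lowers the applied bias the way the production
protocol lowers it to reduce the exchange rate.  The exact functional
form used in the original protocol is not documented anywhere we could
rely on; only its purpose (broadening energy fluctuations) and the
target exchange rates are, and those are what the implementation and its
tests pin down.

Structure mode: a `BeadSystem` (per-atom harmonic tether to a reference)
stands in for the molecular force field; metadynamics forces act through
the contact-map CV gradients.  This exercises the full bias-force chain
rule without pretending to force-field realism.

## Free-energy surfaces

F̂ = −(f/(f−1))·V on a [0,1]² grid (spacing 0.01 — ≥5 cells per hill
width at σ = 0.05), shifted so the global minimum is zero.
Time-dependent offset reweighting is not applied; the plain estimator is
what "integrating the deposited bias" denotes, and the convergence
criterion below bounds what that omission can cost.

1-D projections are Boltzmann marginals,
F₁(a) = −k_BT·ln Σ_b exp(−F(a,b)/k_BT)·Δb, computed with a
log-sum-exp guard and min-zeroed (projection commutes with the shift
convention).

Convergence: two surfaces (both min-zeroed) are compared over cells
where the later surface is ≤ 10 kcal/mol; the maximum |ΔF| over the 2-D
grid and both 1-D projections must stay ≤ 2 kcal/mol.  The trailing
window is expressed as a fraction of deposition time (default: the last
10% of hills), generalizing a fixed final interval to runs of any
length.

Minima are cells strictly below all 8 neighbors; equal-valued plateaus
are grouped by 4-connectivity and resolved to the lowest-index cell when
the whole component is below its surroundings.  Basins are 4-connected
flood fills within a depth window (default 2 kcal/mol, the band used to
label minima) with watershed ties going to the deeper minimum; an
explicit CV rectangle is supported as an alternative basin definition,
since published basin outlines are sometimes drawn as rectangles rather
than iso-contours.  Basin free energies are −k_BT·ln of the
Boltzmann-weighted cell sum, so doubling a basin's area at constant
depth lowers its free energy by exactly k_BT·ln 2.

One stated invariant was weakened after analysis: adding a constant to
every hill *height* is not a constant shift of the surface unless the
hills share a center (the added Gaussians are spatially non-uniform), so
the tests assert linearity in heights and shift-convention invariance
instead.

## Population analysis

gromos clustering: iteratively take the frame with the most neighbors
within the RMSD cutoff (ties to the lowest frame index), emit it with
its neighbors as a cluster, remove them, repeat.  Distances are Cα RMSD
with each pair superposed independently (the behavior of the classical
implementation), cutoff 2 Å.  The representative is the medoid —
smallest summed RMSD to the other members, ties to the lowest index.
Frames are used unreweighted, matching the literal published procedure;
cluster populations from biased trajectories are therefore descriptive,
not equilibrium weights.

Interaction occupancy: fraction of frames in which the minimal distance
between two residues' filtered atoms is ≤ 4 Å.  The 4 Å side-chain N/O
criterion is this package's declared default — interaction tables in the
literature rarely state their cutoff, and 4 Å mirrors the
crystal-contact criterion — and it is configurable.  Classes: strong
> 75%, weak 60–75%, below excluded from the default report.

## Crystal machinery

Symmetry operators are carried in fractional-coordinate convention;
REMARK 290 SMTRY records (orthogonal Å in the PDB standard) are
converted through the cell orthogonalization (a along x, b in the
xy-plane) on read and write.  A built-in table covers P1, P2₁ and
P2₁2₁2₁ — enough for the 4-copies-per-cell case that makes a 2×2×1
supercell contain 16 molecules — and group closure of any supplied set
is checkable.  The contact map scans every non-identity image (including
lattice-shifted identity copies) against the ASU, with a bounding-box
prefilter at criterion + 2 Å margin (a performance guard with a
correctness guarantee, since no residue pair inside the margin is ever
skipped).  Missing residues simply produce no contacts.

## Fluctuation observables

RMSF uses two-pass mean-structure fitting (align to the first frame,
form the mean, re-align to the mean) rather than iterating to
convergence — deterministic and sufficient at desk scale.  RMSF is the
3-D displacement magnitude; B = (8π²/3)·RMSF² converts per atom, and
per-residue values average *after* conversion (the declared order; the
two orders differ slightly for heterogeneous atoms).  B-factor
comparison is Spearman rank correlation only: refined B-factors absorb
static disorder, cryo-cooling and refinement bias, so absolute-scale
agreement with a simulation is not a meaningful target.

Note that superposition removes 6 rigid-body degrees of freedom from the
fluctuation budget, biasing RMSF low by ~6/(3·N_atoms); recovery tests
use ≥40-residue chains so the bias stays inside their 5% tolerance.

## Synthetic data

All generators derive their randomness from `SeedSequence(seed,
spawn_key=...)` and return ground truth in a manifest dictionary
(`write_manifest` serializes it to JSON), so recovery tests never reach
into generator internals.

Two-state references: a near-straight coarse chain (Cα at 3.8 Å steps,
small Cβ/O offsets in a parallel-transported frame) in which planted
contacts bridge (i, i+2) residue pairs — Cβ atoms pulled onto the pair
axis at 4.3 Å in the specific state and splayed >7.4 Å apart in the
other.  The placement offsets were chosen so that every non-planted atom
pair keeps the same side of the 5 Å cutoff in both states, which is what
makes exact (100% precision/recall) recovery of the planted pairs
possible; a final verification recounts presences in the actual noisy
ensembles with an independent distance loop and re-draws the noise if a
marginal pair ever flips, raising a `ConstraintError` when the geometry
cannot be realized.  The two states additionally differ by a rigid 60°
bend at a mid-chain hinge — every pair crossing the hinge stays far from
the cutoff, but the backbones acquire a ~4–6 Å Cα RMSD so that basin
clustering can tell the states apart.  Default conditions: 21 residues,
10 members per ensemble, 0.1–0.12 Å coordinate noise per axis.

What this fixture does *not* emulate: real side-chain chemistry,
cooperative contact formation, or contact distances that drift with
backbone motion.  Passing the recovery tests shows the selection rules
are implemented exactly; it does not show they are robust to the
borderline, correlated contacts of real equilibration ensembles.

Landscapes: sums of inverted Gaussian wells over [0,1]² with soft
harmonic walls; `calibrated_double_well` fixes the realized well-depth
difference and deep-well barrier to stated values (3 and 6 kcal/mol by
default) by a short fixed-point correction for well overlap.  The
Boltzmann sampler is independence Metropolis–Hastings whose proposals
mix a uniform draw (30%) with Gaussians at the well centers, keeping
acceptance high even for wells many k_BT deep; with the default
thinning (5) recorded frames are effectively independent, which is what
the binomial-3σ recovery checks assume.  Ground-truth basin weights are
computed by quadrature over the nearest-center partition — note that for
Gaussian wells of different depth the *basin free-energy* difference is
not the depth difference (deeper wells are effectively narrower), which
is why tests calibrate against the quadrature weights.

Crystal fixture: a sparse straight-chain ASU parked at fractional
(¼,¼,¼) of a deliberately roomy cubic cell; planted contacts rigidly
translate one residue so its image under a chosen operator/shift touches
a target residue at 3.5 Å, approached perpendicular to the chain axis.
A brute-force 3×3×3 expansion verifies that the planted contacts (and
their reciprocal images, which a contact map necessarily also reports)
are the only residue pairs within the criterion + 0.5 Å.

Harmonic trajectories: i.i.d. Gaussian displacements with per-coordinate
variance k_BT/k — by construction free of the correlations a real
trajectory would carry, which is exactly what makes
RMSF = √(3k_BT/k) an analytic target.

## Problem sizes

The default test and acceptance runs use: 800 000 Langevin steps
(40 000 ps of toy time, 20 000 hills) for double-well free-energy
recovery; 20 random fixtures for contact-selection recovery; 120 frames
for clustering-vs-brute-force; 200 frames for occupancy recovery; 10⁵
trials for exchange statistics; 10⁴ frames for RMSF recovery.  These
sizes were chosen so each stochastic estimate sits comfortably inside
its stated tolerance (the free-energy errors roughly halve when doubling
the run, as expected for a converging well-tempered bias).

## Known limitations

- The engine is a desk-scale surrogate: no force field, solvent,
  constraints or barostat; structure mode uses harmonic tethers.
- Biased trajectories are not reweighted to unbiased ensembles, and no
  block-error analysis is provided.
- The contact-selection fixture plants clean, well-separated contacts;
  real ensembles have marginal pairs whose classification is genuinely
  noisy.
- mmCIF writing, hydrogen placement and protonation assignment are out
  of scope; the PDB subset covers ATOM/HETATM, CRYST1, REMARK 290 SMTRY
  and MODEL/ENDMDL records only.
- The built-in space-group table covers P1, P2₁ and P2₁2₁2₁; other
  groups must supply operators explicitly (e.g. parsed from REMARK 290).
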