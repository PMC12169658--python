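# Methods

`cgslab` implements a residue-resolution simulation and analysis pipeline for
liquid-liquid phase separation (LLPS) of disordered and multidomain proteins,
optionally with double-stranded DNA, in the slab-coexistence geometry.

## Coarse-grained model

**Representation.** One bead per amino-acid residue, centered on the Calpha
position; two beads per DNA nucleotide (a charged sugar-phosphate backbone
bead and a neutral base bead). Consecutive protein beads are joined by
harmonic bonds, U = k (r - r0)^2 / 2 with r0 = 3.8 Angstrom and
k = 2.39 kcal/(mol A^2) by default. Folded domains are *rigid groups*: their
internal geometry (taken verbatim from template coordinates, e.g. Calpha
traces of a PDB structure) is constrained exactly and the group moves as a
rigid body.

**Nonbonded energetics.** Two terms, with combining rules
sigma_ij = (sigma_i + sigma_j)/2 and lambda_ij = (lambda_i + lambda_j)/2:

* *Ashbaugh-Hatch (AH) hydropathy-scaled Lennard-Jones.* The attractive well
  of the LJ potential is scaled by the pair hydropathy lambda_ij while the
  repulsive core survives at full strength:

      U(r) = LJ(r) + (1 - lambda_ij) * eps    r <= 2^(1/6) sigma_ij
      U(r) = lambda_ij * LJ(r)                2^(1/6) sigma_ij < r <= r_c

  with LJ(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6]. The form is continuous at
  the LJ minimum. Defaults: eps = 0.2 kcal/mol, cutoff 25 A, plain
  truncation (no shift) -- the truncated tail at 25 A is below 2e-4
  kcal/mol for the largest residue pair.

* *Debye-Hueckel (DH) screened electrostatics.*
  U(r) = C q_i q_j exp(-kappa r) / (eps_r r), C = 332.06 kcal A/(mol e^2),
  eps_r = 80 (temperature-independent), cutoff 35 A. The inverse screening
  length kappa follows the closed form
  kappa^-2 = eps0 eps_r kB T / (2 NA e^2 I); at 100 mM and 320 K the Debye
  length is ~10 A, so the default cutoff spans ~3.5 screening lengths.

**Parameter table.** The packaged per-residue parameters
(`cgslab/data/hps_urry.tsv`) use standard residue masses, the sigma set of
the hydropathy-scale (HPS) model family, integer charges (+1 Arg/Lys,
-1 Asp/Glu) and the Urry hydropathy ranking normalized to [0, 1]
(Trp = 1, Glu = 0). Two deliberate conventions:

* Histidine is neutral. This matches the sequence-statistics convention used
  throughout the package (net charge q = #Arg + #Lys - #Asp - #Glu), which
  reproduces the reference values for the MBD-family proteins (MBD2 q = +23,
  MBD3 q = -10).
* The lambda scale is the plain normalized Urry ranking. Published
  calibrations of this model family sometimes subtract a small global offset
  (~0.08) from all lambda values, which would push Glu slightly negative;
  the table loader enforces 0 <= lambda <= 1.5, so the offset variant must
  be supplied as a user table if wanted. For the qualitative,
  electrostatics-dominated questions this package targets the distinction
  is immaterial.

**DNA duplex stand-in.** The two-bead-per-nucleotide duplex builder places
backbone beads (charge -1 e) on a B-DNA-like helix (3.4 A rise, 36 deg
twist, 9 A backbone radius) and base beads near the axis, then holds the
duplex together with three harmonic bond families (intra-strand
backbone-backbone, backbone-base, and cross-strand base-base pairing) whose
rest lengths are read off the constructed geometry. This is a *geometric
stand-in*, not a transcription of a published nucleic-acid force field: it
carries the correct linear charge density and duplex shape but no
sequence-dependent mechanics and no methylation state. The bead parameters
(`DB`, `DN` rows of the table) are package choices and are replaceable via
a user table.

## Slab systems and initialization

Coexistence simulations use an elongated orthorhombic periodic box (z the
long axis; a typical production geometry for MBD-scale proteins is
180 x 180 x 1260 A with 50-66 chains). Chains are initialized *dense*, in
the central quarter of the z axis, which skips the slow nucleation stage.
Linear chains are grown in situ as 3.8 A self-avoiding walks threading the
already-placed material (minimum inter-molecular bead distance 2 A by
default); at condensed density whole pre-built coils cannot be placed
without clashes, but bead-by-bead growth can. Rigid spans are inserted as
randomly rotated template blocks; non-linear fragments (DNA duplexes) are
placed whole with random orientation. A short displacement-capped steepest
descent (`dynamics.minimize`) relaxes residual overlaps before dynamics;
without it the first Langevin kick on a freshly packed system is violent
enough to trip the integrator's stability guard.

## Dynamics

BAOAB-splitting Langevin integration in the NVT ensemble. Per-bead friction
gamma_i = m_i / tau with tau = 1000 ps by default: with a 10 fs timestep,
this weak friction regime gives fast configurational sampling. Velocities
are drawn from the Maxwell-Boltzmann distribution at start; the O-step uses
the exact Ornstein-Uhlenbeck update, so the thermostat satisfies
fluctuation-dissipation at any timestep.

Rigid groups integrate as rigid bodies: net force -> center-of-mass
translation (drag M/tau), net torque -> rotation via the body-frame Euler
equations (including the gyroscopic term) with a quaternion orientation
update, and an independent Ornstein-Uhlenbeck refresh on each rotational
degree of freedom with the same relaxation time tau. Principal axes with
near-zero inertia are frozen and excluded from the degree-of-freedom count.
The rotational noise convention (isotropic relaxation time tau on all six
degrees of freedom) is one of several defensible choices; engines differ
here, which can shift rigid-body diffusion rates slightly without affecting
equilibrium sampling.

Two execution paths share the same compiled force kernels: fully flexible
systems run inside a single numba-compiled loop with an internal Verlet
pair list (rebuilt by an O(N^2) sweep whenever any bead has moved more than
half the 3 A skin -- at a few thousand beads the quadratic rebuild is
negligible against the pair kernel); systems with rigid groups use a
Python-level driver. Both are bit-deterministic for a given seed, each with
its own random stream. A stability guard aborts when any bead moves more
than half the smallest bead diameter in one step.

Energy bookkeeping uses kcal/mol, Angstrom, g/mol and ps
(1 kcal/mol = 418.4 g A^2 ps^-2 mol^-1; kB = 1.9872e-3 kcal/mol/K).

## Analysis

**Density profiles and C_sat.** After discarding an equilibration fraction
(default 20%, the convention of excluding the first 1 us of a 5 us run),
each frame is recentered so the slab's mass center -- computed as a
circular mean over the periodic z coordinate, which is drift- and
wrap-safe -- sits at z = 0. Species-resolved histograms (default bin 5 A)
are accumulated in both mg/mL (mass) and uM (chain centers of mass). The
coexistence concentrations come from a least-squares fit of

    rho(z) = (rho_d + rho_l)/2 - (rho_d - rho_l)/2 tanh((|z| - z0)/w)

with region averages (dense |z| < z0 - 2w, dilute |z| > z0 + 2w) reported
alongside as a fit-free fallback; the dilute value rho_l is the saturation
concentration C_sat. A profile is flagged phase-separated only when the
fitted contrast rho_d/rho_l >= 1.5 *and* the interface is sharp on the box
scale (w < Lz/8, dilute plateau present). The sharpness condition matters:
per-frame recentering of a homogeneous system aligns its density
fluctuation maxima and imprints a spurious box-wide cosine bump whose
amplitude scales like n_chains^-1/2; gating on interface width rejects it.
Replicates (default: triplicate seeds) are fitted independently and
reported as mean +- sd.

**Contact maps.** Two beads on different molecules are in contact when
r < 1.5 (sigma_i + sigma_j)/2 under minimum image -- reading the model's
sigma parameters as the beads' van der Waals diameters, giving ~9 A
criteria for typical residue pairs. (The alternative reading, 1.5x the
mean *radius* ~ 2.3 A, sits inside the repulsive core and registers almost
nothing; the factor is configurable.) Counts are indexed by intra-chain
position, averaged per frame and per chain pair so maps are comparable
across chain counts, and by default restricted to the condensed phase
(both partners within |z - slab center| < z0 from the coexistence fit).
Neighbor search uses a periodic k-d tree; a brute-force recount oracle in
the test suite pins the implementation exactly.

**Phase diagrams.** A mixture scan varies the A:B chain-count ratio at
fixed total chain count (nearest-integer rounding, realized counts
recorded), runs one slab simulation per ratio and seed (or consumes
pre-made trajectories), extracts per-species dense/dilute concentrations,
and emits mixture points, tie lines (dilute composition <-> dense
composition), and the dense-arm polyline. An optional third species (DNA)
rides along at fixed stoichiometry (default 5 protein chains per duplex)
without becoming a diagram axis. Per-cell JSON caching makes long scans
resumable; a failed replicate flags its point but never aborts the scan.

## Synthetic data

The generators produce every input the pipeline needs with known ground
truth: (i) K/E polyampholytes (G filler) with exact charge counts and a
blockiness dial interpolating strict alternation -> diblock, the minimal
sequence family expressing charge-patterning control of LLPS; (ii) rigid
fixtures (ideal 3.8 A-spaced helix, jammed compact cluster) standing in for
folded-domain templates; (iii) slab trajectories whose chain centers are
sampled each frame from a prescribed tanh density profile, with the
realized parameters (after integer chain-count rounding) recorded in the
trajectory metadata. Chains in (iii) are freely jointed 3.8 A coils with
independent frames: the generators emulate the *geometry and statistics*
of coexistence, not dynamics, so passing analysis tests demonstrates
correct measurement, not correct physics; the physics is exercised by the
Langevin runs.

## Problem sizes used in the shipped tests

The printed reference results of the source system (C_sat shifts across
truncations and with DNA) come from ~5 us runs of 50-66 chains of 300-400
residues -- cluster-scale work. The shipped test and acceptance runs use
desk-scale renditions chosen to express each claim at small cost:
equipartition and diffusion on ensembles of 300-400 noninteracting beads
(3-4e5 steps); bond-variance on 256 independent dimers (8e5 steps; the
kinetic energy decorrelates over ~tau/2 = 5e4 steps, which sets these
sample counts); rigid-body drift over 1e4 steps; and the charge-patterning
contrast on 10 chains of 30-mer K/E polyampholytes in a 50 x 50 x 300 A
slab at 320 K and 100 mM salt (1e5 steps for the diblock, 2.5e5 for the
alternating isomer, AH/DH cutoffs 15/25 A). At this scale the diblock
holds a dense slab with >10x center-to-edge density contrast while the
alternating isomer disperses to near-uniform (<2x). Contrast for these
runs is measured with split-half centering
(``slab_analysis.density_contrast``): each frame is centered on half the
chains while only the other half is histogrammed. A slab drifts bodily
under the thermostat's momentum diffusion (~100 A/ns at this size, so a
fixed frame will not do) and both halves ride it, so the slab is tracked;
in a dispersed system the two halves are independent, so the reference
shift cannot imprint structure -- unlike ordinary per-frame centering,
whose bias is material at 10 chains.

## Known limitations

* Temperature dependence is purely kinetic (kB T in the thermostat and the
  Debye length); the hydropathy scale does not vary with temperature, so
  LCST-type solvent physics is out of reach by construction.
* The DNA model is a geometric stand-in (above); methylated and
  unmethylated CpG are indistinguishable.
* Plain cutoff truncation leaves sub-1e-3 kcal/mol discontinuities; the
  NVE drift test bounds their integrated effect.
* Desk-scale coexistence runs carry finite-size effects; dense-phase
  concentrations at 10-20 chains should be read as qualitative.
* `minimize` is a regularizer, not an optimizer: it removes catastrophic
  overlaps only.
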