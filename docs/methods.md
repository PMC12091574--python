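# Methods

## Scope and model

`hydroshell` quantifies how a protein surface orders the water around it,
at single-molecule resolution. The motivating systems are antifreeze
proteins (AFPs) and ice-nucleating proteins (INPs), whose flat,
threonine-rich ice-binding surfaces (IBS) template ice-like water; the
observable that separates strong from weak water-ordering surfaces is the
rotational entropy of individual hydration-shell waters, supported by
structural (H-bonding, tetrahedrality) and kinetic (shell residence time,
mobility) metrics, and by protein-side rigidity metrics of the threonine
ladders themselves.

All analyses operate on periodic MD trajectories (PDB/GRO topology with
XTC/DCD/multi-model-PDB frames, read through MDAnalysis). Internal units
are angstroms and picoseconds everywhere; readers convert nm-based
formats on load. The box is a 3x3 lattice-vector matrix; all distances
use the minimum-image convention, with an exact 27-image refinement for
triclinic cells.

## Permutation reduction

Waters are indistinguishable, so "water k" has no meaning across frames
once molecules exchange. Each frame is therefore relabelled against a
reference configuration with the permutation minimising the total
squared minimum-image O-O displacement, solved exactly as a linear
assignment problem (`scipy.optimize.linear_sum_assignment`). After
relabelling, every label indexes a localised spatial slot, and per-label
histograms of position and orientation are meaningful. The reference is
the first frame by default (recorded in output metadata); the same frame
anchors the nearest-k water ranking, so "water index k" means one slot
throughout a run. Equal-cost assignments are broken deterministically by
the solver; any tie-respecting assignment satisfies the optimality
invariant (permuted cost <= identity cost, asserted per frame).

## Rotational entropy

For each tracked water, two angles are accumulated relative to a solute
reference point (the nearest IBS hydroxyl oxygen by default; any atom or
fixed point can be configured):

* theta — between the water-O -> solute vector and the dipole
  (O -> midpoint of H1, H2), in [0, 180] deg;
* chi — between the normal of the (solute vector, dipole) plane and the
  H1 -> H2 vector, in [0, 180] deg.

Samples with an undefined normal (dipole parallel to the solute vector)
are flagged and excluded, with a counter. The chi sign convention is
fixed by the H ordering of the water indexing; swapping H labels maps
chi -> 180 - chi, which leaves the entropy of every symmetric
distribution used here unchanged.

With the angular measure d(mu) = sin(theta) dtheta dchi and total domain
measure c = 2*pi, the entropy relative to the uniform orientation
density is

    S_rot = -k_B * sum_bins  p_hat * ln(p_hat * c) * mu_bin ,

i.e. minus the Kullback-Leibler divergence of the binned density from
uniform: exactly 0 for uniform orientations and negative for any
ordering. Results are reported as T*S in kcal/mol (k_B = 0.0019872041
kcal/mol/K; default T = 273 K, the supercooling-relevant temperature).
Defaults: 30x30 grid over (theta, chi), with the exact integral of
sin(theta) over each theta bin as the bin measure, so the piecewise-
uniform closed forms (half-domain: -k_B T ln 2; single bin:
-k_B T ln(c/dOmega)) hold analytically on the grid. The plug-in
estimator is non-positive on uniform data with a bias of about
-(m-1)/(2n) nats for m occupied bins and n samples; the default minimum
sample count is 10^4 (configurable), and a convergence helper computes
the estimate on growing prefixes of the series.

## Translational entropy

The translational analogue ("method: voxel-3D", noted in reports) is the
voxel-histogram differential entropy of one label's permutation-reduced
O positions over the label's local bounding cell, referenced to the
uniform density over that cell: T*S_trans = -k_B T sum f ln(f * N_vox),
zero for uniform occupancy, -k_B T ln 8 for confinement to one octant.
Default 10x10x10 voxels. The reference cell is the per-label bounding
box (cell-referenced, not bulk-density-referenced), so values compare
confinement between labels, not absolute free volumes.

## Hydrogen bonds

Geometric criterion: donor-O to acceptor-O minimum-image distance
<= 3.5 A and O-H...O angle within 30 deg, where the angle is the
deviation between the O_d->H and O_d->O_a vectors (the common
trajectory-analysis convention). The alternative D-H...A >= 150 deg
reading is available behind the criterion's `angle_def` tag. Residence-
time reactant selection uses a distinct 35-deg criterion object rather
than a changed global default. Per-water counts sum donated and accepted
bonds; protein partners (threonine hydroxyl or carbonyl oxygens) enter
through explicit donor/acceptor lists, so pure-water and IBS contexts
are both expressible. "Remains H-bonded" to a hydroxyl means bonded in
at least half the frames (occupancy 0.5, configurable, recorded in the
manifest).

## Water structure

O-O-O angles: for each central water (the water O nearest each
threonine hydroxyl O, per frame), every pair of water-O neighbours
within 3.5 A contributes one angle at the central O; distributions use
1-deg bins and the mode is reported as the left bin edge (the ideal
tetrahedral lattice gives 109).

Conditional tetrahedral order: with the k nearest O neighbours within
3.5 A (2 <= k <= 4; fewer than 2 excluded and counted) and
n_p = k(k-1)/2 pair angles psi,

    t_h = 1 - (9/4) * (1/n_p) * sum (cos psi + 1/3)^2 .

The per-pair normalisation fixes t_h = 1 for perfect tetrahedral angles
at every k and E[t_h] = 0 for isotropic neighbours (since
E[(cos psi + 1/3)^2] = 4/9), making values comparable across k; for
k = 4 it coincides with the Errington-Debenedetti q. Neighbours are
selected by distance only (water O atoms; protein O excluded); an
H-bond-conditioned neighbour definition would be a stricter variant and
is not implied by the distance-only default.

## Shell-exchange kinetics

Residence times follow the stable-state picture: a water is a reactant
when H-bonded to an IBS hydroxyl (3.5 A / 35 deg) at the time origin and
has reached the product once its O exceeds 5.3 A from every IBS hydroxyl
oxygen — a cutoff placed from the site-water radial distribution
function (the `site_water_rdf` helper exists for exactly this). The
survival correlation C(t) = 1 - <p_R(0) p_P(t)> uses a first-passage
(absorbing) product indicator, so transient recrossings inside the
5.3 A shell do not terminate a residence; an instantaneous-indicator
mode is provided for comparison. Origins are taken every
`origin_stride` frames over a fixed window, so all lags average the
same origins and C(t) is non-increasing by construction.

Origin pooling is exact for memoryless (single-rate) exchange; for a
heterogeneous population with no rebinding, later origins over-sample
slow waters, so such analyses should use a single origin (set
`origin_stride` beyond the trajectory length).

C(t) is fitted by least squares with C1 exp(-t/tau1) + C2 exp(-t/tau2)
down to C = 0.01, initialised from a two-segment log-linear split, with
tau bounded by 100x the fitted time range and reported as tau1 <= tau2;
the mean residence time is the amplitude-weighted
tau = (C1 tau1 + C2 tau2)/(C1 + C2). Because that weighting is
pathologically sensitive to a vanishing-amplitude slow component fitted
to tail noise, a single exponential is fitted alongside and kept unless
the second component reduces the RMS residual by >= 30% and both
amplitudes carry >= 2% of the total. A constant C(t) raises a "no
decay" error rather than returning a meaningless tau.

MSD uses multiple time origins over all particles, unwrapping wrapped
coordinates through minimum-image frame increments; D = slope/6 over a
central lag window (default the 20-80% lag range) per the Einstein
relation.

## Protein-side IBS metrics

theta_S (side angle): ladder axis (Calpha of the two x-residues
bounding the TxT ladder) vs the Cbeta -> OG1 vector of each threonine.
theta_T (top angle): neighbouring-threonine Calpha axis vs
Cbeta -> OG1; terminal residues without a forward neighbour are
skipped and counted. Distributions use 2-deg bins, normalised as
densities. Side-chain RMSD superposes each frame on the reference via
backbone atoms (Kabsch, `scipy.spatial.transform.Rotation`), then takes
the heavy-atom side-chain RMSD per residue, so global rigid motion
contributes exactly zero. Ladder Calpha spacing is reported in both
readings — consecutive rungs across coils, and TxT pairs (resid
difference 2) within a strand — because the two geometries are not
interchangeable; both appear side by side. Tyrosine stacking
(Cbeta-Cbeta of adjacent pairs) and Ser(OG)-Gly(O) loop distances are
summarised by their distributions and IQR (sharp = stable contact,
broad = fluctuating loop). Ladder membership is user-supplied
configuration; it is never auto-detected silently.

## Synthetic systems and what they do not emulate

Every generator records its analytic ground truth in a `SyntheticSpec`,
and tests compare pipeline output only against that record:

* diamond-cubic water lattice with ice-rule proton placement (balanced
  Eulerian orientation of the 4-regular neighbour graph): every O-O-O
  angle tetrahedral, t_h = 1, 4 H-bonds per water at zero jitter, plus
  an independent exhaustive H-bond counter for jittered frames;
* prescribed orientation laws (uniform, half-domain, single-bin,
  exp(kappa cos theta)) with closed-form or quadrature T*S_rot;
* Markov two-state shell exchanger with exact bound/free state series;
  survival exp(-k_exit t) and tau = 1/k_exit when rebinding is off;
* Brownian walkers with known D and retained unwrapped coordinates;
* a planar "toy IBS" of hydroxyl-bearing pseudo-threonines (CA, CB,
  OG1, HG1) over a water slab, with optionally pinned, orientation-
  frozen waters and analytic theta_S = theta_T = 90 deg.

Defaults mirror hydration-shell MD scales: O-H 0.9572 A, H-O-H
104.52 deg rigid waters (the lattice generator instead points H along
donated neighbour directions, giving the 109.47-deg lattice geometry);
O-O 2.76 A lattice spacing; 7.4 A hydroxyl register for the toy IBS;
D = 0.2 A^2/ps and exchange rates of order 0.01-0.1/ps. Trajectory
sizes in the shipped analyses (hundreds of waters, hundreds of frames)
are chosen so every statistical recovery sits well inside its stated
tolerance.

These generators validate the estimators, not the physics: they have no
forces, no correlated H-bond network dynamics, no coupling between
orientation and position, and no protein flexibility. Passing tests
demonstrate that each metric recovers known ground truth through the
full I/O and bookkeeping path — they do not demonstrate that any real
protein orders water.

## Numerical choices and degenerate inputs

* Minimum image: fractional rounding for orthorhombic boxes; exact
  27-image search for triclinic. Degenerate boxes (volume <= 0) are
  rejected.
* Water detection is by residue name (SOL/HOH/WAT/TIP*, configurable),
  tolerant of atom order, with an O-H 0.8-1.2 A sanity check; TIP4P/
  TIP5P virtual sites are carried but ignored by all criteria.
* Nearest-water ranking ties break on water id; ranking happens once at
  the reference frame, identities tracked thereafter by permutation
  reduction.
* Empty histogram bins contribute 0 (0 ln 0 := 0) in both entropy
  estimators.
* Waters with fewer than 2 structure neighbours, residues missing
  atoms, and terminal ladder residues are skipped and counted, never
  silently dropped.
* Pipelines abort with the failing stage's name; partial outputs
  written before the failure are preserved, and every applied default
  is listed in the JSON manifest.

## Known limitations

* T*S_trans uses a voxel histogram over a data-driven bounding cell;
  values depend (logarithmically) on voxel count and cell choice and
  are comparative, not absolute.
* The rotational estimator is plug-in; no bias correction is applied
  beyond reporting n and offering the convergence check.
* The assignment step is O(N^3) per frame; trajectories with tens of
  thousands of waters should restrict to the hydration shell of
  interest first (the nearest-k selection exists for this).
* Real-protein runs (PDB-derived IBS ladders) require the user to
  supply ladder residue ids and loop definitions in the configuration.
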