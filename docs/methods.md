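# Methods

This note records the models implemented in `sitedyn`, the assumptions they
make, the defaults and why, and what the synthetic validation does and does
not demonstrate about real simulation data.

## Generalized order parameters

For each selected sidechain a per-frame unit vector μ is taken along the
bond that carries the functional group: Cβ→Cγ for Asp/Asn, Cγ→Cδ for
Glu/Gln. These are the symmetry axes of the carboxylate/amide planes and
correspond to the Cγ/Cδ positions probed by sidechain ¹³C NMR relaxation,
which is why the package restricts itself to the DENQ residue types (other
vectors would be a trivial extension but have no observable to compare to).

The estimator is

S² = ½ ( 3 Σᵢ Σⱼ ⟨μᵢ μⱼ⟩² − 1 ),

with ⟨·⟩ the plain arithmetic average over **all** frames. This is the
long-time plateau of the second-rank reorientational correlation function,
not a windowed correlation-function fit: no internal correlation time is
estimated, and kinetics do not enter — only the stationary orientational
distribution does. Consequences worth knowing:

- The estimate requires prior removal of global rotation. `align_frames`
  does this with an unweighted Kabsch fit per frame; the default fit
  selection is backbone N/CA/C/O of all residues, a conservative standard
  when nothing about the original superposition protocol is known.
- Algebraically S² ∈ [−0.5, 1] (it is a quadratic form in a traceless part
  of a symmetric second-moment matrix); finite sampling of a disordered
  vector gives small positive values of order n^(−1/2) rather than exactly 0.
- The estimator is exactly invariant under μ → −μ and under any common
  rotation of all vectors.

**Errors.** The trajectory is cut into `n_blocks = 10` contiguous equal
blocks (a common block-averaging choice; remainder frames at the end are
dropped from the block estimates only), S² is computed per block, and
SEM = sd(blocks, ddof = 1)/√n_blocks. Sample (ddof = 1) standard deviation
is used; for two blocks with values a, b this gives the hand-checkable
SEM = |a − b|/2. Block averaging absorbs serial correlation on timescales
shorter than a block; it underestimates the error when the slowest motions
are comparable to the trajectory length, which is exactly when any error
estimate from a single trajectory is suspect.

**Condition comparison.** `compare_s2` reports ΔS² with a pooled SEM
(√(sem_a² + sem_b²)) and flags |ΔS²| > 1.96 × pooled SEM. This is a
per-residue judgement at the nominal 5% level with no multiple-testing
correction — matching how such comparisons are conventionally reported —
so across ~20 null residues one false positive is expected.

## Hydrogen-bond occupancy

A (D, H, A) triad is bonded in a frame when |D−A| < 3.1 Å **and** the
geometry is within 25° of linear, both strict inequalities. The angle has
two conventions, selectable on `HBondCriteria`:

- `donor_deviation` (default): the angle at the donor between D→H and D→A.
  A literal included D–H–A angle "below 25°" is geometrically impossible
  for a bonded pair (it approaches 180°, not 0°, at linearity), so the
  stated threshold is interpreted as a deviation-from-linear criterion.
- `dha_supplement`: 180° minus the included D–H–A angle at the hydrogen.
  Both are 0° for a perfectly linear bond but diverge for bent hydrogens;
  the default is the geometry at the donor.

Donors are sidechain N/O atoms with a covalently bound hydrogen (assigned
by distance, < 1.25 Å within the residue — structures must carry explicit
hydrogens; none are reconstructed). Acceptors are sidechain oxygens plus
sidechain nitrogens with no bound hydrogen (the unprotonated His ND1/NE2).
Backbone atoms are excluded by default because the occupancies of interest
are inter-sidechain; `include_backbone=True` lifts this.

Pair occupancy uses OR aggregation: a frame counts if **any** triad of the
pair is bonded, so the two equivalent carboxylate oxygens (or the several
guanidinium hydrogens of Arg) contribute to one pair-level number, which is
therefore ≥ any single triad's occupancy. Distances and angles are
rigid-motion invariant, so this module needs no prior alignment.

## Density maps and residence times

`accumulate_density` bins one atom per frame into an isotropic grid
(default spacing 0.5 Å — fine enough to resolve a ~4 Å inter-site
separation by ~8 voxels) spanning the atom's bounding box padded by 2
voxels. Binning is nearest-voxel on half-open intervals with no smoothing,
because fractional occupancy and its residence-time reading are defined in
frame counts; the output metadata states that the map is unsmoothed.
Values are counts/n_frames, so a single-atom grid sums to exactly 1.

`contour_mask` uses an inclusive ≥ threshold so that a voxel exactly at the
contour level satisfies the "at least" residence-time semantics, and
`occupancy_to_residence` converts a contour level c over a trajectory of
length L ns into c·L·1000 ps (with a rounded-up integer convenience form:
0.05% of 89 ns → 44.5 ps → 45 ps).

Grid values are locked to the grid frame: re-accumulating after a common
rigid transform of the trajectory redistributes boundary counts between
adjacent voxels, so only grid-frame-independent summaries (total occupancy,
weighted centroid up to a voxel diagonal) are exactly comparable across
frames of reference.

## Ion stability metrics

`ion_rmsd` is √⟨|r − r_ref|²⟩ with r_ref defaulting to the frame-0 position
after protein alignment — an "about-initial" RMSD, chosen because the
scientific contrast is between an ion that stays where it was placed and
one that migrates; the reference is a parameter, so about-mean or
about-crystal-site RMSDs are the same call with a different argument (the
about-mean choice is the minimum over references). `endpoint_displacement`
is the distance between mean positions over a head and a tail window,
defaulting to 1% of the frames each (minimum 1) to damp single-frame noise.
Both metrics, and `site_distance`, are invariant under a common rigid
transform of trace and reference.

## Superposition

`kabsch_fit` solves the orthogonal Procrustes problem restricted to proper
rotations (the rotation solve is SciPy's `Rotation.align_vectors`;
reflections are excluded because they are not physical rigid motions),
requires ≥ 3 non-collinear points, and reports the RMSD after the fitted
transform. `transplant_ion` fits the ion-bearing structure onto the target
over backbone atoms common to both (by chain/residue/atom identity) and
maps the ion through that transform — the standard way to seed a
metal-bound simulation from an apo crystal structure when the ion-bound
form is disordered.

## Synthetic generators: what they emulate and what they do not

The generators produce trajectories whose analysis answers are known in
closed form, giving every pipeline an exact oracle:

| generator | ground truth |
|---|---|
| cone (semi-angle θ₀) | S² = [cosθ₀(1+cosθ₀)/2]² |
| two-site jump (β, populations p, 1−p) | S² = 1 − 3p(1−p)sin²β |
| telegraph H-bond (occupancy p) | occupancy = realized Bernoulli fraction |
| confined ion (per-axis σ) | RMSD about center = √3·σ |
| tumbling wrapper | analyses unchanged after alignment |

Deliberate simplifications, and hence the limits of what passing tests
show about real data:

- **Scaffolds are minimal**, not physical peptides: ideal-geometry
  fragments carrying only the atoms each analysis consumes. Nothing about
  force-field realism is tested.
- **Sampling is i.i.d. per frame by default** (the two-site and confined-ion
  generators optionally carry Markov/AR(1) correlation — the confined ion
  defaults to lag-1 autocorrelation 0.8). Plateau values and occupancies
  depend only on the stationary distribution, so this is sufficient for
  correctness of the estimators; it does **not** exercise slow-convergence
  behaviour, and block SEMs on i.i.d. data are smaller than on real
  trajectories.
- The confined-ion well is isotropic and the scaffold perfectly rigid, so
  alignment is exact; real alignment error from internal protein motion is
  not modelled.
- The generators' default conditions are the scales used throughout the
  validation: 10⁶ frames for closed-form S² recovery to ±0.01, 10⁵ for the
  two-site and ion-RMSD checks, 10⁴ for occupancy recovery to ±0.02 and
  density centroids to 0.2 Å, 5×10³ for tumbling removal. These sizes make
  the statistical tolerances comfortable for the estimators' n^(−1/2)
  convergence while keeping the whole validation desk-scale.

One statistical detail: the telegraph-occupancy calibration test checks
that 200 seeded replicates fall inside the central 99% binomial interval of
the generator probability. For n = 1000, p = 0.3 the exact coverage of that
discrete interval is 99.13%, so the count of replicates inside is
Binomial(200, 0.9913); the test thresholds at that distribution's 0.1%
quantile rather than at a naive 198/200, which the exact model itself would
fail about one seed in four.

## Numerical choices

- Coordinates are Å everywhere; times ps internally (trajectory length
  reported in ns); PDB round-trips are exact to the format's 0.001 Å.
- Strict `<` at both hydrogen-bond thresholds; inclusive `≥` at density
  contour thresholds (each matching its stated semantics).
- Unit-vector tolerance 1e-6 on S² inputs; collinearity rejected in Kabsch
  fits when the second singular value falls below 1e-8 of the first.
- Degenerate inputs raise typed exceptions (`sitedyn.exceptions`) rather
  than returning sentinels; the CLI maps them to exit 1, usage errors to
  exit 2.
- DX and TSV outputs use fixed float formatting so identical runs are
  byte-identical.

## Known limitations

- Trajectory frame spacing is user-supplied: neither multi-model PDB nor
  DCD carries it reliably, so residence-time conversions are only as good
  as the `--dt` the user provides.
- No correlation-function fitting (model-free internal correlation times),
  no iRED, no backbone N–H order parameters.
- Hydrogen-bond analysis requires explicit hydrogens; no placement or
  protonation-state prediction is done, and His donor/acceptor roles follow
  only from which hydrogens are present in the input.
- Density maps are single-atom; solvent/multi-atom fields and symmetry
  averaging are out of scope.
- mmCIF and trajectory formats beyond multi-model PDB/DCD are not read.
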