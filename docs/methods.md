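# Methods

`lysotraj` implements the analysis stack used to characterize how a
lysolipid transporter of the major facilitator superfamily (MFS) captures
its substrate: per-frame insertion observables, occlusion geometry
(vestibule distances, hydration, proline kink), HOLE-style pore profiling,
a coordinate-image deep-network state classifier with saliency attribution,
and Gaussian information-theoretic allosteric coupling. Because producing
microsecond all-atom membrane trajectories is out of scope, every stage is
exercised on seeded synthetic systems whose ground truth is known exactly;
the generators are first-class, tested code.

Conventions: coordinates in Å, angles in degrees, entropies in nats,
residue numbering 1-based, and the membrane normal along +z (the
extracellular side up, so the bulk outer leaflet sits near d_z ≈ +20 Å
above the intracellular gate reference).

## Insertion observables (`geometry`)

**d_z** is the signed distance along z between a lipid headgroup phosphorus
and the Cα of the intracellular gate phenylalanine: d_z = z(P) − z(Cα).
An **insertion event** is an episode with d_z ≤ 13 Å. Episodes end only
when d_z rises back above 15 Å (a +2 Å hysteresis); the debounce rule is
this package's choice — event counting from a noisy series needs one, and
the convention is recorded with the outputs. The entry **pathway** is the
lateral portal (TM5/TM8 or TM2/TM11) whose anchor-atom centroid the P atom
approached most closely over the 10 frames up to and including entry; two
events are **concomitant** when their inserted intervals overlap.

The **sodium bridge** criterion marks frames where the nearest cation is
within 2.5 Å of the carboxyl carbon of the headgroup-coordinating glutamate
while the substrate P sits below 6 Å of the same atom; the summary reports
the overall bridge fraction and the conditional fraction P(P < 6 Å | Na ≤
2.5 Å). **Vestibule hydration** counts water molecules (grouped by residue
id) with any atom within 3 Å of any atom of the lining sidechains; a
KD-tree accelerates the search and a naive double loop is kept as an
independent cross-check. **Substrate RMSD** is computed against frame-0
coordinates after least-squares superposition of the transmembrane
backbone on frame 0. Histograms use fixed 0.5 Å bins anchored at 0 and
label peaks as local maxima of a 3-bin moving average, ranked by height;
bin width and smoothing are artifact conventions (configurable).

## Kink angles and pore profiles (`helix_metrics`)

The **kink angle** α is the angle between helix-axis directions of the
segments flanking the kink proline, with the proline ± 1 residue excluded
from both fits. The axis of a Cα segment is estimated by the
successive-bisector construction: second differences of the Cα chain point
from the helix surface toward the axis, and cross products of consecutive
second differences are exactly parallel to the axis for an ideal helix of
any length ≥ 4 residues. A principal-component fit was considered and
rejected: the fractional helical turn left over at segment ends tilts the
principal axis by ~2° at typical segment lengths, which is the same order
as the effect being measured. Degenerate (near-straight-line) traces fall
back to the principal direction.

The **pore profile** fixes the pore axis along z and, at 0.25 Å stations,
finds the in-plane center maximizing the radius of the largest sphere
touching no atom (radius = min over atoms of |center − atom| − r_vdW).
The search is seeded simulated annealing (120 proposals, temperature
0.5 → 0, step 0.8 → 0.05 Å) followed by a Nelder-Mead polish, initialized
from the previous station's center and confined to a 2.5 Å disk around it —
the largest-sphere objective is unbounded outside the atom cloud, so the
walker must track the cavity rather than escape through it. The profile
ends where the radius exceeds a 10 Å bulk cutoff. Van der Waals radii are
the Bondi set with a 1.7 Å fallback. Per-frame **pore direction** is the
principal direction of the sphere centers inside a z-window, oriented +z;
the ensemble direction is the normalized mean, and divergence between two
ensembles is the angle between their directions.

## State classifier and saliency (`classifier`, `nn`)

Each frame is encoded as an RGB image: pixel k is atom k of the encoded
selection (sequential order, top-left to bottom-right), and R, G, B carry
x, y, z min-max-normalized over the pooled training set and quantized to
8 bits. Pooled (not per-frame) bounds keep absolute displacements visible;
at inference, out-of-bounds coordinates are clipped and counted. The image
is the smallest near-square rectangle holding all atoms (73 × 72 with 47
padded, masked pixels for a 5209-atom selection); the encoding is invertible
to within one quantization step.

The classifier is a densely-connected CNN written in NumPy with explicit
forward/backward passes: dense blocks whose 3×3-conv layers concatenate
their growth-channel outputs onto the running feature map, 1×1-conv +
2×2-average-pool transitions with reduction 0.5, global average pooling and
a linear head. The full production descriptor (blocks [6, 12, 36, 24], 96
initial filters, growth 48) is constructible; tests and the pipeline train
the reduced variant (blocks [2, 4], 16 filters, growth 8) — same code path,
flag-selected — because the full network is not desk-scale. Training uses
a 56:24:20 train/validation/test split, seeded shuffling, batch size 32,
and adaptive-moment (Adam) updates at learning rate 1e-3. The rate was
chosen because this no-batch-norm network trains erratically at 1e-4
(seed-dependent stalls in the dead-ReLU regime) and converges stably at
1e-3 on the planted-shift ensembles. Identical seeds reproduce splits,
curves and accuracies exactly.

**Saliency** is the guided-backpropagation gradient of the class score
(logit) with respect to the input pixels — the ReLU backward pass
additionally gates on positive upstream gradients — aggregated as the
absolute-value sum over RGB, averaged over a class's images, zeroed on pad
pixels, and max-normalized to [0, 1]; the 0.6 cutoff is applied to this
class-average map (per-map normalization before cutoff is the documented
alternative switch). Residues are ranked by their maximum per-atom
saliency, ties broken by ascending residue number. Convolutional receptive
fields smear attribution onto pixel neighbours, so on multi-atom planted
regions the package asserts strong localization (planted atoms dominate,
majority above cutoff) rather than exact top-1 ranking; a single planted
residue does rank first. **Exclusion ablation** zeroes and masks a region's
pixels in every image and retrains with the identical protocol and seed,
reporting the accuracy change.

Frames can be positionally and orientationally **scrambled** before
encoding (uniform SO(3) rotation via unit quaternions; centroid re-placed
uniformly at random), which removes every trace of absolute pose: on
ensembles differing only by a rigid placement, the scrambled pipeline
classifies at chance.

## Gaussian information-theoretic allostery (`nbit`)

With rigid-body motion removed by superposition, the covariance C of the
stacked atomic coordinates defines configurational entropy
H = ½ ln|2πe C|, evaluated as ½ Σ ln(2πe λᵢ) over eigenvalues floored at
ε = 1e-8 Ų (superposition leaves near-singular rigid-body directions and
the log-determinant must stay finite). Total correlation of a partition is
TC = Σ H(Xᵢ) − H(joint); the partition of a site is per-atom (the
components of the set's 3N-vector) — the TC of a single undivided block is
identically zero. Coordination information is the drop in receiver TC upon
conditioning on a transmitter site, CI = TC − TC(·|X_m), with conditional
covariances via the Schur complement (pseudo-inverse fallback for
ill-conditioned conditioning blocks). Mutual coordination information
through a channel site is MCI = CI(·|X_m) + CI(·|X_n) − CI(·|X_m ∪ X_n).
CI is also reported normalized as a percentage of the receiver TC — the
denominator convention is configurable, and unnormalized values are always
available. Normalized CI values are grouped low/average/high either by
exact Fisher-Jenks natural breaks (O(k n²) dynamic programming, verified
against exhaustive enumeration) or by fixed 15% / 28% thresholds.

Note that CI can be negative: conditioning on a common driver of two
otherwise-uncorrelated receivers induces conditional anti-correlation
(an interaction-information effect). The estimator is consistent — on
sampled Gaussian ensembles the CI estimate converges to the
planted-covariance value as frames grow — but near zero coupling the
error is bias-dominated and non-monotone seed by seed, which is why
convergence checks average over generator seeds.

## Synthetic study systems (`synthetic`)

All generators are seeded (identical spec ⇒ bit-identical output) and
derive per-entity substreams from (seed, entity-id), so adding a lipid or
water never perturbs existing ones. Each generator emits machine-readable
ground truth sufficient to score the downstream stage without re-deriving
it.

- **Two-state ensembles**: i.i.d. Gaussian draws (σ = 0.5 Å, a typical
  atomic fluctuation scale) around a common base geometry, with the planted
  atoms' mean displaced 3 Å in state B; 500 frames per state. This is the
  classifier's stand-in for first-vs-last-frame ensembles of a
  state-transition trajectory.
- **Coupled-site ensembles**: zero-mean Gaussian frames with an exactly
  known 3N×3N covariance (explicit matrix, block recipe, or one-factor
  shared-driver loading), the oracle for all information quantities.
- **Insertion toy**: lipid P atoms following scripted d_z paths with portal
  approach in xy, scripted per-frame water-shell occupancy, and a cation on
  a scripted distance path to the carboxyl carbon; ground-truth events are
  derived from the noise-free scripts with the same 13 Å / +2 Å rule.
- **Kinked helices**: ideal α-helix Cα traces (1.5 Å rise, 100°/residue,
  2.3 Å radius) whose axis direction changes by exactly the planted angle
  at the proline; the analytic axes are the oracle.
- **Channels**: staggered atom rings at stations along a (possibly tilted)
  axis, placed at r(z) + r_vdW from it so the true accessible radius is
  exactly r(z).

What the generators do **not** emulate: force-field energetics, periodic
images, solvent structure, anisotropic or time-correlated fluctuations,
and non-Gaussian conformational substates. Passing tests therefore
demonstrate that each estimator recovers the quantity it defines under its
own statistical assumptions — not that those assumptions hold in any
particular membrane-protein trajectory.

## Problem sizes and numerical choices

Desk-scale defaults: 100-atom / 500-frame-per-state classifier ensembles
trained 25 epochs (reduced architecture); 5,000–50,000-frame Gaussian
ensembles of 12–24 coordinates for estimator convergence; 400-frame
insertion toys; 20–30-residue helices; ~330-atom channels profiled at
0.25–0.5 Å steps. The end-to-end pipeline (`lysotraj run`) completes in a
few minutes on one CPU. Degenerate inputs fail loudly: collinear
superposition selections, single-frame covariances, non-positive-definite
planted covariances, dihedrals with collinear triples, pore starts inside
filled regions, and overlapping site definitions all raise typed errors.

## Known limitations

- The Gaussian entropy is the quasi-harmonic approximation; no
  histogram/kNN estimators and no dihedral-space variant are provided.
- The pore axis is fixed along z (the tilted-channel test shows direction
  recovery, not curved-axis tracking), and the profiler assumes a simply
  connected cavity at each station.
- The classifier is strictly two-class; image encoding assumes a stable
  atom order between frames (enforced by the trajectory container).
- Trajectory inputs are assumed whole (no periodic-boundary re-imaging)
  and topology-free (no bond perception).
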