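# lysotraj

Analysis stack for molecular-dynamics trajectories of lysolipid
transporters — membrane proteins of the major facilitator superfamily that
capture a single-tailed lipid from the outer membrane leaflet, occlude
around it, and flip it across the bilayer. Written for computational
structural biologists who have (or simulate) such trajectories and want the
full set of observables that characterize substrate capture:

- **Insertion observables** — the insertion depth d_z = z(P) − z(Cα_gate)
  of every lipid phosphorus relative to the intracellular gate residue,
  insertion-event detection (d_z ≤ 13 Å with hysteresis), lateral-portal
  pathway assignment (TM5/TM8 vs TM2/TM11), concomitance, substrate RMSD,
  sodium-bridge detection (Na⁺ ≤ 2.5 Å of the glutamate carboxyl carbon
  with the substrate P < 6 Å), and vestibule water counts (3 Å shell).
- **Occlusion geometry** — proline kink angles from helix-axis fits, and
  HOLE-style pore profiles: at each station z the radius of the largest
  sphere touching no atom, r(z) = max_center min_atoms(|c − a| − r_vdW),
  plus ensemble pore-direction divergence.
- **State classification with saliency** — each frame becomes an RGB image
  (pixel = atom, colour = min-max-normalized x, y, z), a densely-connected
  CNN (NumPy, explicit backprop) is trained to tell two conformational
  ensembles apart, and guided-backpropagation gradients attribute the
  decision back to atoms and residues; exclusion ablation quantifies a
  region's share of the signal.
- **Allosteric coupling** — Gaussian configurational entropy
  H = ½ ln|2πe C|, total correlation TC = Σ H(Xᵢ) − H(X₁…X_N),
  coordination information CI = TC − TC(·|X_m) between transmitter and
  receiver sites, mutual coordination information
  MCI = CI(·|X_m) + CI(·|X_n) − CI(·|X_m∪X_n) through candidate channels,
  and low/average/high clustering of normalized CI (exact Fisher-Jenks, or
  fixed 15%/28% thresholds).
- **Synthetic study systems** — seeded generators with exact ground truth
  (planted-shift ensembles, planted-covariance Gaussians, scripted
  insertion toys, ideal kinked helices, known-radius channels) so every
  stage is verifiable at desk scale without microsecond MD.

Structures are read from PDB, trajectories from DCD/XTC/CSV (MDAnalysis
underneath); selections use the MDAnalysis grammar.

## Worked example

```sh
python analysis/01_generate_synthetic.py --seed 0   # study systems + ground truth
python analysis/02_insertion_observables.py --seed 0
python analysis/05_pore_and_kink.py --seed 0
```

The observables driver prints (seed 0):

```
Detected 2 insertion events ({'TM5/TM8': 1, 'TM2/TM11': 1}), 2 concomitant;
vestibule hydration drops from 3.0 to 2.0 waters after insertion; P stays
<6 A of the carboxyl carbon in 100% of Na-bound frames.
```

i.e. the detector recovered exactly the two scripted crossings — one full
insertion through the TM5/TM8 portal, one partial through TM2/TM11,
overlapping in time (concomitant) — the third lipid that grazes 13.5 Å is
correctly not counted, hydration of the vestibule shell drops when the
substrate inserts, and every frame with a bound Na⁺ also holds the
headgroup phosphorus at the coordinating glutamate. The pore/kink driver
prints:

```
Cylinder radius recovered within 0.025 A; hourglass constriction found at
z = 0.00 A (planted 0) with radius 2.00 A (planted 2); the tilted
channel's pore direction diverges from the straight one by 10.00 deg
(planted 10). Kink angles recovered: 0 -> 0.00, 30 -> 30.00, 34 -> 34.00 deg.
```

`analysis/03_state_classifier.py` trains the reduced network on the
planted-shift ensembles (test accuracy 1.000 at seed 0; excluding the
planted five atoms collapses it to 0.485 ≈ chance), and
`analysis/04_allosteric_coupling.py` reports that the planted transmitter
explains ~75% of the receiver total correlation ("high") versus ~0.1% for
the uncoupled control ("low"), with the coupled site ranked first in the
MCI channel scan.

The same stages run end-to-end from one config via the CLI:

```sh
lysotraj run --out runs/demo --seed 0          # writes summary.json + summary.txt
lysotraj synth --kind kinked_helix --out tmp/  # standalone generators
lysotraj report --run-dir runs/demo
```

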