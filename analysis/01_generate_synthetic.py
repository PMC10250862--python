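#!/usr/bin/env python
"""Generate the synthetic study systems used by every downstream analysis.

Writes, under results/synthetic/: the insertion toy (structure + CSV
trajectory + ground truth), the two-state ensembles for the classifier, a
straight and a 34-degree kinked helix, and a cylindrical channel — each with
its machine-readable ground truth. These are the desk-scale stand-ins for
the microsecond membrane-transporter trajectories the full analysis was
designed around.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from lysotraj import synthetic as syn
from lysotraj.trajectory import write_structure, write_trajectory

def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    # insertion toy: three scripted lipids, two portals, waters, one Na+
    F = 400
    t = np.arange(F)
    spec = syn.SyntheticSpec(
        kind="insertion_toy", n_frames=F, seed=args.seed,
        params={
            "lipids": [
                {"dz_path": np.interp(t, [0, 120, 200, F - 1],
                                      [20.0, 20.0, 5.0, 5.0]),
                 "portal": "TM5/TM8"},
                {"dz_path": np.interp(t, [0, 160, 240, 320, F - 1],
                                      [21.0, 21.0, 11.0, 11.0, 20.0]),
                 "portal": "TM2/TM11"},
                {"dz_path": np.interp(t, [0, 200, F - 1], [22.0, 13.5, 22.0]),
                 "portal": "TM5/TM8"},
            ],
            "jitter_sigma": 0.0,
            "n_shell_waters": np.where(t < 200, 3, 2),
            "n_far_waters": 2,
            "na_distance_path": np.interp(t, [0, 180, 200, F - 1],
                                          [10.0, 10.0, 2.3, 2.3]),
        })
    ref, traj, gt = syn.make_insertion_toy(spec)
    write_structure(ref, out / "toy_structure.pdb")
    write_trajectory(traj, out / "toy_trajectory.csv", "CSV")
    syn.write_ground_truth(gt, out / "toy_ground_truth.json")
    print(f"insertion toy: {traj.n_frames} frames, {traj.n_atoms} atoms, "
          f"{gt['n_events']} scripted insertion events")

    # two-state ensembles (planted local shift) for the classifier
    two = syn.SyntheticSpec(
        kind="two_state", n_atoms=100, n_frames=500, seed=args.seed + 1,
        params={"planted_atoms": list(range(40, 45)),
                "shift_magnitude": 3.0, "noise_sigma": 0.5})
    ta, tb, gt2 = syn.make_two_state_ensemble(two)
    write_structure(ta.reference, out / "two_state_reference.pdb")
    syn.write_ground_truth(gt2, out / "two_state_ground_truth.json")
    print(f"two-state ensembles: {ta.n_frames}+{tb.n_frames} frames, "
          f"planted atoms {list(gt2['planted_atoms'])}")

    # helices and channel for the geometry stages
    for ang in (0.0, 34.0):
        helix, gth = syn.make_kinked_helix(
            syn.SyntheticSpec(kind="kinked_helix", seed=args.seed,
                              params={"kink_angle": ang}))
        write_structure(helix, out / f"helix_kink{ang:g}.pdb")
    stations = np.arange(-10.0, 10.5, 1.0)
    chan, gtc = syn.make_channel_system(
        syn.SyntheticSpec(kind="channel", seed=args.seed,
                          params={"stations": stations,
                                  "radius_profile": np.full(len(stations), 5.0)}))
    write_structure(chan, out / "channel_r5.pdb")
    syn.write_ground_truth({k: gtc[k] for k in ("stations", "radius_profile",
                                                "tilt_deg")},
                           out / "channel_ground_truth.json")
    print(f"helix fixtures (0/34 deg) and cylindrical channel written to {out}")


if __name__ == "__main__":
    main()
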