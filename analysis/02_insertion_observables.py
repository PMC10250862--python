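#!/usr/bin/env python
"""Insertion observables on the scripted toy trajectory.

Computes per-lipid d_z series, detects insertion events (d_z <= 13 A) with
portal assignment and concomitance, counts vestibule waters (3 A sidechain
shell), and evaluates the sodium-bridge criterion (Na+ <= 2.5 A of the
carboxyl carbon with the substrate P < 6 A). Writes CSV tables under
results/observables/ and prints what it found against the generator's
ground truth.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from lysotraj import geometry as geo
from lysotraj import synthetic as syn
from lysotraj.trajectory import Selection


def standard_toy(seed):
    F = 400
    t = np.arange(F)
    spec = syn.SyntheticSpec(
        kind="insertion_toy", n_frames=F, seed=seed,
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
    return syn.make_insertion_toy(spec)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/observables"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    ref, traj, gt = standard_toy(args.seed)
    lipids = Selection.from_indices(gt["lipid_atom_indices"])
    gate = Selection.from_indices([gt["ref_atom_index"]])

    dz = geo.dz_series(traj, lipids, gate)
    pd.DataFrame({f"lipid_{i}": s.values for i, s in enumerate(dz)}
                 ).to_csv(out / "dz_series.csv", index_label="frame")

    events = geo.detect_insertions(
        traj, dz, {"TM5/TM8": Selection.from_indices([2, 3]),
                   "TM2/TM11": Selection.from_indices([4, 5])})
    rows = [{"lipid": e.lipid_id, "entry_frame": e.entry_frame,
             "exit_frame": e.exit_frame, "pathway": e.pathway,
             "min_dz_A": e.min_dz, "concomitant": e.concomitant}
            for e in events]
    pd.DataFrame(rows).to_csv(out / "insertion_events.csv", index=False)

    waters = geo.count_vestibule_waters(
        traj, Selection.from_indices(gt["water_atom_indices"]),
        Selection.from_indices(gt["shell_atom_indices"]))
    series, bridge = geo.na_bridge_series(
        traj, Selection.from_indices([gt["carboxyl_atom_index"]]),
        Selection.from_indices([gt["na_atom_index"]]), lipids)
    pd.DataFrame({"waters": waters.values,
                  "na_distance_A": series["na_distance"].values,
                  "bridge": series["bridge"].values}
                 ).to_csv(out / "waters_and_bridge.csv", index_label="frame")

    hist = geo.histogram(geo.min_dz_series(dz).values, bin_width=0.5)
    pd.DataFrame({"bin_left": hist.bin_edges[:-1],
                  "count": hist.counts}).to_csv(out / "min_dz_histogram.csv",
                                                index=False)

    per_pathway = {}
    for e in events:
        per_pathway[e.pathway] = per_pathway.get(e.pathway, 0) + 1
    summary = {
        "n_events": len(events),
        "events_per_pathway": per_pathway,
        "n_concomitant": sum(e.concomitant for e in events),
        "matches_ground_truth": len(events) == gt["n_events"],
        "water_mean_before_insertion": float(waters.values[:200].mean()),
        "water_mean_after_insertion": float(waters.values[200:].mean()),
        "bridge_fraction": bridge["bridge_fraction"],
        "conditional_P_below_6A_given_Na_below_2.5A":
            bridge["conditional_p_given_na"],
        "min_dz_histogram_peaks_A": hist.peaks[:3].tolist(),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    print(json.dumps(summary, indent=1))
    print(f"\nDetected {len(events)} insertion events "
          f"({per_pathway}), {summary['n_concomitant']} concomitant; "
          f"vestibule hydration drops from "
          f"{summary['water_mean_before_insertion']:.1f} to "
          f"{summary['water_mean_after_insertion']:.1f} waters after insertion; "
          f"P stays <6 A of the carboxyl carbon in "
          f"{100 * summary['conditional_P_below_6A_given_Na_below_2.5A']:.0f}% "
          f"of Na-bound frames.")


if __name__ == "__main__":
    main()
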