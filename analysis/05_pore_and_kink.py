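#!/usr/bin/env python
"""Pore profiling and proline-kink analysis on constructed systems.

Profiles a straight and a 10-degree-tilted cylindrical channel plus an
hourglass channel (largest-sphere radius at 0.5 A stations along +z),
compares ensemble pore directions, and recovers planted helix kink angles
(0/30/34 degrees). Writes profile CSVs under results/pore_kink/ and prints
the recovered numbers next to the planted ones.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from lysotraj import helix_metrics as hm
from lysotraj import synthetic as syn


def channel(radius_profile, stations, seed, **params):
    p = {"stations": stations, "radius_profile": radius_profile}
    p.update(params)
    return syn.make_channel_system(
        syn.SyntheticSpec(kind="channel", seed=seed, params=p))[0]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/pore_kink"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    stations = np.arange(-10.0, 10.5, 1.0)
    flat = np.full(len(stations), 5.0)
    hour = 5.0 - 3.0 * np.exp(-stations ** 2 / 8.0)

    profiles = {}
    for name, chan, start in (
            ("cylinder", channel(flat, stations, args.seed), (0, 0, 0)),
            ("hourglass", channel(hour, stations, args.seed), (0, 0, -5.0)),
            ("tilted10", channel(flat, stations, args.seed, tilt_deg=10.0),
             (0, 0, 0))):
        prof = hm.pore_profile(chan, start, seed=args.seed, step=0.5)
        profiles[name] = prof
        pd.DataFrame({"z": prof.z, "radius_A": prof.radius,
                      "cx": prof.centers[:, 0], "cy": prof.centers[:, 1]}
                     ).to_csv(out / f"profile_{name}.csv", index=False)

    d0 = hm.pore_direction([profiles["cylinder"]], (-8, 8))
    dt = hm.pore_direction([profiles["tilted10"]], (-6, 6))
    divergence = hm.pore_divergence(d0, dt)
    rmin, zmin = profiles["hourglass"].min_radius()

    kinks = {}
    for ang in (0.0, 30.0, 34.0):
        m, gt = syn.make_kinked_helix(
            syn.SyntheticSpec(kind="kinked_helix", seed=args.seed,
                              params={"kink_angle": ang}))
        kinks[f"{ang:g}"] = hm.kink_angle(m.coords, m.resids, gt["kink_resid"])

    inside = (profiles["cylinder"].z >= -10) & (profiles["cylinder"].z <= 10)
    summary = {
        "cylinder_max_radius_error_A": float(
            np.abs(profiles["cylinder"].radius[inside] - 5.0).max()),
        "hourglass_min_radius_A": rmin,
        "hourglass_constriction_z_A": zmin,
        "pore_direction_divergence_deg": divergence,
        "kink_recovered_deg": kinks,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    print(json.dumps(summary, indent=1))
    print(f"\nCylinder radius recovered within "
          f"{summary['cylinder_max_radius_error_A']:.3f} A; hourglass "
          f"constriction found at z = {zmin:.2f} A (planted 0) with radius "
          f"{rmin:.2f} A (planted 2); the tilted channel's pore direction "
          f"diverges from the straight one by {divergence:.2f} deg "
          f"(planted 10). Kink angles recovered: "
          + ", ".join(f"{k} -> {v:.2f}" for k, v in kinks.items()) + " deg.")


if __name__ == "__main__":
    main()
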