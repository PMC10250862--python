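#!/usr/bin/env python
"""Information-theoretic allosteric coupling on planted Gaussian ensembles.

Samples a Gaussian trajectory whose covariance plants a transmitter site
driving two receiver sites (one uncoupled control site), estimates the
covariance, and computes configurational entropies, total correlation,
coordination information (raw and as % of receiver TC) and mutual
coordination information through candidate channels. Normalized CI values
are labelled low/average/high by Fisher-Jenks breaks and by the fixed
15%/28% thresholds. Writes results/nbit/ci_table.csv and prints the table.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from lysotraj import nbit
from lysotraj import synthetic as syn
from lysotraj.trajectory import Selection


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--frames", type=int, default=20_000)
    ap.add_argument("--out", type=Path, default=Path("results/nbit"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    # sites: 0 = transmitter; 1, 2 = coupled receivers; 3 = uncoupled control.
    # One latent factor loads on sites 0-2 (shared-driver coupling); the
    # control site carries independent noise only.
    d = 6  # coordinates per 2-atom site
    load = np.zeros(4 * d)
    load[:3 * d] = 0.7
    C = np.outer(load, load) + np.eye(4 * d)
    spec = syn.SyntheticSpec(kind="coupled_sites", n_frames=args.frames,
                             seed=args.seed, params={"covariance": C})
    traj, C_true = syn.make_coupled_site_ensemble(spec)
    cov = nbit.covariance(traj, Selection.from_indices(range(traj.n_atoms)))

    sites = {name: list(range(i * d, (i + 1) * d))
             for i, name in enumerate(["T_s", "R_a", "R_b", "control"])}
    receivers = [sites["R_a"], sites["R_b"]]

    rows = []
    for cond_name in ("T_s", "control"):
        for M, label in ((cov.C, "estimated"), (C_true, "planted")):
            ci, pct = nbit.coordination_information(
                M, receivers, sites[cond_name], normalized=True)
            rows.append({"conditioning_site": cond_name, "covariance": label,
                         "CI_nats": ci, "CI_pct_of_receiver_TC": pct})
    table = pd.DataFrame(rows)

    est = table[table.covariance == "estimated"]
    pcts = est["CI_pct_of_receiver_TC"].to_numpy()
    _, jenks_labels = nbit.fisher_jenks(
        np.concatenate([pcts, [50.0]]), k=3)   # high anchor for 3 classes
    table_est = est.assign(
        threshold_label=nbit.fixed_threshold_labels(pcts))

    # receiver partitioned per atom (3 coords each): the total correlation of
    # a single undivided block is identically zero
    r_a_atoms = [sites["R_a"][:3], sites["R_a"][3:]]
    mci = nbit.mci_channel_scan(
        cov.C, r_a_atoms, np.array(sites["T_s"]),
        {"R_b": np.array(sites["R_b"]),
         "control": np.array(sites["control"])})

    table.to_csv(out / "ci_table.csv", index=False)
    pd.DataFrame(mci, columns=["channel", "MCI_nats"]
                 ).to_csv(out / "mci_channel_scan.csv", index=False)
    summary = {
        "frames": args.frames,
        "ci_Ts_pct": float(est[est.conditioning_site == "T_s"]
                           ["CI_pct_of_receiver_TC"].iloc[0]),
        "ci_control_pct": float(est[est.conditioning_site == "control"]
                                ["CI_pct_of_receiver_TC"].iloc[0]),
        "threshold_labels": dict(zip(est.conditioning_site,
                                     table_est.threshold_label)),
        "mci_ranking": [m[0] for m in mci],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    print(table.to_string(index=False))
    print()
    print(pd.DataFrame(mci, columns=["channel", "MCI_nats"]).to_string(index=False))
    print(f"\nThe transmitter explains {summary['ci_Ts_pct']:.1f}% of the "
          f"receiver total correlation ({summary['threshold_labels']['T_s']}); "
          f"the uncoupled control explains {summary['ci_control_pct']:.1f}% "
          f"({summary['threshold_labels']['control']}). The coupled site "
          f"outranks the control as a communication channel: "
          f"{summary['mci_ranking']}.")


if __name__ == "__main__":
    main()
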