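"""End-to-end orchestration: synthetic data -> observables -> ensembles ->
classifier + saliency -> information-theoretic allostery -> pore/kink.

A :class:`RunConfig` (YAML round-trippable) declares the synthetic study
conditions, stage toggles, thresholds and seeds; :func:`run` executes the
enabled stages in dependency order, writes per-stage artifacts under the
output directory and collates the headline quantities into a summary
report (JSON + plain text). Stochastic stages are seeded, so re-running an
identical config reproduces the summary byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classifier as clf
from . import geometry as geo
from . import helix_metrics as hm
from . import nbit
from . import synthetic as syn
from .trajectory import Selection, Trajectory

__all__ = ["RunConfig", "ValidationError", "DependencyError",
           "split_ensembles", "run"]


class ValidationError(ValueError):
    """Invalid configuration or inputs (CLI exit code 2)."""


class DependencyError(RuntimeError):
    """A stage needs an artifact from a disabled stage (CLI exit code 3)."""


DEFAULT_STAGES = ("synth", "observables", "split", "classify", "nbit",
                  "pore", "kink")


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in DEFAULT_STAGES})
    # study conditions for the synthetic stages
    n_frames_toy: int = 400
    n_atoms_two_state: int = 100
    frames_per_state: int = 500
    planted_atoms: tuple = (40, 41, 42, 43, 44)
    shift_magnitude: float = 3.0
    noise_sigma: float = 0.5
    epochs: int = 40
    classifier_scale: str = "reduced"
    nbit_frames: int = 20000
    kink_angles: tuple = (0.0, 30.0, 34.0)
    channel_radius: float = 5.0
    # thresholds (defaults are the analysis conventions)
    dz_threshold: float = geo.DZ_INSERTION_THRESHOLD
    na_cut: float = geo.NA_BRIDGE_CUT
    p_cut: float = geo.P_BRIDGE_CUT
    water_cut: float = geo.WATER_SHELL_CUT
    saliency_cutoff: float = clf.SALIENCY_CUTOFF
    ci_low: float = nbit.CI_LOW_THRESHOLD
    ci_high: float = nbit.CI_HIGH_THRESHOLD

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path):
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("planted_atoms", "kink_angles"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def split_ensembles(traj: Trajectory, rule: dict):
    """Split a trajectory into two labelled ensembles.

    rule: ``{"first_n": n, "last_n": m}`` or
    ``{"range_a": [a0, a1), "range_b": [b0, b1)}``; the two ranges must lie
    within the trajectory and must not overlap.
    """
    F = traj.n_frames
    if "first_n" in rule or "last_n" in rule:
        n = int(rule.get("first_n", 0))
        m = int(rule.get("last_n", 0))
        ra, rb = (0, n), (F - m, F)
    else:
        ra = tuple(int(v) for v in rule["range_a"])
        rb = tuple(int(v) for v in rule["range_b"])
    for lo, hi in (ra, rb):
        if not (0 <= lo < hi <= F):
            raise ValidationError(
                f"range [{lo}, {hi}) outside trajectory of {F} frames")
    if ra[0] < rb[1] and rb[0] < ra[1]:
        raise ValidationError(f"ranges {ra} and {rb} overlap")
    a = Trajectory(traj.reference, traj.frames[ra[0]:ra[1]].copy(),
                   traj.frame_stride_ps)
    b = Trajectory(traj.reference, traj.frames[rb[0]:rb[1]].copy(),
                   traj.frame_stride_ps)
    return a, b


def _scripted_toy(cfg: RunConfig):
    """The standard insertion-toy study conditions: three lipids, two portals."""
    F = cfg.n_frames_toy
    t = np.arange(F)
    # lipid 0: full insertion via TM5/TM8 (bulk ~20 A down to ~5 A)
    path0 = np.interp(t, [0, F * 0.3, F * 0.5, F - 1], [20.0, 20.0, 5.0, 5.0])
    # lipid 1: concomitant insertion via TM2/TM11, partial (down to ~11 A)
    path1 = np.interp(t, [0, F * 0.4, F * 0.6, F * 0.8, F - 1],
                      [21.0, 21.0, 11.0, 11.0, 20.0])
    # lipid 2: grazes the threshold without crossing
    path2 = np.interp(t, [0, F * 0.5, F - 1], [22.0, 13.5, 22.0])
    waters = np.where(t < F * 0.5, 3, 2)  # partial dehydration after insertion
    na = np.interp(t, [0, F * 0.45, F * 0.5, F - 1], [10.0, 10.0, 2.3, 2.3])
    spec = syn.SyntheticSpec(
        kind="insertion_toy", n_frames=F, seed=cfg.seed,
        params={
            "lipids": [
                {"dz_path": path0, "portal": "TM5/TM8"},
                {"dz_path": path1, "portal": "TM2/TM11"},
                {"dz_path": path2, "portal": "TM5/TM8"},
            ],
            "jitter_sigma": 0.0,
            "n_shell_waters": waters,
            "n_far_waters": 2,
            "na_distance_path": na,
            "threshold": cfg.dz_threshold,
        })
    return syn.make_insertion_toy(spec)


def run(config: RunConfig, outdir) -> dict:
    """Execute the enabled stages in dependency order; return the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    stages = {s: bool(config.stages.get(s, False)) for s in DEFAULT_STAGES}
    summary: dict = {"seed": config.seed, "stages": stages}

    def need(stage, because):
        if not stages.get(stage):
            raise DependencyError(
                f"stage {because!r} requires disabled stage {stage!r}")

    artifacts = {}

    if stages["synth"]:
        ref, toy_traj, toy_gt = _scripted_toy(config)
        artifacts["toy"] = (ref, toy_traj, toy_gt)
        two_spec = syn.SyntheticSpec(
            kind="two_state", n_atoms=config.n_atoms_two_state,
            n_frames=config.frames_per_state, seed=config.seed + 1,
            params={"planted_atoms": list(config.planted_atoms),
                    "shift_magnitude": config.shift_magnitude,
                    "noise_sigma": config.noise_sigma})
        ta, tb, two_gt = syn.make_two_state_ensemble(two_spec)
        artifacts["two_state"] = (ta, tb, two_gt)
        syn.write_ground_truth(toy_gt, outdir / "toy_ground_truth.json")
        syn.write_ground_truth(two_gt, outdir / "two_state_ground_truth.json")

    if stages["observables"]:
        need("synth", "observables")
        ref, toy, gt = artifacts["toy"]
        lipid_sel = Selection.from_indices(gt["lipid_atom_indices"], "lipid P")
        ref_sel = Selection.from_indices([gt["ref_atom_index"]], "gate CA")
        dz = geo.dz_series(toy, lipid_sel, ref_sel)
        portals = {
            "TM5/TM8": Selection.from_indices([2, 3], "portal 5/8"),
            "TM2/TM11": Selection.from_indices([4, 5], "portal 2/11"),
        }
        events = geo.detect_insertions(toy, dz, portals,
                                       threshold=config.dz_threshold)
        waters = geo.count_vestibule_waters(
            toy, Selection.from_indices(gt["water_atom_indices"], "waters"),
            Selection.from_indices(gt["shell_atom_indices"], "shell"),
            cutoff=config.water_cut)
        bridge_series, bridge = geo.na_bridge_series(
            toy, Selection.from_indices([gt["carboxyl_atom_index"]], "E312 CD"),
            Selection.from_indices([gt["na_atom_index"]], "Na+"),
            lipid_sel, na_cut=config.na_cut, p_cut=config.p_cut)
        pathways = {}
        for ev in events:
            pathways[ev.pathway] = pathways.get(ev.pathway, 0) + 1
        summary["observables"] = {
            "n_insertion_events": len(events),
            "events_per_pathway": pathways,
            "n_concomitant": sum(e.concomitant for e in events),
            "ground_truth_events": gt["n_events"],
            "water_count_mean_before": float(waters.values[:len(waters) // 2].mean()),
            "water_count_mean_after": float(waters.values[len(waters) // 2:].mean()),
            "bridge_fraction": bridge["bridge_fraction"],
            "conditional_p_given_na": bridge["conditional_p_given_na"],
        }
        _write_series_csv(outdir / "observables.csv",
                          {"min_dz": geo.min_dz_series(dz).values,
                           "waters": waters.values,
                           "bridge": bridge_series["bridge"].values})

    if stages["split"] or stages["classify"]:
        need("synth", "split/classify")
        ta, tb, two_gt = artifacts["two_state"]
        # mirror the first-n/last-n ensemble extraction on one long trajectory
        combined = Trajectory(ta.reference,
                              np.concatenate([ta.frames, tb.frames]))
        ens_a, ens_b = split_ensembles(
            combined, {"first_n": ta.n_frames, "last_n": tb.n_frames})
        artifacts["ensembles"] = (ens_a, ens_b)
        summary["split"] = {"n_a": ens_a.n_frames, "n_b": ens_b.n_frames}

    if stages["classify"]:
        ens_a, ens_b = artifacts["ensembles"]
        all_atoms = Selection.from_indices(
            np.arange(ens_a.n_atoms), "all atoms")
        pooled = Trajectory(ens_a.reference,
                            np.concatenate([ens_a.frames, ens_b.frames]))
        _, info = clf.encode_frames(pooled, all_atoms)
        imgs_a, _ = clf.encode_frames(ens_a, all_atoms, bounds=info.bounds)
        imgs_b, _ = clf.encode_frames(ens_b, all_atoms, bounds=info.bounds)
        model, report = clf.train_classifier(
            imgs_a, imgs_b, epochs=config.epochs, seed=config.seed,
            scale=config.classifier_scale, class_labels=("A", "B"))
        sal = clf.saliency(model, imgs_b, class_index=1)
        ranked, above = clf.rank_residues(sal, ens_a.reference,
                                          cutoff=config.saliency_cutoff)
        planted = np.asarray(artifacts["two_state"][2]["planted_atoms"])
        mask = np.zeros(info.n_atoms, dtype=bool)
        mask[planted] = True
        summary["classifier"] = {
            "overall_accuracy": report["overall_accuracy"],
            "per_class_accuracy": report["per_class_accuracy"],
            "final_val_loss": report["curves"]["val_loss"][-1],
            "top_residues": [r[0] for r in ranked[:5]],
            "n_atoms_above_cutoff": len(above),
            "saliency_planted_mean": float(sal.atom_values[mask].mean()),
            "saliency_other_mean": float(sal.atom_values[~mask].mean()),
        }

    if stages["nbit"]:
        # one latent factor drives sites 0-2; site 3 is independent noise
        d_site = 6
        load = np.zeros(4 * d_site)
        load[:3 * d_site] = 0.7
        C_plant = np.outer(load, load) + np.eye(4 * d_site)
        cov_spec = syn.SyntheticSpec(
            kind="coupled_sites", n_frames=config.nbit_frames,
            seed=config.seed + 2, params={"covariance": C_plant})
        traj_c, C_true = syn.make_coupled_site_ensemble(cov_spec)
        sel = Selection.from_indices(np.arange(traj_c.n_atoms), "all")
        cov = nbit.covariance(traj_c, sel)
        d = 6  # coordinates per 2-atom site
        rec = [np.arange(d) + d, np.arange(d) + 2 * d]   # sites 1 and 2
        trans = np.arange(d)                              # site 0 drives both
        indep = np.arange(d) + 3 * d                      # site 3: uncoupled
        ci_t, ci_pct = nbit.coordination_information(cov.C, rec, trans,
                                                     normalized=True)
        ci_i = nbit.coordination_information(cov.C, rec, indep)
        # per-atom receiver partition: a single undivided block has TC = 0
        rec0_atoms = [rec[0][:3], rec[0][3:]]
        mci = nbit.mutual_coordination_information(cov.C, rec0_atoms, trans,
                                                   rec[1])
        scan = nbit.mci_channel_scan(
            cov.C, rec0_atoms, trans,
            {"site2": rec[1], "site3": indep})
        ci_true = nbit.coordination_information(C_true, rec, trans)
        labels = nbit.fixed_threshold_labels(
            [ci_pct], low=config.ci_low, high=config.ci_high)
        summary["nbit"] = {
            "ci_transmitter_nats": ci_t,
            "ci_transmitter_pct": ci_pct,
            "ci_transmitter_true_nats": float(ci_true),
            "ci_independent_nats": float(ci_i),
            "mci_via_coupled_site": float(mci),
            "channel_scan_top": scan[0][0],
            "ci_cluster_label": labels[0],
        }

    if stages["kink"]:
        kres = {}
        for ang in config.kink_angles:
            spec = syn.SyntheticSpec(kind="kinked_helix", seed=config.seed,
                                     params={"kink_angle": float(ang),
                                             "n_pre": 14, "n_post": 14})
            model_h, gt_h = syn.make_kinked_helix(spec)
            rec = hm.kink_angle(model_h.coords, model_h.resids,
                                gt_h["kink_resid"])
            kres[f"{ang:g}"] = {"planted": float(ang), "recovered": rec,
                                "error": abs(rec - float(ang))}
        summary["kink"] = kres

    if stages["pore"]:
        stations = np.arange(-10.0, 10.5, 1.0)
        spec = syn.SyntheticSpec(
            kind="channel", seed=config.seed,
            params={"stations": stations,
                    "radius_profile": np.full(len(stations),
                                              config.channel_radius)})
        chan, gt_c = syn.make_channel_system(spec)
        prof = hm.pore_profile(chan, start_point=(0.0, 0.0, 0.0),
                               seed=config.seed, step=0.5)
        inside = (prof.z > -9) & (prof.z < 9)
        err = np.abs(prof.radius[inside] - config.channel_radius).max()
        spec_t = syn.SyntheticSpec(
            kind="channel", seed=config.seed,
            params={"stations": stations,
                    "radius_profile": np.full(len(stations),
                                              config.channel_radius),
                    "tilt_deg": 10.0})
        chan_t, _ = syn.make_channel_system(spec_t)
        prof_t = hm.pore_profile(chan_t, start_point=(0.0, 0.0, 0.0),
                                 seed=config.seed, step=0.5)
        d0 = hm.pore_direction([prof], (-8.0, 8.0))
        dt = hm.pore_direction([prof_t], (-6.0, 6.0))
        summary["pore"] = {
            "cylinder_max_radius_error": float(err),
            "self_divergence_deg": hm.pore_divergence(d0, d0),
            "tilt_recovered_deg": hm.pore_divergence(
                d0, dt),
        }

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                    sort_keys=True))
    (outdir / "summary.txt").write_text(_render_summary(summary))
    return summary


def _write_series_csv(path, columns: dict):
    import pandas as pd

    pd.DataFrame(columns).to_csv(path, index_label="frame")


def _render_summary(summary: dict) -> str:
    lines = [f"pipeline summary (seed {summary['seed']})", ""]
    for key, val in summary.items():
        if key in ("seed", "stages"):
            continue
        lines.append(f"[{key}]")
        if isinstance(val, dict):
            for k, v in val.items():
                lines.append(f"  {k}: {v}")
        else:
            lines.append(f"  {val}")
        lines.append("")
    return "\n".join(lines)
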