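"""Shared fixtures: synthetic study systems and (expensive) trained models.

Session-scoped so the classifier is trained once and reused by the unit and
acceptance tests.
"""

import numpy as np
import pytest

from lysotraj import classifier as clf
from lysotraj import synthetic as syn
from lysotraj.trajectory import Selection, Trajectory

N_ATOMS = 100
PLANTED = tuple(range(40, 45))
SHIFT = 3.0
NOISE_SIGMA = 0.5
FRAMES_PER_STATE = 500
EPOCHS = 25
GEN_SEED = 7
TRAIN_SEED = 0


def build_two_state(shift, gen_seed=GEN_SEED):
    spec = syn.SyntheticSpec(
        kind="two_state", n_atoms=N_ATOMS, n_frames=FRAMES_PER_STATE,
        seed=gen_seed,
        params={"planted_atoms": list(PLANTED), "shift_magnitude": shift,
                "noise_sigma": NOISE_SIGMA})
    return syn.make_two_state_ensemble(spec)


def encode_pair(ta, tb):
    sel = Selection.from_indices(np.arange(ta.n_atoms))
    pooled = Trajectory(ta.reference, np.concatenate([ta.frames, tb.frames]))
    _, info = clf.encode_frames(pooled, sel)
    imgs_a, _ = clf.encode_frames(ta, sel, bounds=info.bounds)
    imgs_b, _ = clf.encode_frames(tb, sel, bounds=info.bounds)
    return imgs_a, imgs_b, info


@pytest.fixture(scope="session")
def two_state_images():
    ta, tb, gt = build_two_state(SHIFT)
    imgs_a, imgs_b, info = encode_pair(ta, tb)
    return {"images_a": imgs_a, "images_b": imgs_b, "info": info,
            "ground_truth": gt, "reference": ta.reference}


@pytest.fixture(scope="session")
def trained_model(two_state_images):
    model, report = clf.train_classifier(
        two_state_images["images_a"], two_state_images["images_b"],
        epochs=EPOCHS, seed=TRAIN_SEED)
    return model, report


@pytest.fixture(scope="session")
def zero_shift_report():
    ta, tb, _ = build_two_state(0.0)
    imgs_a, imgs_b, _ = encode_pair(ta, tb)
    _, report = clf.train_classifier(imgs_a, imgs_b, epochs=EPOCHS,
                                     seed=TRAIN_SEED)
    return report


@pytest.fixture(scope="session")
def ablation_result(two_state_images, trained_model):
    _, baseline = trained_model
    result, _ = clf.exclusion_ablation(
        two_state_images["images_a"], two_state_images["images_b"],
        Selection.from_indices(PLANTED), baseline_report=baseline,
        epochs=EPOCHS, seed=TRAIN_SEED)
    return result


@pytest.fixture(scope="session")
def class_saliency(two_state_images, trained_model):
    model, _ = trained_model
    return clf.saliency(model, two_state_images["images_b"], class_index=1)


def scripted_toy(seed=0, n_frames=400):
    """Three scripted lipids: full insertion via TM5/TM8, concomitant partial
    insertion via TM2/TM11, and one that grazes the threshold."""
    t = np.arange(n_frames)
    F = n_frames
    path0 = np.interp(t, [0, F * 0.3, F * 0.5, F - 1], [20.0, 20.0, 5.0, 5.0])
    path1 = np.interp(t, [0, F * 0.4, F * 0.6, F * 0.8, F - 1],
                      [21.0, 21.0, 11.0, 11.0, 20.0])
    path2 = np.interp(t, [0, F * 0.5, F - 1], [22.0, 13.5, 22.0])
    waters = np.where(t < F * 0.5, 3, 2)
    na = np.interp(t, [0, F * 0.45, F * 0.5, F - 1], [10.0, 10.0, 2.3, 2.3])
    spec = syn.SyntheticSpec(
        kind="insertion_toy", n_frames=F, seed=seed,
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
        })
    return syn.make_insertion_toy(spec)


@pytest.fixture(scope="session")
def insertion_toy():
    ref, traj, gt = scripted_toy()
    return {"reference": ref, "trajectory": traj, "ground_truth": gt}
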