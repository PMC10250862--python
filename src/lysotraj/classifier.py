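"""Frame-to-image encoding, state classification and saliency attribution.

Each trajectory frame is encoded as a small RGB image in which pixel k
represents atom k of the encoded selection (sequential order, top-left to
bottom-right) and the R, G, B channels carry the atom's x, y, z coordinates
min-max-normalized over the pooled training set and quantized to 8 bits.
A densely-connected CNN is trained to tell two conformational ensembles
apart; guided-backpropagation gradients of the class score, aggregated per
pixel and averaged over a class's images, attribute the decision back to
atoms and residues. Ablation re-training with a region's pixels zeroed
quantifies how much of the classification signal that region carries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import AdamOptimizer, DenseNetLite, softmax_cross_entropy
from .trajectory import Selection, StructureModel, Trajectory

__all__ = [
    "FrameImage",
    "EncodingInfo",
    "ClassifierModel",
    "SaliencyMap",
    "image_shape_for",
    "encode_frames",
    "decode_frame",
    "train_classifier",
    "saliency",
    "rank_residues",
    "exclusion_ablation",
    "SALIENCY_CUTOFF",
]

SALIENCY_CUTOFF = 0.6   # normalized gradient above which an atom is "salient"


def image_shape_for(n_atoms: int) -> tuple[int, int]:
    """Smallest near-square H x W with H*W >= n_atoms (H >= W, minimal |H-W|)."""
    h = int(np.ceil(np.sqrt(n_atoms)))
    w = int(np.ceil(n_atoms / h))
    return h, w


@dataclass
class EncodingInfo:
    """Everything needed to decode images and map pixels back to atoms."""

    atom_indices: np.ndarray      # encoded atoms, pixel order
    shape: tuple                  # (H, W)
    bounds: np.ndarray            # (3, 2) per-axis (min, max) in A
    pad_mask: np.ndarray          # (H*W,) True where pixel is padding
    clipped: int = 0              # coordinates clipped to the bounds

    @property
    def n_atoms(self):
        return len(self.atom_indices)


@dataclass
class FrameImage:
    pixels: np.ndarray            # (H, W, 3) uint8
    info: EncodingInfo


@dataclass
class SaliencyMap:
    pixel_values: np.ndarray      # (H, W) in [0, 1]; pad pixels exactly 0
    atom_values: np.ndarray       # (n_atoms,) in [0, 1]
    class_label: int
    n_averaged: int
    info: EncodingInfo


@dataclass
class ClassifierModel:
    net: DenseNetLite
    class_labels: tuple
    info: EncodingInfo
    training_meta: dict = field(default_factory=dict)


def encode_frames(traj: Trajectory, selection: Selection,
                  bounds=None) -> tuple[list[FrameImage], EncodingInfo]:
    """Encode every frame of `traj` as an RGB coordinate image.

    `bounds` is either None (auto: per-axis min/max over all frames of the
    encoded atoms — compute it over the pooled training set and reuse it at
    inference) or a (3, 2) array; out-of-bounds coordinates are clipped and
    counted.
    """
    idx = selection.indices
    if len(idx) == 0:
        raise ValueError("empty selection")
    coords = traj.frames[:, idx]                       # (F, N, 3)
    if bounds is None:
        bounds = np.stack([coords.reshape(-1, 3).min(axis=0),
                           coords.reshape(-1, 3).max(axis=0)], axis=1)
    bounds = np.asarray(bounds, float).reshape(3, 2)
    span = np.where(bounds[:, 1] > bounds[:, 0], bounds[:, 1] - bounds[:, 0], 1.0)

    h, w = image_shape_for(len(idx))
    pad_mask = np.ones(h * w, dtype=bool)
    pad_mask[:len(idx)] = False

    clipped = int(np.sum((coords < bounds[:, 0]) | (coords > bounds[:, 1])))
    if clipped:
        warnings.warn(f"{clipped} coordinates clipped to encoding bounds")
    norm = (np.clip(coords, bounds[:, 0], bounds[:, 1]) - bounds[:, 0]) / span
    quant = np.minimum((norm * 256.0).astype(np.uint8), 255)

    info = EncodingInfo(atom_indices=idx.copy(), shape=(h, w),
                        bounds=bounds, pad_mask=pad_mask, clipped=clipped)
    images = []
    for f in range(traj.n_frames):
        px = np.zeros((h * w, 3), dtype=np.uint8)
        px[:len(idx)] = quant[f]
        images.append(FrameImage(px.reshape(h, w, 3), info))
    return images, info


def decode_frame(image: FrameImage) -> np.ndarray:
    """Coordinates of the encoded atoms, exact up to one quantization step."""
    info = image.info
    flat = image.pixels.reshape(-1, 3)[:info.n_atoms].astype(float)
    lo, hi = info.bounds[:, 0], info.bounds[:, 1]
    return lo + (flat + 0.5) / 256.0 * (hi - lo)


def _stack(images):
    return np.stack([im.pixels for im in images]).astype(float) / 255.0


def _split_indices(n, fractions, rng):
    fr = np.asarray(fractions, float)
    fr = fr / fr.sum()
    perm = rng.permutation(n)
    n_train = int(round(fr[0] * n))
    n_val = int(round(fr[1] * n))
    return (perm[:n_train], perm[n_train:n_train + n_val],
            perm[n_train + n_val:])


def train_classifier(images_a: list[FrameImage], images_b: list[FrameImage],
                     split=(56, 24, 20), epochs: int = 100, seed: int = 0,
                     scale: str = "reduced", batch_size: int = 32,
                     lr: float = 1e-3, class_labels=(0, 1),
                     balance_tol: float = 0.10,
                     verbose: bool = False):
    """Train the state classifier on two labelled image sets.

    Images are pooled, randomly split train/validation/test by `split`
    (seeded), and the network is trained with adaptive-moment updates.
    Returns (ClassifierModel, report) where the report carries per-class and
    overall test accuracy, per-epoch loss/accuracy curves and the split
    indices (the determinism contract: same seed, same split, same result).
    """
    na, nb = len(images_a), len(images_b)
    if min(na, nb) == 0:
        raise ValueError("both classes need images")
    if abs(na - nb) / max(na, nb) > balance_tol:
        raise ValueError(f"class imbalance {na} vs {nb} exceeds "
                         f"{balance_tol:.0%} tolerance")
    X = np.concatenate([_stack(images_a), _stack(images_b)])
    y = np.concatenate([np.zeros(na, int), np.ones(nb, int)])
    rng = np.random.default_rng(seed)
    tr, va, te = _split_indices(len(X), split, rng)

    net = DenseNetLite(X.shape[1:], n_classes=2, scale=scale, seed=seed + 1)
    opt = AdamOptimizer(net, lr=lr)
    curves = {"train_loss": [], "val_loss": [], "val_acc": []}
    for epoch in range(epochs):
        order = rng.permutation(tr)
        losses = []
        for s in range(0, len(order), batch_size):
            bidx = order[s:s + batch_size]
            logits = net.forward(X[bidx])
            loss, dlog = softmax_cross_entropy(logits, y[bidx])
            net.zero_grad()
            net.backward(dlog)
            opt.step()
            losses.append(loss)
        vlog = net.predict_logits(X[va])
        vloss, _ = softmax_cross_entropy(vlog, y[va])
        vacc = float((np.argmax(vlog, 1) == y[va]).mean())
        curves["train_loss"].append(float(np.mean(losses)))
        curves["val_loss"].append(float(vloss))
        curves["val_acc"].append(vacc)
        if verbose:
            print(f"epoch {epoch + 1:3d}  loss {np.mean(losses):.4f}  "
                  f"val_acc {vacc:.3f}")

    pred = net.predict(X[te])
    overall = float((pred == y[te]).mean())
    per_class = {}
    for c, label in enumerate(class_labels):
        mask = y[te] == c
        per_class[str(label)] = (float((pred[mask] == c).mean())
                                 if mask.any() else float("nan"))
    report = {
        "overall_accuracy": overall,
        "per_class_accuracy": per_class,
        "curves": curves,
        "split_indices": {"train": tr.tolist(), "val": va.tolist(),
                          "test": te.tolist()},
        "epochs": epochs, "seed": seed, "scale": scale,
        "n_images": {"a": na, "b": nb},
    }
    model = ClassifierModel(net=net, class_labels=tuple(class_labels),
                            info=images_a[0].info, training_meta=report)
    return model, report


def saliency(model: ClassifierModel, images: list[FrameImage],
             class_index: int = None, batch: int = 64) -> SaliencyMap:
    """Class-average guided-backpropagation saliency map.

    The gradient of the class score with respect to the input pixels is
    computed with guided backpropagation, magnitude-aggregated over the RGB
    channels, averaged over the given images, zeroed on pad pixels and
    max-normalized to [0, 1]; per-atom values come from the pixel-to-atom
    map.
    """
    if not images:
        raise ValueError("need at least one image")
    if model.net is None:
        raise ValueError("model is untrained")
    info = images[0].info
    if class_index is None:
        class_index = 0
    X = _stack(images)
    acc = np.zeros(info.shape)
    for s in range(0, len(X), batch):
        g = model.net.input_gradient(X[s:s + batch], class_index, guided=True)
        acc += np.abs(g).sum(axis=-1).sum(axis=0)
    acc /= len(X)
    flat = acc.reshape(-1)
    flat[info.pad_mask] = 0.0
    top = flat.max()
    if top > 0:
        flat = flat / top
    return SaliencyMap(pixel_values=flat.reshape(info.shape),
                       atom_values=flat[:info.n_atoms].copy(),
                       class_label=class_index, n_averaged=len(images),
                       info=info)


def rank_residues(sal: SaliencyMap, structure: StructureModel,
                  cutoff: float = SALIENCY_CUTOFF):
    """Rank residues by their maximum per-atom saliency.

    Returns (ranked, above_cutoff): `ranked` is a list of
    (resid, resname, max_saliency) sorted by saliency descending with ties
    broken by ascending residue number; `above_cutoff` lists
    (atom_index, resid, resname, saliency) for atoms at/above the cutoff.
    """
    atoms = sal.info.atom_indices
    resids = structure.resids[atoms]
    resnames = structure.resnames[atoms]
    per_res = {}
    for a, (rid, rname, v) in enumerate(zip(resids, resnames, sal.atom_values)):
        key = int(rid)
        if key not in per_res or v > per_res[key][1]:
            per_res[key] = (str(rname), float(v))
    ranked = sorted(((rid, rn, v) for rid, (rn, v) in per_res.items()),
                    key=lambda r: (-r[2], r[0]))
    above = [(int(atoms[a]), int(resids[a]), str(resnames[a]),
              float(sal.atom_values[a]))
             for a in range(len(atoms)) if sal.atom_values[a] >= cutoff]
    return ranked, above


def save_images_npz(images: list[FrameImage], path) -> None:
    """Archive an image stack with its atom map and bounds (NPZ)."""
    info = images[0].info
    np.savez_compressed(
        path, pixels=np.stack([im.pixels for im in images]),
        atom_indices=info.atom_indices, bounds=info.bounds,
        pad_mask=info.pad_mask, shape=np.array(info.shape))


def save_image_png(image: FrameImage, path, upscale: int = 8) -> None:
    """Write a frame image as PNG (nearest-neighbour upscaled for viewing)."""
    from PIL import Image

    im = Image.fromarray(image.pixels, mode="RGB")
    h, w = image.info.shape
    im.resize((w * upscale, h * upscale), Image.NEAREST).save(path)


def save_saliency_png(sal: SaliencyMap, path, upscale: int = 8) -> None:
    """Write a saliency map as an 8-bit grayscale PNG."""
    from PIL import Image

    gray = np.clip(sal.pixel_values * 255.0, 0, 255).astype(np.uint8)
    im = Image.fromarray(gray, mode="L")
    h, w = sal.info.shape
    im.resize((w * upscale, h * upscale), Image.NEAREST).save(path)


def _mask_images(images: list[FrameImage], exclude_pixels: np.ndarray):
    out = []
    for im in images:
        px = im.pixels.reshape(-1, 3).copy()
        px[exclude_pixels] = 0
        info = im.info
        new_info = EncodingInfo(info.atom_indices, info.shape, info.bounds,
                                info.pad_mask | exclude_pixels, info.clipped)
        out.append(FrameImage(px.reshape(im.pixels.shape), new_info))
    return out


def exclusion_ablation(images_a, images_b, exclude: Selection,
                       baseline_report: dict = None, **train_kwargs):
    """Retrain with a region's pixels zeroed and report the accuracy change.

    `exclude` must be a subset of the encoded atoms. If the exclusion
    removes a class's entire signal the network simply cannot exceed chance;
    that is reported, not raised.
    """
    info = images_a[0].info
    pos = {a: i for i, a in enumerate(info.atom_indices)}
    missing = [a for a in exclude.indices if a not in pos]
    if missing:
        raise ValueError(f"excluded atoms not in the encoding: {missing[:5]}")
    mask = np.zeros(int(np.prod(info.shape)), dtype=bool)
    for a in exclude.indices:
        mask[pos[a]] = True

    if baseline_report is None:
        _, baseline_report = train_classifier(images_a, images_b,
                                              **train_kwargs)
    ma = _mask_images(images_a, mask)
    mb = _mask_images(images_b, mask)
    model, report = train_classifier(ma, mb, **train_kwargs)
    delta = report["overall_accuracy"] - baseline_report["overall_accuracy"]
    return {
        "baseline_accuracy": baseline_report["overall_accuracy"],
        "ablated_accuracy": report["overall_accuracy"],
        "accuracy_delta": float(delta),
        "n_excluded_atoms": int(len(exclude.indices)),
    }, model
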