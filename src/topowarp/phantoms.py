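"""Synthetic phantoms with known, controllable topology.

Offline stand-ins for the two study settings: digit-like
single-structure images in three topology classes (one component with
0, 1 or 2 holes) and cardiac-like multi-structure scenes (an annulus
"myocardium", the inner disc "lv" and an attached outer disc "rv").

Ground-truth labels are manufactured by warping the canonical prior
with a random smooth deformation that is verified to be fold-free, so
every label has the declared Betti numbers by construction.  Images are
rendered as piecewise-constant intensities plus Gaussian noise, with
optional Fourier line-dropout corruption and geometric augmentation
(rotation, translation, flips, resizing).  Everything is a pure,
seeded function of its spec: no downloads, no hidden state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .fields import (
    DeformationField,
    DisplacementField,
    Grid2D,
    SmoothingSpec,
    displacement_activation,
    gaussian_smooth,
    jacobian_determinants,
    scaling_and_squaring,
    warp,
)
from .priors import PriorSpec, make_prior
from .topology import BettiNumbers, betti_2d, scene_report

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "Dataset",
    "random_topology_preserving_warp",
    "render_phantom",
    "fourier_line_dropout",
    "augment",
    "make_dataset",
    "default_prior_spec",
]

_DIGIT_KINDS = ("disc", "annulus", "two_hole_disc")


@dataclass(frozen=True)
class PhantomSpec:
    """Conditions of a synthetic study.

    ``warp_strength`` is the maximum pre-activation displacement fed to
    the bounded activation when manufacturing ground truth;
    ``intensity`` is (foreground mean(s), background mean, noise sd).
    Augmentation ranges follow the cardiac protocol: rotations within
    +/-5 degrees, translations within +/-5 voxels, vertical/horizontal
    flips, resizing within +/-30%.
    """

    task: str = "myo"  # digits | myo | cardiac_scene
    H: int = 64
    W: int = 64
    n_samples: int = 400
    warp_strength: float = 0.35
    warp_smooth_sigma: float = 6.0
    intensity: tuple = (0.75, 0.2, 0.06)
    fourier_dropout: tuple[int, int] = (0, 0)
    rotation_deg: float = 5.0
    translation_vox: float = 5.0
    flip_prob: float = 0.5
    resize_frac: float = 0.3
    augment_geometric: bool = True
    splits: tuple[float, float, float] = (0.75, 0.15, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("digits", "myo", "cardiac_scene"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if abs(sum(self.splits) - 1.0) > 1e-9 or any(s < 0 for s in self.splits):
            raise ValueError(f"split fractions must be non-negative and sum to 1, got {self.splits}")

    @property
    def channels(self) -> int:
        return 3 if self.task == "cardiac_scene" else 1

    @classmethod
    def for_task(cls, task: str, **kw) -> "PhantomSpec":
        """Task presets: digits add Fourier dropout and skip geometric
        augmentation (digit scenes are centred); cardiac scenes use
        per-structure intensities."""
        defaults: dict = {"task": task}
        if task == "digits":
            defaults.update(fourier_dropout=(1, 8), augment_geometric=False)
        elif task == "cardiac_scene":
            defaults.update(intensity=((0.85, 0.55, 0.35), 0.15, 0.06))
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class PhantomSample:
    """One synthetic case: image in [0, 1], binary label and prior."""

    image: np.ndarray  # [H, W]
    label: np.ndarray  # [c, H, W] uint8
    prior: np.ndarray  # [c, H, W] uint8
    meta: dict = field(default_factory=dict)


@dataclass
class Dataset:
    samples: list[PhantomSample]
    manifest: pd.DataFrame
    spec: PhantomSpec

    def split(self, name: str) -> list[PhantomSample]:
        ids = self.manifest.loc[self.manifest["split"] == name, "sample_id"]
        return [self.samples[i] for i in ids]


def default_prior_spec(task: str, H: int, W: int, kind: str | None = None,
                       rv_position: int = 7) -> PriorSpec:
    """Canonical prior geometry for a task, scaled to the grid size."""
    m = min(H, W)
    if task == "cardiac_scene":
        geometry = {
            "myo_outer": round(0.22 * m),
            "myo_wall": max(3, round(0.0625 * m)),
            "rv_radius": round(0.11 * m),
            "rv_position": rv_position,
        }
        return PriorSpec("cardiac_scene", H, W, geometry)
    if task == "myo":
        kind = "annulus"
    if kind == "disc":
        geometry = {"radius": round(0.25 * m)}
    elif kind == "annulus":
        geometry = {"outer_radius": round(0.28 * m), "wall": max(3, round(0.08 * m))}
    elif kind == "two_hole_disc":
        geometry = {"radius": round(0.28 * m), "hole_radius": max(2, round(0.07 * m))}
    else:
        raise ValueError(f"unknown prior kind {kind!r} for task {task!r}")
    return PriorSpec(kind, H, W, geometry)


def random_topology_preserving_warp(
    grid: Grid2D,
    strength: float,
    smooth_sigma: float,
    seed: int,
    max_retries: int = 10,
) -> DeformationField:
    """Smooth random deformation verified to contain no folding voxels.

    Gaussian noise is smoothed, scaled to ``+/-strength``, passed
    through the bounded displacement activation and amplified by
    scaling and squaring (h=6, sigma=2, k=3).  Fields with any
    non-positive Jacobian determinant are rejected and regenerated with
    the next seed (at most ``max_retries`` attempts).
    """
    if strength <= 0:
        raise ValueError("strength must be positive")
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        noise = rng.standard_normal((2, grid.H, grid.W))
        u = gaussian_smooth(
            DisplacementField(noise, grid),
            SmoothingSpec(sigma=smooth_sigma, k=2 * int(np.ceil(2 * smooth_sigma)) + 1),
        ).values
        peak = np.abs(u).max()
        if peak > 0:
            u = u * (strength / peak)
        u1 = displacement_activation(u, grid)
        phi = scaling_and_squaring(u1, h=6, smoothing=SmoothingSpec(sigma=2.0, k=3))
        if jacobian_determinants(phi).count_nonpositive == 0:
            return phi
    raise RuntimeError(
        f"no fold-free field in {max_retries} attempts (seed {seed}); "
        "warp strength is likely too high"
    )


def render_phantom(label: np.ndarray, spec: PhantomSpec, seed: int) -> np.ndarray:
    """Piecewise-constant intensities per structure plus Gaussian noise."""
    label = np.asarray(label)
    if label.ndim == 2:
        label = label[None]
    fg, bg, sd = spec.intensity
    fg = np.atleast_1d(np.asarray(fg, dtype=float))
    if fg.size not in (1, label.shape[0]):
        raise ValueError(f"{fg.size} foreground intensities for {label.shape[0]} channels")
    if fg.size == 1:
        fg = np.repeat(fg, label.shape[0])
    img = np.full(label.shape[-2:], float(bg))
    for k in range(label.shape[0]):
        img[label[k] > 0] = fg[k]
    rng = np.random.default_rng(seed)
    img = img + rng.normal(0.0, sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def fourier_line_dropout(image: np.ndarray, n_lines: int, seed: int) -> np.ndarray:
    """Corrupt an image by zeroing random lines of its 2D spectrum.

    Rows/columns of the FFT (never the DC line) are zeroed together
    with their Hermitian partners so the inverse transform stays real.
    The result is clipped back to [0, 1].
    """
    if n_lines < 0:
        raise ValueError("n_lines must be >= 0")
    image = np.asarray(image, dtype=float)
    if n_lines == 0:
        return image.copy()
    H, W = image.shape
    rng = np.random.default_rng(seed)
    F = np.fft.fft2(image)
    for _ in range(n_lines):
        if rng.random() < 0.5:
            r = int(rng.integers(1, H))
            F[r, :] = 0.0
            F[(H - r) % H, :] = 0.0
        else:
            c = int(rng.integers(1, W))
            F[:, c] = 0.0
            F[:, (W - c) % W] = 0.0
    out = np.fft.ifft2(F).real
    return np.clip(out, 0.0, 1.0)


def _random_affine(spec: PhantomSpec, rng: np.random.Generator):
    theta = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg))
    scale = 1.0 + rng.uniform(-spec.resize_frac, spec.resize_frac)
    trans = rng.uniform(-spec.translation_vox, spec.translation_vox, size=2)
    flip_v = rng.random() < spec.flip_prob
    flip_h = rng.random() < spec.flip_prob
    return theta, scale, trans, flip_v, flip_h


def _affine_matrix(theta, scale, trans, flip_v, flip_h, H, W):
    """Output-to-input mapping for scipy.ndimage.affine_transform."""
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    flip = np.diag([-1.0 if flip_v else 1.0, -1.0 if flip_h else 1.0])
    fwd = rot @ flip * scale
    inv = np.linalg.inv(fwd)
    center = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    offset = center - inv @ (center + np.asarray(trans))
    return inv, offset


def augment(sample: PhantomSample, spec: PhantomSpec, seed: int,
            max_retries: int = 10) -> PhantomSample:
    """Apply one random geometric transform to image and label together.

    The image is interpolated linearly, the label nearest-neighbour,
    and the prior is left untouched.  If the transform breaks any
    channel's Betti numbers (e.g. a structure clipped at the border)
    the draw is rejected and retried; after ``max_retries`` failures the
    sample is returned unaugmented.
    """
    expected = [betti_2d(ch) for ch in sample.label]
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        params = _random_affine(spec, rng)
        inv, offset = _affine_matrix(*params, spec.H, spec.W)
        img = ndimage.affine_transform(
            sample.image, inv, offset=offset, order=1, mode="constant",
            cval=float(np.atleast_1d(spec.intensity[1])[0]),
        )
        lab = np.stack(
            [
                ndimage.affine_transform(
                    ch.astype(float), inv, offset=offset, order=0, mode="constant", cval=0.0
                )
                for ch in sample.label
            ]
        ).astype(np.uint8)
        if [betti_2d(ch) for ch in lab] == expected:
            meta = dict(sample.meta)
            meta.update(
                augment_seed=seed + attempt,
                rotation_rad=float(params[0]),
                scale=float(params[1]),
                translation=tuple(float(t) for t in params[2]),
                flips=(bool(params[3]), bool(params[4])),
            )
            return PhantomSample(np.clip(img, 0.0, 1.0), lab, sample.prior, meta)
    meta = dict(sample.meta)
    meta["augment_skipped"] = True
    return PhantomSample(sample.image, sample.label, sample.prior, meta)


def _make_label(prior: np.ndarray, spec: PhantomSpec, seed: int,
                expected: list[BettiNumbers], expected_union: BettiNumbers,
                max_retries: int = 10) -> tuple[np.ndarray, int]:
    """Warp the prior with a verified fold-free field; reject topology breaks."""
    grid = Grid2D(spec.H, spec.W)
    for attempt in range(max_retries):
        phi = random_topology_preserving_warp(
            grid, spec.warp_strength, spec.warp_smooth_sigma, seed + 1000 * attempt
        )
        soft = warp(prior.astype(float), phi, interp="linear")
        label = (soft >= 0.5).astype(np.uint8)
        rep = scene_report(label, expected, expected_union)
        if rep.all_match and (label.shape[0] == 1 or rep.overlap_voxels == 0):
            return label, seed + 1000 * attempt
    raise RuntimeError(f"could not produce a topology-correct label (seed {seed})")


def make_dataset(spec: PhantomSpec) -> Dataset:
    """Generate a seeded dataset with a subject-level train/val/test split.

    Each family (one base warped label and its rendered, corrupted and
    augmented image) is assigned to exactly one split; fractions follow
    ``spec.splits`` (default 75/15/10).  The manifest records the seed
    and per-channel Betti numbers of every emitted sample.
    """
    root = np.random.SeedSequence(spec.seed)
    family_seeds = root.generate_state(spec.n_samples * 4).reshape(spec.n_samples, 4)
    family_seeds = (family_seeds % (2**31 - 1)).astype(np.int64)

    samples: list[PhantomSample] = []
    rows = []
    split_names = _assign_splits(spec)
    for fam in range(spec.n_samples):
        s_warp, s_noise, s_fourier, s_aug = (int(v) for v in family_seeds[fam])
        if spec.task == "digits":
            kind = _DIGIT_KINDS[fam % 3]
            prior_spec = default_prior_spec("digits", spec.H, spec.W, kind=kind)
        else:
            prior_spec = default_prior_spec(spec.task, spec.H, spec.W)
        prior = make_prior(prior_spec)
        label, used_seed = _make_label(
            prior, spec, s_warp, prior_spec.expected, prior_spec.expected_union
        )
        image = render_phantom(label, spec, s_noise)
        lo, hi = spec.fourier_dropout
        if hi > 0:
            n_lines = int(np.random.default_rng(s_fourier).integers(lo, hi + 1))
            image = fourier_line_dropout(image, n_lines, s_fourier)
        sample = PhantomSample(
            image,
            label,
            prior,
            {
                "family_id": fam,
                "prior_kind": prior_spec.kind,
                "warp_seed": used_seed,
                "split": split_names[fam],
            },
        )
        if spec.augment_geometric:
            sample = augment(sample, spec, s_aug)
        samples.append(sample)
        row = {
            "sample_id": len(samples) - 1,
            "family_id": fam,
            "split": split_names[fam],
            "seed": used_seed,
            "prior_kind": prior_spec.kind,
        }
        for k, ch in enumerate(sample.label):
            b = betti_2d(ch)
            row[f"b0_ch{k}"] = b.b0
            row[f"b1_ch{k}"] = b.b1
        rows.append(row)
    return Dataset(samples, pd.DataFrame(rows), spec)


def _assign_splits(spec: PhantomSpec) -> list[str]:
    n = spec.n_samples
    n_train = int(round(spec.splits[0] * n))
    n_val = int(round(spec.splits[1] * n))
    n_val = min(n_val, n - n_train)
    order = np.random.default_rng(spec.seed).permutation(n)
    names = [""] * n
    for pos, fam in enumerate(order):
        if pos < n_train:
            names[fam] = "train"
        elif pos < n_train + n_val:
            names[fam] = "val"
        else:
            names[fam] = "test"
    return names
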