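"""Betti numbers, scene-topology checks and perimeter tracing for 2D masks.

The topology of a binary mask is summarised by its first two Betti
numbers: ``b0`` counts connected foreground components, ``b1`` counts
enclosed holes.  A hole is a 4-connected component of background voxels
that does not touch the image border (i.e. is surrounded by
foreground).  For multi-structure segmentations the *scene* topology —
the Betti numbers of the union of all channels together with their
mutual non-overlap — captures whether the structures are arranged
correctly relative to each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "BettiNumbers",
    "SceneReport",
    "betti_2d",
    "scene_report",
    "trace_perimeter",
    "relative_perimeter_error",
]

_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class BettiNumbers:
    """(components, holes) of a 2D binary mask."""

    b0: int
    b1: int

    def __post_init__(self) -> None:
        if self.b0 < 0 or self.b1 < 0:
            raise ValueError("Betti numbers must be non-negative")
        if self.b0 == 0 and self.b1 != 0:
            raise ValueError("an empty mask cannot enclose holes")

    def __iter__(self):
        return iter((self.b0, self.b1))


@dataclass
class SceneReport:
    """Per-channel and combined topology of a multi-channel mask."""

    per_channel: list[BettiNumbers]
    union_betti: BettiNumbers
    overlap_voxels: int
    matches_expected: list[bool]
    union_matches: bool

    @property
    def all_match(self) -> bool:
        return all(self.matches_expected) and self.union_matches


def _as_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype == bool:
        return mask
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"mask is not binary; values found: {uniq[:8]}")
    return mask.astype(bool)


def betti_2d(mask: np.ndarray, fg_connectivity: int = 4) -> BettiNumbers:
    """Betti numbers of a binary mask.

    ``b0``: foreground components under ``fg_connectivity`` (4 or 8).
    ``b1``: 4-connected background components not touching the border —
    the operational reading of "background surrounded by foreground".
    """
    mask = _as_binary(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected a 2D mask, got shape {mask.shape}")
    if fg_connectivity not in (4, 8):
        raise ValueError(f"fg_connectivity must be 4 or 8, got {fg_connectivity}")
    struct = _STRUCT_4 if fg_connectivity == 4 else _STRUCT_8
    _, b0 = ndimage.label(mask, structure=struct)
    bg_labels, n_bg = ndimage.label(~mask, structure=_STRUCT_4)
    border = np.concatenate(
        [bg_labels[0, :], bg_labels[-1, :], bg_labels[:, 0], bg_labels[:, -1]]
    )
    touching = np.setdiff1d(np.unique(border), [0]).size
    return BettiNumbers(int(b0), int(n_bg - touching))


def scene_report(
    masks: np.ndarray,
    expected: list[BettiNumbers] | None = None,
    expected_union: BettiNumbers | None = None,
    fg_connectivity: int = 4,
) -> SceneReport:
    """Topology of each channel, of their union, and their overlap.

    ``masks`` is ``[c, H, W]`` binary.  ``overlap_voxels`` counts voxels
    set in two or more channels (anatomical structures should tile the
    scene without overlapping).
    """
    masks = _as_binary(masks)
    if masks.ndim != 3:
        raise ValueError(f"expected [c, H, W] masks, got shape {masks.shape}")
    c = masks.shape[0]
    if expected is not None and len(expected) != c:
        raise ValueError(f"{len(expected)} expectations for {c} channels")
    per = [betti_2d(masks[i], fg_connectivity) for i in range(c)]
    union = betti_2d(np.any(masks, axis=0), fg_connectivity)
    overlap = int(np.count_nonzero(masks.sum(axis=0) >= 2))
    matches = [
        (expected is None) or (per[i] == expected[i]) for i in range(c)
    ]
    union_ok = (expected_union is None) or (union == expected_union)
    return SceneReport(per, union, overlap, matches, union_ok)


def trace_perimeter(mask: np.ndarray) -> int:
    """Contour length as the number of exposed foreground voxel faces.

    A face is exposed when a foreground voxel is 4-adjacent to
    background or to the image border; outer and hole boundaries are
    both included.  Units: voxel edges.
    """
    mask = _as_binary(mask)
    p = np.pad(mask, 1, constant_values=False)
    exposed = 0
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neighbour = np.roll(p, shift, axis=(0, 1))
        exposed += int(np.count_nonzero(p & ~neighbour))
    return exposed


def relative_perimeter_error(pred: np.ndarray, ref: np.ndarray) -> float:
    """``100 * |perim(pred) - perim(ref)| / perim(ref)``; NaN if ref empty."""
    pred = _as_binary(pred)
    ref = _as_binary(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    ref_perim = trace_perimeter(ref)
    if ref_perim == 0:
        return float("nan")
    return 100.0 * abs(trace_perimeter(pred) - ref_perim) / ref_perim
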