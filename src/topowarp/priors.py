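"""Binary prior shapes with prescribed topology.

The segmentation network never labels pixels directly: it deforms one
of these canonical shapes, so the prior's Betti numbers are the
topology the output is meant to inherit.  Single-structure priors cover
the three digit-like topology classes (a solid disc, an annulus, a disc
with two holes); the cardiac scene prior stacks an annulus
("myocardium"), the disc exactly filling its hole ("left ventricle")
and a disc attached to its outside ("right ventricle") into three
disjoint channels whose union is a single solid blob.

Every constructor self-checks the Betti numbers of what it built and
refuses to return a shape with the wrong topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .topology import BettiNumbers, betti_2d, scene_report

__all__ = [
    "PriorSpec",
    "make_disc",
    "make_annulus",
    "make_two_hole_disc",
    "make_cardiac_prior",
    "make_prior",
    "CARDIAC_EXPECTED",
    "CARDIAC_EXPECTED_UNION",
]

#: Expected per-channel topology of the cardiac scene (myo, rv, lv).
CARDIAC_EXPECTED = [BettiNumbers(1, 1), BettiNumbers(1, 0), BettiNumbers(1, 0)]
#: The three structures together form one solid component with no hole.
CARDIAC_EXPECTED_UNION = BettiNumbers(1, 0)


@dataclass(frozen=True)
class PriorSpec:
    """Declarative description of a prior shape.

    ``geometry`` holds per-kind parameters (radii, wall thickness, hole
    offsets, rv_position ...); ``expected`` / ``expected_union`` are the
    Betti numbers the constructed mask must satisfy.
    """

    kind: str  # disc | annulus | two_hole_disc | cardiac_scene
    H: int
    W: int
    geometry: dict = field(default_factory=dict)

    @property
    def channels(self) -> int:
        return 3 if self.kind == "cardiac_scene" else 1

    @property
    def expected(self) -> list[BettiNumbers]:
        return {
            "disc": [BettiNumbers(1, 0)],
            "annulus": [BettiNumbers(1, 1)],
            "two_hole_disc": [BettiNumbers(1, 2)],
            "cardiac_scene": CARDIAC_EXPECTED,
        }[self.kind]

    @property
    def expected_union(self) -> BettiNumbers:
        return CARDIAC_EXPECTED_UNION if self.kind == "cardiac_scene" else self.expected[0]


def _distance_grid(H: int, W: int, center: tuple[float, float]) -> np.ndarray:
    r, c = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float), indexing="ij")
    return np.hypot(r - center[0], c - center[1])


def _check_inside(H: int, W: int, center: tuple[float, float], radius: float, what: str) -> None:
    if (
        center[0] - radius < 0
        or center[1] - radius < 0
        or center[0] + radius > H - 1
        or center[1] + radius > W - 1
    ):
        raise ValueError(
            f"{what} (center {center}, radius {radius}) does not fit inside "
            f"a {H}x{W} grid"
        )


def make_disc(H: int, W: int, center: tuple[float, float], radius: float) -> np.ndarray:
    """Solid disc: foreground where distance from ``center`` < ``radius``."""
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    _check_inside(H, W, center, radius, "disc")
    mask = (_distance_grid(H, W, center) < radius).astype(np.uint8)
    got = betti_2d(mask)
    if got != BettiNumbers(1, 0):
        raise ValueError(f"disc self-check failed: Betti {tuple(got)} != (1, 0)")
    return mask


def make_annulus(
    H: int,
    W: int,
    center: tuple[float, float] | None = None,
    outer_radius: float = 35.0,
    wall: float = 7.0,
) -> np.ndarray:
    """Annulus ("hollow circle"): outer radius, with a wall of ``wall`` voxels.

    Defaults follow the myocardium prior geometry: outer radius 35,
    wall 7 (inner radius 28).
    """
    if center is None:
        center = ((H - 1) / 2.0, (W - 1) / 2.0)
    if wall >= outer_radius:
        raise ValueError(f"wall {wall} must be smaller than outer radius {outer_radius}")
    _check_inside(H, W, center, outer_radius, "annulus")
    d = _distance_grid(H, W, center)
    mask = ((d >= outer_radius - wall) & (d < outer_radius)).astype(np.uint8)
    got = betti_2d(mask)
    if got != BettiNumbers(1, 1):
        raise ValueError(
            f"annulus self-check failed: Betti {tuple(got)} != (1, 1); the "
            "geometry is degenerate (hole closed or ring broken)"
        )
    return mask


def make_two_hole_disc(
    H: int,
    W: int,
    center: tuple[float, float],
    radius: float,
    hole_radius: float,
    hole_offsets: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> np.ndarray:
    """Solid disc minus two disjoint interior discs; Betti (1, 2)."""
    if hole_offsets is None:
        s = radius / 2.2
        hole_offsets = ((0.0, -s), (0.0, s))
    mask = make_disc(H, W, center, radius).astype(bool)
    centres = [(center[0] + dr, center[1] + dc) for dr, dc in hole_offsets]
    gap = np.hypot(
        centres[0][0] - centres[1][0], centres[0][1] - centres[1][1]
    )
    if gap <= 2 * hole_radius:
        raise ValueError("holes overlap or touch; move them apart or shrink them")
    for hc in centres:
        if np.hypot(hc[0] - center[0], hc[1] - center[1]) + hole_radius >= radius - 1:
            raise ValueError("hole touches the disc boundary; keep holes interior")
        mask &= _distance_grid(H, W, hc) >= hole_radius
    mask = mask.astype(np.uint8)
    got = betti_2d(mask)
    if got != BettiNumbers(1, 2):
        raise ValueError(f"two-hole disc self-check failed: Betti {tuple(got)} != (1, 2)")
    return mask


def rv_direction(rv_position: int) -> tuple[float, float]:
    """Unit (row, col) direction of an rv position 1..8.

    Position 1 points to 12 o'clock (up the image); successive positions
    advance counter-clockwise by 45 degrees.
    """
    if rv_position not in range(1, 9):
        raise ValueError(f"rv_position must be in 1..8, got {rv_position}")
    theta = np.deg2rad((rv_position - 1) * 45.0)
    # up = -row; counter-clockwise rotates "up" towards -col.
    return (-float(np.cos(theta)), -float(np.sin(theta)))


def make_cardiac_prior(
    H: int,
    W: int,
    rv_position: int = 7,
    myo_outer: float = 35.0,
    myo_wall: float = 7.0,
    rv_radius: float = 15.0,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Three-channel cardiac scene prior (myo, rv, lv), shape ``[3, H, W]``.

    The left ventricle is the disc that exactly fills the myocardium
    hole; the right ventricle is a disc touching the outside of the
    myocardium ring at 45-degree position ``rv_position`` (1..8),
    overlapping no other channel.  Channels are pairwise disjoint and
    their union is one solid component.
    """
    if center is None:
        center = ((H - 1) / 2.0, (W - 1) / 2.0)
    myo = make_annulus(H, W, center, myo_outer, myo_wall).astype(bool)
    inner = myo_outer - myo_wall
    d = _distance_grid(H, W, center)
    lv = d < inner

    direction = rv_direction(rv_position)
    dist = myo_outer + rv_radius - 1.0  # externally tangent, 4-adjacent
    rv_center = (center[0] + dist * direction[0], center[1] + dist * direction[1])
    try:
        _check_inside(H, W, rv_center, rv_radius, "rv disc")
    except ValueError as err:
        raise ValueError(f"{err}; shrink rv_radius or enlarge the grid") from err
    rv = (_distance_grid(H, W, rv_center) < rv_radius) & ~myo & ~lv

    masks = np.stack([myo, rv, lv]).astype(np.uint8)
    report = scene_report(masks, CARDIAC_EXPECTED, CARDIAC_EXPECTED_UNION)
    if not report.all_match or report.overlap_voxels:
        raise ValueError(
            f"cardiac prior self-check failed: per-channel "
            f"{[tuple(b) for b in report.per_channel]}, union "
            f"{tuple(report.union_betti)}, overlap {report.overlap_voxels}"
        )
    return masks


def make_prior(spec: PriorSpec) -> np.ndarray:
    """Build the mask(s) described by ``spec``; always ``[c, H, W]``."""
    g: dict[str, Any] = dict(spec.geometry)
    center = g.pop("center", ((spec.H - 1) / 2.0, (spec.W - 1) / 2.0))
    if spec.kind == "disc":
        mask = make_disc(spec.H, spec.W, center, **g)
    elif spec.kind == "annulus":
        mask = make_annulus(spec.H, spec.W, center, **g)
    elif spec.kind == "two_hole_disc":
        mask = make_two_hole_disc(spec.H, spec.W, center, **g)
    elif spec.kind == "cardiac_scene":
        return make_cardiac_prior(spec.H, spec.W, center=center, **g)
    else:
        raise ValueError(f"unknown prior kind: {spec.kind!r}")
    return mask[None]
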