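"""Discrete topology-preserving deformation fields on regular 2D grids.

A deformation field is stored as a displacement field ``u`` on a regular
grid of voxel centres; the absolute mapping is ``Phi(x) = u(x) + x``.
Large, smooth deformations are built by repeatedly composing a
small-displacement field with itself (scaling and squaring).  In the
continuous domain such compositions preserve topology; on a discrete
grid interpolation and re-storing can create spurious gradients, so two
counter-measures are provided and used throughout: a bounded activation
that caps each displacement component below half a grid space, and
Gaussian smoothing of the displacement between composition steps.
Jacobian-determinant auditing quantifies any residual folding.

Conventions
-----------
* 0-based ``(row, col)`` indices at voxel centres; channel order of a
  displacement field is ``(row-displacement, col-displacement)``.
* Displacements are expressed in voxels of the field's own grid.
* All sampling defaults to linear interpolation; ``nearest`` and
  ``cubic`` are available where a method argument is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Grid2D",
    "DisplacementField",
    "DeformationField",
    "SmoothingSpec",
    "FoldingReport",
    "displacement_activation",
    "compose",
    "compose_1d",
    "scaling_and_squaring",
    "gaussian_kernel",
    "gaussian_smooth",
    "upsample_field",
    "warp",
    "jacobian_determinants",
]

_INTERP_ORDER = {"nearest": 0, "linear": 1, "cubic": 3}


@dataclass(frozen=True)
class Grid2D:
    """Regular 2D reference grid of ``H`` x ``W`` voxel centres."""

    H: int
    W: int
    spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.H < 2 or self.W < 2:
            raise ValueError(f"grid must be at least 2x2, got {self.H}x{self.W}")
        if self.spacing <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.H, self.W)

    def coords(self) -> np.ndarray:
        """Identity coordinates, shape ``[2, H, W]`` (row, col)."""
        r, c = np.meshgrid(
            np.arange(self.H, dtype=float), np.arange(self.W, dtype=float), indexing="ij"
        )
        return np.stack([r, c])


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors ``u``, shape ``[2, H, W]``."""

    values: np.ndarray
    grid: Grid2D

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (2, self.grid.H, self.grid.W):
            raise ValueError(
                f"displacement shape {self.values.shape} does not match "
                f"grid [2, {self.grid.H}, {self.grid.W}]"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite displacement at index {tuple(int(i) for i in bad)}")

    @classmethod
    def zeros(cls, grid: Grid2D) -> "DisplacementField":
        return cls(np.zeros((2, grid.H, grid.W)), grid)


@dataclass
class DeformationField:
    """Absolute mapping ``Phi(x) = u(x) + x``, stored via its displacement."""

    displacement: DisplacementField

    @property
    def grid(self) -> Grid2D:
        return self.displacement.grid

    @property
    def phi(self) -> np.ndarray:
        """Absolute coordinate view, shape ``[2, H, W]``."""
        return self.displacement.values + self.grid.coords()

    @classmethod
    def identity(cls, grid: Grid2D) -> "DeformationField":
        return cls(DisplacementField.zeros(grid))

    @classmethod
    def from_phi(cls, phi: np.ndarray, grid: Grid2D) -> "DeformationField":
        phi = np.asarray(phi, dtype=float)
        return cls(DisplacementField(phi - grid.coords(), grid))


@dataclass(frozen=True)
class SmoothingSpec:
    """Gaussian smoothing kernel: std-dev ``sigma`` (voxels), odd side ``k``.

    ``sigma = 0`` disables smoothing.
    """

    sigma: float = 2.0
    k: int = 3

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"kernel size must be odd and >= 1, got {self.k}")


@dataclass
class FoldingReport:
    """Jacobian-determinant audit of a deformation field.

    Grid points with ``det <= 0`` are folding voxels: the field crosses
    over itself there and topology preservation is violated.
    """

    jacobian_dets: np.ndarray
    count_nonpositive: int = field(init=False)
    percent_nonpositive: float = field(init=False)

    def __post_init__(self) -> None:
        self.jacobian_dets = np.asarray(self.jacobian_dets, dtype=float)
        self.count_nonpositive = int(np.count_nonzero(self.jacobian_dets <= 0))
        self.percent_nonpositive = 100.0 * self.count_nonpositive / self.jacobian_dets.size

    @property
    def min_det(self) -> float:
        return float(self.jacobian_dets.min())


def displacement_activation(raw: np.ndarray, grid: Grid2D | None = None) -> DisplacementField:
    """Bound raw head outputs to less than half a grid space per component.

    Each component is mapped independently through ``tanh(.) / 2`` so the
    output lies strictly inside ``(-0.5, 0.5)`` voxels, preventing
    adjacent grid points from crossing in a single composition step.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 3 or raw.shape[0] != 2:
        raise ValueError(f"expected raw field of shape [2, H, W], got {raw.shape}")
    if not np.all(np.isfinite(raw)):
        bad = np.argwhere(~np.isfinite(raw))[0]
        raise ValueError(f"non-finite raw displacement at index {tuple(int(i) for i in bad)}")
    if grid is None:
        grid = Grid2D(raw.shape[1], raw.shape[2])
    return DisplacementField(np.tanh(raw) / 2.0, grid)


def _sample_channels(
    source: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    method: str = "linear",
    boundary: str = "border",
) -> np.ndarray:
    """Sample each channel of ``source`` at fractional (rows, cols)."""
    order = _INTERP_ORDER[method]
    mode = {"border": "nearest", "zeros": "constant"}[boundary]
    coords = np.stack([rows, cols])
    out = [
        ndimage.map_coordinates(ch, coords, order=order, mode=mode, cval=0.0)
        for ch in source.reshape((-1,) + source.shape[-2:])
    ]
    return np.stack(out).reshape(source.shape[:-2] + rows.shape)


def compose(
    outer: DeformationField,
    inner: DeformationField,
    method: str = "linear",
    boundary: str = "border",
) -> DeformationField:
    """Composition ``outer o inner``: resample ``outer`` at ``inner``'s outputs.

    ``u_out(x) = u_inner(x) + interp(u_outer)(x + u_inner(x))`` with the
    sample locations clamped to the grid border by default ("border");
    ``boundary="zeros"`` treats the displacement as zero outside.
    """
    if outer.grid != inner.grid:
        raise ValueError(f"grid mismatch: {outer.grid} vs {inner.grid}")
    grid = inner.grid
    target = inner.phi
    sampled = _sample_channels(
        outer.displacement.values, target[0], target[1], method=method, boundary=boundary
    )
    return DeformationField(DisplacementField(inner.displacement.values + sampled, grid))


def compose_1d(phi_values: np.ndarray, n: int = 1) -> np.ndarray:
    """1D analogue of discrete composition, for pedagogy and auditing.

    ``phi_values`` are the absolute positions of a 1D deformation on the
    integer grid ``x = 0..len-1``.  Each composition evaluates the
    piecewise-linear interpolant of the field at its own grid outputs:
    ``Phi^(2)(x) = Phi(Phi(x))``.  Returns the composed grid values.
    """
    x = np.arange(len(phi_values), dtype=float)
    phi = np.asarray(phi_values, dtype=float)
    out = phi
    for _ in range(n):
        out = np.interp(out, x, phi)
    return out


def gaussian_kernel(spec: SmoothingSpec) -> np.ndarray:
    """Truncated ``k x k`` Gaussian, renormalised to sum exactly 1."""
    half = spec.k // 2
    ax = np.arange(-half, half + 1, dtype=float)
    rr, cc = np.meshgrid(ax, ax, indexing="ij")
    if spec.sigma == 0:
        kern = np.where((rr == 0) & (cc == 0), 1.0, 0.0)
    else:
        kern = np.exp(-(rr**2 + cc**2) / (2.0 * spec.sigma**2))
    return kern / kern.sum()


def gaussian_smooth(u: DisplacementField, spec: SmoothingSpec) -> DisplacementField:
    """Per-channel convolution with a normalised truncated Gaussian.

    Replicate padding at borders keeps constant fields exactly constant.
    ``sigma = 0`` is a no-op.
    """
    if spec.sigma == 0:
        return u
    kern = gaussian_kernel(spec)
    smoothed = np.stack(
        [ndimage.convolve(ch, kern, mode="nearest") for ch in u.values]
    )
    return DisplacementField(smoothed, u.grid)


def scaling_and_squaring(
    u1: DisplacementField,
    h: int,
    smoothing: SmoothingSpec | None = None,
    method: str = "linear",
    boundary: str = "border",
) -> DeformationField:
    """Amplify a small displacement through ``h`` squaring layers.

    Each step composes the current field with itself (so ``h`` steps
    realise ``2**h`` unit compositions) and then smooths the resulting
    displacement.  Smoothing is applied after every step, including the
    final one.  ``h = 0`` returns the input displacement unchanged.
    """
    if h < 0:
        raise ValueError(f"squaring steps h must be >= 0, got {h}")
    if smoothing is None:
        smoothing = SmoothingSpec(sigma=0.0, k=1)
    phi = DeformationField(u1)
    for _ in range(h):
        phi = compose(phi, phi, method=method, boundary=boundary)
        phi = DeformationField(gaussian_smooth(phi.displacement, smoothing))
    return phi


def upsample_field(phi: DeformationField, factor: int, method: str = "linear") -> DeformationField:
    """Express a deformation on a ``factor`` x finer grid.

    The displacement is interpolated at the fine positions (fine index
    ``i`` maps to coarse coordinate ``(i + 0.5) / factor - 0.5``, the
    voxel-centre convention) and multiplied by ``factor`` so the same
    physical mapping is described in fine-grid voxel units.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    if factor == 1:
        return phi
    g = phi.grid
    fine = Grid2D(g.H * factor, g.W * factor, g.spacing / factor)
    rf, cf = np.meshgrid(
        (np.arange(fine.H, dtype=float) + 0.5) / factor - 0.5,
        (np.arange(fine.W, dtype=float) + 0.5) / factor - 0.5,
        indexing="ij",
    )
    u = _sample_channels(phi.displacement.values, rf, cf, method=method, boundary="border")
    return DeformationField(DisplacementField(u * factor, fine))


def warp(
    source: np.ndarray,
    phi: DeformationField,
    interp: str = "linear",
) -> np.ndarray:
    """Backward-warp ``source`` with ``phi``: ``out(x) = source(Phi(x) / f)``.

    ``source`` may be ``[H, W]`` or ``[c, H, W]``; the field may live on
    an ``f``-times finer grid (``f`` a positive integer), in which case
    field coordinates are converted to source-grid units before
    sampling, using the voxel-centre convention
    ``(Phi(x) + 0.5) / f - 0.5``.  Samples mapping outside the source
    return 0 (background).  All channels are warped with the same field.
    """
    source = np.asarray(source, dtype=float)
    src_hw = source.shape[-2:]
    fh = phi.grid.H / src_hw[0]
    fw = phi.grid.W / src_hw[1]
    if fh != fw or fh < 1 or int(fh) != fh:
        raise ValueError(
            f"field grid {phi.grid.shape} must be an integer multiple of "
            f"source grid {src_hw}"
        )
    f = fh
    target = (phi.phi + 0.5) / f - 0.5
    out = _sample_channels(source, target[0], target[1], method=interp, boundary="zeros")
    return out


def jacobian_determinants(phi: DeformationField) -> FoldingReport:
    """Finite-difference Jacobian determinants of the absolute mapping.

    Central differences in the interior, one-sided at the borders.
    ``det <= 0`` marks a folding voxel.
    """
    p = phi.phi
    dpr_dr, dpr_dc = np.gradient(p[0])
    dpc_dr, dpc_dc = np.gradient(p[1])
    dets = dpr_dr * dpc_dc - dpr_dc * dpc_dr
    return FoldingReport(dets)
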