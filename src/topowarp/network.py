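"""Prior-deforming segmentation network.

An encoder-decoder backbone predicts two raw displacement fields from
the input image: a coarse *bulk* field that positions and scales the
prior, and a finer *fine-tuning* field that refines its boundary.  Each
head's output is passed through the bounded displacement activation,
amplified by ``h`` scaling-and-squaring layers with Gaussian smoothing
between steps, and upsampled to twice the input resolution.  The prior
is backward-warped by the bulk field, then by the fine-tuning field,
downsampled back to input resolution (max pooling for single
structures, linear for multi-structure scenes) and thresholded at
``T``.  Because the segmentation is a deformation of the prior, smooth
fold-free fields make the output inherit the prior's topology.

Training minimises soft Dice plus weighted gradient penalties on the
final fields (see :mod:`topowarp.losses`); both heads are initialised
to zero so optimisation starts from the identity deformation.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .fields import (
    DeformationField,
    DisplacementField,
    FoldingReport,
    Grid2D,
    SmoothingSpec,
    jacobian_determinants,
)
from .losses import LossWeights, dice_loss, grad_loss
from .metrics import dice_score
from .topology import betti_2d

__all__ = ["ModelConfig", "SegmentationOutput", "SegNet", "build_network", "forward", "train"]


@dataclass
class ModelConfig:
    """Architecture and training hyper-parameters.

    A branch of depth ``d`` emits its field at ``1 / 2**(d-1)`` of the
    input resolution, so ``l_ft = 1`` is full resolution and
    ``l_bulk = l`` the coarsest decoder scale.
    """

    l: int = 4               # encoder depth
    f: int = 12              # initial feature maps
    l_bulk: int = 4          # bulk branch depth
    l_ft: int = 2            # fine-tuning branch depth
    h: int = 8               # scaling-and-squaring steps
    sigma: float = 2.0       # Gaussian smoothing std-dev (voxels)
    k: int = 3               # smoothing kernel side
    alpha: float = 10_000.0  # fine-tuning field gradient weight
    beta: float = 10_000.0   # bulk field gradient weight
    T: float = 0.3           # binarisation threshold
    c: int = 1               # output channels
    use_bulk: bool = True
    use_activation: bool = True  # ablation switch
    downsample_mode: str = "maxpool"  # maxpool | linear
    lr: float = 1e-4
    batch: int = 5
    epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.l >= self.l_ft >= 1):
            raise ValueError(f"need l >= l_ft >= 1, got l={self.l}, l_ft={self.l_ft}")
        if self.use_bulk and not (self.l >= self.l_bulk >= 1):
            raise ValueError(f"need l >= l_bulk >= 1, got l={self.l}, l_bulk={self.l_bulk}")
        if not (0.0 < self.T < 1.0):
            raise ValueError(f"threshold T must be in (0, 1), got {self.T}")
        if self.downsample_mode not in ("maxpool", "linear"):
            raise ValueError(f"unknown downsample_mode {self.downsample_mode!r}")

    @property
    def smoothing(self) -> SmoothingSpec:
        return SmoothingSpec(self.sigma, self.k)

    @property
    def weights(self) -> LossWeights:
        return LossWeights(self.alpha, self.beta if self.use_bulk else 0.0)


@dataclass
class SegmentationOutput:
    """Everything the forward pass produces for one case."""

    soft: np.ndarray                       # [c, H, W] in [0, 1]
    binary: np.ndarray                     # [c, H, W] uint8, soft >= T
    phi_ft: DeformationField               # final field at 2H x 2W
    phi_bulk: DeformationField | None
    folding: dict[str, FoldingReport]


def _he_conv(rng, c_in, c_out, k):
    std = np.sqrt(2.0 / (c_in * k * k))
    w = rng.normal(0.0, std, size=(c_out, c_in, k, k)).astype(np.float32)
    return Tensor(w, requires_grad=True), Tensor(np.zeros(c_out, np.float32), requires_grad=True)


class SegNet:
    """Parameter container plus the differentiable forward pipeline."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(config.seed)
        enc_ch = [config.f * 2**i for i in range(config.l)]
        prev = 1
        for i, ch in enumerate(enc_ch):
            self._add_block(rng, f"enc{i}", prev, ch)
            prev = ch
        bott = config.f * 2**config.l
        self._add_block(rng, "bott0", prev, bott)
        self._add_block(rng, "bott1", bott, bott)
        branches = ["ft"] + (["bulk"] if config.use_bulk else [])
        for name in branches:
            depth = config.l_ft if name == "ft" else config.l_bulk
            prev_d = bott
            for step in range(config.l - depth + 1):
                skip_ch = enc_ch[config.l - 1 - step]
                self._add_block(rng, f"dec_{name}{step}", prev_d + skip_ch, skip_ch)
                prev_d = skip_ch
            # head: zero-initialised 1x1 conv => identity deformation at start
            self.params[f"head_{name}_w"] = Tensor(
                np.zeros((2, prev_d, 1, 1), np.float32), requires_grad=True
            )
            self.params[f"head_{name}_b"] = Tensor(
                np.zeros(2, np.float32), requires_grad=True
            )
        self._smooth_mats: dict[int, np.ndarray] = {}  # 1D smoothing, per size

    def _add_block(self, rng, name, c_in, c_out):
        for j, ci in enumerate((c_in, c_out)):
            w, b = _he_conv(rng, ci, c_out, 3)
            self.params[f"{name}_conv{j}_w"] = w
            self.params[f"{name}_conv{j}_b"] = b
            self.params[f"{name}_in{j}_g"] = Tensor(
                np.ones(c_out, np.float32), requires_grad=True
            )
            self.params[f"{name}_in{j}_b"] = Tensor(
                np.zeros(c_out, np.float32), requires_grad=True
            )

    # -- building blocks ----------------------------------------------
    def _block(self, x: Tensor, name: str) -> Tensor:
        for j in range(2):
            x = ad.conv2d(x, self.params[f"{name}_conv{j}_w"],
                          self.params[f"{name}_conv{j}_b"], pad=1)
            x = ad.instance_norm(x, self.params[f"{name}_in{j}_g"],
                                 self.params[f"{name}_in{j}_b"])
            x = x.relu()
        return x

    def _heads(self, x: Tensor) -> dict[str, Tensor]:
        """Encoder-decoder pass; returns raw 2-channel fields per branch."""
        cfg = self.config
        skips = []
        for i in range(cfg.l):
            x = self._block(x, f"enc{i}")
            skips.append(x)
            x = ad.maxpool2(x)
        x = self._block(x, "bott0")
        x = self._block(x, "bott1")
        raw = {}
        for name in (["ft"] + (["bulk"] if cfg.use_bulk else [])):
            depth = cfg.l_ft if name == "ft" else cfg.l_bulk
            y = x
            for step in range(cfg.l - depth + 1):
                y = ad.upsample_bilinear(y, 2)
                y = ad.concat([y, skips[cfg.l - 1 - step]], axis=1)
                y = self._block(y, f"dec_{name}{step}")
            raw[name] = ad.conv2d(y, self.params[f"head_{name}_w"],
                                  self.params[f"head_{name}_b"], pad=0)
        return raw

    def _smooth_mat(self, size: int) -> np.ndarray:
        """1D replicate-padded Gaussian smoothing as a [size, size] matrix.

        The isotropic k x k kernel is separable, so smoothing is two
        BLAS matmuls; rows sum to 1 exactly like the 2D convolution
        with edge replication.
        """
        if size not in self._smooth_mats:
            cfg = self.config
            half = cfg.k // 2
            ax = np.arange(-half, half + 1, dtype=float)
            k1 = np.exp(-(ax**2) / (2.0 * cfg.sigma**2))
            k1 /= k1.sum()
            S = np.zeros((size, size), dtype=np.float32)
            idx = np.arange(size)
            for off, wgt in zip(range(-half, half + 1), k1):
                S[idx, np.clip(idx + off, 0, size - 1)] += wgt
            self._smooth_mats[size] = S
        return self._smooth_mats[size]

    def _smooth(self, u: Tensor) -> Tensor:
        cfg = self.config
        if cfg.sigma == 0:
            return u
        _, _, h, w = u.data.shape
        return ad.spatial_matmul(self._smooth_mat(h), u, self._smooth_mat(w))

    def _squaring(self, u: Tensor) -> Tensor:
        """Differentiable scaling and squaring with inter-step smoothing."""
        cfg = self.config
        n, _, h, w = u.data.shape
        base_r, base_c = np.meshgrid(
            np.arange(h, dtype=u.data.dtype), np.arange(w, dtype=u.data.dtype),
            indexing="ij",
        )
        base_r = np.broadcast_to(base_r, (n, h, w))
        base_c = np.broadcast_to(base_c, (n, h, w))
        for _ in range(cfg.h):
            rows = u[:, 0] + base_r
            cols = u[:, 1] + base_c
            sampled = ad.grid_sample(u, rows, cols, mode="border")
            u = u + sampled
            u = self._smooth(u)
        return u

    def _pipeline(self, X: np.ndarray, P: np.ndarray) -> dict:
        """Full differentiable forward pass on a batch.

        ``X``: [N, H, W] images in [0, 1]; ``P``: [N, c, H, W] priors.
        Returns tensors for the soft output and both final fields.
        """
        cfg = self.config
        n, H, W = X.shape
        x = Tensor(X[:, None].astype(np.float32))
        raw = self._heads(x)
        fields = {}
        for name, r in raw.items():
            u = r.tanh() * 0.5 if cfg.use_activation else r
            u = self._squaring(u)
            depth = cfg.l_ft if name == "ft" else cfg.l_bulk
            factor = 2 ** depth  # branch scale 1/2**(depth-1) -> 2x input
            if factor > 1:
                u = ad.upsample_bilinear(u, factor) * float(factor)
            fields[name] = u  # [N, 2, 2H, 2W]

        base_r, base_c = np.meshgrid(
            np.arange(2 * H, dtype=np.float32), np.arange(2 * W, dtype=np.float32),
            indexing="ij",
        )
        base_r = np.broadcast_to(base_r, (n, 2 * H, 2 * W))
        base_c = np.broadcast_to(base_c, (n, 2 * H, 2 * W))
        # fine->coarse coordinate conversion follows the voxel-centre
        # convention (x + 0.5)/f - 0.5 so the identity deformation
        # reproduces the prior exactly after downsampling + threshold
        prior = Tensor(P.astype(np.float32))
        if cfg.use_bulk:
            ub = fields["bulk"]
            y = ad.grid_sample(
                prior,
                (ub[:, 0] + base_r + 0.5) * 0.5 - 0.5,
                (ub[:, 1] + base_c + 0.5) * 0.5 - 0.5,
                mode="zeros",
            )
            ft_source = y
            half = False
        else:
            ft_source = prior
            half = True
        uf = fields["ft"]
        rows = uf[:, 0] + base_r
        cols = uf[:, 1] + base_c
        if half:
            rows = (rows + 0.5) * 0.5 - 0.5
            cols = (cols + 0.5) * 0.5 - 0.5
        yhat2 = ad.grid_sample(ft_source, rows, cols, mode="zeros")
        if cfg.downsample_mode == "maxpool":
            soft = ad.maxpool2(yhat2)
        else:
            soft = ad.avgpool2(yhat2)
        return {
            "soft": soft,
            "u_ft": fields["ft"],
            "u_bulk": fields.get("bulk"),
        }

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.asarray(state[k], dtype=p.data.dtype)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.state_dict())
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SegNet":
        path = Path(path)
        config = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(config)
        with np.load(path if path.suffix else path.with_suffix(".npz")) as st:
            model.load_state_dict(dict(st))
        return model


def build_network(config: ModelConfig) -> SegNet:
    """Construct the network with seeded weights and identity heads."""
    return SegNet(config)


def _field_from_tensor(u: np.ndarray) -> DeformationField:
    grid = Grid2D(u.shape[-2], u.shape[-1])
    return DeformationField(DisplacementField(np.asarray(u, dtype=float), grid))


def forward(model: SegNet, X: np.ndarray, P: np.ndarray) -> SegmentationOutput:
    """Segment one image: warp its prior and audit the fields."""
    cfg = model.config
    X = np.asarray(X, dtype=float)
    P = np.asarray(P)
    if P.ndim == 2:
        P = P[None]
    if P.shape[0] != cfg.c:
        raise ValueError(f"prior has {P.shape[0]} channels, config expects {cfg.c}")
    if X.shape != P.shape[-2:]:
        raise ValueError(f"image {X.shape} vs prior {P.shape[-2:]} shape mismatch")
    out = model._pipeline(X[None], P[None])
    soft = np.clip(out["soft"].data[0].astype(float), 0.0, 1.0)
    binary = (soft >= cfg.T).astype(np.uint8)
    phi_ft = _field_from_tensor(out["u_ft"].data[0])
    folding = {"ft": jacobian_determinants(phi_ft)}
    phi_bulk = None
    if out["u_bulk"] is not None:
        phi_bulk = _field_from_tensor(out["u_bulk"].data[0])
        folding["bulk"] = jacobian_determinants(phi_bulk)
    return SegmentationOutput(soft, binary, phi_ft, phi_bulk, folding)


def _batch_loss(model: SegNet, X, Y, P):
    out = model._pipeline(X, P)
    cfg = model.config
    d = dice_loss(Tensor(Y.astype(np.float32)), out["soft"])
    g_ft = grad_loss(out["u_ft"])
    loss = d + cfg.alpha * g_ft
    g_bulk = None
    if out["u_bulk"] is not None:
        g_bulk = grad_loss(out["u_bulk"])
        loss = loss + cfg.beta * g_bulk
    return loss, d, g_ft, g_bulk


def _evaluate_split(model: SegNet, samples, batch: int = 10) -> dict:
    dices, topo, fold = [], [], []
    for start in range(0, len(samples), batch):
        chunk = samples[start:start + batch]
        X = np.stack([s.image for s in chunk])
        P = np.stack([s.prior for s in chunk])
        out = model._pipeline(X, P)
        soft = out["soft"].data
        binary = (soft >= model.config.T).astype(np.uint8)
        for j, s in enumerate(chunk):
            c = s.label.shape[0]
            dices.append(np.mean([dice_score(binary[j, k], s.label[k]) for k in range(c)]))
            topo.append(
                all(betti_2d(binary[j, k]) == betti_2d(s.prior[k]) for k in range(c))
            )
            pct = jacobian_determinants(
                _field_from_tensor(out["u_ft"].data[j])
            ).percent_nonpositive
            if out["u_bulk"] is not None:
                pct = max(
                    pct,
                    jacobian_determinants(
                        _field_from_tensor(out["u_bulk"].data[j])
                    ).percent_nonpositive,
                )
            fold.append(pct)
    return {
        "val_dice": float(np.mean(dices)),
        "val_topology_pct": 100.0 * float(np.mean(topo)),
        "val_max_folding_pct": float(np.max(fold)),
    }


def train(model: SegNet, dataset, config: ModelConfig | None = None,
          verbose: bool = False):
    """Adam training with per-epoch validation bookkeeping.

    ``dataset`` provides ``split("train")`` / ``split("val")`` lists of
    samples carrying ``image``, ``label`` and ``prior``.  Returns the
    model (restored to its best-validation-Dice snapshot) and a
    per-epoch history DataFrame.  Aborts on non-finite loss.
    """
    cfg = config or model.config
    train_samples = dataset.split("train")
    val_samples = dataset.split("val")
    if not train_samples:
        raise ValueError("training split is empty")
    opt = ad.Adam(model.params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    history = []
    best = {"val_dice": -np.inf, "state": model.state_dict()}
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_samples))
        ep = {"loss": 0.0, "dice": 0.0, "grad_ft": 0.0, "grad_bulk": 0.0}
        n_batches = 0
        for start in range(0, len(order), cfg.batch):
            idx = order[start:start + cfg.batch]
            X = np.stack([train_samples[i].image for i in idx])
            Y = np.stack([train_samples[i].label for i in idx])
            P = np.stack([train_samples[i].prior for i in idx])
            loss, d, g_ft, g_bulk = _batch_loss(model, X, Y, P)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite loss at epoch {epoch}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep["loss"] += float(loss.data)
            ep["dice"] += float(d.data)
            ep["grad_ft"] += float(g_ft.data)
            ep["grad_bulk"] += float(g_bulk.data) if g_bulk is not None else 0.0
            n_batches += 1
        row = {"epoch": epoch, **{k: v / n_batches for k, v in ep.items()}}
        if val_samples:
            row.update(_evaluate_split(model, val_samples))
            if row["val_dice"] > best["val_dice"]:
                best = {"val_dice": row["val_dice"], "state": model.state_dict()}
        history.append(row)
        if verbose:
            print(
                f"epoch {epoch:3d}  loss {row['loss']:.4f}  "
                f"val_dice {row.get('val_dice', float('nan')):.4f}  "
                f"val_topo {row.get('val_topology_pct', float('nan')):.1f}%"
            )
    if val_samples and cfg.epochs > 0:
        model.load_state_dict(best["state"])
    return model, pd.DataFrame(history)
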