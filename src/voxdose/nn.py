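"""Learned kernel predictor: density patch -> specific S-value kernel.

A fully convolutional dilated residual network predicts how the specific
S-value kernel of a heterogeneous density patch deviates from the
homogeneous soft-tissue reference kernel.  The regression target is the
sigmoid-normalized log-*ratio* of the specific kernel to the reference:
dividing out the reference removes the fixed four-decade radial falloff
(which a translation-equivariant network cannot represent from a
near-constant input) and leaves the medium-dependent modulation the
density patch actually determines.  The transform is strictly monotone and
exactly invertible, so predictions are mapped back to absolute
depositions at inference.

The architecture follows the dilated-ResNet pattern: 20 convolutional
layers with 3x3x3 windows and a single input/output channel, the first
seven undilated, the next seven with dilation 2, the last six with
dilation 4, LReLU activations, and 9 residual blocks wrapping the 18
interior layers in pairs.

The network is implemented directly on numpy (shift-and-matmul
convolutions with hand-written gradients and an Adam optimizer): the model
is small by design and trains on a CPU in minutes at the reduced "desk"
profile (few channels, a few hundred pairs, cropped patches).  Being fully
convolutional, a model trained on crops predicts full 64^3 patches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .constants import KERNEL_SHAPE, KERNEL_SPACING_MM, SOURCE_INDEX
from .kernels import KernelProvider, material_patch_hash
from .materials import default_material_table
from .volumes import Volume, VoxelKernel

__all__ = ["NormalizationSpec", "ModelSpec", "TrainSpec", "normalize_kernel",
           "denormalize_kernel", "DilatedResNet", "train", "predict",
           "LearnedKernelProvider", "save_model", "load_model"]

_DENSITY_SCALE = 2.0  # input densities divided by this (~max tissue density)


# ---------------------------------------------------------------------------
# Sigmoid intensity normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationSpec:
    """Sigmoid of log deposition: y = sigmoid((log(k + floor) - center)/scale).

    Strictly monotone on [0, inf) hence exactly invertible; ``floor`` keeps
    zero-deposition voxels finite.
    """

    center: float
    scale: float
    floor: float = 1e-12

    def __post_init__(self):
        if self.scale <= 0 or self.floor <= 0:
            raise ValueError("scale and floor must be positive")

    @classmethod
    def fit(cls, kernels, floor_quantile: float = 0.05) -> "NormalizationSpec":
        """Robust fit from the pooled log-deposition distribution.

        center = median, scale = IQR / 2 of log(k + floor) over positive
        voxels; floor = a low quantile of the positive values.
        """
        vals = np.concatenate([
            np.asarray(getattr(k, "deposition", k), dtype=float).ravel()
            for k in kernels])
        pos = vals[vals > 0]
        if pos.size == 0:
            raise ValueError("cannot fit normalization on all-zero kernels")
        floor = float(np.quantile(pos, floor_quantile))
        logv = np.log(vals + floor)
        q1, med, q3 = np.quantile(logv, [0.25, 0.5, 0.75])
        # keep |z| <= ~20 over the whole dynamic range so the sigmoid stays
        # numerically invertible in float64 (no saturation at the source
        # voxel, whose deposition is orders of magnitude above the median)
        span = max(logv.max() - med, med - logv.min(), 1e-6)
        scale = max((q3 - q1) / 2.0, span / 20.0, 1e-6)
        return cls(center=float(med), scale=float(scale), floor=floor)


def normalize_kernel(deposition, spec: NormalizationSpec) -> np.ndarray:
    """Map nonnegative deposition to (0, 1), order-preserving."""
    k = np.asarray(getattr(deposition, "deposition", deposition), dtype=float)
    if np.any(k < 0):
        raise ValueError("deposition must be nonnegative")
    z = (np.log(k + spec.floor) - spec.center) / spec.scale
    return 1.0 / (1.0 + np.exp(-z))


def denormalize_kernel(y, spec: NormalizationSpec) -> np.ndarray:
    """Inverse of :func:`normalize_kernel`; output clamped at 0."""
    y = np.clip(np.asarray(y, dtype=float), 1e-12, 1.0 - 1e-12)
    z = np.log(y / (1.0 - y))
    k = np.exp(z * spec.scale + spec.center) - spec.floor
    return np.clip(k, 0.0, None)


# ---------------------------------------------------------------------------
# Architecture and training configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """20 conv layers, 3^3 windows, dilation 1/2/4 stages, 9 residual blocks."""

    n_layers: int = 20
    window: int = 3
    dilations: tuple = tuple([1] * 7 + [2] * 7 + [4] * 6)
    n_residual_blocks: int = 9
    channels: int = 4          # reduced desk-scale width
    lrelu_slope: float = 0.1

    def __post_init__(self):
        if len(self.dilations) != self.n_layers:
            raise ValueError("one dilation per layer required")
        if self.n_residual_blocks * 2 != self.n_layers - 2:
            raise ValueError("residual blocks must tile the interior layers")


@dataclass
class TrainSpec:
    learning_rate: float = 0.001
    weight_decay: float = 0.0001
    epochs: int = 2
    batch_size: int = 4
    crop: int = 32             # training crop edge (full 64 at inference)
    val_fraction: float = 0.1
    seed: int = 0
    samples_per_volume: int = 1

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


# ---------------------------------------------------------------------------
# Numpy conv net
# ---------------------------------------------------------------------------

@njit(cache=True)
def _conv_fwd_nb(x, w, bias, dil):
    bsz, ci, d, h, wd = x.shape
    co = w.shape[1]
    out = np.empty((bsz, co, d, h, wd), dtype=np.float32)
    for b in range(bsz):
        for o in range(co):
            out[b, o, :, :, :] = bias[o]
    for k in range(27):
        oz = ((k // 9) - 1) * dil
        oy = (((k // 3) % 3) - 1) * dil
        ox = ((k % 3) - 1) * dil
        zlo = max(0, oz)
        zhi = min(d, d + oz)
        ylo = max(0, oy)
        yhi = min(h, h + oy)
        xlo = max(0, ox)
        xhi = min(wd, wd + ox)
        for b in range(bsz):
            for z in range(zlo, zhi):
                for y in range(ylo, yhi):
                    for o in range(co):
                        for i in range(ci):
                            wk = w[k, o, i]
                            if wk == 0.0:
                                continue
                            for xx in range(xlo, xhi):
                                out[b, o, z, y, xx] += \
                                    wk * x[b, i, z - oz, y - oy, xx - ox]
    return out


@njit(cache=True)
def _conv_bwd_nb(x, dy, w, dil, need_dx):
    bsz, ci, d, h, wd = x.shape
    co = w.shape[1]
    dw = np.zeros_like(w)
    dx = np.zeros_like(x)
    for k in range(27):
        oz = ((k // 9) - 1) * dil
        oy = (((k // 3) % 3) - 1) * dil
        ox = ((k % 3) - 1) * dil
        zlo = max(0, oz)
        zhi = min(d, d + oz)
        ylo = max(0, oy)
        yhi = min(h, h + oy)
        xlo = max(0, ox)
        xhi = min(wd, wd + ox)
        for b in range(bsz):
            for z in range(zlo, zhi):
                for y in range(ylo, yhi):
                    for o in range(co):
                        for i in range(ci):
                            acc = np.float32(0.0)
                            wk = w[k, o, i]
                            if need_dx and wk != 0.0:
                                for xx in range(xlo, xhi):
                                    g = dy[b, o, z, y, xx]
                                    acc += g * x[b, i, z - oz, y - oy,
                                                 xx - ox]
                                    dx[b, i, z - oz, y - oy, xx - ox] += \
                                        wk * g
                            else:
                                for xx in range(xlo, xhi):
                                    acc += dy[b, o, z, y, xx] * \
                                        x[b, i, z - oz, y - oy, xx - ox]
                            dw[k, o, i] += acc
    return dw, dx


class _Conv3d:
    """Same-padded 3x3x3 convolution with dilation (numba inner loops).

    Compute runs in float32 (ample for this regression); parameters and
    Adam state stay float64.  Deterministic and single-threaded.
    """

    def __init__(self, c_in, c_out, dilation, rng):
        fan_in = c_in * 27
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(27, c_out, c_in))
        self.b = np.zeros(c_out)
        self.dilation = int(dilation)
        self._x = None
        self.need_dx = True

    def forward(self, x, keep=True):
        x = np.ascontiguousarray(x, dtype=np.float32)
        if keep:
            self._x = x
        return _conv_fwd_nb(x, self.w.astype(np.float32),
                            self.b.astype(np.float32), self.dilation)

    def backward(self, dy):
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        self.db = dy.sum(axis=(0, 2, 3, 4)).astype(np.float64)
        dw, dx = _conv_bwd_nb(self._x, dy, self.w.astype(np.float32),
                              self.dilation, self.need_dx)
        self.dw = dw.astype(np.float64)
        return dx

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


def _lrelu(x, slope):
    return np.where(x > 0, x, slope * x)


def _lrelu_grad(x, slope):
    return np.where(x > 0, 1.0, slope)


class DilatedResNet:
    """The 20-layer dilated residual regression network (single in/out channel)."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        c = spec.channels
        dil = spec.dilations
        self.layers = [_Conv3d(1, c, dil[0], rng)]
        for i in range(1, spec.n_layers - 1):
            self.layers.append(_Conv3d(c, c, dil[i], rng))
        self.layers.append(_Conv3d(c, 1, dil[-1], rng))
        # zero-init each block's second conv and the output layer: the
        # residual stack starts as an identity-like map and the output at
        # zero, which keeps early training stable at this depth
        for i in range(2, spec.n_layers - 1, 2):
            self.layers[i].w[:] = 0.0
        self.layers[-1].w[:] = 0.0
        self.layers[0].need_dx = False  # input gradient is never used
        self._adam = None

    # -- introspection -----------------------------------------------------
    @property
    def n_layers(self):
        return len(self.layers)

    def parameter_count(self):
        return sum(p.size for layer in self.layers
                   for _, p, _ in [("w", layer.w, None), ("b", layer.b, None)])

    # -- forward / backward ------------------------------------------------
    def forward(self, x, keep=False):
        """x: (B, 1, D, H, W) normalized density; returns (B, 1, D, H, W)."""
        s = self.spec.lrelu_slope
        self._pre = []     # pre-activation caches for backward
        self._skips = []
        h = self.layers[0].forward(x, keep)
        self._pre.append(h)
        h = _lrelu(h, s)
        li = 1
        for _ in range(self.spec.n_residual_blocks):
            skip = h
            a = self.layers[li].forward(h, keep)
            self._pre.append(a)
            a = _lrelu(a, s)
            b = self.layers[li + 1].forward(a, keep)
            self._pre.append(b)
            h = skip + _lrelu(b, s)
            if keep:
                self._skips.append(skip)
            li += 2
        out = self.layers[li].forward(h, keep)
        return out

    def backward(self, dout):
        s = self.spec.lrelu_slope
        li = len(self.layers) - 1
        dh = self.layers[li].backward(dout)
        li -= 1
        pre = self._pre
        pi = len(pre) - 1
        for _ in range(self.spec.n_residual_blocks):
            db = dh * _lrelu_grad(pre[pi], s)
            pi -= 1
            da = self.layers[li].backward(db)
            li -= 1
            da = da * _lrelu_grad(pre[pi], s)
            pi -= 1
            dskip = self.layers[li].backward(da)
            li -= 1
            dh = dh + dskip
        d0 = dh * _lrelu_grad(pre[0], s)
        return self.layers[0].backward(d0)

    # -- optimizer ---------------------------------------------------------
    def adam_step(self, lr, weight_decay, t):
        if self._adam is None:
            self._adam = [
                [(np.zeros_like(p), np.zeros_like(p))
                 for _, p, _ in layer.params()]
                for layer in self.layers]
        b1, b2, eps = 0.9, 0.999, 1e-8
        for layer, states in zip(self.layers, self._adam):
            for (name, p, g), (m, v) in zip(layer.params(), states):
                if name == "w" and weight_decay:
                    g = g + weight_decay * p
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                mhat = m / (1 - b1**t)
                vhat = v / (1 - b2**t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)


# ---------------------------------------------------------------------------
# Training / inference
# ---------------------------------------------------------------------------

@dataclass
class LearnedModel:
    """Trained network plus its normalization; the learned-kernel handle.

    ``reference`` is the homogeneous soft-tissue kernel the network's
    log-ratio targets are defined against; ``ref_floor`` is the additive
    floor used when forming ratios (keeps zero voxels finite).
    """

    net: DilatedResNet
    norm: NormalizationSpec
    model_spec: ModelSpec
    train_spec: TrainSpec
    reference: np.ndarray | None = None
    ref_floor: float = 1e-12
    ratio_range: tuple | None = None   # clip band for predicted ratios
    loss_history: list = field(default_factory=list)
    val_loss: tuple | None = None   # (initial, final)


def _center_crop(arr: np.ndarray, crop: int) -> np.ndarray:
    sl = []
    for n in arr.shape:
        lo = n // 2 - crop // 2
        sl.append(slice(lo, lo + crop))
    return arr[tuple(sl)]


def _as_pair(patch, kernel, crop):
    p = np.asarray(getattr(patch, "data", patch), dtype=float)
    k = np.asarray(getattr(kernel, "deposition", kernel), dtype=float)
    if p.shape != k.shape:
        raise ValueError("patch and kernel shapes differ")
    if crop and crop < p.shape[0]:
        p = _center_crop(p, crop)
        k = _center_crop(k, crop)
    return p, k


def train(pairs, model: ModelSpec | None = None,
          spec: TrainSpec | None = None,
          reference=None) -> tuple[LearnedModel, list]:
    """Train the kernel predictor on (density patch, kernel) pairs.

    Targets are the sigmoid-normalized log-ratios of each kernel to the
    homogeneous soft-tissue ``reference`` kernel (simulated on the fly when
    not given).  Pairs are split train/validation by a content hash of the
    density patch (seed-independent membership); the L2 loss is minimized
    with Adam.  Returns (model handle, loss history).
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 training pairs")
    model = model or ModelSpec()
    spec = spec or TrainSpec()
    rng = np.random.default_rng(spec.seed)

    if reference is None:
        from .kernels import build_homogeneous_kernel
        from .phantoms import SOFT_TISSUE
        reference = build_homogeneous_kernel(SOFT_TISSUE, 100_000,
                                             seed=spec.seed,
                                             boundary="vacuum", n_batches=2)
    ref_dep = np.asarray(getattr(reference, "deposition", reference),
                         dtype=float)

    pooled = np.concatenate([
        np.asarray(getattr(k, "deposition", k), dtype=float).ravel()
        for _, k in pairs])
    pos = pooled[pooled > 0]
    if pos.size == 0:
        raise ValueError("cannot train on all-zero kernels")
    ref_floor = float(np.quantile(pos, 0.05))

    data = [_as_pair(p, k, spec.crop) for p, k in pairs]
    ref_crop = (_center_crop(ref_dep, spec.crop)
                if spec.crop and spec.crop < ref_dep.shape[0] else ref_dep)
    ratios = [(k + ref_floor) / (ref_crop + ref_floor) for _, k in data]
    norm = NormalizationSpec.fit(ratios)
    pooled_ratios = np.concatenate([r.ravel() for r in ratios])
    ratio_range = (float(np.quantile(pooled_ratios, 1e-4)),
                   float(np.quantile(pooled_ratios, 1 - 1e-4)))
    xs = np.stack([p for p, _ in data])[:, None] / _DENSITY_SCALE
    ys = np.stack([normalize_kernel(r, norm) for r in ratios])[:, None]

    hashes = [material_patch_hash(
        default_material_table().classify_material(p).astype(np.uint8))
        for p, _ in data]
    order = np.argsort(hashes)
    n_val = max(1, int(round(spec.val_fraction * len(pairs))))
    val_idx = order[:n_val]
    trn_idx = order[n_val:]
    if trn_idx.size == 0:
        trn_idx, val_idx = val_idx, val_idx

    net = DilatedResNet(model, seed=spec.seed)

    val_eval = val_idx[:8]  # bound the cost of the loss probes

    def val_loss():
        tot = 0.0
        for i in val_eval:
            out = net.forward(xs[i:i + 1], keep=False)
            tot += float(np.mean((out - ys[i:i + 1]) ** 2))
        return tot / len(val_eval)

    v0 = val_loss()
    history = []
    t = 0
    for _ in range(spec.epochs):
        perm = rng.permutation(trn_idx)
        for lo in range(0, perm.size, spec.batch_size):
            idx = perm[lo:lo + spec.batch_size]
            xb = xs[idx]
            yb = ys[idx]
            out = net.forward(xb, keep=True)
            err = out - yb
            loss = float(np.mean(err**2))
            net.backward(2.0 * err / err.size)
            t += 1
            net.adam_step(spec.learning_rate, spec.weight_decay, t)
            history.append(loss)
    v1 = val_loss()
    handle = LearnedModel(net=net, norm=norm, model_spec=model,
                          train_spec=spec, reference=ref_dep,
                          ref_floor=ref_floor, ratio_range=ratio_range,
                          loss_history=history, val_loss=(v0, v1))
    return handle, history


def predict(model: LearnedModel, patch: Volume) -> VoxelKernel:
    """Predict the specific S-value kernel of a density patch."""
    if model is None or model.net is None:
        raise ValueError("model is not trained")
    if model.reference is None:
        raise ValueError("model lacks its reference kernel")
    p = np.asarray(getattr(patch, "data", patch), dtype=float)
    x = p[None, None] / _DENSITY_SCALE
    y = model.net.forward(x, keep=False)[0, 0]
    ratio = denormalize_kernel(y, model.norm)
    if model.ratio_range is not None:
        # never extrapolate beyond the modulation range seen in training
        ratio = np.clip(ratio, model.ratio_range[0], model.ratio_range[1])
    ref = model.reference
    if ref.shape != p.shape:
        ref = _center_crop(ref, p.shape[0]) if p.shape[0] < ref.shape[0] \
            else ref
        if ref.shape != p.shape:
            raise ValueError("patch larger than the reference kernel")
    dep = np.clip(ratio * (ref + model.ref_floor) - model.ref_floor,
                  0.0, None)
    src = tuple(n // 2 for n in p.shape)
    return VoxelKernel(deposition=dep, spacing_mm=KERNEL_SPACING_MM,
                       source_index=src, histories=0, medium="predicted",
                       provenance="learned")


@dataclass
class LearnedKernelProvider(KernelProvider):
    """Kernel provider backed by a trained model (cached, deterministic)."""

    model: LearnedModel = None
    _cache: dict = field(default_factory=dict, repr=False)
    mode = "learned"
    needs_reciprocity_correction = True

    def kernel_for(self, patch: Volume) -> VoxelKernel:
        if self.model is None:
            raise ValueError("learned provider has no trained model/weights")
        mats = default_material_table().classify_material(
            patch.data).astype(np.uint8)
        key = material_patch_hash(mats)
        if key not in self._cache:
            self._cache[key] = predict(self.model, patch)
        return self._cache[key]


def synthesize_training_pairs(n_pairs: int = 200, histories: int = 10_000,
                              seed: int = 0, phantom_shape=(64, 64, 64),
                              homogeneous_fraction: float = 0.12):
    """(density patch, MC kernel) pairs sampled from synthetic torso phantoms.

    Source voxels are drawn uniformly from the body of seeded torso
    phantoms (several geometry seeds for diversity); each 64^3 patch is
    simulated with the Monte Carlo engine at the given history count.  A
    small fraction of pairs are fully homogeneous single-medium patches
    (the degenerate cases the per-medium kernel libraries cover), so
    uniform media lie inside the training distribution.  Deterministic for
    a fixed seed.
    """
    from .kernels import homogeneous_patch
    from .phantoms import (ADIPOSE, CORTICAL_BONE, LUNG, SOFT_TISSUE,
                           TRABECULAR_BONE, PhantomSpec, extract_patch,
                           generate_phantom)
    from .transport import simulate_kernel
    from .volumes import Volume

    rng = np.random.default_rng(seed)
    pairs = []

    n_hom = int(round(homogeneous_fraction * n_pairs))
    media = [SOFT_TISSUE, LUNG, ADIPOSE, TRABECULAR_BONE, CORTICAL_BONE]
    for j in range(n_hom):
        mid = media[j % len(media)]
        patch = homogeneous_patch(mid)
        mats = Volume(np.full(patch.shape, mid, dtype=np.uint8),
                      patch.spacing_mm)
        kernel = simulate_kernel(patch, histories,
                                 seed=int(rng.integers(2**31 - 1)),
                                 materials=mats, n_batches=1)
        pairs.append((patch, kernel))

    n_anat = n_pairs - n_hom
    n_phantoms = max(1, min(4, n_anat // 50))
    for pi in range(n_phantoms):
        spec = PhantomSpec.default_torso(phantom_shape)
        density, materials = generate_phantom(spec, seed=seed + 101 * pi)
        body = np.argwhere(materials.data > 0)
        need = (n_anat // n_phantoms
                + (1 if pi < n_anat % n_phantoms else 0))
        picks = body[rng.choice(body.shape[0], size=need, replace=False)]
        for c in picks:
            patch = extract_patch(density, tuple(int(v) for v in c))
            kernel = simulate_kernel(patch, histories,
                                     seed=int(rng.integers(2**31 - 1)),
                                     n_batches=1)
            pairs.append((patch, kernel))
    return pairs


# ---------------------------------------------------------------------------
# Serialization (weights + normalization in one npz)
# ---------------------------------------------------------------------------

def save_model(model: LearnedModel, path):
    arrays = {}
    for i, layer in enumerate(model.net.layers):
        arrays[f"w{i}"] = layer.w
        arrays[f"b{i}"] = layer.b
    if model.reference is not None:
        arrays["reference"] = model.reference
    meta = {
        "norm": asdict(model.norm),
        "model_spec": {**asdict(model.model_spec),
                       "dilations": list(model.model_spec.dilations)},
        "train_spec": asdict(model.train_spec),
        "ref_floor": model.ref_floor,
        "ratio_range": (list(model.ratio_range)
                        if model.ratio_range is not None else None),
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_model(path) -> LearnedModel:
    with np.load(path) as f:
        meta = json.loads(bytes(f["meta"]).decode())
        mspec = ModelSpec(**{**meta["model_spec"],
                             "dilations": tuple(meta["model_spec"]["dilations"])})
        net = DilatedResNet(mspec, seed=0)
        for i, layer in enumerate(net.layers):
            layer.w = f[f"w{i}"]
            layer.b = f[f"b{i}"]
        reference = f["reference"] if "reference" in f else None
        if reference is not None:
            reference = np.array(reference)
    return LearnedModel(net=net, norm=NormalizationSpec(**meta["norm"]),
                        model_spec=mspec,
                        train_spec=TrainSpec(**meta["train_spec"]),
                        reference=reference,
                        ref_floor=float(meta.get("ref_floor", 1e-12)),
                        ratio_range=(tuple(meta["ratio_range"])
                                     if meta.get("ratio_range") else None))
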