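"""Characteristic-prediction CNN with class-activation attention supervision.

The classifier has two cooperating parts sharing one convolutional
backbone: a classification head that predicts each catalogue
characteristic with an independent sigmoid (multi-label), and an
attention part that produces one class-activation map (CAM) per
characteristic from the final convolutional stage. During training the
CAMs are pushed toward the expert-annotated regions of interest with a
soft Dice loss

    L_A = (1/N) sum_i ( 1 - (1/C) sum_c 2*sum(A_ic * H_ic) /
                                       (sum(A_ic) + sum(H_ic) + eps) )

where ``A`` is the min-max normalised, bilinearly upsampled CAM and ``H``
the ground-truth mask (an all-zero matrix for absent characteristics).
The training objective is ``L = lambda_C * L_C + lambda_A * L_A`` with
``L_C`` the mean per-characteristic binary cross-entropy. A *baseline*
mode trains a single-output diagnosis head with cross-entropy only and no
attention supervision.

For a backbone ending in global average pooling followed by a linear
head, Grad-CAM computed on the logits coincides with the plain CAM
(weighted sum of final feature maps) up to a positive factor, so the
differentiable CAM form is used in the training loss and standard
Grad-CAM at inference; both agree after normalisation.

Everything is implemented directly on NumPy arrays — im2col convolutions
with hand-written backward passes and an Adam optimiser — so the
attention supervision is differentiable end to end without an external
autodiff framework.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from dermxai.ontology import DiagnosisClass, Ontology
from dermxai.synthetic import DatasetBundle
from dermxai import augment as _augment

EPS_LOSS = 1e-6  # smoothing in the Dice denominator
_EPS_NORM = 1e-12


class ModelConfigError(ValueError):
    pass


#: the full printed augmentation list used on the real data; the desk-scale
#: experiments use :data:`LIGHT_AUGMENTATION` instead (geometry-only)
DEFAULT_AUGMENTATION = (
    {"name": "transpose", "p": 0.2},
    {"name": "vertical_flip", "p": 0.5},
    {"name": "horizontal_flip", "p": 0.5},
    {"name": "color_jitter", "p": 0.5},
    {"name": "clahe", "p": 0.7, "clip_limit": 4.0},
    {
        "name": "hue_saturation_value",
        "p": 0.5,
        "hue_shift_limit": 10,
        "sat_shift_limit": 20,
        "val_shift_limit": 10,
    },
    {
        "name": "shift_scale_rotate",
        "p": 0.85,
        "shift_limit": 0.1,
        "scale_limit": 0.1,
        "rotate_limit": 15,
    },
    {"name": "resize"},
    {"name": "normalize"},
)

LIGHT_AUGMENTATION = (
    {"name": "transpose", "p": 0.2},
    {"name": "vertical_flip", "p": 0.5},
    {"name": "horizontal_flip", "p": 0.5},
    {"name": "resize"},
    {"name": "normalize"},
)


@dataclass
class ModelConfig:
    """Hyperparameters; defaults are the reference training settings."""

    backbone: str = "tiny_cnn"
    n_outputs: int | None = None  # None: inferred from the bundle / mode
    lambda_C: float = 1.0
    lambda_A: float = 10.0
    dropout: float = 0.4
    learning_rate: float = 1e-4
    adam_epsilon: float = 1e-8
    batch_size: int = 32
    lr_decay: float = 1.0  # multiplicative per-epoch decay (1.0 = constant)
    epochs: int | None = None  # None: 30 in xai mode, 25 in baseline mode
    image_size: tuple = (224, 224)
    seed: int = 42
    balanced_sampling: bool = True
    augmentation: tuple = DEFAULT_AUGMENTATION
    detection_threshold: float = 0.5
    select_best: bool = True  # restore the best-validation-epoch weights

    def validate(self) -> None:
        if self.lambda_C < 0 or self.lambda_A < 0:
            raise ModelConfigError("lambda_C and lambda_A must be >= 0")
        if self.n_outputs is not None and self.n_outputs < 1:
            raise ModelConfigError("n_outputs must be >= 1")
        if self.backbone != "tiny_cnn":
            raise ModelConfigError(
                f"backbone {self.backbone!r} is not available in this build; "
                "the numpy implementation provides 'tiny_cnn'"
            )

    def resolved_epochs(self, mode: str) -> int:
        if self.epochs is not None:
            return self.epochs
        return 30 if mode == "xai" else 25

    def to_json(self) -> str:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        d["augmentation"] = [dict(a) for a in self.augmentation]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        d["image_size"] = tuple(d["image_size"])
        d["augmentation"] = tuple(d["augmentation"])
        return cls(**d)


@dataclass
class AttentionMap:
    """Normalised per-class attention over the full image grid."""

    values: np.ndarray  # (H, W) in [0, 1]
    class_id: int
    source_layer: str = "conv4"


@dataclass
class RawPrediction:
    """Per-characteristic scores and attention for one image."""

    scores: np.ndarray  # (C,) sigmoid probabilities
    logits: np.ndarray  # (C,)
    attention: list  # list[AttentionMap], one per output class


# ---------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class _Conv2d:
    def __init__(self, cin, cout, rng, k=3, stride=1):
        self.k, self.stride, self.cin, self.cout = k, stride, cin, cout
        self.W = _he_init(rng, (cout, cin * k * k), cin * k * k)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        k, s = self.k, self.stride
        pad = k // 2
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        v = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = v.shape[2], v.shape[3]
        cols = np.ascontiguousarray(v.transpose(0, 1, 4, 5, 2, 3)).reshape(
            n, c * k * k, ho * wo
        )
        out = (self.W @ cols + self.b[None, :, None]).reshape(n, self.cout, ho, wo)
        self._cache = (cols, x.shape, ho, wo)
        return out

    def backward(self, dout):
        cols, xshape, ho, wo = self._cache
        n, c, h, w = xshape
        k, s = self.k, self.stride
        pad = k // 2
        dflat = dout.reshape(n, self.cout, ho * wo)
        self.dW += np.einsum("nol,nkl->ok", dflat, cols, optimize=True)
        self.db += dflat.sum(axis=(0, 2))
        dcols = np.einsum("ok,nol->nkl", self.W, dflat, optimize=True)
        dcols = dcols.reshape(n, c, k, k, ho, wo)
        dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
        return dxp[:, :, pad : pad + h, pad : pad + w]

    def params(self, prefix):
        return {f"{prefix}.W": (self.W, self.dW), f"{prefix}.b": (self.b, self.db)}


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


def _bilinear_matrix(dst, src):
    """(dst, src) interpolation matrix with pixel-centre alignment."""
    U = np.zeros((dst, src), dtype=np.float32)
    pos = (np.arange(dst) + 0.5) * src / dst - 0.5
    lo = np.floor(pos).astype(int)
    t = pos - lo
    lo0 = np.clip(lo, 0, src - 1)
    lo1 = np.clip(lo + 1, 0, src - 1)
    U[np.arange(dst), lo0] += 1.0 - t
    U[np.arange(dst), lo1] += t
    return U


class TinyCNN:
    """Four conv blocks -> GAP -> dropout -> linear head.

    Strides 2,2,2,1 reduce the image by 8x; the final convolutional stage
    feeds both the classification head (through global average pooling)
    and the class-activation attention maps.
    """

    FINAL_LAYER = "conv4"

    def __init__(self, config: ModelConfig, n_outputs: int, rng=None):
        config.validate()
        rng = rng or np.random.default_rng(config.seed)
        self.config = config
        self.n_outputs = n_outputs
        ch = (3, 16, 32, 64, 64)
        strides = (2, 2, 2, 1)
        self.convs = [
            _Conv2d(ch[i], ch[i + 1], rng, stride=strides[i]) for i in range(4)
        ]
        self.relus = [_ReLU() for _ in range(4)]
        self.K = ch[-1]
        self.head_W = _he_init(rng, (n_outputs, self.K), self.K)
        self.head_b = np.zeros(n_outputs, dtype=np.float32)
        self.d_head_W = np.zeros_like(self.head_W)
        self.d_head_b = np.zeros_like(self.head_b)
        self._up_cache = {}

    # -- forward -------------------------------------------------------
    def features(self, x):
        """x: (N, 3, H, W) in [0,1] -> final feature maps (N, K, h, w)."""
        z = (x - 0.5).astype(np.float32)
        for conv, relu in zip(self.convs, self.relus):
            z = relu.forward(conv.forward(z))
        return z

    def head(self, feats, train=False, rng=None):
        """GAP + dropout + linear; returns (logits, pooled, drop_mask)."""
        pooled = feats.mean(axis=(2, 3))
        mask = None
        h = pooled
        p = self.config.dropout
        if train and p > 0:
            mask = (rng.uniform(size=pooled.shape) >= p).astype(np.float32) / (1 - p)
            h = pooled * mask
        logits = h @ self.head_W.T + self.head_b
        return logits, pooled, mask

    def _upsampler(self, hw_src, hw_dst):
        key = (hw_src, hw_dst)
        if key not in self._up_cache:
            self._up_cache[key] = (
                _bilinear_matrix(hw_dst[0], hw_src[0]),
                _bilinear_matrix(hw_dst[1], hw_src[1]),
            )
        return self._up_cache[key]

    def cams(self, feats, image_hw):
        """Normalised, upsampled CAMs plus the cache needed for backward."""
        raw = np.einsum("ck,nkhw->nchw", self.head_W, feats, optimize=True)
        pos = raw > 0
        relu = raw * pos
        scale = relu.max(axis=(2, 3), keepdims=True)  # treated as constant
        norm = relu / np.maximum(scale, _EPS_NORM)
        Uh, Uw = self._upsampler(relu.shape[2:], tuple(image_hw))
        up = np.einsum("Hh,nchw,Ww->ncHW", Uh, norm, Uw, optimize=True)
        cache = (feats, pos, scale, Uh, Uw)
        return up, cache

    def cams_backward(self, d_up, cache):
        """Backprop through upsample + normalisation + ReLU + weighting."""
        feats, pos, scale, Uh, Uw = cache
        d_norm = np.einsum("Hh,ncHW,Ww->nchw", Uh, d_up, Uw, optimize=True)
        d_raw = d_norm / np.maximum(scale, _EPS_NORM) * pos
        self.d_head_W += np.einsum("nchw,nkhw->ck", d_raw, feats, optimize=True)
        d_feats = np.einsum("ck,nchw->nkhw", self.head_W, d_raw, optimize=True)
        return d_feats

    def backbone_backward(self, d_feats):
        g = d_feats
        for conv, relu in zip(reversed(self.convs), reversed(self.relus)):
            g = conv.backward(relu.backward(g))
        return g

    # -- parameters -----------------------------------------------------
    def parameters(self):
        out = {}
        for i, conv in enumerate(self.convs):
            out.update(conv.params(f"conv{i + 1}"))
        out["head.W"] = (self.head_W, self.d_head_W)
        out["head.b"] = (self.head_b, self.d_head_b)
        return out

    def zero_grad(self):
        for _, (p, g) in self.parameters().items():
            g[...] = 0.0

    # -- persistence ------------------------------------------------------
    def save(self, path):
        arrays = {name: p for name, (p, _) in self.parameters().items()}
        arrays = {k.replace(".", "__"): v for k, v in arrays.items()}
        np.savez(
            path,
            __config__=np.frombuffer(self.config.to_json().encode(), dtype=np.uint8),
            __n_outputs__=np.array([self.n_outputs]),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "TinyCNN":
        data = np.load(path)
        config = ModelConfig.from_json(bytes(data["__config__"]).decode())
        model = cls(config, int(data["__n_outputs__"][0]))
        for name, (p, _) in model.parameters().items():
            p[...] = data[name.replace(".", "__")]
        return model


# ---------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------


def binary_cross_entropy(logits, labels):
    """Mean per-characteristic BCE on logits (numerically stable)."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if z.shape != y.shape:
        raise ValueError("logit/label shape mismatch")
    return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))


def attention_loss(attention_batch, target_masks, eps: float = EPS_LOSS) -> float:
    """Mean (over samples) of one minus the mean per-class soft Dice.

    ``attention_batch`` and ``target_masks`` are (N, C, H, W); absent
    characteristics use all-zero target masks. The value lies in [0, 1].
    """
    A = np.asarray(attention_batch, dtype=np.float64)
    H = np.asarray(target_masks, dtype=np.float64)
    if A.shape != H.shape or A.ndim != 4:
        raise ValueError(f"shape mismatch: {A.shape} vs {H.shape}")
    inter = (A * H).sum(axis=(2, 3))
    denom = A.sum(axis=(2, 3)) + H.sum(axis=(2, 3)) + eps
    dice = 2.0 * inter / denom
    return float(np.mean(1.0 - dice.mean(axis=1)))


def _attention_loss_grad(A, H, eps=EPS_LOSS):
    """dL_A/dA for the soft Dice attention loss."""
    n, c = A.shape[:2]
    inter = (A * H).sum(axis=(2, 3), keepdims=True)
    denom = A.sum(axis=(2, 3), keepdims=True) + H.sum(axis=(2, 3), keepdims=True) + eps
    return -(2.0 * H * denom - 2.0 * inter) / (denom**2) / (n * c)


def combined_loss(logits, labels, attention_batch, target_masks, config: ModelConfig):
    """lambda_C * L_C + lambda_A * L_A."""
    config.validate()
    lc = binary_cross_entropy(logits, labels)
    la = attention_loss(attention_batch, target_masks)
    return config.lambda_C * lc + config.lambda_A * la


# ---------------------------------------------------------------------
# training
# ---------------------------------------------------------------------


class _Adam:
    def __init__(self, params, lr, eps=1e-8, beta1=0.9, beta2=0.999):
        self.lr, self.eps, self.b1, self.b2 = lr, eps, beta1, beta2
        self.m = {k: np.zeros_like(p) for k, (p, _) in params.items()}
        self.v = {k: np.zeros_like(p) for k, (p, _) in params.items()}
        self.t = 0

    def step(self, params):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, (p, g) in params.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _batch_arrays(samples, ontology, image_hw, mode, rng=None, augmentation=None):
    """Images (N,3,H,W), targets, and (xai only) mask stacks for a batch."""
    xs, ys, ms = [], [], []
    for s in samples:
        img = s.image
        masks = s.mask_stack(ontology) if mode == "xai" else None
        if augmentation is not None:
            img, masks = _augment.apply_pipeline(img, masks, augmentation, image_hw, rng)
        elif img.shape[:2] != tuple(image_hw):
            img, masks = _augment.apply_pipeline(img, masks, ({"name": "resize"},), image_hw, rng)
        xs.append(np.moveaxis(img, -1, 0))
        if mode == "xai":
            ys.append(s.labels.astype(np.float32))
            ms.append((masks > 0.5).astype(np.float32))
        else:
            ys.append(np.array([1.0 if s.diagnosis is DiagnosisClass.MELANOMA else 0.0], dtype=np.float32))
    x = np.stack(xs).astype(np.float32)
    y = np.stack(ys)
    m = np.stack(ms) if mode == "xai" else None
    return x, y, m


def loss_and_grads(model: TinyCNN, x, y, masks, mode: str, train=True, rng=None):
    """One forward/backward pass; returns (L_C, L_A) with grads accumulated."""
    cfg = model.config
    model.zero_grad()
    feats = model.features(x)
    logits, pooled, drop = model.head(feats, train=train, rng=rng)

    # classification gradient
    z = logits.astype(np.float64)
    probs = 1.0 / (1.0 + np.exp(-z))
    lc = binary_cross_entropy(logits, y)
    dlogits = ((probs - y) / y.size).astype(np.float32)

    la = 0.0
    d_feats_cam = 0.0
    if mode == "xai" and cfg.lambda_A > 0:
        cams, cache = model.cams(feats, x.shape[2:])
        la = attention_loss(cams, masks)
        d_up = (_attention_loss_grad(cams, masks) * cfg.lambda_A).astype(np.float32)
        d_feats_cam = model.cams_backward(d_up, cache)

    # head backward
    dlogits = dlogits * cfg.lambda_C
    h = pooled * drop if (train and drop is not None) else pooled
    model.d_head_W += dlogits.T @ h
    model.d_head_b += dlogits.sum(axis=0)
    d_h = dlogits @ model.head_W
    if train and drop is not None:
        d_h = d_h * drop
    n, k = pooled.shape
    hw = feats.shape[2] * feats.shape[3]
    d_feats = d_h[:, :, None, None] / hw * np.ones_like(feats)
    if mode == "xai" and cfg.lambda_A > 0:
        d_feats = d_feats + d_feats_cam
    model.backbone_backward(d_feats.astype(np.float32))
    return lc, la


def _val_balanced_accuracy(model, bundle, mode, image_hw, threshold):
    from dermxai.decision import infer_diagnosis, DetectionSet

    val = bundle.split("val")
    if not val:
        return float("nan")
    truth, pred = [], []
    for i in range(0, len(val), 32):
        chunk = val[i : i + 32]
        x, _, _ = _batch_arrays(chunk, bundle.ontology, image_hw, "baseline")
        feats = model.features(x)
        logits, _, _ = model.head(feats, train=False)
        scores = 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
        for s, row in zip(chunk, scores):
            truth.append(s.diagnosis is DiagnosisClass.MELANOMA)
            if mode == "baseline":
                pred.append(row[0] >= 0.5)
            else:
                det = DetectionSet(
                    detected={
                        bundle.ontology.ids[j]
                        for j in range(len(row))
                        if row[j] >= threshold
                    },
                    detection_threshold=threshold,
                )
                pred.append(
                    infer_diagnosis(det, bundle.ontology) is DiagnosisClass.MELANOMA
                )
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    recalls = []
    for cls in (True, False):
        sel = truth == cls
        if sel.any():
            recalls.append(float((pred[sel] == cls).mean()))
    return float(np.mean(recalls))


def train_model(bundle: DatasetBundle, config: ModelConfig, mode: str = "xai"):
    """Train the characteristic classifier (xai) or the diagnosis baseline.

    Returns ``(model, history)`` where ``history`` is one dict per epoch
    with the mean classification loss, mean attention loss and validation
    balanced accuracy. Training is fully reproducible from ``config.seed``.
    """
    if mode not in ("xai", "baseline"):
        raise ValueError("mode must be 'xai' or 'baseline'")
    config.validate()
    train = bundle.split("train")
    val = bundle.split("val")
    if not train or not val:
        raise ValueError("bundle needs nonempty train and val splits")
    n_out = config.n_outputs
    if mode == "xai":
        if n_out is None:
            n_out = bundle.C
        elif n_out != bundle.C:
            raise ModelConfigError(
                f"n_outputs={n_out} does not match bundle criterion count {bundle.C}"
            )
    else:
        n_out = 1

    rng = np.random.default_rng(config.seed)
    model = TinyCNN(config, n_out, rng=rng)
    opt = _Adam(model.parameters(), config.learning_rate, eps=config.adam_epsilon)

    # balanced sampling: oversample the minority diagnosis
    is_mel = np.array([s.diagnosis is DiagnosisClass.MELANOMA for s in train])
    if config.balanced_sampling and 0 < is_mel.sum() < len(train):
        wts = np.where(is_mel, 0.5 / is_mel.sum(), 0.5 / (~is_mel).sum())
        wts = wts / wts.sum()
    else:
        wts = np.full(len(train), 1.0 / len(train))

    image_hw = tuple(config.image_size)
    history = []
    best = None
    for epoch in range(config.resolved_epochs(mode)):
        opt.lr = config.learning_rate * config.lr_decay**epoch
        idx = rng.choice(len(train), size=len(train), replace=True, p=wts)
        lcs, las = [], []
        for i in range(0, len(idx), config.batch_size):
            chunk = [train[j] for j in idx[i : i + config.batch_size]]
            x, y, m = _batch_arrays(
                chunk, bundle.ontology, image_hw, mode, rng, config.augmentation
            )
            lc, la = loss_and_grads(model, x, y, m, mode, train=True, rng=rng)
            opt.step(model.parameters())
            lcs.append(lc)
            las.append(la)
        history.append(
            {
                "epoch": epoch,
                "loss_c": float(np.mean(lcs)),
                "loss_a": float(np.mean(las)),
                "val_balanced_accuracy": _val_balanced_accuracy(
                    model, bundle, mode, image_hw, config.detection_threshold
                ),
            }
        )
        if config.select_best and (
            best is None or history[-1]["val_balanced_accuracy"] >= best[0]
        ):
            best = (
                history[-1]["val_balanced_accuracy"],
                epoch,
                {k: p.copy() for k, (p, _) in model.parameters().items()},
            )
    if config.select_best and best is not None:
        for k, (p, _) in model.parameters().items():
            p[...] = best[2][k]
        history[-1]["selected_epoch"] = best[1]
    return model, history


# ---------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------


def _prepare_image(model, image):
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {img.shape}")
    if img.shape[:2] != tuple(model.config.image_size):
        img, _ = _augment.apply_pipeline(
            img, None, ({"name": "resize"},), model.config.image_size, None
        )
    return np.moveaxis(img, -1, 0)[None]


def predict_characteristics(model: TinyCNN, image) -> RawPrediction:
    """Scores, logits, and per-class attention maps for one image."""
    x = _prepare_image(model, image)
    feats = model.features(x)
    logits, _, _ = model.head(feats, train=False)
    cams, _ = model.cams(feats, x.shape[2:])
    scores = 1.0 / (1.0 + np.exp(-logits[0].astype(np.float64)))
    attention = [
        AttentionMap(values=cams[0, c], class_id=c, source_layer=model.FINAL_LAYER)
        for c in range(model.n_outputs)
    ]
    return RawPrediction(scores=scores, logits=logits[0], attention=attention)


def class_activation_map(model: TinyCNN, image, class_id: int) -> AttentionMap:
    """Grad-CAM attention for one output class.

    The gradient of the class logit with respect to the final feature
    maps of a GAP + linear architecture is ``head_W[class] / (h*w)``
    everywhere; the Grad-CAM channel weights are therefore the head
    weights up to the positive factor 1/(h*w), and the resulting map
    equals the plain CAM after min-max normalisation.
    """
    if not (0 <= class_id < model.n_outputs):
        raise IndexError(f"class_id {class_id} out of range (C={model.n_outputs})")
    x = _prepare_image(model, image)
    feats = model.features(x)
    h, w = feats.shape[2:]
    alpha = model.head_W[class_id] / (h * w)  # GAP-mean of d logit / d feats
    raw = np.maximum(np.einsum("k,khw->hw", alpha, feats[0]), 0.0)
    m = raw.max()
    norm = raw / m if m > 0 else raw
    Uh, Uw = model._upsampler((h, w), tuple(x.shape[2:]))
    up = np.clip(Uh @ norm @ Uw.T, 0.0, 1.0)
    return AttentionMap(values=up, class_id=class_id, source_layer=model.FINAL_LAYER)


def save_history_csv(history, path):
    import pandas as pd

    pd.DataFrame(history).to_csv(path, index=False)
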