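"""The composite multimodal network for LNM prediction.

Two branches feed a learnable late fusion:

* a multilayer perceptron over the encoded clinical/reader features
  (``MLPoutput = f(W x + b)``);
* a U-Net-style encoder-decoder over the 64x64 MRI-like phantom, producing a
  per-pixel nodal-region classification, with a case-level logit head on the
  globally pooled bottleneck features.

The fused class distribution is ``softmax(alpha * mlp_logits +
beta * cnn_logits)`` with scalar, unconstrained, learnable ``alpha``/``beta``.
Training minimises the fused cross-entropy plus an auxiliary per-pixel
cross-entropy against the phantom mask (weight ``lambda_pixel``).

All parameters live in a flat name->array mapping so federated averaging can
treat the model as plain numerics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError
from .nn import (Conv2d, Dense, GlobalAveragePool, LeakyReLU, MaxPool2, Upsample2,
                 cross_entropy, cross_entropy_grad, softmax)

__all__ = ["ModelConfig", "TextMLP", "UNet", "FusionModel", "fuse",
           "save_parameters", "load_parameters"]


def fuse(alpha: float, beta: float, mlp_logits: np.ndarray,
         cnn_logits: np.ndarray | None = None) -> np.ndarray:
    """Late fusion: ``softmax(alpha * mlp_logits + beta * cnn_logits)``.

    With no image branch (``cnn_logits=None``) this is exactly the beta=0
    text-only mode. Logit vectors must agree in shape.
    """
    mlp_logits = np.asarray(mlp_logits, dtype=float)
    z = alpha * mlp_logits
    if cnn_logits is not None:
        cnn_logits = np.asarray(cnn_logits, dtype=float)
        if cnn_logits.shape != mlp_logits.shape:
            raise InputError(f"logit shapes differ: {mlp_logits.shape} vs {cnn_logits.shape}")
        z = z + beta * cnn_logits
    return softmax(z)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (sizes are CPU-friendly defaults)."""

    n_features: int = 10
    mlp_hidden: tuple[int, ...] = (32, 32)
    image_size: int = 64
    unet_base_channels: int = 4
    unet_depth: int = 3
    leaky_slope: float = 0.01
    mode: str = "multimodal"          # or "text_only"
    lambda_pixel: float = 0.5         # weight of the auxiliary segmentation loss
    pixel_pos_weight: float = 50.0    # class weight of nodal pixels (~1% of image)
    dtype: str = "float32"
    seed: int = 0

    def np_dtype(self):
        return np.dtype(self.dtype)


class TextMLP:
    """MLP text branch: configurable hidden widths, ReLU, 2-logit output."""

    def __init__(self, n_features: int, hidden: tuple[int, ...],
                 rng: np.random.Generator, dtype=np.float32) -> None:
        dims = (n_features, *hidden, 2)
        self.layers = []
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            self.layers.append(Dense(a, b, rng, dtype=dtype))
            if i < len(dims) - 2:
                self.layers.append(LeakyReLU(0.0))  # plain ReLU

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def named_layers(self):
        i = 0
        for layer in self.layers:
            if isinstance(layer, Dense):
                yield f"dense{i}", layer
                i += 1


class UNet:
    """Encoder-decoder with skip connections and a case-level bottleneck head.

    ``depth`` downsampling stages double the channel width each time; the
    decoder mirrors them with nearest-neighbour upsampling and skip
    concatenation. The output block is a 1x1 convolution to 2 per-pixel
    classes; the case head is a dense layer on the globally averaged
    bottleneck features.
    """

    def __init__(self, base: int, depth: int, rng: np.random.Generator,
                 slope: float = 0.01, dtype=np.float32) -> None:
        self.depth = depth
        chans = [base * (2 ** d) for d in range(depth + 1)]   # e.g. [4, 8, 16, 32]
        self.enc = [Conv2d(1, chans[0], rng, dtype=dtype)]
        for d in range(depth):
            self.enc.append(Conv2d(chans[d], chans[d + 1], rng, dtype=dtype))
        self.dec = []
        for d in reversed(range(depth)):
            self.dec.append(Conv2d(chans[d + 1] + chans[d], chans[d], rng, dtype=dtype))
        self.out = Conv2d(chans[0], 2, rng, kernel=1, dtype=dtype)
        self.head = Dense(chans[-1], 2, rng, dtype=dtype)
        self.pool = [MaxPool2() for _ in range(depth)]
        self.up = [Upsample2() for _ in range(depth)]
        self.act_enc = [LeakyReLU(slope) for _ in self.enc]
        self.act_dec = [LeakyReLU(slope) for _ in self.dec]
        self.gap = GlobalAveragePool()

    def forward(self, img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """img is NHWC with one channel; returns (case_logits, pixel_logits)."""
        skips = []
        x = self.act_enc[0].forward(self.enc[0].forward(img))
        for d in range(self.depth):
            skips.append(x)
            x = self.pool[d].forward(x)
            x = self.act_enc[d + 1].forward(self.enc[d + 1].forward(x))
        case_logits = self.head.forward(self.gap.forward(x))
        self._skip_channels = [s.shape[-1] for s in skips]
        for i, d in enumerate(reversed(range(self.depth))):
            x = self.up[i].forward(x)
            x = np.concatenate([x, skips[d]], axis=-1)
            x = self.act_dec[i].forward(self.dec[i].forward(x))
        pixel_logits = self.out.forward(x)
        return case_logits, pixel_logits

    def backward(self, d_case: np.ndarray, d_pixel: np.ndarray) -> None:
        # decoder stage j (executed j-th in forward) consumed skips[depth-1-j]
        d_skips = [None] * self.depth
        dx = self.out.backward(d_pixel)
        for j in reversed(range(self.depth)):
            d = self.depth - 1 - j
            dj = self.dec[j].backward(self.act_dec[j].backward(dx))
            n_up = dj.shape[-1] - self._skip_channels[d]
            d_skips[d] = dj[..., n_up:]
            dx = self.up[j].backward(dj[..., :n_up])
        # bottleneck: gradient from the case head joins the decoder path
        dx = dx + self.gap.backward(self.head.backward(d_case))
        for d in reversed(range(self.depth)):
            dx = self.enc[d + 1].backward(self.act_enc[d + 1].backward(dx))
            dx = self.pool[d].backward(dx)
            dx = dx + d_skips[d]
        self.enc[0].backward(self.act_enc[0].backward(dx))

    def named_layers(self):
        for i, layer in enumerate(self.enc):
            yield f"enc{i}", layer
        for i, layer in enumerate(self.dec):
            yield f"dec{i}", layer
        yield "out", self.out
        yield "head", self.head


class FusionModel:
    """MLP + U-Net + learnable late fusion, with flat named parameters."""

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        dtype = config.np_dtype()
        rng = np.random.default_rng([config.seed, 100])
        self.mlp = TextMLP(config.n_features, config.mlp_hidden, rng, dtype=dtype)
        self.unet = None
        if config.mode == "multimodal":
            self.unet = UNet(config.unet_base_channels, config.unet_depth, rng,
                             slope=config.leaky_slope, dtype=dtype)
        elif config.mode != "text_only":
            raise InputError(f"unknown mode {config.mode!r}")
        self.alpha = np.array(1.0, dtype=dtype)
        self.beta = np.array(1.0, dtype=dtype)
        self.d_alpha = np.zeros_like(self.alpha)
        self.d_beta = np.zeros_like(self.beta)

    # -- parameter plumbing --------------------------------------------------

    def _named_layers(self):
        for name, layer in self.mlp.named_layers():
            yield f"mlp/{name}", layer
        if self.unet is not None:
            for name, layer in self.unet.named_layers():
                yield f"unet/{name}", layer

    def parameter_arrays(self) -> dict[str, np.ndarray]:
        """Live views of every learnable array (including alpha/beta)."""
        out = {}
        for prefix, layer in self._named_layers():
            for pname, arr in layer.params().items():
                out[f"{prefix}/{pname}"] = arr
        out["fusion/alpha"] = self.alpha
        out["fusion/beta"] = self.beta
        return out

    def gradient_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, layer in self._named_layers():
            for pname, arr in layer.grads().items():
                out[f"{prefix}/{pname}"] = arr
        out["fusion/alpha"] = self.d_alpha
        out["fusion/beta"] = self.d_beta
        return out

    def get_parameters(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameter_arrays().items()}

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        live = self.parameter_arrays()
        if set(params) != set(live):
            missing = set(live) ^ set(params)
            raise InputError(f"parameter name mismatch: {sorted(missing)}")
        for k, arr in live.items():
            arr[...] = params[k]

    # -- forward / loss ------------------------------------------------------

    def forward(self, X: np.ndarray, images: np.ndarray | None = None) -> dict:
        """Returns logits, fused probabilities and (multimodal) pixel maps.

        With no image branch (text-only mode, or ``images=None``), fusion
        degenerates to ``softmax(alpha * mlp_logits)`` — identical to beta=0.
        """
        mlp_logits = self.mlp.forward(np.asarray(X, dtype=self.alpha.dtype))
        cnn_logits = pixel_logits = None
        fused = self.alpha * mlp_logits
        if self.unet is not None and images is not None:
            img = np.asarray(images, dtype=self.alpha.dtype)
            if img.ndim == 3:
                img = img[..., None]
            if img.shape[1] != self.config.image_size or img.shape[2] != self.config.image_size:
                raise InputError(f"expected {self.config.image_size}^2 images, got {img.shape}")
            cnn_logits, pixel_logits = self.unet.forward(img)
            fused = fused + self.beta * cnn_logits
        probs = softmax(fused)
        out = {"mlp_logits": mlp_logits, "cnn_logits": cnn_logits,
               "fused_logits": fused, "probs": probs, "pixel_logits": pixel_logits}
        if pixel_logits is not None:
            out["pixel_probs"] = softmax(pixel_logits)
        return out

    def predict_proba(self, X: np.ndarray, images: np.ndarray | None = None) -> np.ndarray:
        return self.forward(X, images)["probs"]

    def loss_and_backward(self, X: np.ndarray, labels: np.ndarray,
                          images: np.ndarray | None = None,
                          masks: np.ndarray | None = None) -> float:
        """Fused cross-entropy (+ auxiliary pixel loss), populating gradients."""
        y = np.asarray(labels).astype(int)
        out = self.forward(X, images)
        loss = cross_entropy(out["probs"], y, reduction="mean")

        d_fused = cross_entropy_grad(out["probs"], y, reduction="mean")
        self.d_alpha[...] = np.sum(d_fused * out["mlp_logits"])
        self.mlp.backward(self.alpha * d_fused)
        if out["cnn_logits"] is not None:
            self.d_beta[...] = np.sum(d_fused * out["cnn_logits"])
            d_case = self.beta * d_fused
            if masks is not None:
                # weighted per-pixel loss: nodal pixels are ~1% of the image, so
                # they carry pixel_pos_weight to keep the segmentation target alive
                m = np.asarray(masks).astype(int)
                lam = self.config.lambda_pixel
                w = np.where(m == 1, self.config.pixel_pos_weight, 1.0)
                p_true = np.take_along_axis(out["pixel_probs"], m[..., None], axis=-1)[..., 0]
                pix_losses = -np.log(np.clip(p_true, 1e-12, 1.0))
                loss += lam * float((w * pix_losses).mean())
                d_pixel = (lam * w[..., None]
                           * cross_entropy_grad(out["pixel_probs"], m, reduction="mean"))
            else:
                d_pixel = np.zeros_like(out["pixel_logits"])
            self.unet.backward(d_case, d_pixel)
        else:
            self.d_beta[...] = 0.0
        return loss


def aggregate_slice_probabilities(p_positive: np.ndarray) -> float:
    """Case-level positive probability from several slices of one patient.

    Convention: the maximum per-slice positive probability — a case is called
    positive if any slice looks positive. The default phantom generator emits
    one slice per case, so this is exercised only for multi-slice inputs.
    """
    p = np.asarray(p_positive, dtype=float)
    if p.size == 0:
        raise InputError("no slice probabilities given")
    return float(p.max())


def save_parameters(path, params: dict[str, np.ndarray], manifest: dict | None = None) -> None:
    """Serialize named arrays (plus a JSON architecture manifest) to one .npz."""
    arrays = {k.replace("/", "__"): v for k, v in params.items()}
    arrays["__manifest__"] = np.frombuffer(
        json.dumps(manifest or {}).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_parameters(path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path) as data:
        manifest = json.loads(bytes(data["__manifest__"]).decode())
        params = {k.replace("__", "/"): data[k] for k in data.files if k != "__manifest__"}
    return params, manifest
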