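"""Encoder-decoder architectures for one-to-all ECG lead conversion.

Three convolutional families share one skeleton:

* ``unet`` — encoder blocks (two convolutions, each with batch
  normalisation and ReLU, then factor-2 max-pooling), a two-convolution
  bottleneck, and decoder blocks (linear upsampling plus two convolutions)
  with skip connections concatenating each encoder block's pre-pooling
  feature map into the matching decoder block;
* ``ae`` — the same without skip connections (a plain convolutional
  autoencoder);
* ``lrn`` — the U-Net with an auxiliary single-channel tanh head on every
  decoder block, so the reconstruction can be supervised at every
  resolution (label-refinement-style coarse-to-fine supervision).

The final head is a single-channel convolution with tanh activation, so
predictions lie strictly inside (-1, 1), matching the [-1, 1] range of
min-max normalised targets.  A fourth family, the ``pointwise`` baseline,
maps each time point's amplitude through a fully-connected network with no
temporal context; it exists to quantify how much of the conversion is
attributable to waveform context rather than instantaneous amplitude.

One model converts a single reference lead into all requested target
leads, either through one shared encoder feeding per-lead decoders or
through fully independent encoder-decoder pairs.

Inputs whose length is not divisible by ``2**depth`` are symmetrically
edge-padded to the next multiple before the encoder and the outputs are
cropped back, so the pooling arithmetic is always exact.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .nn import (
    DTYPE, BatchNorm1d, Chain, Conv1d, Linear, MaxPool1d, Param, ReLU, Tanh,
    UpsampleLinear,
)
from .records import canonical_lead_name

logger = logging.getLogger(__name__)

FAMILIES = ("unet", "ae", "lrn", "pointwise")


class ConfigError(ValueError):
    """Invalid model configuration."""


def default_target_leads(reference_lead: str) -> tuple[str, ...]:
    from .records import STANDARD_LEADS

    ref = canonical_lead_name(reference_lead)
    return tuple(l for l in STANDARD_LEADS if l != ref)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture family, one-to-all scheme and capacity hyperparameters."""

    family: str = "unet"
    reference_lead: str = "II"
    target_leads: tuple[str, ...] | None = None
    encoder_scheme: str = "shared"
    depth: int = 3
    base_channels: int = 16
    kernel_size: int = 9
    input_length: int = 5000

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}")
        if self.encoder_scheme not in ("shared", "individual"):
            raise ConfigError(f"unknown encoder scheme {self.encoder_scheme!r}")
        ref = canonical_lead_name(self.reference_lead)
        targets = (default_target_leads(ref) if self.target_leads is None
                   else tuple(canonical_lead_name(l) for l in self.target_leads))
        if ref in targets:
            raise ConfigError("reference lead cannot be a target lead")
        if len(set(targets)) != len(targets) or not targets:
            raise ConfigError("target leads must be a non-empty set")
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if self.base_channels < 1:
            raise ConfigError("base_channels must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ConfigError("kernel_size must be odd")
        if self.input_length < 2 ** self.depth:
            raise ConfigError("input_length shorter than one pooled sample")
        object.__setattr__(self, "reference_lead", ref)
        object.__setattr__(self, "target_leads", targets)

    @property
    def padded_length(self) -> int:
        m = 2 ** self.depth
        return ((self.input_length + m - 1) // m) * m

    def to_dict(self) -> dict:
        return {
            "family": self.family, "reference_lead": self.reference_lead,
            "target_leads": list(self.target_leads),
            "encoder_scheme": self.encoder_scheme, "depth": self.depth,
            "base_channels": self.base_channels,
            "kernel_size": self.kernel_size, "input_length": self.input_length,
        }


def _conv_bn_relu(c_in, c_out, k, rng) -> list:
    return [Conv1d(c_in, c_out, k, rng), BatchNorm1d(c_out), ReLU()]


class Encoder:
    """``depth`` blocks; block *k* doubles the channel count and halves the
    temporal resolution, exposing pre-pooling feature maps for skips."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        if config.input_length % (2 ** config.depth) != 0:
            raise ConfigError(
                f"input_length {config.input_length} is not divisible by "
                f"2**depth = {2 ** config.depth}")
        self.config = config
        c, k = config.base_channels, config.kernel_size
        self.blocks: list[Chain] = []
        self.pools: list[MaxPool1d] = []
        ch_in = 1
        for i in range(config.depth):
            ch_out = c * (2 ** i)
            self.blocks.append(Chain(
                _conv_bn_relu(ch_in, ch_out, k, rng)
                + _conv_bn_relu(ch_out, ch_out, k, rng)))
            self.pools.append(MaxPool1d())
            ch_in = ch_out
        self.out_channels = ch_in

    def forward(self, x, train):
        skips = []
        for block, pool in zip(self.blocks, self.pools):
            x = block.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        return x, skips

    def backward(self, dz, dskips):
        for block, pool, dskip in zip(
                reversed(self.blocks), reversed(self.pools), reversed(dskips)):
            d = pool.backward(dz)
            if dskip is not None:
                d = d + dskip
            dz = block.backward(d)
        return dz

    def params(self):
        return [p for b in self.blocks for p in b.params()]

    def components(self):
        return self.blocks


class Bottleneck:
    """Two convolutions at the coarsest resolution; channels double once."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        c_in = config.base_channels * (2 ** (config.depth - 1))
        c_out = 2 * c_in
        k = config.kernel_size
        self.chain = Chain(
            _conv_bn_relu(c_in, c_out, k, rng) + _conv_bn_relu(c_out, c_out, k, rng))
        self.out_channels = c_out

    def forward(self, x, train):
        return self.chain.forward(x, train)

    def backward(self, dy):
        return self.chain.backward(dy)

    def params(self):
        return self.chain.params()

    def components(self):
        return [self.chain]


class Decoder:
    """``depth`` mirror blocks (upsample + two convolutions) plus a
    single-channel tanh head; optional per-block auxiliary tanh heads."""

    def __init__(self, config: ModelConfig, with_skips: bool, with_aux: bool,
                 rng: np.random.Generator):
        self.config = config
        self.with_skips, self.with_aux = with_skips, with_aux
        c, k = config.base_channels, config.kernel_size
        self.ups: list[UpsampleLinear] = []
        self.blocks: list[Chain] = []
        self.aux_heads: list[Chain] = []
        self.skip_channels: list[int] = []
        for i in range(config.depth - 1, -1, -1):
            ch_below = c * (2 ** (i + 1))
            skip_ch = c * (2 ** i) if with_skips else 0
            ch_out = c * (2 ** i)
            self.ups.append(UpsampleLinear())
            self.blocks.append(Chain(
                _conv_bn_relu(ch_below + skip_ch, ch_out, k, rng)
                + _conv_bn_relu(ch_out, ch_out, k, rng)))
            self.skip_channels.append(skip_ch)
            if with_aux:
                self.aux_heads.append(Chain([Conv1d(ch_out, 1, k, rng), Tanh()]))
        self.head = Chain([Conv1d(c, 1, k, rng), Tanh()])

    def forward(self, z, skips, train):
        """Returns ``(prediction, aux)``; ``aux`` is coarse-to-fine, one per
        block, empty unless the decoder has auxiliary heads."""
        aux = []
        for j, (up, block) in enumerate(zip(self.ups, self.blocks)):
            z = up.forward(z, train)
            if self.with_skips:
                skip = skips[self.config.depth - 1 - j]
                if skip.shape[2] != z.shape[2]:
                    raise AssertionError("skip/decoder length mismatch")
                z = np.concatenate([z, skip], axis=0)
            z = block.forward(z, train)
            if self.with_aux:
                aux.append(self.aux_heads[j].forward(z, train))
        return self.head.forward(z, train)[0], aux

    def backward(self, dy, daux=None):
        dz = self.head.backward(dy[None])
        dskips: list = [None] * self.config.depth
        for j in range(len(self.blocks) - 1, -1, -1):
            if self.with_aux and daux is not None and daux[j] is not None:
                dz = dz + self.aux_heads[j].backward(daux[j])
            d = self.blocks[j].backward(dz)
            if self.with_skips:
                ch_skip = self.skip_channels[j]
                dskips[self.config.depth - 1 - j] = d[-ch_skip:]
                d = d[:-ch_skip]
            dz = self.ups[j].backward(d)
        return dz, dskips

    def params(self):
        ps = [p for b in self.blocks for p in b.params()]
        for h in self.aux_heads:
            ps.extend(h.params())
        ps.extend(self.head.params())
        return ps

    def components(self):
        return self.blocks + self.aux_heads + [self.head]


def build_encoder(config: ModelConfig, rng: np.random.Generator | None = None) -> Encoder:
    return Encoder(config, rng if rng is not None else np.random.default_rng(0))


def build_bottleneck(config: ModelConfig, rng: np.random.Generator | None = None) -> Bottleneck:
    return Bottleneck(config, rng if rng is not None else np.random.default_rng(0))


def build_decoder(config: ModelConfig, with_skips: bool, with_aux_heads: bool,
                  rng: np.random.Generator | None = None) -> Decoder:
    return Decoder(config, with_skips, with_aux_heads,
                   rng if rng is not None else np.random.default_rng(0))


class ConversionModel:
    """Common interface: ``forward`` maps a batch of reference-lead segments
    to per-target-lead predictions (plus per-level auxiliary predictions for
    the LRN family); ``backward`` propagates per-lead output gradients."""

    config: ModelConfig

    def forward(self, x: np.ndarray, train: bool = False):
        raise NotImplementedError

    def backward(self, dpred: dict, daux: dict | None = None) -> None:
        raise NotImplementedError

    def params(self) -> list[Param]:
        raise NotImplementedError

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, comp in enumerate(self._components()):
            for key, val in comp.state().items():
                out[f"c{i}.{key}"] = val
        return out

    def _components(self):
        raise NotImplementedError

    def predict(self, x: np.ndarray, batch_size: int = 64) -> dict[str, np.ndarray]:
        """Inference-mode prediction over a (n, length) array of segments."""
        outs: dict[str, list[np.ndarray]] = {l: [] for l in self.config.target_leads}
        for i in range(0, len(x), batch_size):
            preds, _ = self.forward(x[i:i + batch_size], train=False)
            for lead, y in preds.items():
                outs[lead].append(y)
        return {lead: np.concatenate(v) for lead, v in outs.items()}


class OneToAllModel(ConversionModel):
    """Encoder-decoder one-to-all conversion (families unet / ae / lrn)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        if config.family == "pointwise":
            raise ConfigError(
                "the pointwise baseline is built with build_pointwise_baseline")
        self.config = config
        rng = np.random.default_rng(seed)
        inner = (config if config.input_length == config.padded_length
                 else replace(config, input_length=config.padded_length))
        if inner.input_length != config.input_length:
            logger.info(
                "input length %d padded to %d for 2**%d pooling",
                config.input_length, inner.input_length, config.depth)
        self._inner = inner
        with_skips = config.family in ("unet", "lrn")
        with_aux = config.family == "lrn"
        self.decoders: dict[str, Decoder] = {}
        if config.encoder_scheme == "shared":
            self.encoder = Encoder(inner, rng)
            self.bottleneck = Bottleneck(inner, rng)
            self.encoders = None
            self.bottlenecks = None
        else:
            self.encoder = None
            self.bottleneck = None
            self.encoders = {}
            self.bottlenecks = {}
            for lead in config.target_leads:
                self.encoders[lead] = Encoder(inner, rng)
                self.bottlenecks[lead] = Bottleneck(inner, rng)
        for lead in config.target_leads:
            self.decoders[lead] = Decoder(inner, with_skips, with_aux, rng)
        self._cache = None

    # -- padding -----------------------------------------------------------
    def _pad(self, x: np.ndarray) -> np.ndarray:
        pad = self._inner.input_length - self.config.input_length
        if pad == 0:
            return x
        lo, hi = pad // 2, pad - pad // 2
        return np.pad(x, ((0, 0), (lo, hi)), mode="edge")

    def _crop(self, y: np.ndarray) -> np.ndarray:
        pad = self._inner.input_length - self.config.input_length
        if pad == 0:
            return y
        lo = pad // 2
        return y[:, lo:lo + self.config.input_length]

    def _uncrop_grad(self, dy: np.ndarray) -> np.ndarray:
        pad = self._inner.input_length - self.config.input_length
        if pad == 0:
            return dy
        lo, hi = pad // 2, pad - pad // 2
        return np.pad(dy, ((0, 0), (lo, hi)), mode="constant")

    # -- forward/backward --------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False):
        if x.ndim != 2 or x.shape[1] != self.config.input_length:
            raise ValueError(
                f"expected input of shape (batch, {self.config.input_length}), "
                f"got {x.shape}")
        if np.max(np.abs(x)) > 1.0 + 1e-6:
            logger.warning("model input exceeds [-1, 1]; was it normalised?")
        xb = self._pad(np.asarray(x, dtype=DTYPE))[None, :, :]
        preds: dict[str, np.ndarray] = {}
        aux: dict[str, list[np.ndarray]] = {}
        if self.config.encoder_scheme == "shared":
            z, skips = self.encoder.forward(xb, train)
            h = self.bottleneck.forward(z, train)
            for lead, dec in self.decoders.items():
                y, a = dec.forward(h, skips, train)
                preds[lead] = self._crop(y)
                aux[lead] = a
        else:
            for lead, dec in self.decoders.items():
                z, skips = self.encoders[lead].forward(xb, train)
                h = self.bottlenecks[lead].forward(z, train)
                y, a = dec.forward(h, skips, train)
                preds[lead] = self._crop(y)
                aux[lead] = a
        return preds, aux

    def backward(self, dpred: dict, daux: dict | None = None) -> None:
        depth = self.config.depth
        if self.config.encoder_scheme == "shared":
            dh_total = None
            dskips_total = [None] * depth
            for lead, dec in self.decoders.items():
                dy = self._uncrop_grad(dpred[lead])
                dh, dskips = dec.backward(dy, daux.get(lead) if daux else None)
                dh_total = dh if dh_total is None else dh_total + dh
                for i, ds in enumerate(dskips):
                    if ds is not None:
                        dskips_total[i] = (ds if dskips_total[i] is None
                                           else dskips_total[i] + ds)
            dz = self.bottleneck.backward(dh_total)
            self.encoder.backward(dz, dskips_total)
        else:
            for lead, dec in self.decoders.items():
                dy = self._uncrop_grad(dpred[lead])
                dh, dskips = dec.backward(dy, daux.get(lead) if daux else None)
                dz = self.bottlenecks[lead].backward(dh)
                self.encoders[lead].backward(dz, dskips)

    def params(self):
        ps: list[Param] = []
        if self.encoder is not None:
            ps += self.encoder.params() + self.bottleneck.params()
        else:
            for lead in self.config.target_leads:
                ps += self.encoders[lead].params() + self.bottlenecks[lead].params()
        for lead in self.config.target_leads:
            ps += self.decoders[lead].params()
        return ps

    def _components(self):
        comps = []
        if self.encoder is not None:
            comps += self.encoder.components() + self.bottleneck.components()
        else:
            for lead in self.config.target_leads:
                comps += (self.encoders[lead].components()
                          + self.bottlenecks[lead].components())
        for lead in self.config.target_leads:
            comps += self.decoders[lead].components()
        return comps


class PointwiseBaseline(ConversionModel):
    """Fully-connected per-time-point baseline: one amplitude in, one
    amplitude per target lead out, with no temporal context at all."""

    def __init__(self, config: ModelConfig, n_hidden_layers: int = 3,
                 hidden_width: int = 64, seed: int = 0):
        if n_hidden_layers < 0 or hidden_width < 1:
            raise ConfigError("invalid pointwise baseline size")
        self.config = config
        self.n_hidden_layers, self.hidden_width = n_hidden_layers, hidden_width
        rng = np.random.default_rng(seed)
        layers: list = []
        w_in = 1
        for _ in range(n_hidden_layers):
            layers += [Linear(w_in, hidden_width, rng), ReLU()]
            w_in = hidden_width
        layers.append(Linear(w_in, len(config.target_leads), rng))
        self.net = Chain(layers)
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False):
        n, length = x.shape
        flat = np.asarray(x, dtype=DTYPE).reshape(n * length, 1)
        out = self.net.forward(flat, train)
        self._shape = (n, length)
        preds = {lead: out[:, j].reshape(n, length)
                 for j, lead in enumerate(self.config.target_leads)}
        return preds, {}

    def backward(self, dpred: dict, daux: dict | None = None) -> None:
        n, length = self._shape
        dout = np.stack(
            [dpred[lead].reshape(n * length)
             for lead in self.config.target_leads], axis=1).astype(DTYPE)
        self.net.backward(dout)

    def params(self):
        return self.net.params()

    def _components(self):
        return [self.net]


def assemble_one_to_all(config: ModelConfig, seed: int = 0) -> OneToAllModel:
    """Build a one-to-all conversion model (families unet / ae / lrn)."""
    return OneToAllModel(config, seed=seed)


def build_pointwise_baseline(
    config: ModelConfig | None = None,
    n_hidden_layers: int = 3,
    hidden_width: int = 64,
    seed: int = 0,
) -> PointwiseBaseline:
    if config is None:
        config = ModelConfig(family="pointwise")
    if config.family != "pointwise":
        config = replace(config, family="pointwise")
    return PointwiseBaseline(config, n_hidden_layers, hidden_width, seed=seed)


def build_model(config: ModelConfig, seed: int = 0) -> ConversionModel:
    if config.family == "pointwise":
        return build_pointwise_baseline(config, seed=seed)
    return assemble_one_to_all(config, seed=seed)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: ConversionModel, path: str | Path,
                    manifest_hash: str | None = None,
                    extra: dict | None = None) -> None:
    """Single-file self-describing checkpoint: parameters, persistent state,
    full model configuration and the preprocessing manifest hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": model.config.to_dict(),
        "manifest_hash": manifest_hash,
        "extra": extra or {},
    }
    if isinstance(model, PointwiseBaseline):
        meta["pointwise"] = {"n_hidden_layers": model.n_hidden_layers,
                             "hidden_width": model.hidden_width}
    arrays = {f"param_{i:04d}": p.data for i, p in enumerate(model.params())}
    arrays.update({f"state__{k}": v for k, v in model.state_arrays().items()})
    buf = io.BytesIO()
    np.savez_compressed(buf, meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    path.write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path) -> tuple[ConversionModel, dict]:
    """Rebuild a model from a checkpoint; returns ``(model, meta)``."""
    data = np.load(Path(path), allow_pickle=False)
    meta = json.loads(bytes(data["meta"]).decode())
    cfg = meta["config"]
    config = ModelConfig(
        family=cfg["family"], reference_lead=cfg["reference_lead"],
        target_leads=tuple(cfg["target_leads"]),
        encoder_scheme=cfg["encoder_scheme"], depth=cfg["depth"],
        base_channels=cfg["base_channels"], kernel_size=cfg["kernel_size"],
        input_length=cfg["input_length"],
    )
    if config.family == "pointwise":
        pw = meta.get("pointwise", {})
        model: ConversionModel = build_pointwise_baseline(
            config, pw.get("n_hidden_layers", 3), pw.get("hidden_width", 64))
    else:
        model = OneToAllModel(config)
    for i, p in enumerate(model.params()):
        arr = data[f"param_{i:04d}"]
        if arr.shape != p.data.shape:
            raise ValueError("checkpoint does not match the rebuilt model")
        p.data[...] = arr
    states = model.state_arrays()
    for key, target in states.items():
        target[...] = data[f"state__{key}"]
    return model, meta


def describe(model: ConversionModel) -> str:
    """Human-readable architecture summary."""
    c = model.config
    lines = [
        f"family: {c.family}   scheme: {c.encoder_scheme}",
        f"reference lead: {c.reference_lead} -> targets: {', '.join(c.target_leads)}",
        f"depth: {c.depth}   base channels: {c.base_channels}   "
        f"kernel: {c.kernel_size}",
        f"input length: {c.input_length}"
        + (f" (padded to {c.padded_length})"
           if c.padded_length != c.input_length else ""),
        f"parameters: {model.n_parameters:,}",
    ]
    return "\n".join(lines)
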