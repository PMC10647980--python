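"""Encoder-decoder (U-net style) network built from the NumPy layers.

The backbone is the classic contracting/expanding design: per resolution
level two 3x3 padded convolutions with ReLU, 2x2 max-pool downsampling,
2x2 stride-2 transposed-convolution upsampling with skip concatenation,
and task heads as 1x1 convolutions (sigmoid for segmentation/contour,
linear for distance regression). One backbone can carry any number of
heads; all heads share every backbone parameter.

``forward`` caches activations so that ``backward`` can return the
gradient with respect to the input image and with respect to any named
intermediate activation — the machinery the saliency analyses need.
"""

from __future__ import annotations

import numpy as np

from .layers import DTYPE, Conv2D, ConvTranspose2x2, Identity, MaxPool2, ReLU, Sigmoid


class ConvBlock:
    """Two same-padded 3x3 convolutions, each followed by ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = Conv2D(cin, cout, 3, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(cout, cout, 3, rng)
        self.relu2 = ReLU()
        self.layers = [self.conv1, self.relu1, self.conv2, self.relu2]

    def forward(self, x):
        return self.relu2.forward(self.conv2.forward(self.relu1.forward(self.conv1.forward(x))))

    def backward(self, dy, guided=False):
        dy = self.relu2.backward(dy, guided=guided)
        dy = self.conv2.backward(dy)
        dy = self.relu1.backward(dy, guided=guided)
        return self.conv1.backward(dy)


class Head:
    """1x1 convolution head with sigmoid or linear activation.

    Sigmoid heads start with a negative bias so the initial foreground
    prediction is sparse; with soft-Dice losses this keeps the gradient
    on small structures (the spinal cord) from being diluted by a huge
    denominator early in training. Linear (regression) heads start at
    zero so an auxiliary regression task ramps in smoothly instead of
    flooding the shared backbone with noise gradients at initialisation.
    """

    SIGMOID_BIAS_INIT = -2.0

    def __init__(self, cin: int, channels: int, activation: str, rng: np.random.Generator):
        if activation not in ("sigmoid", "linear"):
            raise ValueError(f"unknown head activation {activation!r}")
        self.conv = Conv2D(cin, channels, 1, rng)
        if activation == "sigmoid":
            self.conv.params["b"][...] = self.SIGMOID_BIAS_INIT
        else:
            self.conv.params["W"][...] = 0.0
        self.act = Sigmoid() if activation == "sigmoid" else Identity()
        self.activation = activation
        self.layers = [self.conv, self.act]

    def forward(self, x):
        return self.act.forward(self.conv.forward(x))

    def backward(self, dy):
        return self.conv.backward(self.act.backward(dy))


class UNet:
    """Shared backbone with named task heads.

    Parameters
    ----------
    depth : number of resolution levels (>= 2); spatial size is halved
        depth-1 times, so inputs must be divisible by 2**(depth-1).
    base_filters : channel count at full resolution; doubles per level.
    heads : sequence of (name, channels, activation) triples.
    rng : seeded generator for He-uniform weight initialisation.
    """

    def __init__(self, depth: int, base_filters: int, heads, rng: np.random.Generator,
                 in_channels: int = 1):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        if base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        self.depth = depth
        self.base_filters = base_filters
        self.in_channels = in_channels
        filt = [base_filters * 2 ** l for l in range(depth)]
        self.filters = filt

        self.enc_blocks, self.pools = [], []
        cin = in_channels
        for l in range(depth - 1):
            self.enc_blocks.append(ConvBlock(cin, filt[l], rng))
            self.pools.append(MaxPool2())
            cin = filt[l]
        self.bottleneck = ConvBlock(cin, filt[depth - 1], rng)

        self.up_convs, self.dec_blocks = [], []
        for l in range(depth - 2, -1, -1):
            self.up_convs.append(ConvTranspose2x2(filt[l + 1], filt[l], rng))
            self.dec_blocks.append(ConvBlock(2 * filt[l], filt[l], rng))

        self.heads = {name: Head(filt[0], ch, act, rng) for name, ch, act in heads}
        self.dtype = DTYPE
        self.activations: dict[str, np.ndarray] = {}
        self.act_grads: dict[str, np.ndarray] = {}

    # ---- parameter plumbing -------------------------------------------------
    def _modules(self):
        mods = list(self.enc_blocks) + [self.bottleneck] + list(self.up_convs) + \
            list(self.dec_blocks) + list(self.heads.values())
        for m in mods:
            yield from (m.layers if hasattr(m, "layers") else [m])

    def parameters(self):
        """Yield (layer, name, value, grad) for every trainable tensor."""
        for layer in self._modules():
            for name in getattr(layer, "params", {}):
                yield layer, name, layer.params[name], layer.grads[name]

    def n_params(self) -> int:
        return sum(p.size for _, _, p, _ in self.parameters())

    def backbone_param_ids(self) -> set[int]:
        ids = set()
        for m in list(self.enc_blocks) + [self.bottleneck] + list(self.up_convs) + list(self.dec_blocks):
            for layer in m.layers if hasattr(m, "layers") else [m]:
                for p in getattr(layer, "params", {}).values():
                    ids.add(id(p))
        return ids

    def astype(self, dtype) -> "UNet":
        """Convert all parameters/grads in place (float64 for strict
        numerical checks); returns self."""
        self.dtype = np.dtype(dtype)
        for layer in self._modules():
            for name in getattr(layer, "params", {}):
                layer.params[name] = layer.params[name].astype(dtype)
                layer.grads[name] = layer.grads[name].astype(dtype)
        return self

    def zero_grads(self):
        for _, _, _, g in self.parameters():
            g[...] = 0.0

    # ---- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> dict[str, np.ndarray]:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected input (N,{self.in_channels},H,W), got {x.shape}")
        div = 2 ** (self.depth - 1)
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"spatial size {x.shape[2:]} not divisible by 2**(depth-1)={div}")
        self.activations = {"input": x}
        skips = []
        h = x
        for l, (block, pool) in enumerate(zip(self.enc_blocks, self.pools)):
            s = block.forward(h)
            skips.append(s)
            self.activations[f"enc{l}"] = s
            h = pool.forward(s)
        h = self.bottleneck.forward(h)
        self.activations["bottleneck"] = h
        for i, (up, dec) in enumerate(zip(self.up_convs, self.dec_blocks)):
            l = self.depth - 2 - i
            u = up.forward(h)
            h = dec.forward(np.concatenate([skips[l], u], axis=1))
            self.activations[f"dec{l}"] = h
        self.activations["last_conv"] = h
        return {name: head.forward(h) for name, head in self.heads.items()}

    def backward(self, d_heads: dict[str, np.ndarray], guided: bool = False,
                 accumulate: bool = True) -> np.ndarray:
        """Backpropagate head-output gradients; returns d(input).

        ``d_heads`` maps head name -> gradient w.r.t. that head's output;
        omitted heads contribute nothing. Gradients w.r.t. every named
        activation are stored in ``self.act_grads``.
        """
        if not accumulate:
            self.zero_grads()
        self.act_grads = {}
        h_shape = self.activations["last_conv"].shape
        dh = np.zeros(h_shape, dtype=self.dtype)
        for name, dy in d_heads.items():
            dh += self.heads[name].backward(np.asarray(dy, dtype=self.dtype))
        self.act_grads["last_conv"] = dh

        d_skips = [None] * (self.depth - 1)
        for i in range(self.depth - 2, -1, -1):
            l = self.depth - 2 - i
            self.act_grads[f"dec{l}"] = dh
            dcat = self.dec_blocks[i].backward(dh, guided=guided)
            nskip = self.filters[l]
            d_skips[l] = dcat[:, :nskip]
            dh = self.up_convs[i].backward(dcat[:, nskip:])
        self.act_grads["bottleneck"] = dh
        dh = self.bottleneck.backward(dh, guided=guided)
        for l in range(self.depth - 2, -1, -1):
            dh = self.pools[l].backward(dh)
            dh = dh + d_skips[l]
            self.act_grads[f"enc{l}"] = dh
            dh = self.enc_blocks[l].backward(dh, guided=guided)
        self.act_grads["input"] = dh
        return dh
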