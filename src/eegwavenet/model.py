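"""The dual-path WaveNet-LSTM network for EEG abnormality detection.

Path 1 (WaveNet-LSTM) stacks four "wave blocks" of causal dilated
convolutions with gated activation units.  Each gated layer computes
``tanh(conv_f(x)) * sigmoid(conv_g(x))`` and adds a 1x1-projected residual
of its input; successive layers chain through those residuals, and the
block output is the element-wise *sum* of every layer's gated output (there
are no WaveNet-style skip connections to the head).  The first block uses
dilations 1..128, and the maximum dilation halves in each later block, so
early blocks see broad context and later blocks focus locally.  Every block
is followed by temporal average pooling; an LSTM consumes the pooled
sequence and contributes its final hidden state.

Path 2 (attention LSTM) time-reverses ("flips") the raw input, slices it
into fixed windows, encodes each window with one shared LSTM, re-weights
the window-embedding channels with softmax attention, and runs a second
LSTM with dropout followed by a dense layer.

Both path outputs are concatenated into a dense softmax head over
{normal, abnormal}.  Ablation variants drop a path or swap the path-1 LSTM
for global average pooling.  ``count_parameters`` gives a closed-form count
that must agree with the instantiated arrays; the reference configuration
totals 244,882 trainable parameters, within its 244,992 budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, softmax_cross_entropy
from .errors import ParameterError

VARIANTS = ("baseline", "ablation1", "ablation2", "ablation3", "full")

_DEFAULT_DILATIONS = (
    (1, 2, 4, 8, 16, 32, 64, 128),
    (1, 2, 4, 8, 16, 32, 64),
    (1, 2, 4, 8, 16, 32),
    (1, 2, 4, 8, 16),
)


@dataclass
class ModelConfig:
    """All architecture hyperparameters plus the parameter budget.

    Defaults are the reference configuration: 20 TCP channels, 60 s at
    250 Hz (15,000 samples), four wave blocks whose maximum dilation halves
    from 128 down to 16, 32 filters, kernel 3, average-pool factor 4, a
    64-unit path-1 LSTM, 1-s (250-sample) windows encoded by a shared
    32-unit LSTM, a 64-unit path-2 LSTM with dropout 0.2 and a 16-unit
    dense layer, and a two-class softmax head.
    """

    n_input_channels: int = 20
    input_len: int = 15000
    block_dilations: tuple = _DEFAULT_DILATIONS
    conv_filters: int = 32
    kernel_size: int = 3
    pool_factor: int = 4
    path1_rnn_units: int = 64
    window_len: int = 250
    window_rnn_units: int = 32
    path2_rnn_units: int = 64
    path2_dense_units: int = 16
    dropout: float = 0.2
    n_classes: int = 2
    param_budget: int = 244_992
    dtype: str = "float32"

    def __post_init__(self):
        self.block_dilations = tuple(tuple(int(d) for d in blk)
                                     for blk in self.block_dilations)
        for blk in self.block_dilations:
            if not blk or any(d < 1 for d in blk):
                raise ParameterError("dilations must be positive")
            if any(nxt <= prev for nxt, prev in zip(blk[1:], blk)):
                raise ParameterError("each block's dilations must strictly increase")
        if self.input_len % self.window_len != 0:
            raise ParameterError(
                f"input_len {self.input_len} not divisible by "
                f"window_len {self.window_len}")
        if not 0.0 <= self.dropout < 1.0:
            raise ParameterError("dropout must be in [0, 1)")

    @property
    def n_windows(self) -> int:
        return self.input_len // self.window_len

    @classmethod
    def reduced_reference(cls, seg_seconds: float = 10.0, fs: float = 250.0,
                          max_dilation: int = 32, **overrides) -> "ModelConfig":
        """Scaled-down reference: shorter segments, dilations capped.

        Used for desk-scale end-to-end experiments: 10-s segments and every
        dilation schedule truncated at ``max_dilation``.
        """
        dil = tuple(tuple(d for d in blk if d <= max_dilation)
                    for blk in _DEFAULT_DILATIONS)
        return cls(input_len=int(seg_seconds * fs), block_dilations=dil,
                   **overrides)


def receptive_field(dilations, kernel: int) -> int:
    """Receptive field of a stack of causal dilated convolutions.

    ``1 + (kernel - 1) * sum(dilations)`` input steps influence the last
    output position.
    """
    dilations = list(dilations)
    if not dilations:
        raise ParameterError("dilations must be non-empty")
    return 1 + (kernel - 1) * sum(int(d) for d in dilations)


# --------------------------------------------------------------------------
# closed-form parameter counting


def _conv_params(cin: int, k: int, f: int) -> int:
    return cin * k * f + f


def _dense_params(n_in: int, n_out: int) -> int:
    return n_in * n_out + n_out


def _lstm_params(n_in: int, units: int) -> int:
    # single-bias convention: 4 * ((in + units) * units + units)
    return 4 * ((n_in + units) * units + units)


def _gated_layer_params(cin: int, k: int, f: int) -> int:
    # filter conv + gate conv + 1x1 residual projection
    return 2 * _conv_params(cin, k, f) + _conv_params(cin, 1, f)


def count_parameters(cfg: ModelConfig, variant: str = "full") -> int:
    """Closed-form trainable-parameter count for a variant.

    Matches the instantiated model's array sizes exactly (asserted in
    tests): per gated layer two dilated convolutions plus a 1x1 residual
    projection; LSTMs with a single bias vector; dense layers with bias;
    attention as a square dense over the window-embedding channels.
    """
    if variant not in VARIANTS:
        raise ParameterError(f"unknown variant {variant!r}; valid: {VARIANTS}")
    f, k = cfg.conv_filters, cfg.kernel_size
    total = 0
    head_in = 0

    use_path1 = variant != "ablation3"
    use_path2 = variant in ("full", "ablation2", "ablation3")
    path1_lstm = variant in ("full", "ablation1")

    if use_path1:
        cin = cfg.n_input_channels
        for blk in cfg.block_dilations:
            for _ in blk:
                total += _gated_layer_params(cin, k, f)
                cin = f
        if path1_lstm:
            total += _lstm_params(f, cfg.path1_rnn_units)
            head_in += cfg.path1_rnn_units
        else:
            head_in += f  # global average pooling adds no parameters
    if use_path2:
        u_w = cfg.window_rnn_units
        total += _lstm_params(cfg.n_input_channels, u_w)
        total += _dense_params(u_w, u_w)  # channel attention
        total += _lstm_params(u_w, cfg.path2_rnn_units)
        total += _dense_params(cfg.path2_rnn_units, cfg.path2_dense_units)
        head_in += cfg.path2_dense_units
    total += _dense_params(head_in, cfg.n_classes)
    return total


# --------------------------------------------------------------------------
# parameters & layers


class Initializer:
    """Glorot-uniform conv/dense weights, orthogonal recurrent kernels,
    zero biases."""

    def __init__(self, rng: np.random.Generator, dtype):
        self.rng = rng
        self.dtype = dtype

    def glorot(self, shape, fan_in, fan_out) -> Tensor:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w = self.rng.uniform(-limit, limit, size=shape).astype(self.dtype)
        return Tensor(w, requires_grad=True)

    def orthogonal(self, rows, cols) -> Tensor:
        # built from square orthogonal blocks (one per gate for an LSTM)
        blocks = []
        remaining = cols
        while remaining > 0:
            a = self.rng.standard_normal((rows, rows))
            q, r = np.linalg.qr(a)
            q = q * np.sign(np.diag(r))
            take = min(rows, remaining)
            blocks.append(q[:, :take])
            remaining -= take
        return Tensor(np.hstack(blocks).astype(self.dtype), requires_grad=True)

    def zeros(self, shape) -> Tensor:
        return Tensor(np.zeros(shape, dtype=self.dtype), requires_grad=True)


class GatedDilatedLayer:
    """One modified-WaveNet layer: gated dilated convolution + residual.

    ``forward`` returns ``(residual_out, gated)``: the residual output feeds
    the next layer, the gated (pre-residual) output is accumulated into the
    block sum.
    """

    def __init__(self, cin: int, filters: int, kernel: int, dilation: int,
                 init: Initializer):
        self.dilation = dilation
        fan_in, fan_out = cin * kernel, filters * kernel
        self.wf = init.glorot((kernel, cin, filters), fan_in, fan_out)
        self.bf = init.zeros(filters)
        self.wg = init.glorot((kernel, cin, filters), fan_in, fan_out)
        self.bg = init.zeros(filters)
        self.wr = init.glorot((1, cin, filters), cin, filters)
        self.br = init.zeros(filters)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        gated = (x.causal_conv1d(self.wf, self.bf, self.dilation).tanh()
                 * x.causal_conv1d(self.wg, self.bg, self.dilation).sigmoid())
        res = gated + x.causal_conv1d(self.wr, self.br, 1)
        return res, gated

    def parameters(self):
        return [self.wf, self.bf, self.wg, self.bg, self.wr, self.br]


class WaveBlock:
    """A chain of gated dilated layers; output = sum of gated outputs."""

    def __init__(self, cin: int, dilations, filters: int, kernel: int,
                 init: Initializer):
        self.layers = []
        for d in dilations:
            self.layers.append(GatedDilatedLayer(cin, filters, kernel, d, init))
            cin = filters

    def forward(self, x: Tensor) -> Tensor:
        acc = None
        for layer in self.layers:
            x, gated = layer.forward(x)
            acc = gated if acc is None else acc + gated
        return acc

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class LSTMLayer:
    """LSTM returning its final hidden state (single-bias convention)."""

    def __init__(self, cin: int, units: int, init: Initializer):
        self.wx = init.glorot((cin, 4 * units), cin, 4 * units)
        self.wh = init.orthogonal(units, 4 * units)
        self.b = init.zeros(4 * units)

    def forward(self, x: Tensor) -> Tensor:
        return x.lstm_last(self.wx, self.wh, self.b)

    def parameters(self):
        return [self.wx, self.wh, self.b]


class Dense:
    def __init__(self, cin: int, cout: int, init: Initializer):
        self.w = init.glorot((cin, cout), cin, cout)
        self.b = init.zeros(cout)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def parameters(self):
        return [self.w, self.b]


class ChannelAttention:
    """Softmax re-weighting of channels from their temporal mean.

    ``a = softmax(mean_t(h) @ W + b)`` over the channel axis; the sequence
    is scaled per channel by ``a`` (broadcast over steps), so the weights of
    each sample sum to 1.
    """

    def __init__(self, channels: int, init: Initializer):
        self.w = init.glorot((channels, channels), channels, channels)
        self.b = init.zeros(channels)

    def attention_weights(self, h: Tensor) -> Tensor:
        return (h.mean(axis=1) @ self.w + self.b).softmax(axis=-1)

    def forward(self, h: Tensor) -> Tensor:
        a = self.attention_weights(h)  # (N, C)
        n, c = a.shape
        return h * a.reshape(n, 1, c)

    def parameters(self):
        return [self.w, self.b]


# --------------------------------------------------------------------------
# the dual-path model


def gated_dilated_layer(x: Tensor, filters: int, kernel: int, dilation: int,
                        init: Initializer | None = None,
                        layer: GatedDilatedLayer | None = None
                        ) -> tuple[Tensor, Tensor]:
    """Functional wrapper: apply one gated dilated layer to ``(N, L, C)``."""
    if layer is None:
        if init is None:
            init = Initializer(np.random.default_rng(0), np.float32)
        layer = GatedDilatedLayer(x.shape[-1], filters, kernel, dilation, init)
    return layer.forward(x)


def wave_block(x: Tensor, dilations, filters: int, kernel: int,
               init: Initializer | None = None,
               block: WaveBlock | None = None) -> Tensor:
    """Functional wrapper: apply one wave block to ``(N, L, C)``."""
    if block is None:
        if init is None:
            init = Initializer(np.random.default_rng(0), np.float32)
        block = WaveBlock(x.shape[-1], dilations, filters, kernel, init)
    return block.forward(x)


def channel_attention(h: Tensor, att: ChannelAttention | None = None) -> Tensor:
    """Functional wrapper: softmax channel attention on ``(N, T, C)``."""
    if att is None:
        att = ChannelAttention(h.shape[-1],
                               Initializer(np.random.default_rng(0), np.float32))
    return att.forward(h)


class DualPathModel:
    """The assembled network for one variant; see the module docstring."""

    def __init__(self, cfg: ModelConfig, variant: str = "full", seed: int = 0):
        if variant not in VARIANTS:
            raise ParameterError(f"unknown variant {variant!r}; valid: {VARIANTS}")
        self.cfg = cfg
        self.variant = variant
        self.dtype = np.dtype(cfg.dtype)
        init = Initializer(np.random.default_rng(seed), self.dtype)
        self._dropout_rng = np.random.default_rng(seed + 1)

        self.use_path1 = variant != "ablation3"
        self.use_path2 = variant in ("full", "ablation2", "ablation3")
        self.path1_lstm_tail = variant in ("full", "ablation1")

        head_in = 0
        if self.use_path1:
            self.blocks = []
            cin = cfg.n_input_channels
            for dils in cfg.block_dilations:
                self.blocks.append(
                    WaveBlock(cin, dils, cfg.conv_filters, cfg.kernel_size, init))
                cin = cfg.conv_filters
            if self.path1_lstm_tail:
                self.path1_rnn = LSTMLayer(cfg.conv_filters,
                                           cfg.path1_rnn_units, init)
                head_in += cfg.path1_rnn_units
            else:
                self.path1_rnn = None
                head_in += cfg.conv_filters
        if self.use_path2:
            self.window_rnn = LSTMLayer(cfg.n_input_channels,
                                        cfg.window_rnn_units, init)
            self.attention = ChannelAttention(cfg.window_rnn_units, init)
            self.path2_rnn = LSTMLayer(cfg.window_rnn_units,
                                       cfg.path2_rnn_units, init)
            self.path2_dense = Dense(cfg.path2_rnn_units,
                                     cfg.path2_dense_units, init)
            head_in += cfg.path2_dense_units
        self.head = Dense(head_in, cfg.n_classes, init)

    # -- forward -----------------------------------------------------------

    def _forward_path1(self, x: Tensor, until_block: int | None = None) -> Tensor:
        for bi, block in enumerate(self.blocks):
            x = block.forward(x)
            if until_block is not None and bi == until_block:
                return x
            x = x.avg_pool1d(self.cfg.pool_factor)
        if self.path1_lstm_tail:
            return self.path1_rnn.forward(x)
        return x.mean(axis=1)  # global average pooling tail

    def _forward_path2(self, x: Tensor, train: bool) -> Tensor:
        cfg = self.cfg
        n = x.shape[0]
        flipped = x.flip_time(axis=1)
        windows = flipped.reshape(n * cfg.n_windows, cfg.window_len,
                                  cfg.n_input_channels)
        enc = self.window_rnn.forward(windows)  # shared across windows
        enc = enc.reshape(n, cfg.n_windows, cfg.window_rnn_units)
        att = self.attention.forward(enc)
        h = self.path2_rnn.forward(att)
        h = h.dropout(cfg.dropout, self._dropout_rng, train)
        return self.path2_dense.forward(h).relu()

    def forward(self, x, train: bool = False) -> Tensor:
        """Logits for a batch ``(N, L, C)`` (numpy array or Tensor)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.ascontiguousarray(x, dtype=self.dtype))
        outs = []
        if self.use_path1:
            outs.append(self._forward_path1(x))
        if self.use_path2:
            outs.append(self._forward_path2(x, train))
        merged = outs[0] if len(outs) == 1 else concat(outs, axis=-1)
        return self.head.forward(merged)

    def predict_proba(self, x) -> np.ndarray:
        """Softmax class probabilities, rows summing to 1."""
        logits = self.forward(x, train=False)
        return logits.softmax(axis=-1).data

    def loss(self, x, y: np.ndarray, train: bool = True
             ) -> tuple[Tensor, np.ndarray]:
        """Mean cross-entropy and probabilities for a labelled batch."""
        logits = self.forward(x, train=train)
        return softmax_cross_entropy(logits, np.asarray(y))

    # -- parameters ----------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        params = []
        if self.use_path1:
            for block in self.blocks:
                params += block.parameters()
            if self.path1_rnn is not None:
                params += self.path1_rnn.parameters()
        if self.use_path2:
            params += self.window_rnn.parameters()
            params += self.attention.parameters()
            params += self.path2_rnn.parameters()
            params += self.path2_dense.parameters()
        params += self.head.parameters()
        return params

    def n_parameters(self) -> int:
        """Trainable parameters actually instantiated (the framework count)."""
        return sum(p.data.size for p in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights, strict=True):
            p.data = w.astype(self.dtype, copy=True)

    def save_weights(self, path) -> None:
        np.savez_compressed(path, *[p.data for p in self.parameters()])

    def load_weights(self, path) -> None:
        z = np.load(path)
        self.set_weights([z[k] for k in z.files])


def build_model(cfg: ModelConfig, variant: str = "full",
                seed: int = 0) -> DualPathModel:
    """Construct a variant of the dual-path network.

    Variants: ``full`` (both paths), ``baseline`` (path 1 with a global-
    average-pooling tail, no path 2), ``ablation1`` (path 1 with its LSTM,
    no path 2), ``ablation2`` (both paths, path-1 LSTM replaced by global
    average pooling), ``ablation3`` (path 2 only).
    """
    model = DualPathModel(cfg, variant, seed=seed)
    expected = count_parameters(cfg, variant)
    actual = model.n_parameters()
    assert actual == expected, (
        f"parameter accounting drifted: closed-form {expected} vs {actual}")
    if variant == "full" and actual > cfg.param_budget:
        raise ParameterError(
            f"full model has {actual} parameters, over budget {cfg.param_budget}")
    return model
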