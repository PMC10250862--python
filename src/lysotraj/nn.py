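"""A small densely-connected convolutional network in pure NumPy.

Implements the DenseNet family used for two-class conformational-state
classification of coordinate-encoded frame images: an initial 3x3
convolution, dense blocks in which every layer's `growth`-channel output is
concatenated onto the running feature map, 1x1-conv + 2x2-average-pool
transitions with a channel `reduction` ratio, global average pooling and a
linear classification head. Forward and backward passes are written out
explicitly, which makes guided backpropagation (the saliency mode, where
the ReLU backward pass additionally gates on positive upstream gradients)
a one-flag variation rather than a framework surgery.

All randomness (initialization, shuffling) is generator-seeded; evaluation
of fixed parameters on a fixed input is deterministic.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["DenseNetLite", "AdamOptimizer", "softmax_cross_entropy"]


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2D:
    """Same-padded stride-1 convolution (k = 1 or 3), NHWC layout."""

    def __init__(self, cin, cout, k, rng):
        self.k = k
        self.W = _he_init(rng, (k * k * cin, cout), k * k * cin)
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._xshape = None

    def forward(self, x):
        B, H, Wd, C = x.shape
        self._xshape = x.shape
        if self.k == 1:
            cols = x.reshape(-1, C)
        else:
            p = self.k // 2
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
            win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
            # (B, H, W, C, k, k) -> (B*H*W, k*k*C) matching W's flatten order
            cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(-1, self.k * self.k * C)
        self._cols = cols
        out = cols @ self.W + self.b
        return out.reshape(B, H, Wd, -1)

    def backward(self, dy):
        B, H, Wd, C = self._xshape
        dyf = dy.reshape(-1, dy.shape[-1])
        self.dW += self._cols.T @ dyf
        self.db += dyf.sum(axis=0)
        dcols = dyf @ self.W.T
        if self.k == 1:
            return dcols.reshape(B, H, Wd, C)
        p = self.k // 2
        dcols = dcols.reshape(B, H, Wd, self.k, self.k, C)
        dxp = np.zeros((B, H + 2 * p, Wd + 2 * p, C))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i:i + H, j:j + Wd] += dcols[:, :, :, i, j]
        return dxp[:, p:p + H, p:p + Wd]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy, guided=False):
        dx = dy * self._mask
        if guided:
            dx = dx * (dy > 0)
        return dx


class AvgPool2:
    """2x2 average pooling, stride 2; odd dims are zero-padded to even."""

    def forward(self, x):
        B, H, W, C = x.shape
        self._orig = (H, W)
        ph, pw = H % 2, W % 2
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)))
        He, We = x.shape[1], x.shape[2]
        self._padded = (He, We)
        return x.reshape(B, He // 2, 2, We // 2, 2, C).mean(axis=(2, 4))

    def backward(self, dy):
        B = dy.shape[0]
        He, We = self._padded
        H, W = self._orig
        dx = np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) / 4.0
        return dx[:, :H, :W]


class Dense:
    def __init__(self, cin, cout, rng):
        self.W = _he_init(rng, (cin, cout), cin)
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class DenseBlock:
    """`n_layers` of ReLU->Conv3x3(growth), each concatenated onto its input."""

    def __init__(self, n_layers, cin, growth, rng):
        self.relus = []
        self.convs = []
        c = cin
        for _ in range(n_layers):
            self.relus.append(ReLU())
            self.convs.append(Conv2D(c, growth, 3, rng))
            c += growth
        self.cout = c

    def forward(self, x):
        self._cins = []
        feat = x
        for relu, conv in zip(self.relus, self.convs):
            self._cins.append(feat.shape[-1])
            new = conv.forward(relu.forward(feat))
            feat = np.concatenate([feat, new], axis=-1)
        return feat

    def backward(self, dy, guided=False):
        for relu, conv, cin in zip(reversed(self.relus), reversed(self.convs),
                                   reversed(self._cins)):
            d_prev, d_new = dy[..., :cin], dy[..., cin:]
            dy = d_prev + relu.backward(conv.backward(d_new), guided)
        return dy

    def params(self):
        return [p for c in self.convs for p in c.params()]


class Transition:
    """ReLU -> 1x1 conv (channel reduction) -> 2x2 average pool."""

    def __init__(self, cin, reduction, rng):
        self.cout = max(1, int(np.floor(cin * reduction)))
        self.relu = ReLU()
        self.conv = Conv2D(cin, self.cout, 1, rng)
        self.pool = AvgPool2()

    def forward(self, x):
        return self.pool.forward(self.conv.forward(self.relu.forward(x)))

    def backward(self, dy, guided=False):
        return self.relu.backward(self.conv.backward(self.pool.backward(dy)),
                                  guided)

    def params(self):
        return self.conv.params()


ARCHITECTURES = {
    # full model as used at production scale
    "full": {"block_layers": (6, 12, 36, 24), "init_filters": 96,
             "growth": 48, "reduction": 0.5},
    # width/depth-reduced variant for desk-scale training; same code path
    "reduced": {"block_layers": (2, 4), "init_filters": 16,
                "growth": 8, "reduction": 0.5},
}


class DenseNetLite:
    """Densely-connected CNN for two-class frame-image classification."""

    def __init__(self, input_shape, n_classes=2, scale="reduced", seed=0,
                 block_layers=None, init_filters=None, growth=None,
                 reduction=None):
        arch = dict(ARCHITECTURES[scale])
        if block_layers is not None:
            arch["block_layers"] = tuple(block_layers)
        if init_filters is not None:
            arch["init_filters"] = init_filters
        if growth is not None:
            arch["growth"] = growth
        if reduction is not None:
            arch["reduction"] = reduction
        self.arch = arch
        self.input_shape = tuple(input_shape)
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)

        c = self.input_shape[-1]
        self.stem = Conv2D(c, arch["init_filters"], 3, rng)
        c = arch["init_filters"]
        self.blocks = []
        self.transitions = []
        for bi, n_layers in enumerate(arch["block_layers"]):
            blk = DenseBlock(n_layers, c, arch["growth"], rng)
            self.blocks.append(blk)
            c = blk.cout
            if bi < len(arch["block_layers"]) - 1:
                tr = Transition(c, arch["reduction"], rng)
                self.transitions.append(tr)
                c = tr.cout
        self.head_relu = ReLU()
        self.fc = Dense(c, n_classes, rng)
        self._gap_hw = None

    # ------------------------------------------------------------------
    def forward(self, x):
        """Logits for a batch of NHWC float images."""
        h = self.stem.forward(x)
        for bi, blk in enumerate(self.blocks):
            h = blk.forward(h)
            if bi < len(self.transitions):
                h = self.transitions[bi].forward(h)
        h = self.head_relu.forward(h)
        self._gap_hw = h.shape[1:3]
        pooled = h.mean(axis=(1, 2))
        return self.fc.forward(pooled)

    def backward(self, dlogits, guided=False):
        """Gradient of the scalar loss wrt the input batch."""
        dpooled = self.fc.backward(dlogits)
        H, W = self._gap_hw
        dh = np.broadcast_to(dpooled[:, None, None, :],
                             (dpooled.shape[0], H, W, dpooled.shape[1])
                             ).copy() / (H * W)
        dh = self.head_relu.backward(dh, guided)
        for bi in range(len(self.blocks) - 1, -1, -1):
            if bi < len(self.transitions):
                dh = self.transitions[bi].backward(dh, guided)
            dh = self.blocks[bi].backward(dh, guided)
        return self.stem.backward(dh)

    def params(self):
        out = self.stem.params()
        for blk in self.blocks:
            out.extend(blk.params())
        for tr in self.transitions:
            out.extend(tr.params())
        out.extend(self.fc.params())
        return out

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0

    # ------------------------------------------------------------------
    def predict_logits(self, x, batch=256):
        outs = [self.forward(x[i:i + batch]) for i in range(0, len(x), batch)]
        return np.concatenate(outs, axis=0)

    def predict(self, x, batch=256):
        return np.argmax(self.predict_logits(x, batch), axis=1)

    def input_gradient(self, x, class_index, guided=True):
        """Gradient of the class score (logit) wrt the input pixels."""
        logits = self.forward(x)
        d = np.zeros_like(logits)
        d[:, class_index] = 1.0
        self.zero_grad()
        return self.backward(d, guided=guided)


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy and its gradient wrt the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class AdamOptimizer:
    """Adaptive-moment-estimation updates over a model's parameter list."""

    def __init__(self, model, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in model.params()]
        self.v = [np.zeros_like(p) for p, _ in model.params()]

    def step(self):
        self.t += 1
        for (p, g), m, v in zip(self.model.params(), self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)
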