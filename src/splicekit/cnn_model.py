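"""The joint donor/acceptor splice-site classifier.

Architecture (defaults): conv(16 features, kernel 5) -> ReLU -> maxpool(2) ->
conv(16, kernel 5) -> ReLU -> maxpool(2) -> flatten -> dense(2) -> softmax.
One joint model handles donors and acceptors: the two central window columns
are always GT or AG, and the network distinguishes the types from them.

The raw score t of a window is the softmax probability of the "splice site"
class, in [0, 1].  Internal activations at the last max-pooling layer are
exposed for activation-rate analysis and embedding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .training_data import DatasetSplit, stack_windows


@dataclass
class CnnConfig:
    in_channels: int = 4
    window: int = 202
    conv_features: tuple[int, int] = (16, 16)
    kernel_sizes: tuple[int, int] = (5, 5)
    pool_sizes: tuple[int, int] = (2, 2)
    n_classes: int = 2
    seed: int = 0

    def layer_lengths(self) -> list[int]:
        """Sequence lengths after each conv/pool stage; validates the chain."""
        l = self.window
        out = []
        for k, p in zip(self.kernel_sizes, self.pool_sizes):
            l = l - k + 1
            if l <= 0:
                raise ValueError("window too small for kernel sizes")
            out.append(l)
            l = l // p
            if l <= 0:
                raise ValueError("window too small for pooling")
            out.append(l)
        return out

    @property
    def flat_features(self) -> int:
        return self.conv_features[1] * self.layer_lengths()[-1]


@dataclass
class TrainState:
    epoch: int = 0
    train_cost: list[float] = field(default_factory=list)
    val_cost: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_cost: float = float("inf")
    stopped_early: bool = False


class CnnModel:
    """Two-layer 1D-CNN with explicit NumPy weights."""

    def __init__(self, config: CnnConfig | None = None):
        self.config = config or CnnConfig()
        c = self.config
        rng = np.random.default_rng(c.seed)
        f1, f2 = c.conv_features
        k1, k2 = c.kernel_sizes

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float64)

        self.params: dict[str, np.ndarray] = {
            "w1": he((f1, c.in_channels, k1), c.in_channels * k1),
            "b1": np.zeros(f1),
            "w2": he((f2, f1, k2), f1 * k2),
            "b2": np.zeros(f2),
            "wd": np.zeros((c.n_classes, c.flat_features)),
            "bd": np.zeros(c.n_classes),
        }

    # ---- forward / backward -------------------------------------------------

    def _forward_full(self, x: np.ndarray):
        """x: (B, 4, W) -> (probs, last-pool activations, caches)."""
        p = self.params
        c1, cc1 = nn.conv1d_forward(x, p["w1"], p["b1"])
        r1, cr1 = nn.relu_forward(c1)
        p1, cp1 = nn.maxpool1d_forward(r1, self.config.pool_sizes[0])
        c2, cc2 = nn.conv1d_forward(p1, p["w2"], p["b2"])
        r2, cr2 = nn.relu_forward(c2)
        p2, cp2 = nn.maxpool1d_forward(r2, self.config.pool_sizes[1])
        flat = p2.reshape(len(x), -1)
        logits, cd = nn.dense_forward(flat, p["wd"], p["bd"])
        probs = nn.softmax(logits)
        caches = (cc1, cr1, cp1, cc2, cr2, cp2, p2.shape, cd)
        return probs, p2, caches

    def forward(self, windows: np.ndarray) -> np.ndarray:
        """Raw score t in [0,1] (probability of the site class) per window.

        Accepts one (4, W) window or a (B, 4, W) batch.
        """
        x = np.asarray(windows, dtype=np.float64)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.shape[1:] != (self.config.in_channels, self.config.window):
            raise ValueError(
                f"window shape {x.shape[1:]} does not match config "
                f"({self.config.in_channels}, {self.config.window})"
            )
        probs, _, _ = self._forward_full(x)
        t = probs[:, 1]
        return float(t[0]) if single else t

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy and gradients w.r.t. every parameter."""
        probs, _, caches = self._forward_full(np.asarray(x, dtype=np.float64))
        loss = nn.cross_entropy(probs, y)
        cc1, cr1, cp1, cc2, cr2, cp2, p2shape, cd = caches
        dlogits = nn.softmax_ce_backward(probs, y)
        dflat, dwd, dbd = nn.dense_backward(dlogits, cd)
        dp2 = dflat.reshape(p2shape)
        dr2 = nn.maxpool1d_backward(dp2, cp2)
        dc2 = nn.relu_backward(dr2, cr2)
        dp1, dw2, db2 = nn.conv1d_backward(dc2, cc2)
        dr1 = nn.maxpool1d_backward(dp1, cp1)
        dc1 = nn.relu_backward(dr1, cr1)
        _, dw1, db1 = nn.conv1d_backward(dc1, cc1)
        grads = {"w1": dw1, "b1": db1, "w2": dw2, "b2": db2, "wd": dwd, "bd": dbd}
        return loss, grads

    # ---- introspection ------------------------------------------------------

    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def embed(self, windows: np.ndarray) -> np.ndarray:
        """(n, features*positions) activations at the last max-pooling layer."""
        x = np.asarray(windows, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        _, p2, _ = self._forward_full(x)
        return p2.reshape(len(x), -1)

    def last_pool_activations(self, windows: np.ndarray) -> np.ndarray:
        x = np.asarray(windows, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        _, p2, _ = self._forward_full(x)
        return p2

    def activation_rate_diff(
        self, positives: np.ndarray, negatives: np.ndarray
    ) -> np.ndarray:
        """Activation-rate difference at the last max-pooling layer.

        The activation rate of a cell is the frequency of it being strictly
        positive over a window set; the return is rate(pos) - rate(neg), a
        (features x positions) matrix with entries in [-1, 1].
        """
        rp = (self.last_pool_activations(positives) > 0).mean(axis=0)
        rn = (self.last_pool_activations(negatives) > 0).mean(axis=0)
        return rp - rn

    # ---- persistence --------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.array(arrays[k], dtype=np.float64)

    def save(self, path, calibration=None) -> None:
        """Single-file .npz checkpoint: config JSON + weights (+ calibration)."""
        payload = {f"param_{k}": v for k, v in self.params.items()}
        payload["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        if calibration is not None:
            payload.update(calibration.to_arrays())
        np.savez(path, **payload)

    @classmethod
    def load(cls, path):
        """Returns (model, calibration-or-None)."""
        from .calibration import CalibrationTable

        with np.load(path) as z:
            cfg = json.loads(bytes(z["config_json"]).decode())
            for k in ("conv_features", "kernel_sizes", "pool_sizes"):
                cfg[k] = tuple(cfg[k])
            model = cls(CnnConfig(**cfg))
            model.load_state({k[6:]: z[k] for k in z.files if k.startswith("param_")})
            calib = None
            if "calib_P" in z.files:
                calib = CalibrationTable.from_arrays({k: z[k] for k in z.files})
        return model, calib


def train(
    model: CnnModel,
    split: DatasetSplit,
    lr: float = 1e-3,
    batch_size: int = 64,
    max_epochs: int = 100,
    patience: int = 3,
    seed: int = 0,
) -> TrainState:
    """Minimize cross-entropy with Adam; early-stop on validation cost.

    Training stops after `patience` consecutive epochs without improvement of
    the validation cost, and the best-validation weights are restored.
    Fully deterministic for a fixed seed (init, shuffling, batching).
    """
    if not split.train or not split.validation:
        raise ValueError("train and validation sets must both be non-empty")
    Xtr, ytr = stack_windows(split.train)
    Xva, yva = stack_windows(split.validation)
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.params, lr=lr)
    state = TrainState()
    best_weights = model.state_arrays()
    bad_epochs = 0
    for epoch in range(max_epochs):
        order = rng.permutation(len(Xtr))
        costs = []
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            loss, grads = model.loss_and_grad(Xtr[idx], ytr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (cost={loss}) at epoch {epoch}"
                )
            opt.step(grads)
            costs.append(loss)
        probs, _, _ = model._forward_full(Xva.astype(np.float64))
        val_cost = nn.cross_entropy(probs, yva)
        state.epoch = epoch + 1
        state.train_cost.append(float(np.mean(costs)))
        state.val_cost.append(float(val_cost))
        if val_cost < state.best_val_cost:
            state.best_val_cost = float(val_cost)
            state.best_epoch = epoch
            best_weights = model.state_arrays()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= patience:
                state.stopped_early = True
                break
    model.load_state(best_weights)
    return state
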