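"""Sequence regressor: fully connected encoder -> LSTM -> linear head.

Implemented directly on numpy (forward pass, backpropagation through time,
Adam) so training is dependency-free and bit-reproducible from a seed.  Each
time step's input (dynamic drivers concatenated with static fields) passes
through a small fully connected encoder with ReLU and dropout, then a
standard LSTM whose hidden and cell state start at zero, then a linear layer
mapping the hidden state to one scalar prediction per step.

The training objective is mean squared error over the steps flagged by a
loss mask; masked-out steps contribute exactly zero gradient.  Early
stopping monitors a validation loss and restores the best parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = ["ModelConfig", "SeqModel", "build_model", "train", "predict",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    n_features: int = 27
    fc_layers: int = 2
    fc_width: int = 128
    dropout: float = 0.1
    lstm_layers: int = 1
    lstm_hidden: int = 256
    batch_size: int = 20
    learning_rate: float = 1e-3
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.fc_layers < 0 or self.lstm_layers < 1:
            raise ValueError("fc_layers must be >= 0, lstm_layers >= 1")
        for name in ("n_features", "fc_width", "lstm_hidden", "batch_size",
                     "learning_rate", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class SeqModel:
    """Encoder + LSTM + linear head with manual backprop."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, np.ndarray] = {}
        d = cfg.n_features
        for i in range(cfg.fc_layers):
            w = cfg.fc_width
            scale = np.sqrt(2.0 / d)  # He init for ReLU
            self.params[f"enc_W{i}"] = rng.normal(0.0, scale, size=(d, w))
            self.params[f"enc_b{i}"] = np.zeros(w)
            d = w
        for l in range(cfg.lstm_layers):
            h = cfg.lstm_hidden
            bound = 1.0 / np.sqrt(h)
            self.params[f"lstm_Wx{l}"] = rng.uniform(-bound, bound, size=(d, 4 * h))
            self.params[f"lstm_Wh{l}"] = rng.uniform(-bound, bound, size=(h, 4 * h))
            b = np.zeros(4 * h)
            b[h:2 * h] = 1.0  # forget-gate bias: remember by default
            self.params[f"lstm_b{l}"] = b
            d = h
        bound = 1.0 / np.sqrt(d)
        self.params["head_W"] = rng.uniform(-bound, bound, size=(d, 1))
        self.params["head_b"] = np.zeros(1)
        self.history: list[dict] = []

    # -- forward ---------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Run the network on ``x`` of shape (batch, T, n_features).

        Returns predictions (batch, T) and, when ``train``, a cache for
        :meth:`backward`.  Dropout is active only when ``train`` is true.
        """
        cfg = self.cfg
        x = np.asarray(x, dtype=float)
        if x.ndim != 3 or x.shape[2] != cfg.n_features:
            raise ValueError(
                f"expected input (batch, T, {cfg.n_features}); got {x.shape}"
            )
        B, T, _ = x.shape
        cache: dict = {"x": x, "enc": [], "drop": [], "lstm": []}
        a = x.reshape(B * T, -1)
        for i in range(cfg.fc_layers):
            z = a @ self.params[f"enc_W{i}"] + self.params[f"enc_b{i}"]
            relu = np.maximum(z, 0.0)
            if train and cfg.dropout > 0.0:
                if rng is None:
                    raise ValueError("training forward pass needs an rng for dropout")
                keep = 1.0 - cfg.dropout
                mask = (rng.random(relu.shape) < keep) / keep
                out = relu * mask
            else:
                mask = None
                out = relu
            cache["enc"].append((a, z))
            cache["drop"].append(mask)
            a = out
        seq = a.reshape(B, T, -1)
        for l in range(cfg.lstm_layers):
            Wx = self.params[f"lstm_Wx{l}"]
            Wh = self.params[f"lstm_Wh{l}"]
            b = self.params[f"lstm_b{l}"]
            H = cfg.lstm_hidden
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            gates_i = np.empty((T, B, H)); gates_f = np.empty((T, B, H))
            gates_g = np.empty((T, B, H)); gates_o = np.empty((T, B, H))
            cs = np.empty((T, B, H)); tanh_cs = np.empty((T, B, H))
            hs = np.empty((T, B, H)); h_prevs = np.empty((T, B, H))
            c_prevs = np.empty((T, B, H))
            xW = seq @ Wx  # (B, T, 4H)
            for t in range(T):
                z = xW[:, t] + h @ Wh + b
                i_g = _sigmoid(z[:, :H])
                f_g = _sigmoid(z[:, H:2 * H])
                g_g = np.tanh(z[:, 2 * H:3 * H])
                o_g = _sigmoid(z[:, 3 * H:])
                h_prevs[t] = h; c_prevs[t] = c
                c = f_g * c + i_g * g_g
                tc = np.tanh(c)
                h = o_g * tc
                gates_i[t], gates_f[t] = i_g, f_g
                gates_g[t], gates_o[t] = g_g, o_g
                cs[t], tanh_cs[t], hs[t] = c, tc, h
            cache["lstm"].append(
                dict(x=seq, i=gates_i, f=gates_f, g=gates_g, o=gates_o,
                     c=cs, tanh_c=tanh_cs, h=hs, h_prev=h_prevs, c_prev=c_prevs)
            )
            seq = np.moveaxis(hs, 0, 1)  # (B, T, H)
        cache["top"] = seq
        y = (seq.reshape(B * T, -1) @ self.params["head_W"]
             + self.params["head_b"]).reshape(B, T)
        if train:
            return y, cache
        return y

    # -- backward --------------------------------------------------------

    def backward(self, cache: dict, dy: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss with upstream dL/dy of shape (B, T)."""
        cfg = self.cfg
        B, T = dy.shape
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        top = cache["top"].reshape(B * T, -1)
        dflat = dy.reshape(B * T, 1)
        grads["head_W"] = top.T @ dflat
        grads["head_b"] = dflat.sum(axis=0)
        dseq = (dflat @ self.params["head_W"].T).reshape(B, T, -1)
        H = cfg.lstm_hidden
        for l in range(cfg.lstm_layers - 1, -1, -1):
            st = cache["lstm"][l]
            Wx = self.params[f"lstm_Wx{l}"]
            Wh = self.params[f"lstm_Wh{l}"]
            dWx = np.zeros_like(Wx); dWh = np.zeros_like(Wh)
            db = np.zeros(4 * H)
            dx = np.empty_like(st["x"])
            dh_next = np.zeros((B, H)); dc_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                dh = dseq[:, t] + dh_next
                o = st["o"][t]; tc = st["tanh_c"][t]
                do = dh * tc
                dc = dh * o * (1.0 - tc * tc) + dc_next
                i_g = st["i"][t]; f_g = st["f"][t]; g_g = st["g"][t]
                di = dc * g_g
                df = dc * st["c_prev"][t]
                dg = dc * i_g
                dc_next = dc * f_g
                dz = np.concatenate(
                    [di * i_g * (1 - i_g), df * f_g * (1 - f_g),
                     dg * (1 - g_g * g_g), do * o * (1 - o)], axis=1)
                dWx += st["x"][:, t].T @ dz
                dWh += st["h_prev"][t].T @ dz
                db += dz.sum(axis=0)
                dx[:, t] = dz @ Wx.T
                dh_next = dz @ Wh.T
            grads[f"lstm_Wx{l}"] = dWx
            grads[f"lstm_Wh{l}"] = dWh
            grads[f"lstm_b{l}"] = db
            dseq = dx
        da = dseq.reshape(B * T, -1)
        for i in range(cfg.fc_layers - 1, -1, -1):
            a_in, z = cache["enc"][i]
            mask = cache["drop"][i]
            if mask is not None:
                da = da * mask
            dz = da * (z > 0)
            grads[f"enc_W{i}"] = a_in.T @ dz
            grads[f"enc_b{i}"] = dz.sum(axis=0)
            da = dz @ self.params[f"enc_W{i}"].T
        return grads

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, mask: np.ndarray,
                       rng: np.random.Generator):
        """Masked MSE and its parameter gradients for one mini-batch."""
        mask = np.asarray(mask, dtype=bool)
        n = mask.sum()
        if n == 0:
            raise ValueError("loss mask selects no time steps")
        pred, cache = self.forward(x, train=True, rng=rng)
        resid = np.where(mask, pred - y, 0.0)
        loss = float(np.sum(resid * resid) / n)
        dy = 2.0 * resid / n
        return loss, self.backward(cache, dy)

    # -- parameter bookkeeping -------------------------------------------

    def get_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()

    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())


def build_model(cfg: ModelConfig) -> SeqModel:
    """Construct a sequence model with seeded, deterministic initialization."""
    return SeqModel(cfg)


def save_checkpoint(model: SeqModel, path: str | Path,
                    extra: dict | None = None) -> Path:
    """Serialize parameters with the config (and e.g. standardization
    statistics) embedded, plus the training log as CSV alongside."""
    path = Path(path)
    meta = {"config": asdict(model.cfg), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.params)
    if model.history:
        lines = ["epoch,train_loss,val_loss"] + [
            f"{h['epoch']},{h['train_loss']},{h['val_loss']}"
            for h in model.history]
        path.with_suffix(".log.csv").write_text("\n".join(lines) + "\n")
    return path if path.suffix == ".npz" else path.with_suffix(
        path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> tuple[SeqModel, dict]:
    """Rebuild a model from :func:`save_checkpoint` output."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = SeqModel(ModelConfig(**meta["config"]))
        model.set_params({k: data[k] for k in model.params})
    return model, meta["extra"]


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


def _masked_mse(model: SeqModel, batches) -> float:
    num = den = 0.0
    for x, y, mask in batches:
        pred = model.forward(x)
        m = np.asarray(mask, bool)
        r = np.where(m, pred - y, 0.0)
        num += float(np.sum(r * r))
        den += int(m.sum())
    if den == 0:
        raise ValueError("validation mask selects no time steps")
    return num / den


def train(model: SeqModel, train_batches, val_batches, cfg: ModelConfig | None = None,
          rng: np.random.Generator | None = None) -> SeqModel:
    """Adam training with masked MSE and early stopping.

    ``train_batches`` is either a list of ``(x, y, loss_mask)`` tuples or a
    callable ``f(rng) -> iterable of such tuples``, invoked once per epoch so
    that callers can redraw permutation schemes.  ``val_batches`` is a static
    list evaluated with dropout off.  The parameters achieving the best
    validation loss are restored before returning; per-epoch losses are
    appended to ``model.history``.
    """
    cfg = cfg or model.cfg
    rng = rng or np.random.default_rng(cfg.seed + 1)
    opt = _Adam(model.params, cfg.learning_rate)
    best_val = np.inf
    best_params = model.get_params()
    bad_epochs = 0
    for epoch in range(cfg.max_epochs):
        batches = train_batches(rng) if callable(train_batches) else train_batches
        losses = []
        saw_mask = False
        for x, y, mask in batches:
            if not np.any(mask):
                continue
            saw_mask = True
            loss, grads = model.loss_and_grads(x, y, mask, rng)
            opt.step(model.params, grads)
            losses.append(loss)
        if not saw_mask:
            raise ValueError("every training batch has an empty loss mask")
        val = _masked_mse(model, val_batches)
        model.history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val}
        )
        if val < best_val:
            best_val = val
            best_params = model.get_params()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.patience:
                break
    model.set_params(best_params)
    return model


def predict(model: SeqModel, features: np.ndarray, warmup_steps: int = 0
            ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic predictions plus an evaluable-step mask.

    The first ``warmup_steps`` of each sequence are predicted but flagged as
    excluded from evaluation: the recurrent state starts at zero and needs to
    encode some history first.
    """
    features = np.asarray(features, dtype=float)
    single = features.ndim == 2
    if single:
        features = features[None]
    B, T, _ = features.shape
    if T < warmup_steps:
        raise ValueError(f"sequence length {T} shorter than warmup {warmup_steps}")
    pred = model.forward(features)
    evaluable = np.ones((B, T), dtype=bool)
    evaluable[:, :warmup_steps] = False
    if single:
        return pred[0], evaluable[0]
    return pred, evaluable
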