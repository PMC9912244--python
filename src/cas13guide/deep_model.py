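"""The two-branch convolutional-recurrent guide-efficiency network.

One branch reads the one-hot spacer sequence (L x 4), the other the
one-hot dot-bracket secondary structure (L x 3).  Each branch is

    conv -> batch-norm -> ReLU
    conv -> batch-norm -> ReLU
    dropout(0.5) -> masked max-pool
    LSTM -> dropout(0.3) -> dense

and the two branch embeddings are concatenated and passed through a
fully connected layer to a single sigmoid-bounded output, the "deep
score" in [0, 1].  Training minimizes mean squared error against the
sigmoid-normalized LFC target (see :mod:`cas13guide.encoding`).

The network is small (well under a million parameters) and runs on CPU;
it is implemented directly on the numpy autodiff in
:mod:`cas13guide.nn`, so identical seeds give identical results.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from . import nn
from .encoding import (
    DEFAULT_LENGTH,
    EncodedGuide,
    SigmoidParams,
    encode_guide,
    lfc_to_target,
    solve_sigmoid_params,
    stack_encoded,
)
from .structure import default_engine, fold_mfe


@dataclass
class ModelConfig:
    """Hyperparameters of the guide-efficiency network.

    The topology (two conv layers per branch, 50% conv dropout, 30%
    recurrent dropout, LSTM, dense head with a sigmoid output) is fixed;
    the sizes below are configurable.
    """

    conv_filters: int = 32
    conv_kernel: int = 4          # receptive field along the sequence axis
    dense_units: int = 64
    dropout_conv: float = 0.5
    dropout_lstm: float = 0.3
    recurrent_units: int = 64
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_filters < 1 or self.recurrent_units < 1 or self.dense_units < 1:
            raise ValueError("layer sizes must be >= 1")
        if not (0.0 <= self.dropout_conv < 1.0 and 0.0 <= self.dropout_lstm < 1.0):
            raise ValueError("dropout rates must be in [0, 1)")
        if self.optimizer not in nn.OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}; choose from {sorted(nn.OPTIMIZERS)}")


class _BatchNorm:
    def __init__(self, channels: int):
        self.gamma = nn.Tensor(np.ones(channels), requires_grad=True)
        self.beta = nn.Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = 0.9
        self.eps = 1e-5

    def __call__(self, x: nn.Tensor, train: bool) -> nn.Tensor:
        if train:
            mu = x.mean(axis=(0, 1), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 1), keepdims=True)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu.data.ravel()
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var.data.ravel()
            xn = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = nn.Tensor(self.running_mean)
            var = nn.Tensor(self.running_var)
            xn = (x - mu) / ((var + self.eps) ** 0.5)
        return xn * self.gamma + self.beta

    @property
    def params(self) -> list[nn.Tensor]:
        return [self.gamma, self.beta]


class _LSTM:
    """Single-layer LSTM returning the final hidden state."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int):
        s = 1.0 / np.sqrt(n_in + n_hidden)
        self.W = nn.Tensor(rng.uniform(-s, s, (n_in, 4 * n_hidden)), requires_grad=True)
        self.U = nn.Tensor(rng.uniform(-s, s, (n_hidden, 4 * n_hidden)), requires_grad=True)
        self.b = nn.Tensor(np.zeros(4 * n_hidden), requires_grad=True)
        self.n_hidden = n_hidden

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        B, T, _ = x.data.shape
        H = self.n_hidden
        h = nn.Tensor(np.zeros((B, H)))
        c = nn.Tensor(np.zeros((B, H)))
        for t in range(T):
            xt = x[:, t, :]
            gates = xt @ self.W + h @ self.U + self.b
            i = gates[:, :H].sigmoid()
            f = gates[:, H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h

    @property
    def params(self) -> list[nn.Tensor]:
        return [self.W, self.U, self.b]


class _Dense:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        s = np.sqrt(2.0 / n_in)
        self.W = nn.Tensor(rng.normal(0.0, s, (n_in, n_out)), requires_grad=True)
        self.b = nn.Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return x @ self.W + self.b

    @property
    def params(self) -> list[nn.Tensor]:
        return [self.W, self.b]


class _Branch:
    """conv-BN-ReLU x2 -> dropout -> masked max-pool -> LSTM -> dropout -> dense."""

    def __init__(self, rng: np.random.Generator, cfg: ModelConfig, channels_in: int):
        k, F = cfg.conv_kernel, cfg.conv_filters
        s1 = np.sqrt(2.0 / (k * channels_in))
        s2 = np.sqrt(2.0 / (k * F))
        self.w1 = nn.Tensor(rng.normal(0.0, s1, (k, channels_in, F)), requires_grad=True)
        self.b1 = nn.Tensor(np.zeros(F), requires_grad=True)
        self.bn1 = _BatchNorm(F)
        self.w2 = nn.Tensor(rng.normal(0.0, s2, (k, F, F)), requires_grad=True)
        self.b2 = nn.Tensor(np.zeros(F), requires_grad=True)
        self.bn2 = _BatchNorm(F)
        self.lstm = _LSTM(rng, F, cfg.recurrent_units)
        self.dense = _Dense(rng, cfg.recurrent_units, cfg.dense_units)
        self.cfg = cfg
        self.n_conv_layers = 2

    def __call__(self, x: nn.Tensor, mask: np.ndarray, train: bool,
                 rng: np.random.Generator | None) -> nn.Tensor:
        cfg = self.cfg
        h = nn.conv1d_same(x, self.w1, self.b1)
        h = self.bn1(h, train).relu()
        h = nn.conv1d_same(h, self.w2, self.b2)
        h = self.bn2(h, train).relu()
        if train and cfg.dropout_conv > 0:
            keep = (rng.random(h.data.shape) >= cfg.dropout_conv) / (1 - cfg.dropout_conv)
            h = h * nn.Tensor(keep)
        h = h * nn.Tensor(mask[:, :, None])  # silence padded positions
        h = nn.maxpool1d(h, 2)
        h = self.lstm(h)
        if train and cfg.dropout_lstm > 0:
            keep = (rng.random(h.data.shape) >= cfg.dropout_lstm) / (1 - cfg.dropout_lstm)
            h = h * nn.Tensor(keep)
        return self.dense(h).relu()

    @property
    def params(self) -> list[nn.Tensor]:
        return ([self.w1, self.b1] + self.bn1.params + [self.w2, self.b2]
                + self.bn2.params + self.lstm.params + self.dense.params)


class CRNN:
    """The full two-branch network.  Build with :func:`build_crnn`."""

    def __init__(self, config: ModelConfig, L: int = DEFAULT_LENGTH,
                 use_structure: bool = True):
        if config.conv_kernel > L:
            raise ValueError(f"conv kernel {config.conv_kernel} larger than input length {L}")
        self.config = config
        self.L = L
        self.use_structure = use_structure
        rng = np.random.default_rng(config.seed)
        self.seq_branch = _Branch(rng, config, channels_in=4)
        self.struct_branch = _Branch(rng, config, channels_in=3) if use_structure else None
        n_embed = config.dense_units * (2 if use_structure else 1)
        self.fc = _Dense(rng, n_embed, config.dense_units)
        self.head = _Dense(rng, config.dense_units, 1)
        self.trained = False

    # ------------------------------------------------------------ forward
    def forward(self, seq: nn.Tensor, struct: nn.Tensor, mask: np.ndarray,
                train: bool = False, rng: np.random.Generator | None = None) -> nn.Tensor:
        hs = self.seq_branch(seq, mask, train, rng)
        if self.use_structure:
            ht = self.struct_branch(struct, mask, train, rng)
            h = nn.concat([hs, ht], axis=1)
        else:
            h = hs
        h = self.fc(h).relu()
        out = self.head(h).sigmoid()
        return out.reshape(-1)

    @property
    def params(self) -> list[nn.Tensor]:
        p = list(self.seq_branch.params)
        if self.use_structure:
            p += self.struct_branch.params
        p += self.fc.params + self.head.params
        return p

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def architecture_summary(self) -> dict:
        branches = {"sequence": {"conv_layers": self.seq_branch.n_conv_layers,
                                 "dropout_conv": self.config.dropout_conv,
                                 "dropout_recurrent": self.config.dropout_lstm}}
        if self.use_structure:
            branches["structure"] = {"conv_layers": self.struct_branch.n_conv_layers,
                                     "dropout_conv": self.config.dropout_conv,
                                     "dropout_recurrent": self.config.dropout_lstm}
        return {"branches": branches, "output": "sigmoid", "n_parameters": self.n_parameters()}


def build_crnn(config: ModelConfig | None = None, L: int = DEFAULT_LENGTH,
               use_structure: bool = True) -> CRNN:
    """Construct the untrained two-branch network."""
    return CRNN(config or ModelConfig(), L=L, use_structure=use_structure)


def fit(model: CRNN, seq: np.ndarray, struct: np.ndarray, mask: np.ndarray,
        targets: np.ndarray, config: ModelConfig | None = None) -> list[float]:
    """Train the network with minibatch MSE; returns per-epoch loss history.

    ``targets`` must already be on the (0, 1) normalized scale.
    Aborts with diagnostics if the loss goes non-finite.
    """
    cfg = config or model.config
    n = len(targets)
    if n < 100:
        import warnings

        warnings.warn(f"only {n} training pairs; the fit may be unstable", stacklevel=2)
    rng = np.random.default_rng(cfg.seed + 1)
    opt_cls = nn.OPTIMIZERS[cfg.optimizer]
    opt = opt_cls(model.params, lr=cfg.learning_rate)
    history: list[float] = []
    y = np.asarray(targets, dtype=np.float64)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = nn.Tensor(seq[idx])
            sb = nn.Tensor(struct[idx])
            pred = model.forward(xb, sb, mask[idx], train=True, rng=rng)
            loss = ((pred - nn.Tensor(y[idx])) ** 2).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: loss={loss.data!r}; "
                    f"lr={cfg.learning_rate}, optimizer={cfg.optimizer}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(idx))
        history.append(sum(losses) / n)
    model.trained = True
    return history


def predict_deep_score(model: CRNN, seq: np.ndarray, struct: np.ndarray,
                       mask: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Deep scores in [0, 1] for encoded guides (eval mode, deterministic)."""
    if not model.trained:
        raise RuntimeError("model is untrained; call fit() first")
    out = []
    for start in range(0, len(seq), batch_size):
        sl = slice(start, start + batch_size)
        pred = model.forward(nn.Tensor(seq[sl]), nn.Tensor(struct[sl]), mask[sl], train=False)
        out.append(pred.data)
    return np.concatenate(out)


def tune_grid(grid: dict[str, list], seq: np.ndarray, struct: np.ndarray,
              mask: np.ndarray, targets: np.ndarray, seed: int = 0,
              base_config: ModelConfig | None = None,
              val_fraction: float = 0.2) -> tuple[ModelConfig, pd.DataFrame]:
    """Exhaustive grid search over hyperparameters; selects min held-out MSE.

    ``grid`` maps ModelConfig field names (e.g. dense_units, dropout_conv,
    optimizer, learning_rate) to candidate values.  Returns the winning
    config and a results table with one row per combination.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must have at least one non-empty axis")
    base = base_config or ModelConfig(seed=seed)
    rng = np.random.default_rng(seed)
    n = len(targets)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    rows = []
    best_cfg, best_mse = None, np.inf
    keys = sorted(grid)
    for combo in itertools.product(*(grid[k] for k in keys)):
        cfg = replace(base, **dict(zip(keys, combo)), seed=seed)
        model = build_crnn(cfg, L=seq.shape[1])
        try:
            fit(model, seq[train_idx], struct[train_idx], mask[train_idx],
                targets[train_idx], cfg)
            pred = predict_deep_score(model, seq[val_idx], struct[val_idx], mask[val_idx])
            mse = float(np.mean((pred - targets[val_idx]) ** 2))
        except RuntimeError:  # diverged (e.g. absurd learning rate)
            mse = np.inf
        rows.append({**dict(zip(keys, combo)), "val_mse": mse})
        if mse < best_mse:
            best_mse, best_cfg = mse, cfg
    return best_cfg, pd.DataFrame(rows)


def _bn_layers(model: CRNN) -> list[_BatchNorm]:
    bns = [model.seq_branch.bn1, model.seq_branch.bn2]
    if model.use_structure:
        bns += [model.struct_branch.bn1, model.struct_branch.bn2]
    return bns


def save_model(model: CRNN, path_prefix: str) -> None:
    """Serialize weights to {prefix}.npz and config to {prefix}.json."""
    import dataclasses
    import json

    arrays = {f"param_{i}": p.data for i, p in enumerate(model.params)}
    for j, bn in enumerate(_bn_layers(model)):
        arrays[f"bn_{j}_mean"] = bn.running_mean
        arrays[f"bn_{j}_var"] = bn.running_var
    np.savez(path_prefix + ".npz", **arrays)
    meta = {"config": dataclasses.asdict(model.config), "L": model.L,
            "use_structure": model.use_structure, "trained": model.trained}
    with open(path_prefix + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_model(path_prefix: str) -> CRNN:
    """Restore a network written by :func:`save_model`."""
    import json

    with open(path_prefix + ".json") as fh:
        meta = json.load(fh)
    model = CRNN(ModelConfig(**meta["config"]), L=meta["L"],
                 use_structure=meta["use_structure"])
    with np.load(path_prefix + ".npz") as data:
        for i, p in enumerate(model.params):
            p.data = data[f"param_{i}"]
        for j, bn in enumerate(_bn_layers(model)):
            bn.running_mean = data[f"bn_{j}_mean"]
            bn.running_var = data[f"bn_{j}_var"]
    model.trained = bool(meta["trained"])
    return model


class DeepGuideScorer(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator for Cas13d guide efficiency.

    ``fit(X, y)`` takes spacers and their measured log2 fold changes;
    the LFCs are normalized internally through the calibrated sigmoid
    and the network is trained against the normalized target.
    ``predict(X)`` returns deep scores in [0, 1]; higher = more likely
    an effective guide.

    Parameters mirror :class:`ModelConfig` plus:

    L : int
        Model input length (guides are right-padded).
    engine : {"auto", "thermo", "maxpair"}
        Folding engine used to build the structure channel.
    use_structure : bool
        If False the structure branch is dropped (ablation).
    target : {"lfc", "score"}
        Whether ``y`` holds raw LFCs (normalized internally) or
        already-normalized scores in (0, 1).
    """

    def __init__(self, conv_filters: int = 32, conv_kernel: int = 4,
                 dense_units: int = 64, dropout_conv: float = 0.5,
                 dropout_lstm: float = 0.3, recurrent_units: int = 64,
                 optimizer: str = "adam", learning_rate: float = 1e-3,
                 epochs: int = 100, batch_size: int = 64, seed: int = 0,
                 L: int = DEFAULT_LENGTH, engine: str = "auto",
                 use_structure: bool = True, target: str = "lfc"):
        self.conv_filters = conv_filters
        self.conv_kernel = conv_kernel
        self.dense_units = dense_units
        self.dropout_conv = dropout_conv
        self.dropout_lstm = dropout_lstm
        self.recurrent_units = recurrent_units
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.L = L
        self.engine = engine
        self.use_structure = use_structure
        self.target = target

    # ------------------------------------------------------------ helpers
    def _config(self) -> ModelConfig:
        return ModelConfig(
            conv_filters=self.conv_filters, conv_kernel=self.conv_kernel,
            dense_units=self.dense_units, dropout_conv=self.dropout_conv,
            dropout_lstm=self.dropout_lstm, recurrent_units=self.recurrent_units,
            optimizer=self.optimizer, learning_rate=self.learning_rate,
            epochs=self.epochs, batch_size=self.batch_size, seed=self.seed,
        )

    def _encode(self, X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if isinstance(X, tuple) and len(X) == 3:
            return X
        if len(X) and isinstance(X[0], EncodedGuide):
            return stack_encoded(list(X))
        eng = default_engine() if self.engine == "auto" else self.engine
        encoded = [encode_guide(s, fold_mfe(s, engine=eng), L=self.L) for s in X]
        return stack_encoded(encoded)

    # ---------------------------------------------------------------- API
    def fit(self, X, y):
        seq, struct, mask = self._encode(X)
        y = np.asarray(y, dtype=np.float64)
        if self.target == "lfc":
            self.sigmoid_params_: SigmoidParams = solve_sigmoid_params()
            targets = lfc_to_target(y, self.sigmoid_params_)
        elif self.target == "score":
            self.sigmoid_params_ = solve_sigmoid_params()
            targets = y
        else:
            raise ValueError(f"unknown target kind {self.target!r}")
        self.model_ = build_crnn(self._config(), L=seq.shape[1],
                                 use_structure=self.use_structure)
        self.history_ = fit(self.model_, seq, struct, mask, targets)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        seq, struct, mask = self._encode(X)
        return predict_deep_score(self.model_, seq, struct, mask)
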