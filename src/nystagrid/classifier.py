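"""Canal classification from grid images.

Two classifiers are provided:

* :class:`CNNClassifier` — a small convolutional network over the 3x10
  single-channel grid: ``conv_depth`` repetitions of [3x3 convolution
  (edge padding) -> batch normalization -> ReLU], channel width starting
  at ``base_neurons`` and doubling per block (capped at 512), then a fully
  connected softmax layer with 8 outputs.  It is trained with
  cross-entropy, the Adam optimizer and early stopping on validation loss.
  The network, its backpropagation and the optimizer are implemented
  directly on NumPy arrays: the input is tiny, so a dedicated deep-learning
  runtime buys nothing, and a from-scratch implementation keeps every
  operation inspectable and exactly seedable.

* :func:`rule_classify` — a deterministic clinical-rule classifier mapping
  decoded grid amplitudes to canal diagnoses: torsional + upbeat in a
  Dix-Hallpike column means posterior-canal BPPV of that side; an opposing
  horizontal pattern across the two supine-roll columns means lateral-canal
  BPPV (geotropic when beating toward the lower ear, ageotropic toward the
  upper ear, side by the standard laterality conventions); torsional +
  downbeat in head-hanging or Dix-Hallpike columns means anterior-canal
  BPPV.  It serves as an independent oracle for the network on clean
  template grids and as a transparent fallback classifier.

Grids are normalized to ``(value - 128) / 128`` before entering the
network, so neutral cells are exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .grid import CLASS_LABELS, TEST_ORDER, GridImage, decode_grid
from .synthetic import GridDataset

__all__ = [
    "NetworkConfig",
    "Prediction",
    "CNNClassifier",
    "build_network",
    "train",
    "predict",
    "rule_classify",
]

_COL = {name: i for i, name in enumerate(TEST_ORDER)}


@dataclass
class NetworkConfig:
    """Architecture and training hyper-parameters of the grid CNN.

    ``conv_depth`` (1-12) and ``base_neurons`` (2-512) span the tuning
    ranges explored for this architecture; defaults sit mid-range for a
    3x10 input.  One integer seed governs parameter initialization and
    data shuffling.
    """

    conv_depth: int = 3
    base_neurons: int = 32
    batch_size: int = 128
    max_epochs: int = 50
    learning_rate: float = 1e-3
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.conv_depth <= 12:
            raise ValueError("conv_depth must be in [1, 12]")
        if not 2 <= self.base_neurons <= 512:
            raise ValueError("base_neurons must be in [2, 512]")
        if self.batch_size < 1 or self.max_epochs < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training hyper-parameters")


@dataclass
class Prediction:
    """Per-class probabilities (summing to 1) and the argmax class."""

    probabilities: np.ndarray
    label: str

    @property
    def label_index(self) -> int:
        return int(np.argmax(self.probabilities))


# ----------------------------------------------------------------------
# layers (forward + backward on plain arrays)
# ----------------------------------------------------------------------

def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patches under 3x3 edge padding."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="edge")
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # N,C,H,W,3,3
    n, c, h, w = x.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add, folding edge padding)."""
    n, c, h, w = shape
    d6 = dcols.reshape(n, h, w, c, 3, 3).transpose(0, 3, 1, 2, 4, 5)
    pad = np.zeros((n, c, h + 2, w + 2))
    for di in range(3):
        for dj in range(3):
            pad[:, :, di : di + h, dj : dj + w] += d6[:, :, :, :, di, dj]
    dx = pad[:, :, 1:-1, 1:-1].copy()
    dx[:, :, 0, :] += pad[:, :, 0, 1:-1]
    dx[:, :, -1, :] += pad[:, :, -1, 1:-1]
    dx[:, :, :, 0] += pad[:, :, 1:-1, 0]
    dx[:, :, :, -1] += pad[:, :, 1:-1, -1]
    dx[:, :, 0, 0] += pad[:, :, 0, 0]
    dx[:, :, 0, -1] += pad[:, :, 0, -1]
    dx[:, :, -1, 0] += pad[:, :, -1, 0]
    dx[:, :, -1, -1] += pad[:, :, -1, -1]
    return dx


class _Conv:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, c_out))
        self.b = np.zeros(c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x)
        n, _, h, w = x.shape
        out = self._cols @ self.w + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, h, w = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, f)
        self.dw = self._cols.T @ dflat
        self.db = dflat.sum(axis=0)
        return _col2im(dflat @ self.w.T, self._shape)

    def params(self):
        return [("w", self), ("b", self)]


class _BatchNorm:
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mu, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu[None, :, None, None]) / self._std[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / self._std[None, :, None, None]
        return dx


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, lr: float):
        self.lr, self.b1, self.b2, self.eps = lr, 0.9, 0.999, 1e-8
        self.t = 0
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self, params: list[tuple[np.ndarray, np.ndarray]]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(params):
            m, v = self.state.get(i, (np.zeros_like(p), np.zeros_like(p)))
            m = self.b1 * m + (1 - self.b1) * g
            v = self.b2 * v + (1 - self.b2) * g * g
            self.state[i] = (m, v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class CNNClassifier:
    """Small CNN over 3x10 grid images; see the module docstring."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.blocks: list[tuple[_Conv, _BatchNorm]] = []
        c_in = 1
        for d in range(config.conv_depth):
            c_out = min(config.base_neurons * 2**d, 512)
            self.blocks.append((_Conv(c_in, c_out, rng), _BatchNorm(c_out)))
            c_in = c_out
        self.fc = _Dense(c_in * 3 * 10, len(CLASS_LABELS), rng)
        self.history: dict[str, list[float]] = {}

    # -- forward / backward -------------------------------------------------
    def _forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for conv, bn in self.blocks:
            x = conv.forward(x)
            x = bn.forward(x, training)
            if training:
                conv._relu_mask = x > 0  # saved on conv for the backward pass
            x = np.maximum(x, 0.0)
        n = x.shape[0]
        self._flat_shape = x.shape
        return self.fc.forward(x.reshape(n, -1))

    def _backward(self, dlogits: np.ndarray) -> None:
        dx = self.fc.backward(dlogits).reshape(self._flat_shape)
        for conv, bn in reversed(self.blocks):
            dx = dx * conv._relu_mask
            dx = bn.backward(dx)
            dx = conv.backward(dx)

    def _grad_params(self):
        out = []
        for conv, bn in self.blocks:
            out += [(conv.w, conv.dw), (conv.b, conv.db), (bn.gamma, bn.dgamma), (bn.beta, bn.dbeta)]
        out += [(self.fc.w, self.fc.dw), (self.fc.b, self.fc.db)]
        return out

    # -- weights ------------------------------------------------------------
    def _weight_arrays(self) -> dict[str, np.ndarray]:
        w = {}
        for i, (conv, bn) in enumerate(self.blocks):
            w[f"conv{i}_w"], w[f"conv{i}_b"] = conv.w, conv.b
            w[f"bn{i}_gamma"], w[f"bn{i}_beta"] = bn.gamma, bn.beta
            w[f"bn{i}_mean"], w[f"bn{i}_var"] = bn.run_mean, bn.run_var
        w["fc_w"], w["fc_b"] = self.fc.w, self.fc.b
        return w

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self._weight_arrays().items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in self._weight_arrays().items():
            v[...] = weights[k]

    def save(self, path: str | Path) -> None:
        """Serialize weights (.npz) with a plain-text config manifest."""
        path = Path(path)
        np.savez(path, **self._weight_arrays())
        manifest = path.with_suffix(".json")
        manifest.write_text(json.dumps(asdict(self.config), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CNNClassifier":
        path = Path(path)
        config = NetworkConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(config)
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
            model.set_weights({k: z[k] for k in z.files})
        return model

    # -- inference ----------------------------------------------------------
    def predict_proba(self, grids: np.ndarray) -> np.ndarray:
        """Probabilities for a batch of grids, shape (N, 3, 10) -> (N, 8)."""
        x = (np.asarray(grids, dtype=float) - 128.0) / 128.0
        if x.ndim != 3 or x.shape[1:] != (3, 10):
            raise ValueError("grids must have shape (N, 3, 10)")
        return _softmax(self._forward(x[:, None], training=False))


def build_network(config: NetworkConfig) -> CNNClassifier:
    """Construct (and seed-initialize) the grid CNN."""
    return CNNClassifier(config)


def _xy(dataset: GridDataset | tuple[np.ndarray, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, GridDataset):
        return dataset.grids, dataset.labels
    return dataset


def train(
    model: CNNClassifier,
    train_set: GridDataset | tuple[np.ndarray, np.ndarray],
    val_set: GridDataset | tuple[np.ndarray, np.ndarray],
) -> dict[str, list[float]]:
    """Train with cross-entropy + Adam, early-stopping on validation loss.

    Stops when the validation loss has not improved for ``patience``
    consecutive epochs (or at ``max_epochs``) and restores the best
    weights.  Returns the per-epoch history with keys ``train_loss``,
    ``train_acc``, ``val_loss``, ``val_acc``.
    """
    cfg = model.config
    xtr, ytr = _xy(train_set)
    xva, yva = _xy(val_set)
    if len(xtr) == 0 or len(xva) == 0:
        raise ValueError("empty dataset")
    xtr = (np.asarray(xtr, dtype=float) - 128.0) / 128.0
    xva = (np.asarray(xva, dtype=float) - 128.0) / 128.0
    rng = np.random.default_rng(cfg.seed + 1)
    opt = _Adam(cfg.learning_rate)
    history: dict[str, list[float]] = {k: [] for k in ("train_loss", "train_acc", "val_loss", "val_acc")}
    best_loss, best_weights, stall = np.inf, model.get_weights(), 0
    n = len(xtr)
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            xb, yb = xtr[idx][:, None], ytr[idx]
            logits = model._forward(xb, training=True)
            p = _softmax(logits)
            losses.append(float(-np.log(p[np.arange(len(yb)), yb] + 1e-12).mean()) * len(yb))
            correct += int((p.argmax(axis=1) == yb).sum())
            dlogits = p.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            model._backward(dlogits / len(yb))
            opt.step(model._grad_params())
        vp = _softmax(model._forward(xva[:, None], training=False))
        vloss = float(-np.log(vp[np.arange(len(yva)), yva] + 1e-12).mean())
        history["train_loss"].append(sum(losses) / n)
        history["train_acc"].append(correct / n)
        history["val_loss"].append(vloss)
        history["val_acc"].append(float((vp.argmax(axis=1) == yva).mean()))
        if vloss < best_loss - 1e-6:
            best_loss, best_weights, stall = vloss, model.get_weights(), 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    model.set_weights(best_weights)
    model.history = history
    return history


def predict(model: CNNClassifier, grid: GridImage | np.ndarray) -> Prediction:
    """Classify one grid image; deterministic given model and input."""
    values = grid.values if isinstance(grid, GridImage) else np.asarray(grid)
    if values.shape != (3, 10):
        raise ValueError("grid must be 3x10")
    p = model.predict_proba(values[None])[0]
    return Prediction(p, CLASS_LABELS[int(p.argmax())])


# ----------------------------------------------------------------------
# rule-based oracle
# ----------------------------------------------------------------------

def rule_classify(
    grid: GridImage,
    active_threshold: float = 50.0,
    amplitude_cap: float = 1000.0,
) -> str:
    """Deterministic canal diagnosis from decoded grid amplitudes.

    A cell is *active* when its |decoded amplitude| exceeds the threshold.
    Candidate diagnoses are scored by the total active amplitude of their
    supporting cells and the largest total wins; with no matching pattern
    the result is ``"indeterminate"``.
    """
    amp = decode_grid(grid, amplitude_cap)
    H, V, T = amp[0], amp[1], amp[2]

    def active(x: float) -> bool:
        return abs(x) > active_threshold

    candidates: dict[str, float] = {}

    # posterior canal: torsional + upbeat in a Dix-Hallpike column
    for side in ("right", "left"):
        j = _COL[f"dix_hallpike_{side}"]
        if active(V[j]) and V[j] > 0 and active(T[j]):
            candidates[f"psc_{side}"] = abs(V[j]) + abs(T[j])

    # lateral canal: opposing horizontal beats across the two roll columns
    jr, jl = _COL["roll_right"], _COL["roll_left"]
    hr, hl = H[jr], H[jl]
    if active(hr) and active(hl) and np.sign(hr) != np.sign(hl):
        score = abs(hr) + abs(hl)
        if hr > 0:  # beats toward the lower ear -> geotropic
            side = "right" if abs(hr) >= abs(hl) else "left"
            candidates[f"lsc_geo_{side}"] = score
        else:  # beats toward the upper ear -> ageotropic
            side = "right" if abs(hr) < abs(hl) else "left"
            candidates[f"lsc_ageo_{side}"] = score
    # anterior canal: torsional + downbeat in head-hanging or Dix-Hallpike
    asc_cols = [_COL["head_hanging"], _COL["dix_hallpike_right"], _COL["dix_hallpike_left"]]
    score, tors = 0.0, 0.0
    for j in asc_cols:
        if active(V[j]) and V[j] < 0 and active(T[j]):
            score += abs(V[j]) + abs(T[j])
            tors += T[j]
    if score > 0:
        candidates[f"asc_{'right' if tors >= 0 else 'left'}"] = score

    if not candidates:
        return "indeterminate"
    return max(candidates.items(), key=lambda kv: kv[1])[0]
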